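"""End-to-end orchestration: coverage -> expressed regions -> ORF screen ->
small-RNA screen -> editing, with TSV/BED outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coverage as cov
from . import editing as ed
from . import orfs as orf_mod
from . import smallrna as srna
from .config import PipelineConfig
from .genome_io import (
    FeatureTable,
    Genome,
    LibrarySet,
    load_alignments,
    load_reference,
    write_bed,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("coverage", "regions", "orfs", "smallrna", "editing")


@dataclass
class PipelineResult:
    genome: Genome
    annotation: FeatureTable
    libraries: LibrarySet
    thresholds: dict = field(default_factory=dict)
    mrna_profiles: dict = field(default_factory=dict)  # library_id -> WindowProfile
    mito_track: object = None  # pooled mito-enriched mRNA CoverageTrack
    regions: list = field(default_factory=list)
    rpkm: pd.DataFrame | None = None
    dropoffs: list = field(default_factory=list)
    orfs_all: list = field(default_factory=list)
    orfs_remote: list = field(default_factory=list)
    orfs_selected: list = field(default_factory=list)
    smallrna_candidates: list = field(default_factory=list)
    smallrna_mrna_r: float | None = None
    edit_sites: list = field(default_factory=list)
    edit_sites_unique: list = field(default_factory=list)
    edit_summary: ed.CategorySummary | None = None
    out_dir: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    genome_path: str | Path,
    annotation_path: str | Path,
    libraries_path: str | Path,
    alignment_paths: dict[str, str | Path],
    out_dir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
) -> PipelineResult:
    """Run the requested stages and write all tables under ``out_dir``.

    ``alignment_paths`` maps library_id -> SAM/BAM path; library roles,
    replicates, assays and totals come from the libraries TSV (totals of 0
    are recounted from the alignments).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    stage_name = "load"
    try:
        genome, annotation = load_reference(genome_path, annotation_path)
        libraries = LibrarySet.from_tsv(libraries_path)
        result = PipelineResult(genome=genome, annotation=annotation, libraries=libraries, out_dir=out)

        def reads(lib_id):
            return load_alignments(alignment_paths[lib_id], lib_id, genome)

        mrna_libs = [l for l in libraries if l.assay == "mrna" and l.library_id in alignment_paths]
        srna_libs = [l for l in libraries if l.assay == "smallrna" and l.library_id in alignment_paths]
        for lib in list(mrna_libs) + list(srna_libs):
            if lib.total_mapped_reads <= 0:
                lib.total_mapped_reads = sum(1 for _ in reads(lib.library_id))
        timings[stage_name] = time.time() - t0

        mito_mrna = [l for l in mrna_libs if l.role == "mito_enriched"]
        tc_mrna = [l for l in mrna_libs if l.role == "total_cellular"]

        tracks: dict[str, cov.CoverageTrack] = {}
        if set(stages) & {"coverage", "regions", "orfs", "smallrna"}:
            stage_name = "coverage"
            t = time.time()
            for lib in mrna_libs:
                tracks[lib.library_id] = cov.compute_depth(reads(lib.library_id), genome, lib.library_id)
                profile = cov.window_profile(
                    tracks[lib.library_id], config.mrna_window, config.mrna_step, libraries
                )
                result.mrna_profiles[lib.library_id] = profile
                cov.profile_to_tsv(profile, out / f"windows_{lib.library_id}.tsv")
            if mito_mrna:
                result.mito_track = cov.CoverageTrack.sum_tracks(
                    [tracks[l.library_id] for l in mito_mrna], "mito_pooled"
                )
            mito_profiles = [result.mrna_profiles[l.library_id] for l in mito_mrna]
            if mito_profiles:
                mean_profile = cov.average_profiles(mito_profiles, "mito_mean")
                result.thresholds["tail_threshold"] = cov.tail_threshold(
                    mean_profile, config.tail_fraction
                )
            timings[stage_name] = time.time() - t

        if "regions" in stages and mito_mrna:
            stage_name = "regions"
            t = time.time()
            mito_profiles = [result.mrna_profiles[l.library_id] for l in mito_mrna]
            tc_profiles = [result.mrna_profiles[l.library_id] for l in tc_mrna]
            mean_profile = cov.average_profiles(mito_profiles, "mito_mean")
            mean_track = cov.CoverageTrack.sum_tracks(
                [tracks[l.library_id] for l in mito_mrna], "mito_mean"
            )
            for chrom in mean_track.depth:  # averaged, not pooled, depth
                for s in "+-":
                    mean_track.depth[chrom][s] = mean_track.depth[chrom][s] / len(mito_mrna)
            regions = cov.detect_expressed_regions(
                mean_profile, config.region_depth_floor, annotation,
                exclusion_margin=config.utr_margin, track=mean_track,
            )
            for r in regions:
                if tc_profiles:
                    r.enrichment = cov.classify_enrichment(
                        r, mito_profiles, tc_profiles, fold=config.enrichment_fold
                    )
                r.cross_map = cov.flag_cross_mapping(r, genome, annotation, k=config.crossmap_k)
            result.regions = regions
            cov.regions_to_tsv(regions, out / "expressed_regions.tsv")
            write_bed(
                [(r.chromosome, r.start, r.end, r.enrichment) for r in regions],
                out / "expressed_regions.bed",
            )
            # per-gene RPKM per mRNA library
            rpkm_rows = []
            for lib in mrna_libs:
                recs = list(reads(lib.library_id))
                for gene in annotation.gene_like():
                    rpkm_rows.append(
                        {
                            "feature_id": gene.feature_id,
                            "library_id": lib.library_id,
                            "rpkm": cov.gene_expression_rpkm(gene, recs, libraries, lib.library_id),
                        }
                    )
            result.rpkm = pd.DataFrame(rpkm_rows)
            result.rpkm.to_csv(out / "gene_rpkm.tsv", sep="\t", index=False, float_format="%.4f")
            # 3' drop-off reports on the pooled mito track
            if result.mito_track is not None:
                for gene in annotation.of_type("gene"):
                    segs = annotation.cds_segments(gene.feature_id)
                    if not segs:
                        continue
                    result.dropoffs.append(
                        cov.cds_coverage_dropoff(result.mito_track, segs, gene_id=gene.feature_id)
                    )
                pd.DataFrame([vars(d) for d in result.dropoffs]).to_csv(
                    out / "dropoff_reports.tsv", sep="\t", index=False, float_format="%.4f"
                )
            timings[stage_name] = time.time() - t

        if "orfs" in stages and result.mito_track is not None:
            stage_name = "orfs"
            t = time.time()
            result.orfs_all = orf_mod.find_orfs(genome, min_length=config.orf_min_length)
            result.orfs_remote = orf_mod.filter_remote_orfs(
                result.orfs_all, annotation, min_distance=config.orf_distance
            )
            result.orfs_selected = orf_mod.rank_orfs_by_depth(
                result.orfs_remote, result.mito_track,
                top_fraction=config.orf_top_fraction,
                depth_floor=config.region_depth_floor,
            )
            orf_mod.orfs_to_tsv(result.orfs_remote, out / "orfs_remote.tsv")
            orf_mod.orfs_to_tsv(result.orfs_selected, out / "orfs_selected.tsv")
            orf_mod.orfs_to_protein_fasta(result.orfs_selected, genome, out / "orfs_selected.faa")
            orf_mod.orfs_to_gff3(result.orfs_selected, out / "orfs_selected.gff3")
            timings[stage_name] = time.time() - t

        if "smallrna" in stages and srna_libs:
            stage_name = "smallrna"
            t = time.time()
            all_srna = []
            srna_tracks = []
            for lib in srna_libs:
                recs = list(reads(lib.library_id))
                all_srna.extend(recs)
                srna_tracks.append(cov.compute_depth(recs, genome, lib.library_id, assay="smallrna"))
            filtered = srna.filter_smallrna_reads(
                all_srna, annotation,
                min_length=config.smallrna_min_length,
                max_length=config.smallrna_max_length,
            )
            candidates = srna.stack_candidates(
                filtered, genome, libraries,
                min_depth=config.stack_min_depth,
                max_neighbor_overlap=config.max_neighbor_overlap,
            )
            for c in candidates:
                c.mito_overrepresented = srna.flag_mito_overrepresentation(c, libraries)
            result.smallrna_candidates = candidates
            srna.candidates_to_tsv(candidates, libraries, out / "smallrna_candidates.tsv")
            srna.candidates_to_fasta(candidates, out / "smallrna_candidates.fasta")
            # small RNA vs mRNA coverage correlation on a matched fine grid
            mito_srna = [l for l in srna_libs if l.role == "mito_enriched"]
            if mito_srna and result.mito_track is not None:
                pooled_srna = cov.CoverageTrack.sum_tracks(
                    [t_ for t_, l in zip(srna_tracks, srna_libs) if l.role == "mito_enriched"],
                    "srna_mito_pooled",
                )
                pooled_srna.library_id = mito_srna[0].library_id
                srna_profile = cov.window_profile(
                    pooled_srna, config.smallrna_window, config.smallrna_step, libraries
                )
                mito_track = result.mito_track
                mito_track.library_id = mito_mrna[0].library_id
                mrna_profile = cov.window_profile(
                    mito_track, config.smallrna_window, config.smallrna_step, libraries
                )
                try:
                    result.smallrna_mrna_r = srna.smallrna_mrna_correlation(srna_profile, mrna_profile)
                except srna.UndefinedCorrelationError:
                    result.smallrna_mrna_r = None
            timings[stage_name] = time.time() - t

        if "editing" in stages and mito_mrna:
            stage_name = "editing"
            t = time.time()
            def mito_reads():
                for lib in mito_mrna:
                    yield from reads(lib.library_id)
            pile = ed.build_pileup(mito_reads(), genome, trim_margin=config.end_trim)
            called = ed.call_edit_sites(
                pile, min_depth=config.edit_min_depth, min_freq=config.edit_min_frequency
            )
            classified = []
            for site in called:
                kept = ed.classify_edit_site(
                    site, genome, annotation,
                    utr_margin=config.utr_margin,
                    intron_edge_exclusion=config.intron_edge_exclusion,
                )
                if kept is not None:
                    classified.append(kept)
            classified = ed.end_trim_recheck(
                mito_reads(), genome, classified,
                extra_trim=config.end_trim,
                min_depth=config.edit_min_depth,
                min_freq=config.edit_min_frequency,
            )
            pairs = ed.repeat_pairs_from_features(annotation)
            unique_sites, summary = ed.dedupe_and_summarize(classified, pairs)
            result.edit_sites = classified
            result.edit_sites_unique = unique_sites
            result.edit_summary = summary
            ed.sites_to_tsv(classified, out / "edit_sites.tsv")
            ed.sites_to_vcf(classified, genome, out / "edit_sites.vcf")
            summary.to_tsv(out / "edit_summary.tsv")
            timings[stage_name] = time.time() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    # run manifest: config echo, input checksums, timings
    config.to_file(out / "config_used.cfg")
    manifest = {
        "config": config.asdict(),
        "stages": list(stages),
        "thresholds": result.thresholds,
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [genome_path, annotation_path, libraries_path, *alignment_paths.values()]
        },
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
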