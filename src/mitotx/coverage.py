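"""Strand-specific depth, sliding-window profiles, expressed-region calling,
enrichment classification, RPKM, 3'-drop-off detection and cross-mapping flags.

Window tiling convention: windows start at 1, 1+step, 1+2*step, ...; the
final window is truncated at the chromosome end and its mean uses the
truncated length. Region calling keeps windows whose mean depth is
*strictly* above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    AlignmentRecord,
    Feature,
    FeatureTable,
    GENE_LIKE_TYPES,
    Genome,
    LibrarySet,
    reverse_complement,
)


@dataclass
class CoverageTrack:
    """Per-chromosome, per-strand read depth for one library."""

    library_id: str
    assay: str
    depth: dict[str, dict[str, np.ndarray]]  # chromosome -> strand -> int vector

    def combined(self, chromosome: str) -> np.ndarray:
        d = self.depth[chromosome]
        return d["+"] + d["-"]

    def strand_depth(self, chromosome: str, strand: str) -> np.ndarray:
        return self.depth[chromosome][strand]

    def total_mass(self) -> int:
        return int(sum(v.sum() for d in self.depth.values() for v in d.values()))

    @staticmethod
    def sum_tracks(tracks: Sequence["CoverageTrack"], library_id: str = "pooled") -> "CoverageTrack":
        first = tracks[0]
        depth = {
            chrom: {s: sum(t.depth[chrom][s] for t in tracks) for s in ("+", "-")}
            for chrom in first.depth
        }
        return CoverageTrack(library_id=library_id, assay=first.assay, depth=depth)


def compute_depth(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    library_id: str,
    assay: str = "mrna",
) -> CoverageTrack:
    """Per-base depth: each record adds 1 at every reference position of its block."""
    lengths = genome.lengths
    deltas = {
        chrom: {s: np.zeros(n + 1, dtype=np.int64) for s in ("+", "-")}
        for chrom, n in lengths.items()
    }
    for rec in alignments:
        if rec.start < 1 or rec.end > lengths[rec.chromosome]:
            raise ValueError(
                f"alignment {rec.read_id} out of bounds on {rec.chromosome}"
            )
        d = deltas[rec.chromosome][rec.strand]
        d[rec.start - 1] += 1
        d[rec.end] -= 1
    depth = {
        chrom: {s: np.cumsum(d[s][:-1]) for s in ("+", "-")}
        for chrom, d in deltas.items()
    }
    return CoverageTrack(library_id=library_id, assay=assay, depth=depth)


@dataclass
class WindowProfile:
    """Sliding-window mean depth and CPM over a coverage track."""

    windows: pd.DataFrame  # columns: chromosome, start, end, mean_depth, cpm
    window_size: int
    step: int
    strand_mode: str
    library_id: str

    def same_grid(self, other: "WindowProfile") -> bool:
        a, b = self.windows, other.windows
        return (
            self.window_size == other.window_size
            and self.step == other.step
            and len(a) == len(b)
            and (a["chromosome"].values == b["chromosome"].values).all()
            and (a["start"].values == b["start"].values).all()
        )


def _window_means(depth: np.ndarray, window_size: int, step: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(depth)
    starts = np.arange(0, n, step)  # 0-based
    ends = np.minimum(starts + window_size, n)
    csum = np.concatenate([[0], np.cumsum(depth)])
    sums = csum[ends] - csum[starts]
    means = sums / (ends - starts)
    return starts + 1, ends, means  # back to 1-based inclusive


def window_profile(
    track: CoverageTrack,
    window_size: int,
    step: int,
    totals: LibrarySet,
    strand_mode: str = "combined",
) -> WindowProfile:
    """Tile each chromosome and compute per-window mean depth and CPM.

    CPM normalizes the window mean depth by the library's total mapped
    reads: ``mean_depth * 1e6 / total_mapped_reads``.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    total = totals.total_mapped(track.library_id)
    rows = []
    for chrom in track.depth:
        if strand_mode == "combined":
            depth = track.combined(chrom)
        elif strand_mode in ("forward", "+"):
            depth = track.strand_depth(chrom, "+")
        elif strand_mode in ("reverse", "-"):
            depth = track.strand_depth(chrom, "-")
        else:
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        starts, ends, means = _window_means(depth, window_size, step)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start": starts,
                    "end": ends,
                    "mean_depth": means,
                    "cpm": means * 1e6 / total,
                }
            )
        )
    windows = pd.concat(rows, ignore_index=True)
    return WindowProfile(
        windows=windows,
        window_size=window_size,
        step=step,
        strand_mode=strand_mode,
        library_id=track.library_id,
    )


def average_profiles(profiles: Sequence[WindowProfile], library_id: str = "mean") -> WindowProfile:
    """Average per-library window profiles on an identical grid (mean of
    per-library mean depths and of per-library CPMs)."""
    first = profiles[0]
    for p in profiles[1:]:
        if not first.same_grid(p):
            raise ValueError("profiles are not on the same window grid")
    windows = first.windows.copy()
    windows["mean_depth"] = np.mean([p.windows["mean_depth"].values for p in profiles], axis=0)
    windows["cpm"] = np.mean([p.windows["cpm"].values for p in profiles], axis=0)
    return WindowProfile(
        windows=windows,
        window_size=first.window_size,
        step=first.step,
        strand_mode=first.strand_mode,
        library_id=library_id,
    )


def tail_threshold(profile: WindowProfile, tail_fraction: float = 0.05) -> float:
    """Depth value at the upper ``tail_fraction`` of the window-mean
    distribution (nearest-rank quantile): the smallest window mean such
    that at most ``tail_fraction`` of windows exceed it."""
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    depths = np.sort(profile.windows["mean_depth"].values)
    n = len(depths)
    if n == 0:
        raise ValueError("empty window profile")
    rank = int(np.ceil((1 - tail_fraction) * n))  # nearest-rank, 1-based
    return float(depths[rank - 1])


@dataclass
class ExpressedRegion:
    chromosome: str
    start: int
    end: int
    mean_depth: float
    mean_cpm: float
    n_windows: int
    enrichment: str = "unclassified"
    cross_map: bool = False
    overlaps_annotation: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_expressed_regions(
    profile: WindowProfile,
    threshold: float,
    annotation: FeatureTable,
    exclusion_margin: int = 2000,
    merge_gap: int = 0,
    track: CoverageTrack | None = None,
) -> list[ExpressedRegion]:
    """Merge super-threshold windows (strictly > threshold) into maximal
    regions and flag those within ``exclusion_margin`` of an annotated gene.

    When ``track`` is given, region mean depth/CPM are recomputed exactly
    over the merged footprint; otherwise they are averaged over the
    contributing windows.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = profile.windows[profile.windows["mean_depth"] > threshold]
    regions: list[ExpressedRegion] = []
    for chrom, grp in keep.groupby("chromosome", sort=False):
        cur_start = cur_end = None
        members: list[tuple[float, float]] = []
        def flush():
            if cur_start is None:
                return
            depths = np.array([m[0] for m in members])
            cpms = np.array([m[1] for m in members])
            regions.append(
                ExpressedRegion(
                    chromosome=chrom,
                    start=int(cur_start),
                    end=int(cur_end),
                    mean_depth=float(depths.mean()),
                    mean_cpm=float(cpms.mean()),
                    n_windows=len(members),
                )
            )
        for row in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
                members = [(row.mean_depth, row.cpm)]
            elif row.start <= cur_end + 1 + merge_gap:
                cur_end = max(cur_end, row.end)
                members.append((row.mean_depth, row.cpm))
            else:
                flush()
                cur_start, cur_end = row.start, row.end
                members = [(row.mean_depth, row.cpm)]
        flush()
    if track is not None:
        for r in regions:
            depth = track.combined(r.chromosome)[r.start - 1 : r.end]
            mean_depth = float(depth.mean())
            # keep the CPM on the same per-library scale as the profile
            if r.mean_depth > 0:
                r.mean_cpm = r.mean_cpm * mean_depth / r.mean_depth
            r.mean_depth = mean_depth
    genes = annotation.gene_like()
    for r in regions:
        r.overlaps_annotation = any(
            g.overlaps(r.chromosome, r.start - exclusion_margin, r.end + exclusion_margin)
            for g in genes
        )
    return regions


def region_mean_cpm(region: ExpressedRegion, profile: WindowProfile) -> float:
    """Mean CPM of a profile's windows overlapping the region footprint."""
    w = profile.windows
    hit = w[
        (w["chromosome"] == region.chromosome)
        & (w["start"] <= region.end)
        & (w["end"] >= region.start)
    ]
    if hit.empty:
        raise ValueError(
            f"region {region.chromosome}:{region.start}-{region.end} outside profile coverage"
        )
    return float(hit["cpm"].mean())


def classify_enrichment(
    region: ExpressedRegion,
    mito_profiles: Sequence[WindowProfile],
    tc_profiles: Sequence[WindowProfile],
    fold: float = 2.0,
) -> str:
    """Label a region mito_enriched / tc_enriched / ambiguous.

    mito_enriched requires the region CPM to be higher in every
    mito-vs-total-cellular replicate pairing *and* the pooled mito/TC fold
    to be >= ``fold``; tc_enriched is the mirrored condition.
    """
    if not mito_profiles or not tc_profiles:
        raise ValueError("need at least one profile per condition")
    m = [region_mean_cpm(region, p) for p in mito_profiles]
    t = [region_mean_cpm(region, p) for p in tc_profiles]
    mito_higher = all(mi > ti for mi in m for ti in t)
    tc_higher = all(ti > mi for mi in m for ti in t)
    mean_m, mean_t = float(np.mean(m)), float(np.mean(t))
    if mito_higher and mean_t > 0 and mean_m / mean_t >= fold:
        return "mito_enriched"
    if mito_higher and mean_t == 0 and mean_m > 0:
        return "mito_enriched"
    if tc_higher and mean_m > 0 and mean_t / mean_m >= fold:
        return "tc_enriched"
    if tc_higher and mean_m == 0 and mean_t > 0:
        return "tc_enriched"
    return "ambiguous"


def gene_expression_rpkm(
    feature: Feature,
    alignments: Iterable[AlignmentRecord],
    totals: LibrarySet,
    library_id: str | None = None,
) -> float:
    """Reads per kilobase of feature per million mapped reads, counting
    reads overlapping the feature on its coding strand."""
    if feature.length <= 0:
        raise ValueError("feature must have positive length")
    count = 0
    lib = library_id
    for rec in alignments:
        if lib is None:
            lib = rec.library_id
        if (
            rec.chromosome == feature.chromosome
            and rec.strand == feature.strand
            and rec.start <= feature.end
            and rec.end >= feature.start
        ):
            count += 1
    if lib is None:
        return 0.0
    total = totals.total_mapped(lib)
    return count / ((feature.length / 1e3) * (total / 1e6))


@dataclass
class DropoffReport:
    gene_id: str
    mean_depth_cds_tail: float
    mean_depth_after_stop: float
    ratio_after_stop: float
    has_sharp_3prime_dropoff: bool
    internal_min_ratio: float
    internal_min_position: int  # 1-based position within the CDS (transcript coords)
    has_internal_drop: bool


def _transcript_depth(track: CoverageTrack, segments: Sequence[Feature]) -> np.ndarray:
    """Coding-strand depth over concatenated CDS segments, 5'->3'."""
    strand = segments[0].strand
    parts = []
    ordered = sorted(segments, key=lambda s: s.start, reverse=(strand == "-"))
    for seg in ordered:
        d = track.strand_depth(seg.chromosome, strand)[seg.start - 1 : seg.end]
        parts.append(d[::-1] if strand == "-" else d)
    return np.concatenate(parts).astype(float)


def cds_coverage_dropoff(
    track: CoverageTrack,
    cds: Feature | Sequence[Feature],
    gene_id: str | None = None,
    flank: int = 100,
    ratio_cutoff: float = 0.1,
) -> DropoffReport:
    """Detect a sharp 3' drop-off after the stop codon and internal coverage
    collapses within the CDS.

    ``ratio_after_stop`` compares the mean depth over the ``flank`` nt
    downstream of the stop codon with the final ``flank`` nt of CDS. The
    internal scan takes, at each CDS position p, the ratio of the mean depth
    over the ``flank`` nt after p to the ``flank`` nt before p, and reports
    the minimum. Zero-depth denominators yield non-flagging NaN ratios.
    """
    segments = [cds] if isinstance(cds, Feature) else list(cds)
    strand = segments[0].strand
    chrom = segments[0].chromosome
    d = _transcript_depth(track, segments)
    if len(d) < flank:
        warnings.warn(
            f"CDS shorter than {flank} nt; drop-off computed over available length",
            stacklevel=2,
        )
    tail_len = min(flank, len(d))
    # genomic flank downstream of the stop codon
    last = max(segments, key=lambda s: s.start) if strand == "+" else min(segments, key=lambda s: s.start)
    chrom_depth = track.strand_depth(chrom, strand)
    if strand == "+":
        lo, hi = last.end, min(last.end + flank, len(chrom_depth))
        after = chrom_depth[lo:hi].astype(float)
    else:
        lo, hi = max(last.start - 1 - flank, 0), last.start - 1
        after = chrom_depth[lo:hi][::-1].astype(float)
    mean_tail = float(d[-tail_len:].mean())
    mean_after = float(after.mean()) if len(after) else 0.0
    ratio_after = mean_after / mean_tail if mean_tail > 0 else float("nan")
    # internal scan with cumulative sums
    internal_ratio, internal_pos = float("nan"), 0
    if len(d) >= 2 * flank:
        csum = np.concatenate([[0.0], np.cumsum(d)])
        ps = np.arange(flank, len(d) - flank + 1)
        before = (csum[ps] - csum[ps - flank]) / flank
        after_w = (csum[ps + flank] - csum[ps]) / flank
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(before > 0, after_w / before, np.nan)
        if np.any(~np.isnan(ratios)):
            i = int(np.nanargmin(ratios))
            internal_ratio = float(ratios[i])
            internal_pos = int(ps[i]) + 1
    sharp = (not np.isnan(ratio_after)) and ratio_after < ratio_cutoff
    internal = (not np.isnan(internal_ratio)) and internal_ratio < ratio_cutoff
    gid = gene_id or (segments[0].parent or segments[0].feature_id)
    return DropoffReport(
        gene_id=gid,
        mean_depth_cds_tail=mean_tail,
        mean_depth_after_stop=mean_after,
        ratio_after_stop=ratio_after,
        has_sharp_3prime_dropoff=bool(sharp),
        internal_min_ratio=internal_ratio,
        internal_min_position=internal_pos,
        has_internal_drop=bool(internal),
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def flag_cross_mapping(
    region: ExpressedRegion,
    genome: Genome,
    gene_features: FeatureTable,
    k: int = 50,
) -> bool:
    """True when the region shares an exact k-mer (either strand) with an
    annotated gene located elsewhere in the genome, so its depth may be
    inflated by cross-mapping reads."""
    if k < 20:
        raise ValueError("k must be >= 20")
    region_seq = genome.sequence(region.chromosome, region.start, region.end)
    region_kmers = _kmers(region_seq, k) | _kmers(reverse_complement(region_seq), k)
    if not region_kmers:
        return False
    for gene in gene_features.gene_like():
        if gene.overlaps(region.chromosome, region.start, region.end):
            continue  # the region's own annotation is not cross-mapping
        gseq = genome.sequence(gene.chromosome, gene.start, gene.end)
        if _kmers(gseq, k) & region_kmers:
            return True
    return False


def profile_to_tsv(profile: WindowProfile, path) -> None:
    profile.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def regions_to_tsv(regions: Sequence[ExpressedRegion], path) -> None:
    rows = [
        {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "mean_depth": round(r.mean_depth, 4),
            "mean_cpm": round(r.mean_cpm, 4),
            "n_windows": r.n_windows,
            "enrichment": r.enrichment,
            "cross_map": r.cross_map,
            "overlaps_annotation": r.overlaps_annotation,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "mean_depth", "mean_cpm",
            "n_windows", "enrichment", "cross_map", "overlaps_annotation",
        ],
    ).to_csv(path, sep="\t", index=False)
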