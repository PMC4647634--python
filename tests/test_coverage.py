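"""Depth, window profiling, thresholding, region calling, RPKM, drop-offs
and cross-mapping — each checked against independent brute-force oracles."""

import numpy as np
import pytest

from mitotx.coverage import (
    CoverageTrack,
    ExpressedRegion,
    classify_enrichment,
    cds_coverage_dropoff,
    compute_depth,
    detect_expressed_regions,
    flag_cross_mapping,
    gene_expression_rpkm,
    tail_threshold,
    window_profile,
)
from mitotx.genome_io import Feature, FeatureTable, Genome
from .conftest import make_read, random_reads


def brute_force_depth(reads, genome):
    """Position-by-position recount, the slow way."""
    depth = {
        c: {s: np.zeros(len(genome[c]), dtype=int) for s in "+-"} for c in genome.names
    }
    for r in reads:
        for p in range(r.start, r.end + 1):
            depth[r.chromosome][r.strand][p - 1] += 1
    return depth


class TestComputeDepth:
    def test_no_alignments_gives_zero_track(self, toy_genome):
        track = compute_depth([], toy_genome, "mito1")
        assert all(
            track.depth[c][s].sum() == 0 for c in toy_genome.names for s in "+-"
        )

    def test_single_read_covers_its_span_on_its_strand(self, toy_genome):
        read = make_read("c1", 10, "+", toy_genome["c1"][9:30])  # 21 nt at position 10
        track = compute_depth([read], toy_genome, "mito1")
        fwd = track.depth["c1"]["+"]
        assert fwd[9:30].tolist() == [1] * 21
        assert fwd.sum() == 21
        assert track.depth["c1"]["-"].sum() == 0

    def test_matches_brute_force_recount(self, toy_genome):
        rng = np.random.default_rng(11)
        reads = random_reads(rng, toy_genome, 1000, length=30)
        track = compute_depth(reads, toy_genome, "mito1")
        oracle = brute_force_depth(reads, toy_genome)
        for c in toy_genome.names:
            for s in "+-":
                assert np.array_equal(track.depth[c][s], oracle[c][s])

    def test_depth_mass_equals_total_aligned_bases(self, toy_genome):
        rng = np.random.default_rng(12)
        reads = random_reads(rng, toy_genome, 500, length=42)
        track = compute_depth(reads, toy_genome, "mito1")
        assert track.total_mass() == sum(r.span for r in reads)


class TestWindowProfile:
    def test_constant_depth_gives_constant_window_means(self, toy_genome, four_libraries):
        track = CoverageTrack(
            "mito1", "mrna",
            {c: {"+": np.full(len(toy_genome[c]), 7), "-": np.zeros(len(toy_genome[c]), dtype=int)}
             for c in toy_genome.names},
        )
        prof = window_profile(track, 200, 100, four_libraries)
        assert np.allclose(prof.windows["mean_depth"], 7.0)

    def test_window_tiling_with_truncated_last_window(self, four_libraries):
        genome = Genome({"c1": "A" * 1000})
        track = CoverageTrack("mito1", "mrna", {"c1": {"+": np.ones(1000, dtype=int), "-": np.zeros(1000, dtype=int)}})
        prof = window_profile(track, 500, 250, four_libraries)
        assert prof.windows["start"].tolist() == [1, 251, 501, 751]
        assert prof.windows["end"].tolist() == [500, 750, 1000, 1000]

    def test_window_means_match_brute_force_slices(self, toy_genome, four_libraries):
        rng = np.random.default_rng(13)
        reads = random_reads(rng, toy_genome, 800, length=35)
        track = compute_depth(reads, toy_genome, "mito1")
        prof = window_profile(track, 120, 37, four_libraries)
        for row in prof.windows.itertuples():
            combined = track.combined(row.chromosome)
            expected = combined[row.start - 1 : row.end].mean()
            assert row.mean_depth == pytest.approx(expected)
            assert row.cpm == pytest.approx(expected * 1e6 / 1_000_000)


class TestTailThreshold:
    def _profile_from_depths(self, depths, four_libraries):
        genome = Genome({"c1": "A" * (len(depths) * 10)})
        vec = np.repeat(np.asarray(depths, dtype=int), 10)
        track = CoverageTrack("mito1", "mrna", {"c1": {"+": vec, "-": np.zeros_like(vec)}})
        return window_profile(track, 10, 10, four_libraries)

    def test_degenerate_distribution_returns_its_value(self, four_libraries):
        prof = self._profile_from_depths([3] * 50, four_libraries)
        for frac in (0.01, 0.05, 0.5):
            assert tail_threshold(prof, frac) == 3

    def test_matches_brute_force_nearest_rank(self, four_libraries):
        depths = list(range(1, 1001))
        prof = self._profile_from_depths(depths, four_libraries)
        got = tail_threshold(prof, 0.05)
        # independent nearest-rank: smallest value with <= 5 % of windows above it
        srt = sorted(prof.windows["mean_depth"])
        oracle = srt[int(np.ceil(0.95 * len(srt))) - 1]
        assert got == oracle == 950

    def test_five_percent_tail_above_100(self, four_libraries):
        # 950 windows at or below 100 (max exactly 100), 50 above: the 5 % tail
        depths = [100 - (i % 90) for i in range(950)] + [150 + i for i in range(50)]
        prof = self._profile_from_depths(depths, four_libraries)
        assert tail_threshold(prof, 0.05) == 100


class TestDetectExpressedRegions:
    def _profile(self, depth_vec, four_libraries, window=100, step=50):
        genome = Genome({"c1": "A" * len(depth_vec)})
        track = CoverageTrack("mito1", "mrna", {"c1": {"+": depth_vec, "-": np.zeros_like(depth_vec)}})
        return window_profile(track, window, step, four_libraries)

    def test_all_zero_profile_yields_no_regions(self, four_libraries):
        prof = self._profile(np.zeros(2000, dtype=int), four_libraries)
        assert detect_expressed_regions(prof, 10, FeatureTable([])) == []

    def test_isolated_window_becomes_single_region(self, four_libraries):
        vec = np.zeros(2000, dtype=int)
        vec[1000:1100] = 500  # lights up a small set of overlapping windows
        prof = self._profile(vec, four_libraries)
        regions = detect_expressed_regions(prof, 100, FeatureTable([]))
        assert len(regions) == 1
        assert regions[0].start <= 1001 <= 1100 <= regions[0].end

    def test_annotation_proximity_flag(self, four_libraries):
        vec = np.zeros(5000, dtype=int)
        vec[100:600] = 300
        vec[4000:4500] = 300
        prof = self._profile(vec, four_libraries)
        ann = FeatureTable([Feature("g", "c1", 700, 900, "+", "gene")])
        regions = detect_expressed_regions(prof, 100, ann, exclusion_margin=2000)
        flags = {(r.start <= 600): r.overlaps_annotation for r in regions}
        assert flags[True] is True  # region near the gene
        assert flags[False] is False  # region 3 kb away

    def test_planted_igs_regions_recovered_with_window_accuracy(
        self, default_dataset, pipeline_result
    ):
        window = 500
        unannotated = [r for r in pipeline_result.regions if not r.overlaps_annotation]
        for planted in default_dataset.truth.planted_igs_regions:
            if planted.depth_mito < 200:
                continue
            hits = [
                r for r in unannotated
                if r.chromosome == planted.chromosome
                and abs(r.start - planted.start) <= window
                and abs(r.end - planted.end) <= window
            ]
            assert len(hits) == 1, f"planted region {planted} not recovered"

    def test_no_false_regions_on_background_only_data(self, tmp_path, four_libraries):
        # pure noise at the default rate must not cross the 100x floor
        from mitotx.simulate import SimulationSpec, generate_dataset
        from mitotx.genome_io import load_alignments

        spec = SimulationSpec(seed=5, n_genes=0, igs_depths=(), n_chromosomes=3,
                              n_empty_chromosomes=2, chromosome_length_range=(30_000, 40_000))
        ds = generate_dataset(spec, tmp_path)
        track = compute_depth(
            load_alignments(ds.mrna_paths["mito1"], "mito1", ds.genome), ds.genome, "mito1"
        )
        prof = window_profile(track, 500, 250, ds.libraries)
        regions = detect_expressed_regions(prof, 100.0, ds.features)
        assert len(regions) == 0  # < 1 false region per 100 kb


class TestClassifyEnrichment:
    def _region_and_profiles(self, cpms, four_libraries):
        genome_len = 1000
        region = ExpressedRegion("c1", 101, 300, 50.0, 0.0, 2)
        profiles = []
        for lib, cpm in zip(["mito1", "mito2", "tc1", "tc2"], cpms):
            vec = np.full(genome_len, int(cpm), dtype=int)
            track = CoverageTrack(lib, "mrna", {"c1": {"+": vec, "-": np.zeros_like(vec)}})
            profiles.append(window_profile(track, 100, 100, four_libraries))
        return region, profiles[:2], profiles[2:]

    def test_clear_mito_separation(self, four_libraries):
        region, mito, tc = self._region_and_profiles((40, 44, 2, 3), four_libraries)
        assert classify_enrichment(region, mito, tc) == "mito_enriched"

    def test_identical_cpm_is_ambiguous(self, four_libraries):
        region, mito, tc = self._region_and_profiles((5, 5, 5, 5), four_libraries)
        assert classify_enrichment(region, mito, tc) == "ambiguous"

    def test_antisymmetric_under_condition_swap(self, four_libraries):
        region, mito, tc = self._region_and_profiles((40, 44, 2, 3), four_libraries)
        assert classify_enrichment(region, tc, mito) == "tc_enriched"

    def test_planted_plastid_insert_is_tc_enriched(self, default_dataset, pipeline_result):
        for planted in default_dataset.truth.planted_igs_regions:
            if planted.origin == "mito":
                continue
            hits = [
                r for r in pipeline_result.regions
                if r.chromosome == planted.chromosome
                and r.start <= planted.end and planted.start <= r.end
            ]
            assert hits and all(r.enrichment == "tc_enriched" for r in hits)


class TestRpkm:
    def test_zero_reads_zero_rpkm(self, four_libraries):
        gene = Feature("g", "c1", 1, 500, "+", "gene")
        assert gene_expression_rpkm(gene, [], four_libraries, "mito1") == 0.0

    def test_closed_form(self, four_libraries):
        four_libraries.get("mito1").total_mapped_reads = 4_000_000
        gene = Feature("g", "c1", 1001, 1500, "+", "gene")
        reads = [make_read("c1", 1100, "+", "A" * 50, read_id=f"r{i}") for i in range(2000)]
        assert gene_expression_rpkm(gene, reads, four_libraries, "mito1") == pytest.approx(1000.0)

    def test_matches_brute_force_count(self, toy_genome, four_libraries):
        rng = np.random.default_rng(21)
        reads = random_reads(rng, toy_genome, 2000, length=40)
        gene = Feature("g", "c1", 500, 1200, "-", "gene")
        got = gene_expression_rpkm(gene, reads, four_libraries, "mito1")
        n = sum(
            1 for r in reads
            if r.chromosome == "c1" and r.strand == "-" and r.start <= 1200 and r.end >= 500
        )
        assert got == pytest.approx(n / (0.701 * 1.0))


class TestDropoff:
    def _track(self, vec):
        return CoverageTrack(
            "m", "mrna", {"c1": {"+": np.asarray(vec), "-": np.zeros(len(vec), dtype=int)}}
        )

    def test_sharp_drop_after_stop(self):
        vec = np.zeros(1000, dtype=int)
        vec[99:600] = 1000
        vec[600:700] = 20
        cds = Feature("g_cds", "c1", 100, 600, "+", "CDS", parent="g")
        rep = cds_coverage_dropoff(self._track(vec), cds)
        assert rep.ratio_after_stop == pytest.approx(0.02)
        assert rep.has_sharp_3prime_dropoff

    def test_uniform_coverage_no_flags(self):
        vec = np.full(1000, 50, dtype=int)
        cds = Feature("g_cds", "c1", 100, 600, "+", "CDS", parent="g")
        rep = cds_coverage_dropoff(self._track(vec), cds)
        assert rep.ratio_after_stop == pytest.approx(1.0)
        assert not rep.has_sharp_3prime_dropoff and not rep.has_internal_drop

    def test_planted_mid_cds_collapse_detected_near_breakpoint(
        self, default_dataset, pipeline_result
    ):
        truth = {d.gene_id: d for d in default_dataset.truth.planted_dropoffs}
        reports = {r.gene_id: r for r in pipeline_result.dropoffs}
        for gid, planted in truth.items():
            rep = reports[gid]
            if planted.kind == "internal":
                assert rep.has_internal_drop
                assert abs(rep.internal_min_position - planted.breakpoint) <= 100
            else:
                assert rep.has_sharp_3prime_dropoff and not rep.has_internal_drop


class TestCrossMapping:
    def test_no_shared_kmer_is_false(self, toy_genome):
        ann = FeatureTable([Feature("g", "c2", 100, 400, "+", "gene")])
        region = ExpressedRegion("c1", 100, 400, 10.0, 1.0, 3)
        # random 3-kb and 1.5-kb sequences share no 50-mer
        assert flag_cross_mapping(region, toy_genome, ann, k=50) is False

    def test_verbatim_gene_fragment_is_flagged(self):
        rng = np.random.default_rng(31)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        c1 = rng.choice(bases, size=2000).tobytes().decode()
        c2 = list(rng.choice(bases, size=2000).tobytes().decode())
        # copy the 390-nt 3' end of the gene into the region
        c2[500:890] = c1[610:1000]
        genome = Genome({"c1": c1, "c2": "".join(c2)})
        ann = FeatureTable([Feature("g", "c1", 1, 1000, "+", "gene")])
        region = ExpressedRegion("c2", 401, 1000, 500.0, 10.0, 4)
        assert flag_cross_mapping(region, genome, ann, k=50) is True

    def test_agrees_with_brute_force_kmer_intersection(self, toy_genome):
        from mitotx.genome_io import reverse_complement

        ann = FeatureTable([Feature("g", "c2", 50, 700, "+", "gene")])
        rng = np.random.default_rng(32)
        for _ in range(10):
            start = int(rng.integers(1, 2500))
            region = ExpressedRegion("c1", start, start + 400, 10.0, 1.0, 2)
            rseq = toy_genome.sequence("c1", region.start, region.end)
            gseq = toy_genome.sequence("c2", 50, 700)
            k = 50
            fwd = {rseq[i : i + k] for i in range(len(rseq) - k + 1)}
            rev = {reverse_complement(rseq)[i : i + k] for i in range(len(rseq) - k + 1)}
            gk = {gseq[i : i + k] for i in range(len(gseq) - k + 1)}
            expected = bool(gk & (fwd | rev))
            assert flag_cross_mapping(region, toy_genome, ann, k=k) == expected
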