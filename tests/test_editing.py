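"""Pileup construction, edit-site calling, canonical typing, category
assignment, end-trim artifact flagging and repeat deduplication."""

import numpy as np
import pytest

from mitotx.editing import (
    CategorySummary,
    EditSite,
    RepeatPair,
    build_pileup,
    call_edit_sites,
    classify_edit_site,
    dedupe_and_summarize,
    end_trim_recheck,
    repeat_pairs_from_features,
)
from mitotx.genome_io import AlignmentRecord, Feature, FeatureTable, Genome, reverse_complement
from .conftest import make_read, random_reads

# the standard genetic code, written out independently of the implementation
_CODON_TABLE = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for i, b1 in enumerate("TCAG"):
    for j, b2 in enumerate("TCAG"):
        for k, b3 in enumerate("TCAG"):
            _CODON_TABLE[b1 + b2 + b3] = _AAS[16 * i + 4 * j + k]


def reads_with_variant(genome, chrom, pos, alt, n_total, n_variant, strand="+",
                       read_len=40, lib="mito1"):
    """n_total reads covering pos mid-read, n_variant of them carrying alt."""
    reads = []
    start = pos - read_len // 2
    for i in range(n_total):
        bases = bytearray(genome[chrom][start - 1 : start - 1 + read_len].encode())
        nm = 0
        if i < n_variant:
            bases[pos - start] = ord(alt)
            nm = 1
        reads.append(AlignmentRecord(f"v{i}", lib, chrom, start, strand, bases.decode(), nm))
    return reads


class TestBuildPileup:
    def test_single_matching_read(self, toy_genome):
        read = make_read("c1", 100, "+", toy_genome["c1"][99:120])
        pile = build_pileup([read], toy_genome, trim_margin=5)
        col = pile.column("c1", 110, "+")
        assert col.depth == 1 and col.counts[toy_genome["c1"][109]] == 1

    def test_two_reads_disagreeing_at_one_position(self, toy_genome):
        ref = toy_genome["c1"][99:120]
        alt = "G" if ref[10] != "G" else "T"
        r1 = make_read("c1", 100, "+", ref)
        r2 = make_read("c1", 100, "+", ref[:10] + alt + ref[11:], nm=1)
        pile = build_pileup([r1, r2], toy_genome)
        col = pile.column("c1", 110, "+")
        assert col.depth == 2
        assert col.counts[ref[10]] == 1 and col.counts[alt] == 1

    def test_matches_brute_force_recount(self, toy_genome):
        rng = np.random.default_rng(61)
        reads = random_reads(rng, toy_genome, 400, length=30, mutate=0.5)
        pile = build_pileup(reads, toy_genome, trim_margin=5)
        counts = {}
        end_counts = {}
        for r in reads:
            for off, base in enumerate(r.bases):
                pos = r.start + off
                key = (r.chromosome, r.strand, pos, base)
                counts[key] = counts.get(key, 0) + 1
                at_end = (r.span - off <= 5) if r.strand == "+" else (off < 5)
                if at_end:
                    end_counts[key] = end_counts.get(key, 0) + 1
        for (chrom, strand, pos, base), n in counts.items():
            col = pile.column(chrom, pos, strand)
            assert col.counts[base] == n
            assert col.end_counts[base] == end_counts.get((chrom, strand, pos, base), 0)


class TestCallEditSites:
    def test_depth_boundary_100(self, toy_genome):
        pos = 500
        ref = toy_genome["c1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        shallow = reads_with_variant(toy_genome, "c1", pos, alt, 99, 50)
        pile = build_pileup(shallow, toy_genome)
        assert call_edit_sites(pile, min_depth=100, min_freq=0.2) == []
        deep = reads_with_variant(toy_genome, "c1", pos, alt, 100, 50)
        sites = call_edit_sites(build_pileup(deep, toy_genome), min_depth=100, min_freq=0.2)
        assert len(sites) == 1 and sites[0].position == pos and sites[0].alt == alt

    def test_frequency_boundary_20_percent(self, toy_genome):
        pos = 700
        ref = toy_genome["c1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        low = reads_with_variant(toy_genome, "c1", pos, alt, 1000, 190)
        assert call_edit_sites(build_pileup(low, toy_genome)) == []
        exact = reads_with_variant(toy_genome, "c1", pos, alt, 1000, 200)
        sites = call_edit_sites(build_pileup(exact, toy_genome))
        assert len(sites) == 1 and sites[0].frequency == pytest.approx(0.2)

    def test_planted_sites_recovered_with_binomial_accuracy(
        self, default_dataset, pipeline_result
    ):
        called = {
            (s.chromosome, s.position): s
            for s in pipeline_result.edit_sites
            if not s.artifact
        }
        for planted in default_dataset.truth.planted_edit_sites:
            if planted.is_artifact or planted.category == "excluded":
                continue
            key = (planted.chromosome, planted.position)
            if planted.frequency >= 0.3:
                assert key in called, f"planted site {key} missed"
                s = called[key]
                tol = 4 * np.sqrt(planted.frequency * (1 - planted.frequency) / s.depth)
                assert abs(s.frequency - planted.frequency) <= tol
                assert s.strand == planted.strand
                assert (s.edit_type == "canonical_CtoU") == planted.canonical
            elif planted.frequency <= 0.15:
                assert key not in called

    def test_no_unplanted_sites_called(self, default_dataset, pipeline_result):
        planted = {
            (p.chromosome, p.position) for p in default_dataset.truth.planted_edit_sites
        }
        for s in pipeline_result.edit_sites:
            assert (s.chromosome, s.position) in planted


class TestClassification:
    def _genome_with_cds(self, cds_seq, strand="+", pad=3000):
        rng = np.random.default_rng(62)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        left = rng.choice(bases, size=pad).tobytes().decode()
        right = rng.choice(bases, size=pad).tobytes().decode()
        locus = cds_seq if strand == "+" else reverse_complement(cds_seq)
        genome = Genome({"c1": left + locus + right})
        start, end = pad + 1, pad + len(cds_seq)
        ann = FeatureTable(
            [
                Feature("g", "c1", start, end, strand, "gene"),
                Feature("g_cds", "c1", start, end, strand, "CDS", parent="g"),
                Feature("g_exon", "c1", start, end, strand, "exon", parent="g"),
            ]
        )
        return genome, ann, start, end

    def test_forward_strand_nonsynonymous_pro_to_ser(self):
        # CCA (Pro) -> TCA (Ser) via C->T at codon position 1
        genome, ann, start, _ = self._genome_with_cds("ATG" + "CCA" + "TAA")
        site = EditSite("c1", start + 3, "+", "C", "T", 500, 0.5)
        out = classify_edit_site(site, genome, ann)
        assert out.edit_type == "canonical_CtoU"
        assert out.category == "coding_nonsynonymous"

    def test_reverse_strand_synonymous_tyr_to_tyr(self):
        # transcript TAC -> TAT (Tyr) via genomic G->A on a - strand CDS
        genome, ann, start, end = self._genome_with_cds("ATG" + "TAC" + "TAA", strand="-")
        # transcript offset 5 (third base of TAC codon) -> genomic position end-5
        site = EditSite("c1", end - 5, "-", "G", "A", 500, 0.5)
        out = classify_edit_site(site, genome, ann)
        assert out.edit_type == "canonical_CtoU"
        assert out.category == "coding_synonymous"

    def test_stop_gain_counts_as_nonsynonymous(self):
        # CAA (Gln) -> TAA (stop)
        genome, ann, start, _ = self._genome_with_cds("ATG" + "CAA" + "GGG" + "TAA")
        site = EditSite("c1", start + 3, "+", "C", "T", 500, 0.5)
        assert classify_edit_site(site, genome, ann).category == "coding_nonsynonymous"

    def test_synonymy_agrees_with_independent_codon_table(self):
        # exhaustive over all codons x positions x alternative bases
        for codon in _CODON_TABLE:
            if _CODON_TABLE[codon] == "*":
                continue
            genome, ann, start, _ = self._genome_with_cds("ATG" + codon + "TAA")
            for off in range(3):
                ref = codon[off]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    edited = codon[:off] + alt + codon[off + 1 :]
                    site = EditSite("c1", start + 3 + off, "+", ref, alt, 500, 0.5)
                    out = classify_edit_site(site, genome, ann)
                    expected = (
                        "coding_synonymous"
                        if _CODON_TABLE[edited] == _CODON_TABLE[codon]
                        else "coding_nonsynonymous"
                    )
                    assert out.category == expected, (codon, off, alt)

    def test_intron_edge_exclusion_boundaries(self):
        rng = np.random.default_rng(63)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq = rng.choice(bases, size=10_000).tobytes().decode()
        genome = Genome({"c1": seq})
        ann = FeatureTable(
            [
                Feature("g", "c1", 1000, 2299, "+", "gene"),
                Feature("e1", "c1", 1000, 1599, "+", "exon", parent="g"),
                Feature("cds1", "c1", 1000, 1599, "+", "CDS", parent="g"),
                Feature("e2", "c1", 2000, 2299, "+", "exon", parent="g"),
                Feature("cds2", "c1", 2000, 2299, "+", "CDS", parent="g"),
            ]
        )
        def classify_at(pos):
            site = EditSite("c1", pos, "+", genome["c1"][pos - 1], "T", 500, 0.5)
            return classify_edit_site(site, genome, ann)

        assert classify_at(1600 + 18) is None      # 19 nt into the intron: excluded
        assert classify_at(1600 + 20) is not None  # 21 nt in: retained
        assert classify_at(1600 + 20).category == "intron"

    def test_utr_versus_igs_two_kb_cutoff(self):
        genome, ann, start, end = self._genome_with_cds("ATG" + "GGG" * 20 + "TAA", pad=5000)
        near = EditSite("c1", start - 1500, "+", "C", "T", 500, 0.5)
        far = EditSite("c1", start - 2500, "+", "C", "T", 500, 0.5)
        assert classify_edit_site(near, genome, ann).category == "UTR"
        assert classify_edit_site(far, genome, ann).category == "IGS"

    def test_strand_consistency_under_reverse_complement(self, toy_genome):
        # calling on the reverse-complemented genome with flipped reads gives
        # the mirrored site with the same canonical type
        chrom = "c1"
        L = len(toy_genome[chrom])
        pos = 1000
        genome = toy_genome
        # ensure a C reference so the edit is canonical on +
        seq = list(genome[chrom]); seq[pos - 1] = "C"
        genome = Genome({chrom: "".join(seq)})
        reads = reads_with_variant(genome, chrom, pos, "T", 200, 100, strand="+")
        sites = call_edit_sites(build_pileup(reads, genome))
        rc = Genome({chrom: reverse_complement(genome[chrom])})
        flipped = [
            AlignmentRecord(r.read_id, r.library_id, chrom, L - r.end + 1, "-",
                            reverse_complement(r.bases), r.mismatch_count)
            for r in reads
        ]
        rc_sites = call_edit_sites(build_pileup(flipped, rc))
        assert len(sites) == len(rc_sites) == 1
        assert rc_sites[0].position == L - pos + 1
        assert rc_sites[0].strand == "-"
        assert rc_sites[0].edit_type == sites[0].edit_type == "canonical_CtoU"


class TestEndTrimRecheck:
    def test_end_only_support_is_flagged(self, toy_genome):
        pos = 800
        ref = toy_genome["c1"][pos - 1]
        alt = "A" if ref != "A" else "G"
        reads = []
        for i in range(200):  # every read ends exactly at the site
            start = pos - 39
            bases = bytearray(toy_genome["c1"][start - 1 : start + 39].encode())
            if i < 120:
                bases[-1] = ord(alt)
            reads.append(AlignmentRecord(f"e{i}", "m", "c1", start, "+", bases.decode(), 1))
        sites = call_edit_sites(build_pileup(reads, toy_genome))
        assert len(sites) == 1
        out = end_trim_recheck(reads, toy_genome, sites, extra_trim=5)
        assert out[0].artifact is True

    def test_mid_read_support_is_retained(self, toy_genome):
        pos = 800
        ref = toy_genome["c1"][pos - 1]
        alt = "A" if ref != "A" else "G"
        reads = reads_with_variant(toy_genome, "c1", pos, alt, 300, 150)
        sites = call_edit_sites(build_pileup(reads, toy_genome))
        out = end_trim_recheck(reads, toy_genome, sites, extra_trim=5)
        assert out[0].artifact is False

    def test_planted_artifacts_flagged_canonical_sites_unaffected(
        self, default_dataset, pipeline_result
    ):
        truth = {
            (p.chromosome, p.position): p
            for p in default_dataset.truth.planted_edit_sites
            if p.category != "excluded"
        }
        seen_artifacts = 0
        for s in pipeline_result.edit_sites:
            planted = truth[(s.chromosome, s.position)]
            assert s.artifact == planted.is_artifact
            seen_artifacts += s.artifact
        assert seen_artifacts == sum(p.is_artifact for p in truth.values())


class TestDedupeAndSummary:
    def _site(self, chrom, pos, freq=0.5, category="IGS", ref="C", alt="T"):
        return EditSite(chrom, pos, "+", ref, alt, 500, freq,
                        edit_type="canonical_CtoU", category=category)

    def test_homologous_repeat_sites_collapse(self):
        pair = RepeatPair("c1", 1000, 1999, "c2", 5000, 5999)
        sites = [self._site("c1", 1200), self._site("c2", 5200)]
        unique, summary = dedupe_and_summarize(sites, [pair])
        assert len(unique) == 1
        assert sites[0].duplicate_group == sites[1].duplicate_group is not None
        assert summary.table.loc["IGS", "sites_all"] == 2
        assert summary.table.loc["IGS", "sites_unique"] == 1

    def test_unequal_repeat_intervals_fatal(self):
        with pytest.raises(ValueError, match="unequal length"):
            RepeatPair("c1", 1, 100, "c2", 1, 150)

    def test_summary_matches_brute_force_aggregation(self):
        rng = np.random.default_rng(64)
        cats = ["coding_synonymous", "coding_nonsynonymous", "pseudogene", "intron", "UTR", "IGS"]
        pair = RepeatPair("c1", 1000, 1999, "c2", 5000, 5999)
        sites = []
        for i in range(60):
            chrom = ["c1", "c2", "c3"][int(rng.integers(3))]
            pos = int(rng.integers(1, 8000))
            sites.append(self._site(chrom, pos, freq=float(rng.random()),
                                    category=cats[int(rng.integers(len(cats)))]))
        unique, summary = dedupe_and_summarize(sites, [pair])
        # brute force: canonical key via explicit position mapping
        keys = {}
        for s in sites:
            if s.chromosome == "c2" and 5000 <= s.position <= 5999:
                key = ("c1", s.position - 4000, s.ref, s.alt)
            else:
                key = (s.chromosome, s.position, s.ref, s.alt)
            keys.setdefault(key, []).append(s)
        assert summary.total_unique == len(keys)
        for cat in cats:
            assert summary.table.loc[cat, "sites_all"] == sum(
                1 for s in sites if s.category == cat
            )

    def test_repeat_pairs_extracted_from_annotation(self, default_dataset):
        pairs = repeat_pairs_from_features(default_dataset.features)
        truth = default_dataset.truth.repeat_pairs[0]
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.chrom_a, p.start_a, p.end_a) == (truth.chrom_a, truth.start_a, truth.end_a)

    def test_planted_duplicate_pair_collapses(self, default_dataset, pipeline_result):
        dup_truth = [
            p for p in default_dataset.truth.planted_edit_sites if p.duplicate_group
        ]
        called_dups = [s for s in pipeline_result.edit_sites if s.duplicate_group]
        assert len(called_dups) == len(dup_truth) == 2
        unique_positions = {
            (s.chromosome, s.position)
            for s in pipeline_result.edit_sites_unique
            if s.duplicate_group
        }
        assert len(unique_positions) == 1

    def test_category_counts_match_truth(self, default_dataset, pipeline_result):
        expected = {}
        for p in default_dataset.truth.planted_edit_sites:
            if p.is_artifact or p.category == "excluded" or p.frequency < 0.2:
                continue
            expected[p.category] = expected.get(p.category, 0) + 1
        table = pipeline_result.edit_summary.table
        for cat, n in expected.items():
            assert table.loc[cat, "sites_all"] == n
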