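"""Synthetic multichromosomal mitochondrial transcriptome datasets with
machine-readable planted truth.

The generator emulates, at desk scale, the structures seen in large
multichromosomal plant mitochondrial genomes: a handful of expressed
protein-coding genes (one intron-containing, one with a mid-CDS coverage
collapse), tRNA/rRNA genes, an expressed pseudogene, highly transcribed
intergenic regions (some on otherwise 'empty' chromosomes, one hosting a
novel ORF, one carrying a duplicated gene fragment that triggers
cross-mapping flags), plastid/nuclear insertions expressed mainly in
total-cellular libraries, an identical large repeat whose reads map
arbitrarily to either copy, planted C-to-U editing sites at chosen
frequencies, read-end mismatch artifact sites, and a small-RNA assay with
discrete read stacks versus degradation smears.

Reads are emitted pre-mapped as SAM: mapping is upstream of this package,
and emitting alignments directly makes the planted truth exact. All
randomness flows from a single seeded generator, so outputs are
byte-identical for a given spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    AlignmentRecord,
    Feature,
    FeatureTable,
    Genome,
    Library,
    LibrarySet,
    reverse_complement,
    write_sam,
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationSpec:
    """Scale and noise parameters of the toy dataset.

    The defaults are a desk-scale stand-in for a 7-Mb, 63-chromosome
    genome: 8 chromosomes of 20-60 kb, 10 protein-coding genes, 2 'empty'
    chromosomes carrying no annotation.
    """

    n_chromosomes: int = 8
    chromosome_length_range: tuple[int, int] = (20_000, 60_000)
    n_genes: int = 10
    n_empty_chromosomes: int = 2
    mrna_read_length: int = 100
    smallrna_length_range: tuple[int, int] = (17, 25)
    gene_depth: float = 500.0  # mito-enriched mean depth over gene transcripts
    igs_depths: tuple[float, ...] = (400.0, 800.0, 400.0, 450.0, 350.0)
    pseudogene_depth: float = 300.0
    insert_depth_mito: float = 150.0
    insert_depth_tc: float = 1200.0
    tc_mito_factor: float = 0.1  # total-cellular depth of mito-origin transcripts
    background_depth: float = 10.0  # combined-strand spurious transcription, mRNA assay
    smallrna_background_depth: float = 0.04
    smear_reads: int = 400  # per region per mito small-RNA library
    utr_margin_5p: int = 200
    utr_margin_3p: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.mrna_read_length < 50:
            raise ValueError("mRNA read length must be >= 50 nt")
        if self.n_empty_chromosomes >= self.n_chromosomes:
            raise ValueError("need at least one non-empty chromosome")
        lo, hi = self.smallrna_length_range
        if lo < 17 or hi > 25 or lo > hi:
            raise ValueError("small-RNA lengths must lie within 17-25 nt")
        for name in ("n_chromosomes", "n_genes", "n_empty_chromosomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {json.dumps(list(v) if isinstance(v, tuple) else v)}\n")


@dataclass
class PlantedGene:
    feature_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    depth_mito: float
    depth_tc: float


@dataclass
class PlantedRegion:
    chromosome: str
    start: int
    end: int
    depth_mito: float
    depth_tc: float
    origin: str  # mito | plastid | nuclear


@dataclass
class PlantedEditSite:
    chromosome: str
    position: int
    strand: str
    ref: str
    alt: str
    frequency: float
    canonical: bool
    is_artifact: bool = False
    category: str | None = None  # expected annotation category; "excluded" for intron-edge
    duplicate_group: str | None = None


@dataclass
class PlantedStack:
    chromosome: str
    start: int
    length: int
    strand: str
    counts: dict[str, int]
    planted_neighbors: int = 0


@dataclass
class PlantedSmear:
    chromosome: str
    start: int
    end: int
    total_reads: int


@dataclass
class PlantedRepeat:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int


@dataclass
class PlantedDropoff:
    gene_id: str
    kind: str  # sharp_3prime | internal
    breakpoint: int  # transcript offset within the CDS (internal drops), else 0


@dataclass
class TruthTable:
    """Everything the generator planted, for recovery scoring."""

    seed: int
    planted_genes: list[PlantedGene] = field(default_factory=list)
    planted_igs_regions: list[PlantedRegion] = field(default_factory=list)
    planted_edit_sites: list[PlantedEditSite] = field(default_factory=list)
    planted_smallrna_stacks: list[PlantedStack] = field(default_factory=list)
    planted_smears: list[PlantedSmear] = field(default_factory=list)
    repeat_pairs: list[PlantedRepeat] = field(default_factory=list)
    planted_dropoffs: list[PlantedDropoff] = field(default_factory=list)

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        def dump(name, items):
            pd.DataFrame([asdict(x) for x in items]).to_csv(
                out / f"{name}.tsv", sep="\t", index=False
            )
        dump("genes", self.planted_genes)
        dump("igs_regions", self.planted_igs_regions)
        edits = []
        for e in self.planted_edit_sites:
            d = asdict(e)
            edits.append(d)
        pd.DataFrame(edits).to_csv(out / "edit_sites.tsv", sep="\t", index=False)
        stacks = []
        for s in self.planted_smallrna_stacks:
            d = asdict(s)
            d["counts"] = json.dumps(s.counts, sort_keys=True)
            stacks.append(d)
        pd.DataFrame(stacks).to_csv(out / "stacks.tsv", sep="\t", index=False)
        dump("smears", self.planted_smears)
        dump("repeats", self.repeat_pairs)
        dump("dropoffs", self.planted_dropoffs)
        with open(out / "meta.tsv", "w") as fh:
            fh.write(f"seed\t{self.seed}\n")


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes())


_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SAFE_CODONS = [
    c
    for c in _ALL_CODONS
    if c not in _STOPS
    and c not in ("ATG", "CAT")
    and c[2] in "CG"
    and not c.startswith(("TG", "AT"))
]


def _make_cds(rng: np.random.Generator, n_codons: int, forced: dict[int, str] | None = None) -> str:
    """ATG + (n_codons-2) random non-stop codons + TAA; ``forced`` overrides
    internal codons by index (1 = first codon after ATG)."""
    non_stop = [c for c in _ALL_CODONS if c not in _STOPS]
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        codons.append(non_stop[int(rng.integers(len(non_stop)))])
    codons.append("TAA")
    for idx, codon in (forced or {}).items():
        if codon in _STOPS or not 1 <= idx <= n_codons - 2:
            raise ValueError("forced codon invalid")
        codons[idx] = codon
    return "".join(codons)


def _make_clean_orf_region(rng: np.random.Generator, orf_codons: int, flank: int) -> tuple[str, int]:
    """A region containing exactly one ORF (ATG...TAA, no other ATG on either
    strand anywhere in the region). Returns (sequence, 0-based ORF start)."""
    body = ["ATG"] + [
        _SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))] for _ in range(orf_codons - 2)
    ] + ["TAA"]
    orf = "".join(body)
    seq = list(
        _random_seq(rng, flank).decode() + orf + _random_seq(rng, flank).decode()
    )
    orf_start = flank
    # scrub stray ATG (sense starts) and CAT (antisense starts) outside the planted start
    for _ in range(200):
        text = "".join(seq)
        dirty = False
        for pat in ("ATG", "CAT"):
            i = text.find(pat)
            while i != -1:
                if not (pat == "ATG" and i == orf_start):
                    # mutate a base outside the ORF span when possible
                    for j in (i, i + 1, i + 2):
                        if not (orf_start <= j < orf_start + len(orf)):
                            seq[j] = "C" if seq[j] != "C" else "G"
                            break
                    dirty = True
                i = text.find(pat, i + 1)
        if not dirty:
            break
    else:  # pragma: no cover - pattern scrub failed to converge
        raise RuntimeError("could not construct a single-ORF region")
    return "".join(seq), orf_start


class _Allocator:
    """Sequential interval placement with spacing, per chromosome."""

    def __init__(self, lengths: dict[str, int], rng: np.random.Generator, margin: int = 2000):
        self.lengths = lengths
        self.rng = rng
        self.margin = margin
        self.cursor = {c: margin + 1 for c in lengths}

    def place(self, chrom: str, length: int, gap: int = 3000) -> int:
        start = self.cursor[chrom]
        jitter = int(self.rng.integers(0, 1000))
        if start + length + self.margin > self.lengths[chrom]:
            raise ValueError(f"chromosome {chrom} too short for placement")
        self.cursor[chrom] = start + length + gap + jitter
        return start


# ---------------------------------------------------------------------------
# read bookkeeping


class _Read:
    __slots__ = ("library", "chromosome", "start", "strand", "length", "muts")

    def __init__(self, library, chromosome, start, strand, length, muts=None):
        self.library = library
        self.chromosome = chromosome
        self.start = start
        self.strand = strand
        self.length = length
        self.muts = muts  # dict position -> base, or None

    @property
    def end(self):
        return self.start + self.length - 1

    def set_mut(self, pos: int, base: str) -> None:
        if self.muts is None:
            self.muts = {}
        self.muts[pos] = base


def _span_reads(rng, library, chrom, lo, hi, strand, depth, read_len, out):
    """Reads with uniform starts covering [lo, hi] at the given mean depth."""
    if hi - lo + 1 < read_len:
        return
    n = int(round(depth * (hi - lo + 1) / read_len))
    starts = rng.integers(lo, hi - read_len + 2, size=n)
    for s in np.sort(starts):
        out.append(_Read(library, chrom, int(s), strand, read_len))


# ---------------------------------------------------------------------------
# generator


MRNA_LIBS = ("mito1", "mito2", "tc1", "tc2")
SRNA_LIBS = ("smito1", "smito2", "stc1", "stc2")


@dataclass
class SyntheticDataset:
    genome: Genome
    features: FeatureTable
    libraries: LibrarySet
    mrna_paths: dict[str, Path]
    smallrna_paths: dict[str, Path]
    truth: TruthTable
    out_dir: Path

    @property
    def genome_path(self) -> Path:
        return self.out_dir / "genome.fasta"

    @property
    def annotation_path(self) -> Path:
        return self.out_dir / "annotation.gff3"


def generate_dataset(spec: SimulationSpec, out_dir) -> SyntheticDataset:
    """Generate the toy genome, annotation, four mRNA and four small-RNA
    alignment libraries, and the truth table; write everything to ``out_dir``.
    Deterministic: the same spec and seed give byte-identical outputs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    R = spec.mrna_read_length
    truth = TruthTable(seed=spec.seed)

    if spec.n_genes == 0 and not spec.igs_depths:
        return _generate_background_only(spec, rng, out, truth)
    if spec.n_chromosomes < 8:
        raise ValueError("the planted feature design needs at least 8 chromosomes")

    # --- genome scaffold ---------------------------------------------------
    n_feat_chroms = spec.n_chromosomes - spec.n_empty_chromosomes
    lo, hi = spec.chromosome_length_range
    lengths: dict[str, int] = {}
    for i in range(spec.n_chromosomes):
        name = f"chr{i + 1}"
        if i < n_feat_chroms:
            lengths[name] = int(rng.integers(max(lo, 45_000), hi + 1))
        else:
            lengths[name] = int(rng.integers(lo, min(hi, 35_000) + 1))
    seqs = {c: _random_seq(rng, n) for c, n in lengths.items()}
    alloc = _Allocator(lengths, rng)
    features: list[Feature] = []
    reads: list[_Read] = []

    def write_seq(chrom: str, start: int, s: str) -> None:
        seqs[chrom][start - 1 : start - 1 + len(s)] = s.encode()

    def set_base(chrom: str, pos: int, base: str) -> None:
        seqs[chrom][pos - 1] = ord(base)

    gene_chroms = ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2", "chr3", "chr3", "chr4", "chr4"]
    gene_strands = ["+", "+", "-", "+", "-", "+", "+", "-", "-", "+"]
    genes: list[dict] = []

    # gene1 carries an intron; gene7 carries a mid-CDS coverage collapse;
    # gene10 sits inside a duplicated repeat.
    forced_codons = {
        2: {10: "CCA", 20: "TAC"},  # gene2: nonsynonymous + synonymous edit targets
        3: {12: "CCA"},
        5: {15: "CCA"},
        10: {8: "CCA"},
    }
    for gi in range(min(spec.n_genes, 10)):
        gid = f"gene{gi + 1}"
        chrom, strand = gene_chroms[gi], gene_strands[gi]
        n_codons = int(rng.integers(320, 480))
        cds = _make_cds(rng, n_codons, forced_codons.get(gi + 1))
        if gi == 0:  # two exons with a 300-nt intron between codons 150 and 151
            intron = _random_seq(rng, 300).decode()
            exon1_len = 450
            genomic = cds[:exon1_len] + intron + cds[exon1_len:]
        else:
            intron = None
            genomic = cds if strand == "+" else None
        locus = genomic if strand == "+" else None
        if strand == "-":
            locus = reverse_complement(cds if intron is None else cds)  # introns only in gene1 (+)
        span = len(genomic) if strand == "+" else len(locus)
        start = alloc.place(chrom, span, gap=4500)
        end = start + span - 1
        if strand == "+":
            write_seq(chrom, start, genomic)
        else:
            write_seq(chrom, start, locus)
        features.append(Feature(gid, chrom, start, end, strand, "gene"))
        if gi == 0:
            e1s, e1e = start, start + exon1_len - 1
            i_s, i_e = e1e + 1, e1e + 300
            e2s, e2e = i_e + 1, end
            features += [
                Feature(f"{gid}_cds1", chrom, e1s, e1e, strand, "CDS", parent=gid),
                Feature(f"{gid}_exon1", chrom, e1s, e1e, strand, "exon", parent=gid),
                Feature(f"{gid}_intron1", chrom, i_s, i_e, strand, "intron", parent=gid),
                Feature(f"{gid}_cds2", chrom, e2s, e2e, strand, "CDS", parent=gid),
                Feature(f"{gid}_exon2", chrom, e2s, e2e, strand, "exon", parent=gid),
            ]
            genes.append(dict(id=gid, chrom=chrom, start=start, end=end, strand=strand,
                              intron=(i_s, i_e), cds_len=len(cds)))
        else:
            features.append(Feature(f"{gid}_cds", chrom, start, end, strand, "CDS", parent=gid))
            features.append(Feature(f"{gid}_exon", chrom, start, end, strand, "exon", parent=gid))
            genes.append(dict(id=gid, chrom=chrom, start=start, end=end, strand=strand,
                              intron=None, cds_len=len(cds)))

    # tRNA / rRNA on chr3
    t_start = alloc.place("chr3", 75, gap=4000)
    features.append(Feature("trna1", "chr3", t_start, t_start + 74, "+", "tRNA"))
    r_start = alloc.place("chr3", 1200, gap=4000)
    features.append(Feature("rrna1", "chr3", r_start, r_start + 1199, "+", "rRNA"))

    # pseudogene on chr4: gene-like sequence with internal stops, no CDS child
    ps_seq = _make_cds(rng, 400)
    ps_seq = ps_seq[:300] + "TAA" + ps_seq[303:]
    ps_start = alloc.place("chr4", len(ps_seq), gap=4500)
    ps_end = ps_start + len(ps_seq) - 1
    write_seq("chr4", ps_start, ps_seq)
    features.append(Feature("pseudo1", "chr4", ps_start, ps_end, "+", "pseudogene"))

    # --- intergenic expressed regions --------------------------------------
    igs: list[dict] = []
    igs_chroms = ["chr5", "chr5", "chr6", "chr6", "chr7"]
    for k, depth in enumerate(spec.igs_depths[:5]):
        chrom = igs_chroms[k]
        if k == 1:  # hosts the planted novel ORF (729 nt), the top-expression analog
            region_seq, orf_off = _make_clean_orf_region(rng, 243, flank=150)
            start = alloc.place(chrom, len(region_seq), gap=4500)
            write_seq(chrom, start, region_seq)
            end = start + len(region_seq) - 1
            igs.append(dict(chrom=chrom, start=start, end=end, depth=depth,
                            orf_start=start + orf_off, orf_end=start + orf_off + 728))
        else:
            size = int(rng.integers(1100, 1500))
            start = alloc.place(chrom, size, gap=4500)
            end = start + size - 1
            igs.append(dict(chrom=chrom, start=start, end=end, depth=depth))
        truth.planted_igs_regions.append(
            PlantedRegion(chrom, igs[-1]["start"], igs[-1]["end"], depth,
                          depth * spec.tc_mito_factor, "mito")
        )
    # igs3 carries a verbatim copy of gene1's 390-nt CDS 3' end -> cross-mapping flag
    g1 = genes[0]
    frag = seqs[g1["chrom"]][g1["end"] - 390 : g1["end"]].decode()
    ig3 = igs[2]
    frag_start = ig3["start"] + 300
    write_seq(ig3["chrom"], frag_start, frag)

    # plastid / nuclear inserts, expressed mainly in total-cellular libraries
    inserts = []
    for chrom, typ, origin in (("chr5", "plastid_insert", "plastid"), ("chr6", "nuclear_insert", "nuclear")):
        size = 1000
        start = alloc.place(chrom, size, gap=4500)
        end = start + size - 1
        features.append(Feature(f"{origin}_ins1", chrom, start, end, "+", typ))
        inserts.append(dict(chrom=chrom, start=start, end=end, origin=origin))
        truth.planted_igs_regions.append(
            PlantedRegion(chrom, start, end, spec.insert_depth_mito, spec.insert_depth_tc, origin)
        )

    # --- identical repeat pair around gene10 -------------------------------
    g10 = genes[9]
    rep_a = (g10["start"] - 400, g10["end"] + 400)
    rep_len = rep_a[1] - rep_a[0] + 1
    rep_b_start = alloc.place("chr6", rep_len, gap=4500)
    rep_b = (rep_b_start, rep_b_start + rep_len - 1)
    write_seq("chr6", rep_b_start, seqs[g10["chrom"]][rep_a[0] - 1 : rep_a[1]].decode())
    shift = rep_b[0] - rep_a[0]
    features.append(Feature("rep1_a", g10["chrom"], rep_a[0], rep_a[1], "+", "repeat", parent="repeat_pair_1"))
    features.append(Feature("rep1_b", "chr6", rep_b[0], rep_b[1], "+", "repeat", parent="repeat_pair_1"))
    features.append(Feature("gene10c", "chr6", g10["start"] + shift, g10["end"] + shift, g10["strand"], "gene"))
    features.append(Feature("gene10c_cds", "chr6", g10["start"] + shift, g10["end"] + shift, g10["strand"], "CDS", parent="gene10c"))
    features.append(Feature("gene10c_exon", "chr6", g10["start"] + shift, g10["end"] + shift, g10["strand"], "exon", parent="gene10c"))
    truth.repeat_pairs.append(PlantedRepeat(g10["chrom"], rep_a[0], rep_a[1], "chr6", rep_b[0], rep_b[1]))

    # --- planted edit sites -------------------------------------------------
    # (engineered reference bases make each site canonical or not by design)
    def cds_pos(g, transcript_offset):
        """Genomic position of a 0-based CDS transcript offset (single-exon genes)."""
        return g["start"] + transcript_offset if g["strand"] == "+" else g["end"] - transcript_offset

    edit_plan: list[PlantedEditSite] = []
    g2, g3, g4, g5 = genes[1], genes[2], genes[3], genes[4]
    # gene2 (+): CCA->TCA (Pro->Ser) nonsynonymous; TAC->TAT (Tyr) synonymous
    edit_plan.append(PlantedEditSite(g2["chrom"], cds_pos(g2, 30), "+", "C", "T", 0.9, True, category="coding_nonsynonymous"))
    edit_plan.append(PlantedEditSite(g2["chrom"], cds_pos(g2, 62), "+", "C", "T", 0.5, True, category="coding_synonymous"))
    # gene3 (-): transcript CCA->TCA, genomic G->A
    edit_plan.append(PlantedEditSite(g3["chrom"], cds_pos(g3, 36), "-", "G", "A", 0.75, True, category="coding_nonsynonymous"))
    # gene5 (-): below the 20 % frequency cutoff, must not be called
    edit_plan.append(PlantedEditSite(g5["chrom"], cds_pos(g5, 45), "-", "G", "A", 0.1, True, category="coding_nonsynonymous"))
    # gene1 intron: one retained mid-intron site, one edge-excluded site
    i_s, i_e = g1["intron"]
    set_base(g1["chrom"], i_s + 150, "C")
    edit_plan.append(PlantedEditSite(g1["chrom"], i_s + 150, "+", "C", "T", 0.6, True, category="intron"))
    set_base(g1["chrom"], i_s + 9, "C")
    edit_plan.append(PlantedEditSite(g1["chrom"], i_s + 9, "+", "C", "T", 0.5, True, category="excluded"))
    # gene4 5' UTR site (150 nt upstream of the CDS start, inside the transcript)
    utr_pos = g4["start"] - 150
    set_base(g4["chrom"], utr_pos, "C")
    edit_plan.append(PlantedEditSite(g4["chrom"], utr_pos, "+", "C", "T", 0.35, True, category="UTR"))
    # pseudogene site
    set_base("chr4", ps_start + 200, "C")
    edit_plan.append(PlantedEditSite("chr4", ps_start + 200, "+", "C", "T", 0.5, True, category="pseudogene"))
    # IGS sites: one on a feature chromosome, one on an 'empty' chromosome
    for region, f in ((igs[0], 0.45), (igs[4], 0.30)):
        pos = (region["start"] + region["end"]) // 2
        set_base(region["chrom"], pos, "C")
        edit_plan.append(PlantedEditSite(region["chrom"], pos, "+", "C", "T", f, True, category="IGS"))
    # gene10 repeat site: called in both copies, collapsed by deduplication
    rp_pos = cds_pos(g10, 24)
    edit_plan.append(PlantedEditSite(g10["chrom"], rp_pos, "+", "C", "T", 0.5, True,
                                     category="coding_nonsynonymous", duplicate_group="dup_plant1"))
    edit_plan.append(PlantedEditSite("chr6", rp_pos + shift, "+", "C", "T", 0.5, True,
                                     category="coding_nonsynonymous", duplicate_group="dup_plant1"))

    # read-end artifact sites (noncanonical, supported only by 3'-terminal calls)
    artifact_plan = []
    for chrom in ("chr2", "chr3"):
        slot = alloc.place(chrom, 200, gap=3000)
        pos = slot + 150
        ref = seqs[chrom][pos - 1 : pos].decode()
        alt = "A" if ref != "A" else "G"
        artifact_plan.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt))
        edit_plan.append(PlantedEditSite(chrom, pos, "+", ref, alt, 0.9, False,
                                         is_artifact=True, category="IGS"))
    truth.planted_edit_sites = edit_plan

    # --- finalize genome ----------------------------------------------------
    genome = Genome({c: seqs[c].decode() for c in seqs})
    table = FeatureTable(features)
    table.validate(genome)

    # --- mRNA reads ---------------------------------------------------------
    tc_f = spec.tc_mito_factor
    lib_depth = {"mito1": 1.0, "mito2": 1.0, "tc1": tc_f, "tc2": tc_f}
    for lib in MRNA_LIBS:
        f = lib_depth[lib]
        for gi, g in enumerate(genes):
            d = spec.gene_depth * f
            a = g["start"] - spec.utr_margin_5p if g["strand"] == "+" else g["start"] - spec.utr_margin_3p
            b = g["end"] + spec.utr_margin_3p if g["strand"] == "+" else g["end"] + spec.utr_margin_5p
            if gi == 6:  # coverage collapse: transcripts end 60 % into the CDS
                brk = int(g["cds_len"] * 0.6)
                if g["strand"] == "+":
                    b = g["start"] + brk
                else:
                    a = g["end"] - brk
            _span_reads(rng, lib, g["chrom"], a, b, g["strand"], d, R, reads)
        _span_reads(rng, lib, "chr4", ps_start - 50, ps_end + 5, "+", spec.pseudogene_depth * f, R, reads)
        _span_reads(rng, lib, "chr3", t_start - 20, t_start + 94, "+", spec.gene_depth * f, R, reads)
        _span_reads(rng, lib, "chr3", r_start - 20, r_start + 1219, "+", spec.gene_depth * f, R, reads)
        for region in igs:
            _span_reads(rng, lib, region["chrom"], region["start"], region["end"],
                        "+", region["depth"] * f, R, reads)
        is_tc = lib.startswith("tc")
        for ins in inserts:
            d = spec.insert_depth_tc if is_tc else spec.insert_depth_mito
            _span_reads(rng, lib, ins["chrom"], ins["start"], ins["end"], "+", d, R, reads)
        # background spurious transcription, both strands, genome-wide
        per_strand = spec.background_depth / 2
        for strand in "+-":
            for chrom, L in lengths.items():
                _span_reads(rng, lib, chrom, 1, L, strand, per_strand, R, reads)
        # artifact clusters: reads sharing an exact 3' terminus with a
        # terminal-base mismatch (a 1-bp adapter-remnant analog)
        n_art = 150 if not is_tc else 15
        for art in artifact_plan:
            for _ in range(n_art):
                rd = _Read(lib, art["chrom"], art["pos"] - R + 1, "+", R)
                if rng.random() < 0.9:
                    rd.set_mut(art["pos"], art["alt"])
                reads.append(rd)

    # realize planted edit frequencies: flip each covering read independently
    by_key: dict[tuple, list[int]] = {}
    starts_by_key: dict[tuple, np.ndarray] = {}
    order = np.argsort([r.start for r in reads], kind="stable")
    for idx in order:
        r = reads[idx]
        by_key.setdefault((r.chromosome, r.strand), []).append(int(idx))
    for key, idxs in by_key.items():
        starts_by_key[key] = np.array([reads[i].start for i in idxs])
    for site in edit_plan:
        if site.is_artifact:
            continue
        key = (site.chromosome, site.strand)
        if key not in by_key:
            continue
        starts = starts_by_key[key]
        lo_i = int(np.searchsorted(starts, site.position - R + 1, side="left"))
        hi_i = int(np.searchsorted(starts, site.position, side="right"))
        for j in range(lo_i, hi_i):
            rd = reads[by_key[key][j]]
            if rd.start <= site.position <= rd.end and rng.random() < site.frequency:
                rd.set_mut(site.position, site.alt)

    # repeat cross-mapping: reads wholly inside copy A map to either copy
    for rd in reads:
        if (
            rd.chromosome == g10["chrom"]
            and rd.start >= rep_a[0]
            and rd.end <= rep_a[1]
            and rng.random() < 0.5
        ):
            rd.chromosome = "chr6"
            rd.start += shift
            if rd.muts:
                rd.muts = {p + shift: b for p, b in rd.muts.items()}

    # --- truth: genes, dropoffs --------------------------------------------
    for gi, g in enumerate(genes):
        d = spec.gene_depth
        if gi == 9:
            d = spec.gene_depth / 2  # reads split between the two repeat copies
        truth.planted_genes.append(
            PlantedGene(g["id"], g["chrom"], g["start"], g["end"], g["strand"], d, d * tc_f)
        )
        if gi == 6:
            truth.planted_dropoffs.append(
                PlantedDropoff(g["id"], "internal", int(g["cds_len"] * 0.6))
            )
        elif gi != 9:
            truth.planted_dropoffs.append(PlantedDropoff(g["id"], "sharp_3prime", 0))
    truth.planted_genes.append(
        PlantedGene("gene10c", "chr6", g10["start"] + shift, g10["end"] + shift,
                    g10["strand"], spec.gene_depth / 2, spec.gene_depth * tc_f / 2)
    )

    # --- write mRNA SAMs ----------------------------------------------------
    chrom_order = {c: i for i, c in enumerate(genome.names)}
    mrna_paths: dict[str, Path] = {}
    libraries = []
    mrna_totals: dict[str, int] = {}
    for lib in MRNA_LIBS:
        lib_reads = [r for r in reads if r.library == lib]
        lib_reads.sort(key=lambda r: (chrom_order[r.chromosome], r.start, r.strand, r.length))
        records = []
        for i, r in enumerate(lib_reads):
            bases = bytearray(seqs[r.chromosome][r.start - 1 : r.start - 1 + r.length])
            nm = 0
            if r.muts:
                for p, b in r.muts.items():
                    bases[p - r.start] = ord(b)
                nm = len(r.muts)
            records.append(
                AlignmentRecord(f"{lib}_{i:07d}", lib, r.chromosome, r.start, r.strand,
                                bases.decode(), nm)
            )
        path = out / f"{lib}.sam"
        write_sam(records, genome, path)
        mrna_paths[lib] = path
        mrna_totals[lib] = len(records)
    for i, lib in enumerate(MRNA_LIBS):
        role = "mito_enriched" if lib.startswith("mito") else "total_cellular"
        libraries.append(Library(lib, role, i % 2 + 1, "mrna", mrna_totals[lib]))

    # --- small-RNA assay ----------------------------------------------------
    srna_rng = np.random.default_rng(int((spec.seed + 10_007) % 2**31))
    stack_plan = _plan_stacks(alloc, truth)
    srna_paths, srna_totals = generate_smallrna_assay(
        spec, truth, genome, table, out, rng=srna_rng, stack_plan=stack_plan,
        genes=genes, igs=igs,
    )
    for i, lib in enumerate(SRNA_LIBS):
        role = "mito_enriched" if lib.startswith("smito") else "total_cellular"
        libraries.append(Library(lib, role, i % 2 + 1, "smallrna", srna_totals[lib]))

    library_set = LibrarySet(libraries)

    # --- write reference, annotation, truth, spec ---------------------------
    genome.to_fasta(out / "genome.fasta")
    table.to_gff3(out / "annotation.gff3")
    library_set.to_tsv(out / "libraries.tsv")
    truth.to_dir(out / "truth")
    spec.to_file(out / "simulation.cfg")

    return SyntheticDataset(
        genome=genome,
        features=table,
        libraries=library_set,
        mrna_paths=mrna_paths,
        smallrna_paths=srna_paths,
        truth=truth,
        out_dir=out,
    )


def _generate_background_only(
    spec: SimulationSpec, rng: np.random.Generator, out: Path, truth: TruthTable
) -> SyntheticDataset:
    """Null dataset: no planted features, only spurious-transcription noise."""
    lo, hi = spec.chromosome_length_range
    lengths = {f"chr{i + 1}": int(rng.integers(lo, hi + 1)) for i in range(spec.n_chromosomes)}
    genome = Genome({c: _random_seq(rng, n).decode() for c, n in lengths.items()})
    table = FeatureTable([])
    R = spec.mrna_read_length
    chrom_order = {c: i for i, c in enumerate(genome.names)}
    libraries, mrna_paths, srna_paths = [], {}, {}
    for i, lib in enumerate(MRNA_LIBS):
        reads: list[_Read] = []
        for strand in "+-":
            for chrom, L in lengths.items():
                _span_reads(rng, lib, chrom, 1, L, strand, spec.background_depth / 2, R, reads)
        reads.sort(key=lambda r: (chrom_order[r.chromosome], r.start, r.strand))
        records = [
            AlignmentRecord(f"{lib}_{k:07d}", lib, r.chromosome, r.start, r.strand,
                            genome[r.chromosome][r.start - 1 : r.start - 1 + r.length], 0)
            for k, r in enumerate(reads)
        ]
        path = out / f"{lib}.sam"
        write_sam(records, genome, path)
        mrna_paths[lib] = path
        role = "mito_enriched" if lib.startswith("mito") else "total_cellular"
        libraries.append(Library(lib, role, i % 2 + 1, "mrna", max(len(records), 1)))
    lo_len, hi_len = spec.smallrna_length_range
    for i, lib in enumerate(SRNA_LIBS):
        reads = []
        n_per = spec.smallrna_background_depth / 2
        for strand in "+-":
            for chrom, L in lengths.items():
                n = int(round(n_per * L / ((lo_len + hi_len) / 2)))
                starts = np.sort(rng.integers(1, L - hi_len + 1, size=n))
                lens = rng.integers(lo_len, hi_len + 1, size=n)
                for s, ln in zip(starts, lens):
                    reads.append(_Read(lib, chrom, int(s), strand, int(ln)))
        reads.sort(key=lambda r: (chrom_order[r.chromosome], r.start, r.strand, r.length))
        records = [
            AlignmentRecord(f"{lib}_{k:07d}", lib, r.chromosome, r.start, r.strand,
                            genome[r.chromosome][r.start - 1 : r.start - 1 + r.length], 0)
            for k, r in enumerate(reads)
        ]
        path = out / f"{lib}.sam"
        write_sam(records, genome, path)
        srna_paths[lib] = path
        role = "mito_enriched" if lib.startswith("smito") else "total_cellular"
        libraries.append(Library(lib, role, i % 2 + 1, "smallrna", max(len(records), 1)))
    library_set = LibrarySet(libraries)
    genome.to_fasta(out / "genome.fasta")
    table.to_gff3(out / "annotation.gff3")
    library_set.to_tsv(out / "libraries.tsv")
    truth.to_dir(out / "truth")
    spec.to_file(out / "simulation.cfg")
    return SyntheticDataset(genome, table, library_set, mrna_paths, srna_paths, truth, out)


def _plan_stacks(alloc: _Allocator, truth: TruthTable) -> list[PlantedStack]:
    """Fixed stack design: counts chosen to exercise the pooled >= 50 depth
    rule, the mito-overrepresentation flag, and the neighbor-overlap filter."""
    plans = [
        # (chrom, length, strand, counts, neighbors)
        ("chr7", 22, "+", {"smito1": 100, "smito2": 100, "stc1": 3, "stc2": 2}, 0),
        ("chr7", 21, "-", {"smito1": 110, "smito2": 110, "stc1": 5, "stc2": 6}, 0),
        ("chr7", 19, "+", {"smito1": 40, "smito2": 40, "stc1": 210, "stc2": 215}, 0),
        ("chr8", 22, "-", {"smito1": 30, "smito2": 30, "stc1": 2, "stc2": 1}, 0),
        ("chr8", 20, "+", {"smito1": 20, "smito2": 15, "stc1": 1, "stc2": 1}, 0),
        ("chr8", 23, "-", {"smito1": 28, "smito2": 27, "stc1": 0, "stc2": 1}, 2),
    ]
    stacks = []
    for chrom, length, strand, counts, neighbors in plans:
        slot = alloc.place(chrom, 120, gap=3000)
        stacks.append(PlantedStack(chrom, slot + 40, length, strand, counts, neighbors))
    truth.planted_smallrna_stacks = stacks
    return stacks


def generate_smallrna_assay(
    spec: SimulationSpec,
    truth: TruthTable,
    genome: Genome,
    annotation: FeatureTable,
    out_dir,
    rng: np.random.Generator | None = None,
    stack_plan: Sequence[PlantedStack] | None = None,
    genes: Sequence[dict] | None = None,
    igs: Sequence[dict] | None = None,
) -> tuple[dict[str, Path], dict[str, int]]:
    """Write the four small-RNA SAM libraries: planted discrete stacks,
    degradation smears over expressed transcripts, and sparse background."""
    if rng is None:
        rng = np.random.default_rng(int((spec.seed + 10_007) % 2**31))
    out = Path(out_dir)
    stacks = list(stack_plan or truth.planted_smallrna_stacks)
    for st in stacks:
        if not 17 <= st.length <= 25:
            raise ValueError(f"planted stack length {st.length} outside 17-25 nt")
    lo_len, hi_len = spec.smallrna_length_range
    reads: list[_Read] = []

    for st in stacks:
        for lib, n in sorted(st.counts.items()):
            for _ in range(n):
                reads.append(_Read(lib, st.chromosome, st.start, st.strand, st.length))
        # planted neighbor reads contaminate the footprint
        for k in range(st.planted_neighbors):
            lib = f"smito{k % 2 + 1}"
            reads.append(_Read(lib, st.chromosome, st.start + 3 + k, st.strand, max(lo_len, st.length - 2)))

    # degradation smears: scattered fragments of expressed transcripts
    smear_regions: list[tuple[str, int, int, str]] = []
    if genes is not None:
        for g in genes[:9]:
            smear_regions.append((g["chrom"], g["start"], g["end"], g["strand"]))
    if igs is not None:
        for region in igs:
            smear_regions.append((region["chrom"], region["start"], region["end"], "+"))
    if not smear_regions:  # standalone use: smear over truth smear entries
        smear_regions = [(s.chromosome, s.start, s.end, "+") for s in truth.planted_smears]
        truth.planted_smears = []
    for chrom, a, b, strand in smear_regions:
        total = 0
        for lib in SRNA_LIBS:
            n = spec.smear_reads if lib.startswith("smito") else spec.smear_reads // 10
            starts = rng.integers(a, b - hi_len + 1, size=n)
            lens = rng.integers(lo_len, hi_len + 1, size=n)
            sense = rng.random(n) < 0.8
            for s, L, is_sense in zip(np.sort(starts), lens, sense):
                reads.append(_Read(lib, chrom, int(s), strand if is_sense else ("-" if strand == "+" else "+"), int(L)))
            total += n
        truth.planted_smears.append(PlantedSmear(chrom, a, b, total))

    # sparse genome-wide background, avoiding planted stack neighborhoods
    masks: dict[str, list[tuple[int, int]]] = {}
    for st in stacks:
        masks.setdefault(st.chromosome, []).append((st.start - 30, st.start + st.length + 29))
    per_strand = spec.smallrna_background_depth / 2
    mean_len = (lo_len + hi_len) / 2
    for lib in SRNA_LIBS:
        for strand in "+-":
            for chrom in genome.names:
                L = len(genome[chrom])
                n = int(round(per_strand * L / mean_len))
                starts = np.sort(rng.integers(1, L - hi_len + 1, size=n))
                lens = rng.integers(lo_len, hi_len + 1, size=n)
                for s, ln in zip(starts, lens):
                    s = int(s)
                    if any(m[0] <= s <= m[1] or m[0] <= s + int(ln) - 1 <= m[1]
                           for m in masks.get(chrom, ())):
                        continue
                    reads.append(_Read(lib, chrom, s, strand, int(ln)))

    # filter-exercise reads: too short, too long, imperfect, and sense-on-gene
    g1 = annotation.get("gene1") if any(f.feature_id == "gene1" for f in annotation) else None
    for lib in ("smito1", "smito2"):
        if g1 is not None:
            spot = g1.start + 50
            for k in range(20):
                reads.append(_Read(lib, g1.chromosome, spot + k, g1.strand, 16))       # too short
                reads.append(_Read(lib, g1.chromosome, spot + k, g1.strand, 26))       # too long
                reads.append(_Read(lib, g1.chromosome, spot + 200 + k, g1.strand, 20))  # sense on gene
            # one mismatch each -> fails the perfect-match rule
            tail = len(genome[g1.chromosome]) - 3000
            for k in range(20):
                pos = tail + k * 30
                rd = _Read(lib, g1.chromosome, pos, "+", 20)
                ref = genome[g1.chromosome][pos + 4]
                rd.set_mut(pos + 5, "A" if ref != "A" else "G")
                reads.append(rd)

    chrom_order = {c: i for i, c in enumerate(genome.names)}
    paths: dict[str, Path] = {}
    totals: dict[str, int] = {}
    for lib in SRNA_LIBS:
        lib_reads = [r for r in reads if r.library == lib]
        lib_reads.sort(key=lambda r: (chrom_order[r.chromosome], r.start, r.strand, r.length))
        records = []
        for i, r in enumerate(lib_reads):
            bases = bytearray(genome[r.chromosome][r.start - 1 : r.start - 1 + r.length].encode())
            nm = 0
            if r.muts:
                for p, b in r.muts.items():
                    bases[p - r.start] = ord(b)
                nm = len(r.muts)
            records.append(
                AlignmentRecord(f"{lib}_{i:07d}", lib, r.chromosome, r.start, r.strand,
                                bases.decode(), nm)
            )
        path = out / f"{lib}.sam"
        write_sam(records, genome, path)
        paths[lib] = path
        totals[lib] = len(records)
    return paths, totals
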