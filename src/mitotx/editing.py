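"""RNA-DNA mismatch calling from strand-specific pileups, canonical C-to-U
typing, annotation-category assignment, read-end artifact re-checking,
repeat deduplication and category summaries.

Canonical plant-organellar editing converts cytidine to uridine on the
transcript; against the genome this is a C->T mismatch for a + -strand
transcript and a G->A mismatch for a - -strand transcript. Every other
RNA-DNA difference is typed non-canonical and, in plant mitochondria, is
usually an artifact.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_io import (
    AlignmentRecord,
    Feature,
    FeatureTable,
    Genome,
    reverse_complement,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CATEGORIES = (
    "coding_synonymous",
    "coding_nonsynonymous",
    "pseudogene",
    "intron",
    "UTR",
    "IGS",
)
NONCODING_CATEGORIES = ("pseudogene", "intron", "UTR", "IGS")


def _seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(len(arr), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


@dataclass(slots=True)
class PileupColumn:
    chromosome: str
    position: int  # 1-based
    strand: str  # transcript strand of the contributing reads
    ref: str
    counts: dict  # base -> count
    end_counts: dict  # base -> count of calls within trim_margin of the read 3' end

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class Pileup:
    """Per-position, per-transcript-strand base counts over a genome.

    Each base call is additionally tagged when it lies within
    ``trim_margin`` nt of its read's 3' sequencing end, so that the
    end-trim re-analysis can mask terminal calls without touching the
    alignments again.
    """

    def __init__(self, genome: Genome, trim_margin: int = 5):
        if trim_margin < 0:
            raise ValueError("trim_margin must be >= 0")
        self.genome = genome
        self.trim_margin = trim_margin
        self._ref_codes = {c: _seq_to_codes(genome[c]) for c in genome.names}
        self.counts: dict[str, dict[str, np.ndarray]] = {
            c: {s: np.zeros((4, len(genome[c])), dtype=np.int32) for s in "+-"}
            for c in genome.names
        }
        self.end_counts: dict[str, dict[str, np.ndarray]] = {
            c: {s: np.zeros((4, len(genome[c])), dtype=np.int32) for s in "+-"}
            for c in genome.names
        }

    def add(self, rec: AlignmentRecord) -> None:
        codes = _seq_to_codes(rec.bases)
        valid = codes >= 0  # '-' (deletion) and N carry no base call
        pos = np.arange(rec.start - 1, rec.start - 1 + rec.span)
        m = self.trim_margin
        if m == 0:
            in_end = np.zeros(rec.span, dtype=bool)
        elif rec.strand == "+":
            in_end = np.arange(rec.span) >= rec.span - m
        else:  # 3' sequencing end of a - read is its leftmost reference positions
            in_end = np.arange(rec.span) < m
        cnt = self.counts[rec.chromosome][rec.strand]
        np.add.at(cnt, (codes[valid], pos[valid]), 1)
        ev = valid & in_end
        if ev.any():
            ec = self.end_counts[rec.chromosome][rec.strand]
            np.add.at(ec, (codes[ev], pos[ev]), 1)

    def column(self, chromosome: str, position: int, strand: str) -> PileupColumn:
        i = position - 1
        c = self.counts[chromosome][strand][:, i]
        e = self.end_counts[chromosome][strand][:, i]
        return PileupColumn(
            chromosome=chromosome,
            position=position,
            strand=strand,
            ref=self.genome[chromosome][i],
            counts={b: int(c[j]) for j, b in enumerate(BASES)},
            end_counts={b: int(e[j]) for j, b in enumerate(BASES)},
        )

    def columns(self, min_depth: int = 1) -> Iterator[PileupColumn]:
        for chrom in self.genome.names:
            for strand in "+-":
                depth = self.counts[chrom][strand].sum(axis=0)
                for i in np.nonzero(depth >= min_depth)[0]:
                    yield self.column(chrom, int(i) + 1, strand)


def build_pileup(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    trim_margin: int = 5,
) -> Pileup:
    pile = Pileup(genome, trim_margin=trim_margin)
    for rec in alignments:
        if rec.chromosome not in genome:
            raise ValueError(
                f"alignment {rec.read_id} on chromosome {rec.chromosome!r} "
                f"absent from the reference"
            )
        pile.add(rec)
    return pile


@dataclass(slots=True)
class EditSite:
    chromosome: str
    position: int
    strand: str  # transcript strand
    ref: str  # genomic reference base (forward orientation)
    alt: str  # observed variant base (forward orientation)
    depth: int
    frequency: float
    edit_type: str = "noncanonical"  # canonical_CtoU | noncanonical
    category: str | None = None
    artifact: bool = False
    duplicate_group: str | None = None
    strand_ambiguous: bool = False
    codon_change: str | None = None

    @property
    def is_canonical(self) -> bool:
        return self.edit_type == "canonical_CtoU"


def _canonical_type(strand: str, ref: str, alt: str) -> str:
    if (strand == "+" and ref == "C" and alt == "T") or (
        strand == "-" and ref == "G" and alt == "A"
    ):
        return "canonical_CtoU"
    return "noncanonical"


def call_edit_sites(
    pileup: Pileup,
    min_depth: int = 100,
    min_freq: float = 0.20,
) -> list[EditSite]:
    """Emit candidate sites where, on a single transcript strand, depth
    reaches ``min_depth`` and the most frequent non-reference base reaches
    ``min_freq`` (variant count / strand depth). When both strands pass at a
    position, the deeper strand is reported (ties keep + and set the
    ambiguity flag)."""
    if not 0 < min_freq <= 1:
        raise ValueError("min_freq must be in (0, 1]")
    hits: dict[tuple[str, int], list[EditSite]] = defaultdict(list)
    for chrom in pileup.genome.names:
        ref_codes = pileup._ref_codes[chrom]
        for strand in "+-":
            cnt = pileup.counts[chrom][strand]
            depth = cnt.sum(axis=0)
            ok = depth >= min_depth
            if not ok.any():
                continue
            nonref = cnt.copy()
            cols = np.nonzero(ok)[0]
            nonref[ref_codes[cols], cols] = 0
            top = nonref[:, cols].argmax(axis=0)
            topcount = nonref[top, cols]
            freq = topcount / depth[cols]
            called = freq >= min_freq
            for i in np.nonzero(called)[0]:
                pos = int(cols[i]) + 1
                ref = chrom_ref = BASES[ref_codes[cols[i]]] if ref_codes[cols[i]] >= 0 else "N"
                alt = BASES[int(top[i])]
                site = EditSite(
                    chromosome=chrom,
                    position=pos,
                    strand=strand,
                    ref=ref,
                    alt=alt,
                    depth=int(depth[cols[i]]),
                    frequency=float(freq[i]),
                )
                site.edit_type = _canonical_type(strand, ref, alt)
                hits[(chrom, pos)].append(site)
    sites = []
    for key in sorted(hits):
        group = hits[key]
        if len(group) == 1:
            sites.append(group[0])
        else:
            group.sort(key=lambda s: (-s.depth, s.strand))
            best = group[0]
            if group[0].depth == group[1].depth:
                best = next(s for s in group if s.strand == "+")
                best.strand_ambiguous = True
            sites.append(best)
    return sites


def _transcript_offset(pos: int, segments: Sequence[Feature], strand: str) -> int:
    """0-based offset of a genomic position within concatenated CDS segments."""
    ordered = sorted(segments, key=lambda s: s.start, reverse=(strand == "-"))
    off = 0
    for seg in ordered:
        if seg.start <= pos <= seg.end:
            return off + (pos - seg.start if strand == "+" else seg.end - pos)
        off += seg.length
    raise ValueError(f"position {pos} not inside CDS segments")


def _genomic_position(offset: int, segments: Sequence[Feature], strand: str) -> int:
    ordered = sorted(segments, key=lambda s: s.start, reverse=(strand == "-"))
    for seg in ordered:
        if offset < seg.length:
            return seg.start + offset if strand == "+" else seg.end - offset
        offset -= seg.length
    raise ValueError("offset beyond CDS length")


def _codon_effect(
    site: EditSite, genome: Genome, segments: Sequence[Feature]
) -> tuple[str, str]:
    """(category, codon_change) for a site inside a CDS, by translating the
    codon with and without the edit; a stop-gain is nonsynonymous."""
    strand = segments[0].strand
    off = _transcript_offset(site.position, segments, strand)
    codon_start = off - off % 3
    gpos = [_genomic_position(codon_start + k, segments, strand) for k in range(3)]
    bases = [genome[site.chromosome][p - 1] for p in gpos]
    if strand == "-":
        bases = [_COMP[b] for b in bases]
    codon = "".join(bases)
    alt_t = site.alt if strand == "+" else _COMP[site.alt]
    edited = list(codon)
    edited[off % 3] = alt_t
    edited = "".join(edited)
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(edited).translate())
    change = f"{codon}({aa_ref})->{edited}({aa_alt})"
    cat = "coding_synonymous" if aa_ref == aa_alt else "coding_nonsynonymous"
    return cat, change


def classify_edit_site(
    site: EditSite,
    genome: Genome,
    annotation: FeatureTable,
    utr_margin: int = 2000,
    intron_edge_exclusion: int = 20,
) -> EditSite | None:
    """Assign the annotation category with precedence CDS > pseudogene >
    intron > UTR > IGS, on the site's transcript strand.

    Intronic sites within ``intron_edge_exclusion`` nt of an exon boundary
    are dropped entirely (returns None): read mapping across splice
    boundaries is unreliable there. UTR covers unannotated positions within
    ``utr_margin`` nt of a same-strand CDS; everything further is IGS.
    """
    chrom, pos, strand = site.chromosome, site.position, site.strand
    site.edit_type = _canonical_type(strand, site.ref, site.alt)
    # CDS
    for f in annotation.of_type("CDS"):
        if f.strand == strand and f.overlaps(chrom, pos, pos):
            parent = f.parent or f.feature_id
            segments = annotation.cds_segments(parent) or [f]
            if sum(s.length for s in segments) % 3 != 0:
                raise ValueError(f"cannot resolve codon phase of CDS {parent}")
            site.category, site.codon_change = _codon_effect(site, genome, segments)
            return site
    # pseudogene
    for f in annotation.of_type("pseudogene"):
        if f.strand == strand and f.overlaps(chrom, pos, pos):
            site.category = "pseudogene"
            return site
    # intron: explicit features plus introns implied by exon gaps
    intron_intervals: list[tuple[int, int, str]] = []
    for f in annotation.of_type("intron"):
        if f.chromosome == chrom:
            intron_intervals.append((f.start, f.end, f.strand))
    for gene in annotation.of_type("gene"):
        if gene.chromosome != chrom:
            continue
        for s, e in annotation.implied_introns(gene.feature_id):
            intron_intervals.append((s, e, gene.strand))
    for s, e, f_strand in intron_intervals:
        if f_strand == strand and s <= pos <= e:
            edge = min(pos - s + 1, e - pos + 1)
            if edge <= intron_edge_exclusion:
                return None
            site.category = "intron"
            return site
    # UTR vs IGS by distance to the nearest same-strand CDS
    best = None
    for f in annotation.of_type("CDS"):
        if f.chromosome != chrom or f.strand != strand:
            continue
        d = 0 if f.start <= pos <= f.end else min(abs(pos - f.start), abs(pos - f.end))
        best = d if best is None else min(best, d)
    site.category = "UTR" if best is not None and best <= utr_margin else "IGS"
    return site


def end_trim_recheck(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    sites: Sequence[EditSite],
    extra_trim: int = 5,
    min_depth: int = 100,
    min_freq: float = 0.20,
) -> list[EditSite]:
    """Re-evaluate each site with base calls within ``extra_trim`` nt of the
    read 3' end masked, emulating re-mapping after additional end trimming.
    Sites that no longer meet (min_depth, min_freq) are flagged as artifacts.
    """
    if extra_trim < 1:
        raise ValueError("extra_trim must be >= 1")
    pile = build_pileup(alignments, genome, trim_margin=extra_trim)
    for site in sites:
        col = pile.column(site.chromosome, site.position, site.strand)
        depth = col.depth - sum(col.end_counts.values())
        var = col.counts[site.alt] - col.end_counts[site.alt]
        ok = depth >= min_depth and var / depth >= min_freq if depth > 0 else False
        site.artifact = not ok
    return list(sites)


@dataclass
class RepeatPair:
    """Two identical-sequence intervals; sites at homologous offsets collapse."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self):
        if self.end_a - self.start_a != self.end_b - self.start_b:
            raise ValueError("repeat pair intervals have unequal length")

    def canonical_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map a position in copy B to copy A; positions in A map to themselves."""
        if chrom == self.chrom_a and self.start_a <= pos <= self.end_a:
            return (self.chrom_a, pos)
        if chrom == self.chrom_b and self.start_b <= pos <= self.end_b:
            return (self.chrom_a, self.start_a + (pos - self.start_b))
        return None


def repeat_pairs_from_features(annotation: FeatureTable) -> list[RepeatPair]:
    """Repeat features sharing a parent id form a pair (genomic order: A first)."""
    groups: dict[str, list[Feature]] = defaultdict(list)
    for f in annotation.of_type("repeat"):
        if f.parent:
            groups[f.parent].append(f)
    pairs = []
    for pid in sorted(groups):
        feats = sorted(groups[pid], key=lambda f: (f.chromosome, f.start))
        if len(feats) != 2:
            continue
        a, b = feats
        pairs.append(RepeatPair(a.chromosome, a.start, a.end, b.chromosome, b.start, b.end))
    return pairs


@dataclass
class CategorySummary:
    """Per-category editing-site counts (all and duplicate-collapsed) with
    mean editing frequency over unique sites, plus a totals row."""

    table: pd.DataFrame  # index: category + "total"; columns: sites_all, sites_unique, mean_frequency_pct

    @property
    def total_unique(self) -> int:
        return int(self.table.loc["total", "sites_unique"])

    @property
    def noncoding_unique(self) -> int:
        return int(self.table.loc[list(NONCODING_CATEGORIES), "sites_unique"].sum())

    @classmethod
    def from_unique_counts(cls, unique_counts: dict[str, int]) -> "CategorySummary":
        """Build a summary from per-category unique counts alone (frequency
        columns empty); totals are computed, never supplied."""
        rows = {}
        for cat in CATEGORIES:
            n = int(unique_counts.get(cat, 0))
            rows[cat] = {"sites_all": np.nan, "sites_unique": n, "mean_frequency_pct": np.nan}
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.loc["total"] = table.sum(numeric_only=False)
        table.loc["total", "mean_frequency_pct"] = np.nan
        return cls(table=table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="category", float_format="%.4g")


def dedupe_and_summarize(
    sites: Sequence[EditSite],
    repeat_pairs: Sequence[RepeatPair],
) -> tuple[list[EditSite], CategorySummary]:
    """Collapse edit sites at homologous offsets of identical repeat pairs
    (same base change) and build the per-category summary.

    Returns the unique (representative) sites — artifact-flagged sites
    excluded from counts and frequencies — and the summary table. Each
    duplicated site gets a ``duplicate_group`` id on input order.
    """
    groups: dict[tuple, list[EditSite]] = defaultdict(list)
    for site in sites:
        key = None
        for pair in repeat_pairs:
            mapped = pair.canonical_position(site.chromosome, site.position)
            if mapped is not None:
                key = (mapped[0], mapped[1], site.strand, site.ref, site.alt)
                break
        if key is None:
            key = (site.chromosome, site.position, site.strand, site.ref, site.alt)
        groups[key].append(site)
    unique_sites: list[EditSite] = []
    gid = 0
    for key in sorted(groups):
        members = groups[key]
        if len(members) > 1:
            gid += 1
            for m in members:
                m.duplicate_group = f"dup{gid}"
        rep = max(members, key=lambda s: s.depth)
        unique_sites.append(rep)
    live = [s for s in sites if not s.artifact and s.category]
    live_unique = [s for s in unique_sites if not s.artifact and s.category]
    rows = {}
    for cat in CATEGORIES:
        cat_all = [s for s in live if s.category == cat]
        cat_unique = [s for s in live_unique if s.category == cat]
        rows[cat] = {
            "sites_all": len(cat_all),
            "sites_unique": len(cat_unique),
            "mean_frequency_pct": (
                100 * float(np.mean([s.frequency for s in cat_unique]))
                if cat_unique
                else np.nan
            ),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    totals = {
        "sites_all": int(table["sites_all"].sum()),
        "sites_unique": int(table["sites_unique"].sum()),
        "mean_frequency_pct": (
            100 * float(np.mean([s.frequency for s in live_unique])) if live_unique else np.nan
        ),
    }
    table.loc["total"] = totals
    return unique_sites, CategorySummary(table=table)


def sites_to_tsv(sites: Sequence[EditSite], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chromosome\tposition\tstrand\tref\talt\tedit_type\tcategory\t"
            "depth\tfrequency\tartifact\tduplicate_group\n"
        )
        for s in sites:
            fh.write(
                f"{s.chromosome}\t{s.position}\t{s.strand}\t{s.ref}\t{s.alt}\t"
                f"{s.edit_type}\t{s.category or ''}\t{s.depth}\t{s.frequency:.4f}\t"
                f"{s.artifact}\t{s.duplicate_group or ''}\n"
            )


def sites_to_vcf(sites: Sequence[EditSite], genome: Genome, path) -> None:
    """Minimal VCF-like text export with type/category/frequency INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={len(genome[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda x: (x.chromosome, x.position)):
            info = (
                f"TYPE={s.edit_type};CATEGORY={s.category or 'NA'};"
                f"FREQ={s.frequency:.4f};STRAND={s.strand};DP={s.depth}"
            )
            filt = "artifact" if s.artifact else "PASS"
            fh.write(
                f"{s.chromosome}\t{s.position}\t.\t{s.ref}\t{s.alt}\t.\t{filt}\t{info}\n"
            )
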