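"""Candidate small-RNA calling: the 17-25 nt perfect-match filter, discrete
read-stack detection versus degradation smears, mito-enrichment flags, and
the small-RNA / mRNA coverage correlation.

A *stack* is a set of reads sharing an identical start coordinate and
length — the signature of a discrete processed small RNA — with essentially
no overlapping reads at neighboring positions. Degradation products of
longer transcripts instead produce smears of overlapping reads with
scattered start positions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_io import (
    AlignmentRecord,
    CODING_STRAND_TYPES,
    FeatureTable,
    Genome,
    LibrarySet,
)
from .coverage import WindowProfile


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (too few windows or zero variance)."""


def filter_smallrna_reads(
    alignments: Iterable[AlignmentRecord],
    annotation: FeatureTable,
    min_length: int = 17,
    max_length: int = 25,
) -> list[AlignmentRecord]:
    """Apply the candidate small-RNA read filter.

    Retains reads that (1) are 17-25 nt long, (2) match the reference
    perfectly, and (3) do not lie on the coding strand of an annotated
    protein/tRNA/rRNA gene (antisense overlap is retained).
    """
    coding = [f for f in annotation if f.type in CODING_STRAND_TYPES]
    by_chrom: dict[str, list] = defaultdict(list)
    for f in coding:
        by_chrom[f.chromosome].append(f)
    kept = []
    for rec in alignments:
        if not (min_length <= rec.span <= max_length):
            continue
        if rec.mismatch_count != 0:
            continue
        sense_hit = any(
            f.strand == rec.strand and f.start <= rec.end and rec.start <= f.end
            for f in by_chrom.get(rec.chromosome, ())
        )
        if sense_hit:
            continue
        kept.append(rec)
    return kept


@dataclass
class SmallRnaCandidate:
    chromosome: str
    start: int
    end: int
    length: int
    strand: str
    sequence: str
    counts: dict[str, int]  # library_id -> read count
    neighbor_overlap: int
    mito_overrepresented: bool | None = None

    def pooled_count(self, library_ids: Sequence[str]) -> int:
        return sum(self.counts.get(l, 0) for l in library_ids)


def stack_candidates(
    reads: Sequence[AlignmentRecord],
    genome: Genome,
    libraries: LibrarySet,
    min_depth: int = 50,
    max_neighbor_overlap: int = 1,
) -> list[SmallRnaCandidate]:
    """Group filtered reads by exact (chromosome, start, length, strand) and
    keep groups whose pooled mito-enriched count reaches ``min_depth`` with
    at most ``max_neighbor_overlap`` other filtered reads overlapping the
    footprint.

    Output order is (chromosome, start, length, strand), independent of the
    input read order.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    srna_libs = [l for l in libraries if l.assay == "smallrna"] or list(libraries)
    mito_ids = [l.library_id for l in srna_libs if l.role == "mito_enriched"]
    groups: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for rec in reads:
        groups[(rec.chromosome, rec.start, rec.span, rec.strand)][rec.library_id] += 1
    # interval lists per chromosome for neighbor counting
    by_chrom: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in reads:
        by_chrom[rec.chromosome].append(rec)
    candidates = []
    for key in sorted(groups):
        chrom, start, length, strand = key
        counts = groups[key]
        pooled = sum(counts.get(l, 0) for l in mito_ids)
        if pooled < min_depth:
            continue
        end = start + length - 1
        neighbors = sum(
            1
            for rec in by_chrom[chrom]
            if rec.start <= end
            and rec.end >= start
            and (rec.chromosome, rec.start, rec.span, rec.strand) != key
        )
        if neighbors > max_neighbor_overlap:
            continue
        candidates.append(
            SmallRnaCandidate(
                chromosome=chrom,
                start=start,
                end=end,
                length=length,
                strand=strand,
                sequence=genome.sequence(chrom, start, end, strand),
                counts={l.library_id: counts.get(l.library_id, 0) for l in srna_libs},
                neighbor_overlap=neighbors,
            )
        )
    return candidates


def flag_mito_overrepresentation(
    candidate: SmallRnaCandidate, totals: LibrarySet
) -> bool:
    """True when the candidate's CPM is higher in both mito-enriched
    libraries than in both total-cellular libraries."""
    mito = totals.by_role("mito_enriched", assay="smallrna") or totals.by_role("mito_enriched")
    tc = totals.by_role("total_cellular", assay="smallrna") or totals.by_role("total_cellular")
    if not mito or not tc:
        raise ValueError("library set must contain both conditions")
    def cpm(lib):
        return candidate.counts.get(lib.library_id, 0) * 1e6 / totals.total_mapped(lib.library_id)
    return all(cpm(m) > cpm(t) for m in mito for t in tc)


def smallrna_mrna_correlation(
    smallrna_profile: WindowProfile, mrna_profile: WindowProfile
) -> float:
    """Pearson correlation between small-RNA and mRNA CPM over matched windows."""
    if not smallrna_profile.same_grid(mrna_profile):
        raise ValueError("profiles are not on identical window grids")
    x = smallrna_profile.windows["cpm"].values
    y = mrna_profile.windows["cpm"].values
    if len(x) < 3:
        raise UndefinedCorrelationError("fewer than 3 windows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a profile")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def candidates_to_tsv(candidates: Sequence[SmallRnaCandidate], totals: LibrarySet, path) -> None:
    """Candidate table with one count column per library (mito replicates
    first, then total-cellular), plus the genomic sequence."""
    libs = totals.by_role("mito_enriched", assay="smallrna") + totals.by_role(
        "total_cellular", assay="smallrna"
    )
    if not libs:
        libs = list(totals)
    with open(path, "w") as fh:
        cols = ["chromosome", "start", "end", "length", "strand"]
        cols += [l.library_id for l in libs]
        cols += ["mito_overrepresented", "sequence"]
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [c.chromosome, str(c.start), str(c.end), str(c.length), c.strand]
            row += [str(c.counts.get(l.library_id, 0)) for l in libs]
            row += [str(c.mito_overrepresented), c.sequence]
            fh.write("\t".join(row) + "\n")


def candidates_to_fasta(candidates: Sequence[SmallRnaCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.chromosome}_{c.start}_{c.end}_{c.strand}\n{c.sequence}\n")
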