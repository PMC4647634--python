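"""Six-frame ORF discovery, annotation-distance filtering and expression ranking.

Plant mitochondria translate with the standard genetic code, so ORFs are
ATG-to-stop spans under the standard table; the stop codon is included in
the reported span (a 201-nt ORF encodes 66 amino acids plus the stop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import (
    Feature,
    FeatureTable,
    GENE_LIKE_TYPES,
    Genome,
    reverse_complement,
)
from .coverage import CoverageTrack

START_CODONS = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(slots=True)
class OrfRecord:
    chromosome: str
    start: int  # 1-based inclusive, includes the stop codon
    end: int
    strand: str
    frame: int  # 0-2 on the ORF's own strand
    length: int
    protein_length: int
    mean_depth: float | None = None
    distance_to_gene: float | None = None
    high_depth: bool = False

    def key(self) -> tuple:
        return (self.chromosome, self.start, self.end, self.strand)


def _scan_strand(seq: str, min_length: int, mode: str) -> list[tuple[int, int, int]]:
    """ORFs on the forward orientation of ``seq`` as 0-based (start, end, frame),
    end exclusive of nothing: [start, end] covers ATG..stop inclusive."""
    out = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                for s in starts:
                    length = pos + 3 - s
                    if length >= min_length:
                        out.append((s, pos + 2, frame))
                    if mode == "maximal":
                        break
                starts = []
            elif codon in START_CODONS:
                if mode == "all_starts" or not starts:
                    starts.append(pos)
        # ORFs without a terminal stop are not reported
    return out


def find_orfs(genome: Genome, min_length: int = 201, mode: str = "maximal") -> list[OrfRecord]:
    """All ATG-to-stop ORFs of at least ``min_length`` nt on both strands.

    ``mode='maximal'`` reports, per frame, the ORF from the first ATG after
    the previous stop; ``mode='all_starts'`` reports one ORF per in-frame ATG.
    """
    if min_length < 6 or min_length % 3 != 0:
        raise ValueError("min_length must be >= 6 and divisible by 3")
    if mode not in ("maximal", "all_starts"):
        raise ValueError(f"unknown mode {mode!r}")
    orfs: list[OrfRecord] = []
    for chrom in genome.names:
        seq = genome[chrom]
        n = len(seq)
        for s, e, frame in _scan_strand(seq, min_length, mode):
            orfs.append(
                OrfRecord(
                    chromosome=chrom,
                    start=s + 1,
                    end=e + 1,
                    strand="+",
                    frame=frame,
                    length=e - s + 1,
                    protein_length=(e - s + 1) // 3 - 1,
                )
            )
        rc = reverse_complement(seq)
        for s, e, frame in _scan_strand(rc, min_length, mode):
            # map reverse-strand coordinates back to the forward reference
            orfs.append(
                OrfRecord(
                    chromosome=chrom,
                    start=n - e,
                    end=n - s,
                    strand="-",
                    frame=frame,
                    length=e - s + 1,
                    protein_length=(e - s + 1) // 3 - 1,
                )
            )
    orfs.sort(key=lambda o: (o.chromosome, o.start, o.end, o.strand))
    return orfs


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge distance between two intervals; 0 when they overlap."""
    if a_start <= b_end and b_start <= a_end:
        return 0
    return b_start - a_end if b_start > a_end else a_start - b_end


def filter_remote_orfs(
    orfs: Sequence[OrfRecord],
    annotation: FeatureTable,
    min_distance: int = 2000,
) -> list[OrfRecord]:
    """Keep ORFs strictly more than ``min_distance`` nt from any annotated
    gene/tRNA/rRNA/pseudogene (same chromosome; overlap counts as distance 0)."""
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    genes = annotation.gene_like()
    kept = []
    for orf in orfs:
        dists = [
            _edge_distance(orf.start, orf.end, g.start, g.end)
            for g in genes
            if g.chromosome == orf.chromosome
        ]
        d = min(dists) if dists else math.inf
        orf.distance_to_gene = d
        if d > min_distance:
            kept.append(orf)
    return kept


def rank_orfs_by_depth(
    orfs: Sequence[OrfRecord],
    track: CoverageTrack,
    top_fraction: float = 0.05,
    depth_floor: float = 100.0,
) -> list[OrfRecord]:
    """Annotate each ORF with its coding-strand mean depth, return the top
    ``ceil(n * top_fraction)`` by depth, and flag (``high_depth``) those whose
    mean depth is strictly above ``depth_floor``.

    Ties break deterministically by (depth desc, chromosome, start).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    for orf in orfs:
        d = track.strand_depth(orf.chromosome, orf.strand)[orf.start - 1 : orf.end]
        orf.mean_depth = float(d.mean())
        orf.high_depth = orf.mean_depth > depth_floor
    ranked = sorted(orfs, key=lambda o: (-o.mean_depth, o.chromosome, o.start))
    n_select = math.ceil(len(ranked) * top_fraction) if ranked else 0
    return ranked[:n_select]


def orfs_to_tsv(orfs: Sequence[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chromosome\tstart\tend\tstrand\tframe\tlength\tprotein_length\t"
            "mean_depth\tdistance_to_gene\thigh_depth\n"
        )
        for o in orfs:
            depth = "" if o.mean_depth is None else f"{o.mean_depth:.4f}"
            dist = "" if o.distance_to_gene is None else (
                "inf" if math.isinf(o.distance_to_gene) else str(int(o.distance_to_gene))
            )
            fh.write(
                f"{o.chromosome}\t{o.start}\t{o.end}\t{o.strand}\t{o.frame}\t"
                f"{o.length}\t{o.protein_length}\t{depth}\t{dist}\t{o.high_depth}\n"
            )


def orfs_to_protein_fasta(orfs: Sequence[OrfRecord], genome: Genome, path) -> None:
    """Write translated ORFs (stop codon excluded) for external homology search."""
    from Bio.Seq import Seq

    with open(path, "w") as fh:
        for o in orfs:
            nt = genome.sequence(o.chromosome, o.start, o.end, o.strand)
            aa = str(Seq(nt[:-3]).translate())
            name = f"{o.chromosome}_{o.start}_{o.end}_{o.strand}"
            fh.write(f">{name}\n{aa}\n")


def orfs_to_gff3(orfs: Sequence[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs, 1):
            fh.write(
                f"{o.chromosome}\tmitotx\tORF\t{o.start}\t{o.end}\t.\t{o.strand}\t0\t"
                f"ID=orf{i};length={o.length}\n"
            )
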