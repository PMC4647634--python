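"""Reference, annotation and alignment I/O with the package's coordinate conventions.

All coordinates are 1-based and fully inclusive (the GFF convention); the
single exception is BED export, which converts to 0-based half-open at the
boundary. Strand is ``+`` or ``-``. Alignments are treated as ungapped
blocks: one query base per covered reference position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")
STRANDS = ("+", "-")

#: Feature types that count as "annotated genes" for distance/exclusion logic.
GENE_LIKE_TYPES = frozenset({"gene", "tRNA", "rRNA", "pseudogene"})

#: Feature types whose coding strand disqualifies small-RNA reads.
CODING_STRAND_TYPES = frozenset({"gene", "tRNA", "rRNA"})

FEATURE_TYPES = frozenset(
    {
        "gene", "CDS", "exon", "intron", "tRNA", "rRNA", "pseudogene",
        "repeat", "plastid_insert", "nuclear_insert",
    }
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An ordered collection of named chromosome sequences (A/C/G/T/N)."""

    def __init__(self, chromosomes: dict[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq.upper()) - VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
        self.chromosomes: dict[str, str] = {n: s.upper() for n, s in chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def sequence(self, chromosome: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence at 1-based inclusive ``[start, end]``; reverse-complemented for ``-``."""
        seq = self.chromosomes[chromosome][start - 1 : end]
        return reverse_complement(seq) if strand == "-" else seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(slots=True)
class Feature:
    """One annotated interval, 1-based inclusive."""

    feature_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    type: str
    parent: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"feature {self.feature_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return self.chromosome == chromosome and self.start <= end and start <= self.end


class FeatureTable:
    """Validated annotation: genes, CDS/exon structure, and auxiliary features."""

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        self._by_id = {f.feature_id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return False
        key = lambda f: (f.chromosome, f.start, f.end, f.type, f.feature_id)
        return sorted(self.features, key=key) == sorted(other.features, key=key)

    def get(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def of_type(self, *types: str) -> list[Feature]:
        wanted = set(types)
        return [f for f in self.features if f.type in wanted]

    def gene_like(self) -> list[Feature]:
        return [f for f in self.features if f.type in GENE_LIKE_TYPES]

    def children(self, parent_id: str, type: str | None = None) -> list[Feature]:
        out = [f for f in self.features if f.parent == parent_id]
        if type is not None:
            out = [f for f in out if f.type == type]
        return sorted(out, key=lambda f: f.start)

    def cds_segments(self, gene_id: str) -> list[Feature]:
        """CDS segments of a gene in genomic order (ascending start)."""
        return self.children(gene_id, type="CDS")

    def implied_introns(self, gene_id: str) -> list[tuple[int, int]]:
        """Intron intervals implied by gaps between a gene's exons (or CDS segments)."""
        segs = self.children(gene_id, type="exon") or self.cds_segments(gene_id)
        introns = []
        for a, b in zip(segs, segs[1:]):
            if b.start > a.end + 1:
                introns.append((a.end + 1, b.start - 1))
        return introns

    def validate(self, genome: Genome) -> None:
        for f in self.features:
            if f.chromosome not in genome:
                raise ValueError(
                    f"feature {f.feature_id} is on unknown chromosome {f.chromosome!r}"
                )
            if f.end > len(genome[f.chromosome]):
                raise ValueError(
                    f"feature {f.feature_id} extends past the end of {f.chromosome} "
                    f"({f.end} > {len(genome[f.chromosome])})"
                )
        # CDS must concatenate to a whole number of codons
        parents = {f.parent for f in self.features if f.type == "CDS" and f.parent}
        for pid in sorted(parents):
            total = sum(f.length for f in self.cds_segments(pid))
            if total % 3 != 0:
                raise ValueError(f"CDS of {pid} has length {total}, not divisible by 3")
        # explicit introns must not overlap sibling exons
        for f in self.features:
            if f.type != "intron" or f.parent is None:
                continue
            for ex in self.children(f.parent, type="exon"):
                if f.overlaps(ex.chromosome, ex.start, ex.end):
                    raise ValueError(
                        f"intron {f.feature_id} overlaps exon {ex.feature_id}"
                    )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "FeatureTable":
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="error", sort_attribute_values=True,
        )
        features = []
        for f in db.all_features(order_by=("seqid", "start")):
            parents = f.attributes.get("Parent")
            features.append(
                Feature(
                    feature_id=f.id,
                    chromosome=f.seqid,
                    start=f.start,
                    end=f.end,
                    strand=f.strand if f.strand in STRANDS else "+",
                    type=f.featuretype,
                    parent=parents[0] if parents else None,
                )
            )
        return cls(features)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                attrs = f"ID={f.feature_id}"
                if f.parent:
                    attrs += f";Parent={f.parent}"
                fh.write(
                    f"{f.chromosome}\tmitotx\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )


@dataclass(slots=True)
class AlignmentRecord:
    """One mapped read as an ungapped block.

    ``bases`` holds one reference-orientation query base per covered
    reference position; ``-`` marks a reference position deleted in the
    query (ignored for pileup base counts).
    """

    read_id: str
    library_id: str
    chromosome: str
    start: int
    strand: str
    bases: str
    mismatch_count: int | None = 0

    @property
    def span(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        return self.start + len(self.bases) - 1

    def validate(self, genome: Genome) -> None:
        if self.start < 1 or self.end > len(genome[self.chromosome]):
            raise ValueError(
                f"read {self.read_id} at {self.chromosome}:{self.start}-{self.end} "
                f"is out of bounds"
            )
        if self.mismatch_count is not None and self.mismatch_count > self.span:
            raise ValueError(f"read {self.read_id}: mismatch_count exceeds read length")


@dataclass(slots=True)
class Library:
    library_id: str
    role: str  # mito_enriched | total_cellular
    replicate: int
    assay: str  # mrna | smallrna
    total_mapped_reads: int = 0


class LibrarySet:
    """The four-library design: mito-enriched ×2 and total-cellular ×2, per assay."""

    def __init__(self, libraries: Iterable[Library]):
        self.libraries = list(libraries)
        keys = [(l.role, l.replicate, l.assay) for l in self.libraries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (role, replicate, assay) in library set")

    def __iter__(self) -> Iterator[Library]:
        return iter(self.libraries)

    def get(self, library_id: str) -> Library:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(f"unknown library {library_id!r}")

    def by_role(self, role: str, assay: str | None = None) -> list[Library]:
        out = [l for l in self.libraries if l.role == role]
        if assay is not None:
            out = [l for l in out if l.assay == assay]
        return sorted(out, key=lambda l: l.replicate)

    def total_mapped(self, library_id: str) -> int:
        n = self.get(library_id).total_mapped_reads
        if n <= 0:
            raise ValueError(f"library {library_id} has no mapped reads recorded")
        return n

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("library_id\trole\treplicate\tassay\ttotal_mapped_reads\n")
            for l in self.libraries:
                fh.write(
                    f"{l.library_id}\t{l.role}\t{l.replicate}\t{l.assay}\t{l.total_mapped_reads}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibrarySet":
        libs = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                libs.append(
                    Library(
                        library_id=row["library_id"],
                        role=row["role"],
                        replicate=int(row["replicate"]),
                        assay=row["assay"],
                        total_mapped_reads=int(row["total_mapped_reads"]),
                    )
                )
        return cls(libs)


def load_reference(
    genome_path: str | Path, annotation_path: str | Path
) -> tuple[Genome, FeatureTable]:
    """Load and cross-validate a FASTA reference and its GFF3 annotation."""
    genome = Genome.from_fasta(genome_path)
    table = FeatureTable.from_gff3(annotation_path)
    table.validate(genome)
    return genome, table


def load_alignments(
    path: str | Path,
    library_id: str,
    genome: Genome | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped, primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped. Strand comes
    from flag 0x10, the mismatch count from the NM tag (``None`` when the
    tag is absent). Gapped records are accepted but deletion positions carry
    no base call and insertions are dropped, with a warning.
    """
    warned_gaps = False
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if genome is not None:
            refs = set(af.references or ())
            missing = refs - set(genome.names)
            if missing:
                raise ValueError(
                    f"alignment header names chromosomes absent from the genome: {sorted(missing)}"
                )
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            if nm is None:
                logger.warning("read %s lacks an NM tag; mismatch count unknown", rec.query_name)
            cigar = rec.cigartuples or ()
            if all(op == 0 for op, _ in cigar):
                bases = rec.query_sequence
            else:
                if not warned_gaps:
                    warnings.warn(
                        "gapped alignment records present; indel positions are "
                        "ignored for pileup", stacklevel=2,
                    )
                    warned_gaps = True
                span = rec.reference_end - rec.reference_start
                block = ["-"] * span
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                    block[rpos - rec.reference_start] = rec.query_sequence[qpos]
                bases = "".join(block)
            record = AlignmentRecord(
                read_id=rec.query_name,
                library_id=library_id,
                chromosome=rec.reference_name,
                start=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                bases=bases.upper(),
                mismatch_count=nm,
            )
            if genome is not None:
                record.validate(genome)
            yield record


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: Genome,
    path: str | Path,
) -> int:
    """Write ungapped AlignmentRecords as SAM (records must be pre-sorted)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in genome.names],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.bases
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = genome.names.index(rec.chromosome)
            a.reference_start = rec.start - 1
            a.mapping_quality = 60
            a.cigartuples = [(0, len(rec.bases))]
            if rec.mismatch_count is not None:
                a.set_tag("NM", rec.mismatch_count)
            out.write(a)
            n += 1
    return n


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chromosome, start, end[, name[, score[, strand]]]) 1-based
    inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *rest = iv
            cols = [chrom, str(start - 1), str(end)] + [str(x) for x in rest]
            fh.write("\t".join(cols) + "\n")
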