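"""Shared fixtures: one default synthetic dataset and one full pipeline run
per test session, plus small hand-built references."""

import numpy as np
import pytest

from mitotx.config import PipelineConfig
from mitotx.genome_io import AlignmentRecord, Feature, FeatureTable, Genome, Library, LibrarySet
from mitotx.pipeline import run_pipeline
from mitotx.simulate import SimulationSpec, generate_dataset

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(SimulationSpec(seed=DEFAULT_SEED), out)


@pytest.fixture(scope="session")
def pipeline_result(default_dataset, tmp_path_factory):
    ds = default_dataset
    out = tmp_path_factory.mktemp("pipeline")
    paths = {**ds.mrna_paths, **ds.smallrna_paths}
    return run_pipeline(
        PipelineConfig(seed=DEFAULT_SEED),
        ds.genome_path,
        ds.annotation_path,
        ds.out_dir / "libraries.tsv",
        paths,
        out,
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Genome(
        {
            "c1": rng.choice(bases, size=3000).tobytes().decode(),
            "c2": rng.choice(bases, size=1500).tobytes().decode(),
        }
    )


@pytest.fixture
def four_libraries():
    return LibrarySet(
        [
            Library("mito1", "mito_enriched", 1, "mrna", 1_000_000),
            Library("mito2", "mito_enriched", 2, "mrna", 1_000_000),
            Library("tc1", "total_cellular", 1, "mrna", 1_000_000),
            Library("tc2", "total_cellular", 2, "mrna", 1_000_000),
        ]
    )


def make_read(chrom, start, strand, bases, lib="mito1", read_id="r", nm=0):
    return AlignmentRecord(read_id, lib, chrom, start, strand, bases, nm)


def random_reads(rng, genome, n, lib="mito1", length=50, mutate=0.0):
    """Random ungapped reads drawn from the genome, optional mismatches."""
    reads = []
    names = genome.names
    for i in range(n):
        chrom = names[int(rng.integers(len(names)))]
        L = len(genome[chrom])
        start = int(rng.integers(1, L - length + 2))
        bases = bytearray(genome[chrom][start - 1 : start - 1 + length].encode())
        nm = 0
        if mutate and rng.random() < mutate:
            off = int(rng.integers(length))
            old = chr(bases[off])
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
            bases[off] = ord(new)
            nm = 1
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(AlignmentRecord(f"{lib}_{i}", lib, chrom, start, strand, bases.decode(), nm))
    return reads
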