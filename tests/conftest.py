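import numpy as np
import pytest

from xrprofile import (
    Genome,
    GenomicInterval,
    ReadSet,
    SimLibraryConfig,
    SyntheticSpec,
    generate_dataset,
    simulate_matched_library,
)


def make_reads(rows):
    """rows: iterable of (chrom, start, end, strand[, name])."""
    chrom, start, end, strand, names = [], [], [], [], []
    for i, r in enumerate(rows):
        chrom.append(r[0])
        start.append(r[1])
        end.append(r[2])
        strand.append(r[3])
        names.append(r[4] if len(r) > 4 else f"r{i}")
    return ReadSet(
        np.array(chrom, dtype=object),
        np.array(start),
        np.array(end),
        np.array(strand),
        np.array(names, dtype=object),
        np.zeros(len(chrom)),
    )


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.4) -> Genome:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes = rng.choice(4, size=length, p=p)
    return Genome({"chr1": bases[codes].tobytes().decode()})


def random_reads(
    rng: np.random.Generator, genome: Genome, n: int, length: int = 27
) -> ReadSet:
    chroms = genome.names
    rows = []
    for i in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, len(genome[c]) - length))
        rows.append((c, s, s + length, "+" if rng.random() < 0.5 else "-", f"rr{i}"))
    return make_reads(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by unit tests."""
    spec = SyntheticSpec(seed=5, n_reads=20_000, n_genes=60, chrom_length=120_000)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_sim(small_dataset):
    sim, report = simulate_matched_library(
        small_dataset.reads, small_dataset.genome, SimLibraryConfig(seed=55)
    )
    return sim, report
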