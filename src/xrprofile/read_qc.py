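"""Quality-control statistics of excision-product reads.

Length distributions, positional mono- and dinucleotide frequencies along
reads of a fixed length, and the dinucleotide composition at the damage
site. In excision products of nucleotide excision repair the lesion
dinucleotide sits at a fixed distance from the 3' end: positions
(L-7, L-6) in 1-based read coordinates for a read of length L, i.e. the
20th/21st position of a 27-mer.

Position indexing throughout is 1-based along the read's 5'->3' sequence.
Reads with N at a queried window are excluded from that window's
denominator, not from the library.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .genome_io import DINUCLEOTIDES, Genome, N_DINUC, check_chromosomes
from .intervals import ReadSet

PYRIMIDINE_DINUCS = ("CC", "CT", "TC", "TT")


@dataclass(frozen=True)
class DamageSiteSpec:
    """Location of the damage dinucleotide within a read.

    ``offset3`` counts from the 3' end: the dinucleotide occupies 1-based
    positions (L - offset3, L - offset3 + 1). The default of 7 places it at
    positions 20-21 of a 27-mer, where UV photoproducts sit in excision
    products; it is configurable so the same code serves other damage
    chemistries. Reads shorter than ``min_length`` are skipped.
    """

    offset3: int = 7
    min_length: int = 9

    def positions(self, read_length: int) -> tuple[int, int]:
        p1 = read_length - self.offset3
        return p1, p1 + 1


@dataclass
class LengthHistogram:
    """Read-length counts and fractions, with the modal length and the
    fraction inside the primary (full-length product) window."""

    counts: dict[int, int]
    fractions: dict[int, float]
    total: int
    modal_length: int  # ties break toward the smaller length
    primary_window: tuple[int, int]
    primary_fraction: float

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame(
            {
                "length": lengths,
                "count": [self.counts[l] for l in lengths],
                "fraction": [self.fractions[l] for l in lengths],
            }
        )


@dataclass
class PositionalDinucProfile:
    """Fractions of the 16 dinucleotides at each start position 1..L-1 of
    reads of one exact length."""

    read_length: int
    matrix: pd.DataFrame  # index: 16 dinucleotides; columns: positions 1..L-1
    n_reads: int

    @property
    def pyrimidine_subset(self) -> pd.DataFrame:
        return self.matrix.loc[list(PYRIMIDINE_DINUCS)]

    def to_long_frame(self) -> pd.DataFrame:
        long = self.matrix.stack().rename("fraction").reset_index()
        long.columns = ["dinucleotide", "position", "fraction"]
        long.insert(0, "read_length", self.read_length)
        return long


@dataclass
class DamageSiteComposition:
    """Distribution over the 16 dinucleotides at the damage site."""

    fractions: pd.Series  # indexed by dinucleotide, sums to 1
    counts: pd.Series
    n_used: int
    n_skipped_short: int
    n_skipped_n: int
    read_length: int | None  # None = all lengths pooled
    spec: DamageSiteSpec = field(default_factory=DamageSiteSpec)

    @property
    def pyrimidine_share(self) -> float:
        return float(self.fractions[list(PYRIMIDINE_DINUCS)].sum())


# --------------------------------------------------------------------------
# Vectorized sequence-code helpers
# --------------------------------------------------------------------------

def read_base_codes(reads: ReadSet, genome: Genome, read_length: int) -> np.ndarray:
    """(n_reads x L) base-code matrix in 5'->3' read orientation.

    Only reads of exactly ``read_length`` may be passed. Codes: A=0 C=1 G=2
    T=3 N=4.
    """
    check_chromosomes(reads, genome)
    n = len(reads)
    out = np.empty((n, read_length), dtype=np.uint8)
    offs = np.arange(read_length)
    for chrom in set(reads.chrom.tolist()):
        enc = genome.encoded(chrom)
        for strand in ("+", "-"):
            mask = (reads.chrom == chrom) & (reads.strand == strand)
            if not mask.any():
                continue
            starts = reads.start[mask]
            ends = reads.end[mask]
            if (ends > len(enc)).any():
                raise InputError(f"read exceeds chromosome {chrom!r} bounds")
            if strand == "+":
                idx = starts[:, None] + offs
                out[mask] = enc[idx]
            else:
                idx = ends[:, None] - 1 - offs
                from .genome_io import _COMP

                out[mask] = _COMP[enc[idx]]
    return out


def damage_dinuc_ids(
    reads: ReadSet, genome: Genome, spec: DamageSiteSpec | None = None
) -> np.ndarray:
    """Damage-site dinucleotide id (0..15; 16 when N) for each read.

    Reads shorter than ``spec.min_length`` get id -1 (skipped).
    """
    spec = spec or DamageSiteSpec()
    check_chromosomes(reads, genome)
    n = len(reads)
    out = np.full(n, -1, dtype=np.int32)
    lengths = reads.lengths
    ok = lengths >= spec.min_length
    for chrom in set(reads.chrom.tolist()):
        for strand in ("+", "-"):
            mask = ok & (reads.chrom == chrom) & (reads.strand == strand)
            if not mask.any():
                continue
            if strand == "+":
                # dinucleotide starts offset3+1 bases before the read 3' end
                j = reads.end[mask] - spec.offset3 - 1
                out[mask] = genome.dinuc_plus(chrom)[j]
            else:
                j = reads.start[mask] + spec.offset3 - 1
                out[mask] = genome.dinuc_minus(chrom)[j]
    return out


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def length_distribution(
    reads: ReadSet, primary_window: tuple[int, int] = (25, 28)
) -> LengthHistogram:
    """Histogram of read lengths with modal length and primary-window mass."""
    if len(reads) == 0:
        raise InputError("length_distribution: empty read set")
    lengths, counts = np.unique(reads.lengths, return_counts=True)
    total = int(counts.sum())
    counts_d = {int(l): int(c) for l, c in zip(lengths, counts)}
    fracs = {l: c / total for l, c in counts_d.items()}
    # modal length; ties break toward the smaller length
    mode = int(lengths[np.argmax(counts)])
    lo, hi = primary_window
    primary = sum(c for l, c in counts_d.items() if lo <= l <= hi) / total
    return LengthHistogram(counts_d, fracs, total, mode, (lo, hi), primary)


def positional_nucleotide_frequencies(
    reads: ReadSet, genome: Genome, read_length: int
) -> pd.DataFrame:
    """4 x L matrix of A/C/G/T fractions at each 1-based read position.

    Uses only reads of exactly ``read_length``. Ns are excluded from the
    denominator of the positions they occupy.
    """
    sub = reads[reads.lengths == read_length]
    if len(sub) == 0:
        raise InputError(f"no reads of length {read_length}")
    codes = read_base_codes(sub, genome, read_length)
    freq = np.zeros((4, read_length))
    for p in range(read_length):
        cnt = np.bincount(codes[:, p], minlength=5).astype(float)
        denom = cnt[:4].sum()
        if denom > 0:
            freq[:, p] = cnt[:4] / denom
    return pd.DataFrame(freq, index=list("ACGT"), columns=np.arange(1, read_length + 1))


def positional_dinucleotide_frequencies(
    reads: ReadSet, genome: Genome, read_length: int
) -> PositionalDinucProfile:
    """Fractions of the 16 dinucleotides starting at positions 1..L-1."""
    sub = reads[reads.lengths == read_length]
    if len(sub) == 0:
        raise InputError(f"no reads of length {read_length}")
    codes = read_base_codes(sub, genome, read_length)
    a = codes[:, :-1].astype(np.int16)
    b = codes[:, 1:].astype(np.int16)
    ids = 4 * a + b
    ids[(a > 3) | (b > 3)] = N_DINUC
    freq = np.zeros((16, read_length - 1))
    for p in range(read_length - 1):
        cnt = np.bincount(ids[:, p], minlength=17).astype(float)
        denom = cnt[:16].sum()
        if denom > 0:
            freq[:, p] = cnt[:16] / denom
    matrix = pd.DataFrame(
        freq, index=DINUCLEOTIDES, columns=np.arange(1, read_length)
    )
    return PositionalDinucProfile(read_length, matrix, len(sub))


def damage_site_composition(
    reads: ReadSet,
    genome: Genome,
    spec: DamageSiteSpec | None = None,
    read_length: int | None = None,
) -> DamageSiteComposition:
    """Dinucleotide distribution at the damage site (positions L-7/L-6).

    ``read_length`` restricts to reads of one exact length; ``None`` pools
    all reads, each queried at its own damage position. Reads shorter than
    ``spec.min_length`` and reads with N at the site are skipped and
    reported.
    """
    spec = spec or DamageSiteSpec()
    sub = reads if read_length is None else reads[reads.lengths == read_length]
    if len(sub) == 0:
        raise InputError(
            "no reads to profile"
            + (f" of length {read_length}" if read_length is not None else "")
        )
    ids = damage_dinuc_ids(sub, genome, spec)
    n_short = int((ids == -1).sum())
    n_with_n = int((ids == N_DINUC).sum())
    valid = ids[(ids >= 0) & (ids < N_DINUC)]
    if valid.size == 0:
        raise InputError("no reads with a determinable damage-site dinucleotide")
    cnt = np.bincount(valid, minlength=16)
    counts = pd.Series(cnt, index=DINUCLEOTIDES, name="count")
    fracs = counts / counts.sum()
    return DamageSiteComposition(
        fractions=fracs.rename("fraction"),
        counts=counts,
        n_used=int(cnt.sum()),
        n_skipped_short=n_short,
        n_skipped_n=n_with_n,
        read_length=read_length,
        spec=spec,
    )
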