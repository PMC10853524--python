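"""Core genomic interval types and the columnar read container.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted at the parsing boundary (see :mod:`xrprofile.genome_io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise InputError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise InputError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadRecord:
    """One aligned excision-product read. Reads always have a definite strand."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise InputError("a read must be on strand '+' or '-'")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span with a stable identifier."""

    id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise InputError(f"gene {self.id} must be stranded")


@dataclass(frozen=True)
class ChromatinSegment:
    """One segment of a chromatin-state segmentation (unstranded)."""

    interval: GenomicInterval
    state: str


class ReadSet:
    """Columnar container for aligned reads.

    Stores chrom/start/end/strand (and optionally name/score) as numpy
    arrays so that counting and sequence extraction stay vectorized.
    Iteration yields :class:`ReadRecord` objects.
    """

    __slots__ = ("chrom", "start", "end", "strand", "name", "score")

    def __init__(
        self,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,
        name: np.ndarray | None = None,
        score: np.ndarray | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = np.asarray(strand, dtype="<U1")
        n = len(self.chrom)
        for arr in (self.start, self.end, self.strand):
            if len(arr) != n:
                raise InputError("ReadSet column lengths differ")
        if name is not None:
            name = np.asarray(name, dtype=object)
            if len(name) != n:
                raise InputError("ReadSet column lengths differ")
        if score is not None:
            score = np.asarray(score, dtype=np.float64)
            if len(score) != n:
                raise InputError("ReadSet column lengths differ")
        self.name = name
        self.score = score
        if n:
            if not np.isin(self.strand, ("+", "-")).all():
                raise InputError("reads must be on strand '+' or '-'")
            if (self.start < 0).any() or (self.end <= self.start).any():
                raise InputError("reads must satisfy 0 <= start < end")

    # -- construction -------------------------------------------------
    @classmethod
    def empty(cls) -> "ReadSet":
        return cls(
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=np.int64),
            np.array([], dtype="<U1"),
        )

    @classmethod
    def from_records(cls, records: Sequence[ReadRecord]) -> "ReadSet":
        if not records:
            return cls.empty()
        return cls(
            np.array([r.interval.chrom for r in records], dtype=object),
            np.array([r.interval.start for r in records], dtype=np.int64),
            np.array([r.interval.end for r in records], dtype=np.int64),
            np.array([r.interval.strand for r in records], dtype="<U1"),
            np.array([r.name for r in records], dtype=object),
            np.array([r.score for r in records], dtype=np.float64),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadSet":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(dtype=np.int64),
            df["end"].to_numpy(dtype=np.int64),
            df["strand"].to_numpy(dtype="<U1"),
            df["name"].to_numpy(dtype=object) if "name" in df else None,
            df["score"].to_numpy(dtype=np.float64) if "score" in df else None,
        )

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "name": self.name if self.name is not None else np.full(n, ".", dtype=object),
                "score": self.score if self.score is not None else np.zeros(n),
                "strand": self.strand,
            }
        )

    # -- container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self.chrom)

    def __iter__(self) -> Iterator[ReadRecord]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, key):
        if isinstance(key, (int, np.integer)):
            i = int(key)
            return ReadRecord(
                GenomicInterval(
                    str(self.chrom[i]), int(self.start[i]), int(self.end[i]), str(self.strand[i])
                ),
                str(self.name[i]) if self.name is not None else ".",
                float(self.score[i]) if self.score is not None else 0.0,
            )
        # slice or boolean/integer mask
        return ReadSet(
            self.chrom[key],
            self.start[key],
            self.end[key],
            self.strand[key],
            self.name[key] if self.name is not None else None,
            self.score[key] if self.score is not None else None,
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_names(self) -> list[str]:
        return sorted(set(self.chrom.tolist()))

    @classmethod
    def concat(cls, parts: Sequence["ReadSet"]) -> "ReadSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        has_names = all(p.name is not None for p in parts)
        has_scores = all(p.score is not None for p in parts)
        return cls(
            np.concatenate([p.chrom for p in parts]),
            np.concatenate([p.start for p in parts]),
            np.concatenate([p.end for p in parts]),
            np.concatenate([p.strand for p in parts]),
            np.concatenate([p.name for p in parts]) if has_names else None,
            np.concatenate([p.score for p in parts]) if has_scores else None,
        )

    def equals(self, other: "ReadSet", check_names: bool = True) -> bool:
        if len(self) != len(other):
            return False
        same = (
            (self.chrom == other.chrom).all()
            and (self.start == other.start).all()
            and (self.end == other.end).all()
            and (self.strand == other.strand).all()
        )
        if not same:
            return False
        if check_names and self.name is not None and other.name is not None:
            return bool((self.name == other.name).all())
        return True


def as_interval_arrays(features) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalize a feature collection to (chrom, start, end, strand) arrays.

    Accepts a :class:`ReadSet`, or any iterable of objects that are either
    :class:`GenomicInterval` or expose an ``.interval`` attribute
    (:class:`GeneModel`, :class:`ChromatinSegment`, :class:`ReadRecord`).
    """
    if isinstance(features, ReadSet):
        return features.chrom, features.start, features.end, features.strand
    ivs = []
    for f in features:
        iv = f if isinstance(f, GenomicInterval) else f.interval
        ivs.append(iv)
    if not ivs:
        z = np.array([], dtype=object)
        return z, np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype="<U1")
    return (
        np.array([iv.chrom for iv in ivs], dtype=object),
        np.array([iv.start for iv in ivs], dtype=np.int64),
        np.array([iv.end for iv in ivs], dtype=np.int64),
        np.array([iv.strand for iv in ivs], dtype="<U1"),
    )
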