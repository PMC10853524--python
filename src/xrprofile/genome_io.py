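"""Readers/writers for the standard formats the pipeline touches.

FASTA genomes, BED6 read files, GFF3/BED gene annotations, chromatin-state
BED segmentations, chrom.sizes tables and RPM-normalized bedGraph output.
Also provides strand-aware sequence access and coordinate-based read
deduplication.
"""
from __future__ import annotations

import logging
import re
from collections.abc import Mapping
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .intervals import ChromatinSegment, GeneModel, GenomicInterval, ReadSet

logger = logging.getLogger(__name__)

# Base encoding: A=0, C=1, G=2, T=3, N=4. Anything else is rejected on load.
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # complement in code space
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]
N_DINUC = 16  # sentinel id for dinucleotides containing N


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


class Genome(Mapping):
    """In-memory genome: chromosome name -> uppercase sequence.

    Caches encoded base arrays plus per-position dinucleotide identities on
    both strands, which the QC and simulation modules use for vectorized
    sequence lookups.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)
        self._enc: dict[str, np.ndarray] = {}
        self._dplus: dict[str, np.ndarray] = {}
        self._dminus: dict[str, np.ndarray] = {}
        self._nprefix: dict[str, np.ndarray] = {}

    # Mapping protocol --------------------------------------------------
    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    # Cached encodings ---------------------------------------------------
    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._enc:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._enc[chrom] = _CODES[arr]
        return self._enc[chrom]

    def dinuc_plus(self, chrom: str) -> np.ndarray:
        """Dinucleotide id (0..15, or 16 if N) starting at each + strand position."""
        if chrom not in self._dplus:
            e = self.encoded(chrom)
            a, b = e[:-1], e[1:]
            ids = (4 * a.astype(np.int16) + b).astype(np.int16)
            ids[(a > 3) | (b > 3)] = N_DINUC
            self._dplus[chrom] = ids
        return self._dplus[chrom]

    def dinuc_minus(self, chrom: str) -> np.ndarray:
        """id of revcomp(genome[j:j+2]): the dinucleotide a minus-strand read
        reports when its damage window starts at genome position j."""
        if chrom not in self._dminus:
            e = self.encoded(chrom)
            a, b = e[:-1], e[1:]
            ids = (4 * _COMP[b].astype(np.int16) + _COMP[a]).astype(np.int16)
            ids[(a > 3) | (b > 3)] = N_DINUC
            self._dminus[chrom] = ids
        return self._dminus[chrom]

    def n_prefix(self, chrom: str) -> np.ndarray:
        """Prefix sums of the N indicator; window [s, e) has N iff P[e] > P[s]."""
        if chrom not in self._nprefix:
            e = self.encoded(chrom)
            self._nprefix[chrom] = np.concatenate(
                [[0], np.cumsum(e == 4, dtype=np.int64)]
            )
        return self._nprefix[chrom]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA genome, uppercasing and validating the ACGTN alphabet.

    Chromosome names are the first whitespace-delimited token of each header.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise InputError(f"{path}: duplicate chromosome name {name!r}")
        s = str(rec.seq).upper()
        if not s:
            raise InputError(f"{path}: empty sequence for {name!r}")
        m = re.search(r"[^ACGTN]", s)
        if m:
            raise InputError(
                f"{path}: illegal character {s[m.start()]!r} in {name!r} "
                f"at position {m.start() + 1}"
            )
        seqs[name] = s
    if not seqs:
        raise InputError(f"{path}: no FASTA records found")
    return Genome(seqs)


def write_fasta(genome: Mapping, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            s = genome[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path} line {ln}: expected two tab-separated columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sizes:
            fh.write(f"{name}\t{sizes[name]}\n")


# --------------------------------------------------------------------------
# BED6 reads
# --------------------------------------------------------------------------

def read_bed6(path: str | Path) -> ReadSet:
    """Read aligned reads from a BED6 file (>= 6 tab-separated columns).

    File order is preserved. Strand must be ``+`` or ``-``; ``start < end``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, keep_default_na=False,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return ReadSet.empty()
    if df.shape[1] < 6:
        raise InputError(f"{path}: BED6 requires >= 6 columns, found {df.shape[1]}")
    try:
        start = pd.to_numeric(df[1], errors="raise").to_numpy(np.int64)
        end = pd.to_numeric(df[2], errors="raise").to_numpy(np.int64)
        score = pd.to_numeric(df[4].replace(".", "0"), errors="raise").to_numpy(np.float64)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: non-numeric coordinate or score field ({exc})")
    strand = df[5].to_numpy(dtype="<U1")
    bad = ~np.isin(strand, ("+", "-"))
    if bad.any():
        ln = int(np.flatnonzero(bad)[0]) + 1
        raise InputError(f"{path} line {ln}: read strand must be '+' or '-', got {strand[bad][0]!r}")
    bad = start >= end
    if bad.any():
        ln = int(np.flatnonzero(bad)[0]) + 1
        raise InputError(f"{path} line {ln}: start >= end")
    if (start < 0).any():
        ln = int(np.flatnonzero(start < 0)[0]) + 1
        raise InputError(f"{path} line {ln}: negative start")
    return ReadSet(
        df[0].to_numpy(dtype=object), start, end, strand,
        df[3].to_numpy(dtype=object), score,
    )


def write_bed6(reads: ReadSet, path: str | Path) -> None:
    df = reads.to_frame()
    # scores render as integers when integral, matching common BED output
    score = df["score"]
    if (score == score.round()).all():
        df["score"] = score.astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# Gene annotation
# --------------------------------------------------------------------------

_BIOTYPE_KEYS = ("biotype", "gene_biotype", "locus_type")


def read_gene_annotation(
    path: str | Path,
    format: str = "gff3",
    biotype_filter: str | None = "protein_coding",
    biotype_key: str | None = None,
) -> list[GeneModel]:
    """Load gene models from GFF3 (``gene`` features) or BED6.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Genes without a definite strand are dropped with a logged warning count;
    duplicate gene IDs are an error. ``biotype_filter`` is applied to the
    configured attribute key for GFF3 (BED files carry no biotype and are
    not filtered).
    """
    path = Path(path)
    if format not in ("gff3", "bed6"):
        raise InputError(f"unknown annotation format {format!r}")
    if format == "bed6":
        reads_like = read_bed6(path)  # same column layout; strand already validated
        genes = [
            GeneModel(
                str(reads_like.name[i]),
                GenomicInterval(
                    str(reads_like.chrom[i]),
                    int(reads_like.start[i]),
                    int(reads_like.end[i]),
                    str(reads_like.strand[i]),
                ),
                "",
            )
            for i in range(len(reads_like))
        ]
        _check_unique_ids(genes, path)
        return genes

    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
        )
    except ValueError as exc:
        raise InputError(f"{path}: {exc}")
    keys = (biotype_key,) if biotype_key else _BIOTYPE_KEYS
    genes: list[GeneModel] = []
    n_unstranded = 0
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            n_unstranded += 1
            continue
        biotype = ""
        for k in keys:
            if k in feat.attributes:
                biotype = feat.attributes[k][0]
                break
        if biotype_filter is not None and biotype != biotype_filter:
            continue
        genes.append(
            GeneModel(
                feat.id,
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand),
                biotype,
            )
        )
    if n_unstranded:
        logger.warning("%s: dropped %d gene(s) without strand", path, n_unstranded)
    _check_unique_ids(genes, path)
    return genes


def _check_unique_ids(genes: Iterable[GeneModel], path) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise InputError(f"{path}: duplicate gene ID {g.id!r}")
        seen.add(g.id)


def write_gff3(
    genes: Iterable[GeneModel],
    path: str | Path,
    transcripts: pd.DataFrame | None = None,
) -> None:
    """Write gene (and optionally mRNA) rows as GFF3.

    ``transcripts`` may carry columns transcript_id/gene_id/length to emit
    mRNA children anchored at the gene 5' end.
    """
    by_gene: dict[str, pd.DataFrame] = {}
    if transcripts is not None:
        by_gene = {g: sub for g, sub in transcripts.groupby("gene_id")}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.id}"
            if g.biotype:
                attrs += f";biotype={g.biotype}"
            fh.write(
                f"{iv.chrom}\txrprofile\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for _, t in by_gene.get(g.id, pd.DataFrame()).iterrows():
                tlen = int(t["length"])
                if iv.strand == "+":
                    ts, te = iv.start + 1, iv.start + tlen
                else:
                    ts, te = iv.end - tlen + 1, iv.end
                fh.write(
                    f"{iv.chrom}\txrprofile\tmRNA\t{ts}\t{te}\t.\t{iv.strand}\t.\t"
                    f"ID={t['transcript_id']};Parent={g.id}\n"
                )


# --------------------------------------------------------------------------
# Chromatin states
# --------------------------------------------------------------------------

def read_chromatin_states(path: str | Path) -> list[ChromatinSegment]:
    """Read a BED file with the state label in column 4.

    Segments must be non-overlapping; an overlap is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 4:
        raise InputError(f"{path}: chromatin-state BED requires >= 4 columns")
    start = pd.to_numeric(df[1]).to_numpy(np.int64)
    end = pd.to_numeric(df[2]).to_numpy(np.int64)
    segs = [
        ChromatinSegment(
            GenomicInterval(str(c), int(s), int(e), "."), str(lab)
        )
        for c, s, e, lab in zip(df[0], start, end, df[3])
    ]
    _validate_disjoint(segs, path)
    return segs


def _validate_disjoint(segs: list[ChromatinSegment], path) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segs:
        by_chrom.setdefault(seg.interval.chrom, []).append(
            (seg.interval.start, seg.interval.end)
        )
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InputError(
                    f"{path}: overlapping segments on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )


def write_chromatin_states(segs: Iterable[ChromatinSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segs:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state}\n")


# --------------------------------------------------------------------------
# Sequence access, dedup, cross-checks
# --------------------------------------------------------------------------

def fetch_sequence(genome: Mapping, interval: GenomicInterval) -> str:
    """Return the 5'->3' sequence of the interval's strand of origin.

    Forward slice for ``+`` (and ``.``); reverse complement for ``-``.
    """
    if interval.chrom not in genome:
        raise InputError(f"unknown chromosome {interval.chrom!r}")
    seq = genome[interval.chrom]
    if interval.end > len(seq):
        raise InputError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds chromosome length {len(seq)}"
        )
    s = seq[interval.start : interval.end]
    return reverse_complement(s) if interval.strand == "-" else s


def check_chromosomes(reads, genome: Mapping) -> None:
    """Fail loudly when read chromosomes are absent from the genome.

    Emits the full mismatch report before raising, so that a naming mismatch
    (e.g. 'Chr1' vs 'chr1') never silently produces zero counts.
    """
    names = set(reads.chrom.tolist()) if isinstance(reads, ReadSet) else set(reads)
    missing = sorted(n for n in names if n not in genome)
    if missing:
        logger.error("chromosomes present in reads but absent from genome: %s", missing)
        raise InputError(
            "chromosome name mismatch; reads reference unknown chromosomes: "
            + ", ".join(missing)
        )


def deduplicate_reads(reads: ReadSet) -> tuple[ReadSet, int]:
    """Coordinate-based duplicate removal.

    At most one record per (chrom, start, end, strand); the first occurrence
    is kept and output is sorted by that key. Returns (reads, n_removed).
    """
    if len(reads) == 0:
        return reads, 0
    df = reads.to_frame()
    kept = df.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    kept = kept.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    return ReadSet.from_frame(kept.reset_index(drop=True)), len(df) - len(kept)


# --------------------------------------------------------------------------
# bedGraph output
# --------------------------------------------------------------------------

def write_bedgraph_rpm(
    reads: ReadSet,
    chrom_sizes: Mapping,
    path: str | Path,
    split_by_strand: bool = False,
) -> list[Path]:
    """Write per-base coverage scaled to reads-per-million as bedGraph.

    Adjacent equal-value runs are merged and zero runs omitted. With
    ``split_by_strand`` two files (``.plus`` / ``.minus`` inserted before the
    suffix) are written; the RPM denominator stays the full library size.
    Returns the list of paths written.
    """
    if len(reads) == 0:
        raise InputError("cannot write bedGraph for an empty read set (RPM undefined)")
    check_chromosomes(reads, chrom_sizes)
    scale = 1e6 / len(reads)
    path = Path(path)
    if split_by_strand:
        out = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            sub = reads[reads.strand == strand]
            p = path.with_name(path.stem + f".{tag}" + path.suffix)
            _write_one_bedgraph(sub, chrom_sizes, p, scale)
            out.append(p)
        return out
    _write_one_bedgraph(reads, chrom_sizes, path, scale)
    return [path]


def _write_one_bedgraph(reads: ReadSet, chrom_sizes: Mapping, path: Path, scale: float) -> None:
    with open(path, "w") as fh:
        for chrom in chrom_sizes:
            size = int(chrom_sizes[chrom]) if not isinstance(chrom_sizes, Genome) else len(
                chrom_sizes[chrom]
            )
            mask = reads.chrom == chrom
            if not mask.any():
                continue
            diff = np.zeros(size + 1, dtype=np.int64)
            np.add.at(diff, reads.start[mask], 1)
            np.add.at(diff, np.minimum(reads.end[mask], size), -1)
            cov = np.cumsum(diff[:-1])
            change = np.flatnonzero(np.diff(cov))
            run_starts = np.concatenate([[0], change + 1])
            run_ends = np.concatenate([change + 1, [size]])
            vals = cov[run_starts]
            for s, e, v in zip(run_starts, run_ends, vals):
                if v > 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v * scale:.6g}\n")
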