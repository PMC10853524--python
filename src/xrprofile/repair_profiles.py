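"""Normalized-repair quantification.

The central quantity everywhere is *normalized repair*: the RPKM of real
excision-repair reads over a feature divided by the RPKM of the
sequence-content-matched simulated background over the same feature.
Values above 1 mean more repair than the damage opportunity of the local
sequence would predict.

Strand conventions: the excised oligonucleotide aligns to its strand of
origin, so for a gene on strand ``+`` the template (transcribed) strand is
``-``. Reads on the strand *opposite* the gene are therefore TS
(transcription-coupled) repair events; same-strand reads are NTS.

Metagene binning: each gene's span is extended by half its length on both
sides and the 2L-long region is cut into ``n_bins`` equal bins (body =
central half). Within the metagene a read is assigned to the single bin
containing its midpoint, so per-gene bin counts are conserved; whole-gene
and segment counts use >=1 bp overlap counting (``count_overlaps``),
matching interval-intersection semantics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .intervals import ChromatinSegment, GeneModel, ReadSet, as_interval_arrays

logger = logging.getLogger(__name__)

STRAND_MODES = ("same", "opposite", "ignore")
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def rpkm(count, length_bp, library_total):
    """Reads per kilobase per million mapped reads.

    ``count / ((length_bp / 1e3) * (library_total / 1e6))``; array-friendly.
    """
    length_bp = np.asarray(length_bp, dtype=float)
    library_total = float(library_total)
    if np.any(length_bp <= 0):
        raise InputError("rpkm: length_bp must be > 0")
    if library_total <= 0:
        raise InputError("rpkm: library_total must be > 0")
    out = np.asarray(count, dtype=float) / ((length_bp / 1e3) * (library_total / 1e6))
    return out if out.ndim else float(out)


def count_overlaps(
    features,
    reads: ReadSet,
    strand_mode: str = "same",
    min_overlap: int = 1,
) -> np.ndarray:
    """Per-feature read counts under a strand rule.

    A read counts toward *every* feature it overlaps by at least
    ``min_overlap`` bp. ``strand_mode``: ``same`` (read strand equals the
    feature strand), ``opposite``, or ``ignore``. Implemented with sorted
    coordinate arrays and binary search; exact for any ``min_overlap``.
    """
    if strand_mode not in STRAND_MODES:
        raise InputError(f"unknown strand_mode {strand_mode!r}")
    fch, fs, fe, fstr = as_interval_arrays(features)
    n = len(fch)
    counts = np.zeros(n, dtype=np.int64)
    if n == 0 or len(reads) == 0:
        return counts
    keep = reads.lengths >= min_overlap  # shorter reads can never qualify
    groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(reads.chrom[keep].tolist()):
        for strand in ("+", "-"):
            m = keep & (reads.chrom == chrom) & (reads.strand == strand)
            if m.any():
                groups[(chrom, strand)] = (
                    np.sort(reads.start[m]),
                    np.sort(reads.end[m]),
                )
    flip = {"+": "-", "-": "+"}
    for (chrom, strand), (starts, ends) in groups.items():
        if strand_mode == "ignore":
            mask = fch == chrom
        elif strand_mode == "same":
            mask = (fch == chrom) & (fstr == strand)
        else:
            mask = (fch == chrom) & (fstr == flip[strand])
        if not mask.any():
            continue
        s, e = fs[mask], fe[mask]
        a = np.searchsorted(starts, e - min_overlap, side="right")
        b = np.searchsorted(ends, s + min_overlap - 1, side="right")
        c = np.maximum(a - b, 0)
        c[(e - s) < min_overlap] = 0
        counts[mask] += c
    return counts


# --------------------------------------------------------------------------
# Metagene profiles
# --------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Pooled, background-normalized repair along genes and flanks.

    ``tables[cls]`` (cls in {"TS", "NTS"}) has one row per bin with pooled
    real/sim counts, pooled bin length, both RPKMs and the normalized
    repair (NaN where the pooled simulated count is zero).
    """

    n_bins: int
    flank_fraction: float
    bin_layout: str
    tables: dict[str, pd.DataFrame]
    n_genes_used: int
    skipped_genes: list[str]
    body_slice: tuple[int, int]  # bin index range [lo, hi) covering gene bodies

    def normalized(self, cls: str) -> np.ndarray:
        return self.tables[cls]["normalized"].to_numpy()

    def ts_nts_ratio(self) -> np.ndarray:
        return self.normalized("TS") / self.normalized("NTS")

    def mean_body_ts_nts(self) -> float:
        lo, hi = self.body_slice
        r = self.ts_nts_ratio()[lo:hi]
        return float(np.nanmean(r))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cls, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "strand_class", cls)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _gene_bin_edges(gene: GeneModel, n_bins: int, flank_fraction: float, layout: str):
    """Integer bin edges over the extended gene region (5'-most bin first
    handled by the caller reversing minus-strand genes)."""
    iv = gene.interval
    L = iv.length
    flank = int(round(L * flank_fraction))
    if layout == "inclusive":
        ext_start, ext_end = iv.start - flank, iv.end + flank
        edges = ext_start + np.rint(
            np.linspace(0, ext_end - ext_start, n_bins + 1)
        ).astype(np.int64)
        return edges, (ext_start, ext_end)
    # 'appended': n_bins over the gene body, plus n_bins//4 bins per flank
    fb = max(n_bins // 4, 1)
    up = (iv.start - flank) + np.rint(np.linspace(0, flank, fb + 1)).astype(np.int64)
    body = iv.start + np.rint(np.linspace(0, L, n_bins + 1)).astype(np.int64)
    down = iv.end + np.rint(np.linspace(0, flank, fb + 1)).astype(np.int64)
    edges = np.concatenate([up[:-1], body, down[1:]])
    return edges, (iv.start - flank, iv.end + flank)


def metagene_profile(
    genes: Sequence[GeneModel],
    real_reads: ReadSet,
    sim_reads: ReadSet,
    chrom_sizes: Mapping,
    n_bins: int = 100,
    flank_fraction: float = 0.5,
    bin_layout: str = "inclusive",
    real_total: int | None = None,
    sim_total: int | None = None,
) -> MetageneProfile:
    """Pooled TS/NTS metagene profile over genes with half-length flanks.

    Genes whose extended region leaves the chromosome (or is shorter than
    the number of bins) are skipped and reported. Counts are pooled across
    genes per bin index (sum of counts and of bin lengths), each pooled
    count is RPKM-normalized with the respective library total, and
    normalized repair is the real/sim RPKM ratio per bin.
    """
    if bin_layout not in ("inclusive", "appended"):
        raise InputError(f"unknown bin_layout {bin_layout!r}")
    if not genes:
        raise InputError("metagene_profile: no genes supplied")
    real_total = real_total if real_total is not None else len(real_reads)
    sim_total = sim_total if sim_total is not None else len(sim_reads)
    if real_total == 0 or sim_total == 0:
        raise InputError("metagene_profile: empty library")

    sizes = (
        chrom_sizes.chrom_sizes() if hasattr(chrom_sizes, "chrom_sizes") else dict(chrom_sizes)
    )
    # sorted read midpoints per (chrom, strand) per library
    def midindex(reads: ReadSet):
        out = {}
        mids = (reads.start + reads.end) // 2
        for chrom in set(reads.chrom.tolist()):
            for strand in ("+", "-"):
                m = (reads.chrom == chrom) & (reads.strand == strand)
                if m.any():
                    out[(chrom, strand)] = np.sort(mids[m])
        return out

    mids = {"real": midindex(real_reads), "sim": midindex(sim_reads)}

    if bin_layout == "inclusive":
        total_bins = n_bins
        body_lo = int(round(n_bins * flank_fraction / (1 + 2 * flank_fraction)))
        body_hi = total_bins - body_lo
    else:
        fb = max(n_bins // 4, 1)
        total_bins = n_bins + 2 * fb
        body_lo, body_hi = fb, fb + n_bins

    counts = {
        (lib, cls): np.zeros(total_bins, dtype=np.int64)
        for lib in ("real", "sim")
        for cls in ("TS", "NTS")
    }
    pooled_len = np.zeros(total_bins, dtype=np.int64)
    used = 0
    skipped: list[str] = []
    flip = {"+": "-", "-": "+"}
    for gene in genes:
        iv = gene.interval
        if iv.chrom not in sizes:
            skipped.append(gene.id)
            continue
        edges, (ext_s, ext_e) = _gene_bin_edges(gene, n_bins, flank_fraction, bin_layout)
        if ext_s < 0 or ext_e > sizes[iv.chrom] or np.any(np.diff(edges) < 0) or (
            ext_e - ext_s
        ) < total_bins:
            skipped.append(gene.id)
            continue
        used += 1
        blen = np.diff(edges)
        pooled_len += blen[::-1] if iv.strand == "-" else blen
        for lib in ("real", "sim"):
            for cls in ("TS", "NTS"):
                read_strand = flip[iv.strand] if cls == "TS" else iv.strand
                arr = mids[lib].get((iv.chrom, read_strand))
                if arr is None:
                    continue
                lo = np.searchsorted(arr, ext_s, side="left")
                hi = np.searchsorted(arr, ext_e, side="left")
                if hi == lo:
                    continue
                idx = np.searchsorted(edges, arr[lo:hi], side="right") - 1
                idx = idx[(idx >= 0) & (idx < total_bins)]
                c = np.bincount(idx, minlength=total_bins)
                counts[(lib, cls)] += c[::-1] if iv.strand == "-" else c
    if used == 0:
        raise InputError("metagene_profile: no usable genes (all skipped)")
    if skipped:
        logger.info("metagene_profile: skipped %d gene(s)", len(skipped))

    tables = {}
    for cls in ("TS", "NTS"):
        real_c = counts[("real", cls)]
        sim_c = counts[("sim", cls)]
        with np.errstate(divide="ignore", invalid="ignore"):
            safe_len = np.where(pooled_len > 0, pooled_len, np.nan)
            r_rpkm = real_c / ((safe_len / 1e3) * (real_total / 1e6))
            s_rpkm = sim_c / ((safe_len / 1e3) * (sim_total / 1e6))
            norm = np.where(sim_c > 0, r_rpkm / s_rpkm, np.nan)
        tables[cls] = pd.DataFrame(
            {
                "bin": np.arange(1, total_bins + 1),
                "real_count": real_c,
                "sim_count": sim_c,
                "bin_bp": pooled_len,
                "rpkm_real": r_rpkm,
                "rpkm_sim": s_rpkm,
                "normalized": norm,
            }
        )
    return MetageneProfile(
        n_bins=n_bins,
        flank_fraction=flank_fraction,
        bin_layout=bin_layout,
        tables=tables,
        n_genes_used=used,
        skipped_genes=skipped,
        body_slice=(body_lo, body_hi),
    )


# --------------------------------------------------------------------------
# Per-gene TS/NTS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRepairRecord:
    """Per-gene normalized repair on both strands and their log2 ratio."""

    gene_id: str
    real_ts: int
    real_nts: int
    sim_ts: int
    sim_nts: int
    norm_ts: float
    norm_nts: float
    log2_ts_nts: float
    defined: bool


def gene_ts_nts(
    genes: Sequence[GeneModel],
    real_reads: ReadSet,
    sim_reads: ReadSet,
    real_total: int | None = None,
    sim_total: int | None = None,
) -> pd.DataFrame:
    """Per-gene normalized TS and NTS repair and log2(TS/NTS).

    Whole-gene spans, >=1 bp overlap counting. Genes with any zero among
    the four counts keep their row but are flagged ``defined=False`` and
    excluded from summary statistics downstream.
    """
    if not genes:
        raise InputError("gene_ts_nts: no genes supplied")
    real_total = real_total if real_total is not None else len(real_reads)
    sim_total = sim_total if sim_total is not None else len(sim_reads)
    if real_total == 0 or sim_total == 0:
        raise InputError("gene_ts_nts: empty library")
    lengths = np.array([g.interval.length for g in genes], dtype=float)
    real_ts = count_overlaps(genes, real_reads, "opposite")
    real_nts = count_overlaps(genes, real_reads, "same")
    sim_ts = count_overlaps(genes, sim_reads, "opposite")
    sim_nts = count_overlaps(genes, sim_reads, "same")
    rk = lambda c, tot: np.asarray(rpkm(c, lengths, tot))
    r_ts, r_nts = rk(real_ts, real_total), rk(real_nts, real_total)
    s_ts, s_nts = rk(sim_ts, sim_total), rk(sim_nts, sim_total)
    defined = (real_ts > 0) & (real_nts > 0) & (sim_ts > 0) & (sim_nts > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_ts = np.where(sim_ts > 0, r_ts / s_ts, np.nan)
        norm_nts = np.where(sim_nts > 0, r_nts / s_nts, np.nan)
        log2_ratio = np.where(defined, np.log2(norm_ts / norm_nts), np.nan)
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genes],
            "strand": [g.interval.strand for g in genes],
            "length_bp": lengths.astype(np.int64),
            "real_ts": real_ts,
            "real_nts": real_nts,
            "sim_ts": sim_ts,
            "sim_nts": sim_nts,
            "rpkm_real_ts": r_ts,
            "rpkm_real_nts": r_nts,
            "rpkm_sim_ts": s_ts,
            "rpkm_sim_nts": s_nts,
            "norm_ts": norm_ts,
            "norm_nts": norm_nts,
            "log2_ts_nts": log2_ratio,
            "defined": defined,
        }
    )


@dataclass
class TsNtsSummary:
    """Boxplot-ready summary of per-gene log2 TS/NTS ratios."""

    summary: pd.DataFrame  # one row per library label
    long_table: pd.DataFrame  # gene-level values, labeled
    comparison_p: float | None = None  # Mann-Whitney between the two labels


def ts_nts_distribution_summary(
    records: pd.DataFrame,
    comparison_records: pd.DataFrame | None = None,
    label: str = "library",
    comparison_label: str = "comparison",
) -> TsNtsSummary:
    """Quartile summary of defined per-gene log2 TS/NTS ratios; optional
    two-sample comparison of the two distributions."""

    def one(df: pd.DataFrame, lab: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        vals = df.loc[df["defined"], "log2_ts_nts"].to_numpy(dtype=float)
        if vals.size == 0:
            raise InputError(f"no defined TS/NTS ratios for {lab!r}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        s = pd.DataFrame(
            {
                "label": [lab],
                "n": [vals.size],
                "q1": [q1],
                "median": [med],
                "q3": [q3],
                "mean": [vals.mean()],
            }
        )
        lt = pd.DataFrame(
            {"label": lab, "gene_id": df.loc[df["defined"], "gene_id"], "log2_ts_nts": vals}
        )
        return s, lt

    s1, l1 = one(records, label)
    if comparison_records is None:
        return TsNtsSummary(s1, l1)
    s2, l2 = one(comparison_records, comparison_label)
    p = float(
        stats.mannwhitneyu(
            l1["log2_ts_nts"], l2["log2_ts_nts"], alternative="two-sided"
        ).pvalue
    )
    return TsNtsSummary(
        pd.concat([s1, s2], ignore_index=True),
        pd.concat([l1, l2], ignore_index=True),
        p,
    )


# --------------------------------------------------------------------------
# Chromatin states
# --------------------------------------------------------------------------

@dataclass
class StateRepairTable:
    """Segment-level normalized repair grouped by chromatin state."""

    segments: pd.DataFrame  # state, chrom, start, end, length, real, sim, normalized
    n_excluded_zero_sim: int
    excluded_states: list[str]

    @property
    def vectors(self) -> dict[str, np.ndarray]:
        ok = self.segments[self.segments["normalized"].notna()]
        return {
            state: sub["normalized"].to_numpy(dtype=float)
            for state, sub in ok.groupby("state", sort=True)
        }

    def state_means(self) -> pd.Series:
        ok = self.segments[self.segments["normalized"].notna()]
        return ok.groupby("state")["normalized"].mean()


def chromatin_state_repair(
    segments: Sequence[ChromatinSegment],
    real_reads: ReadSet,
    sim_reads: ReadSet,
    real_total: int | None = None,
    sim_total: int | None = None,
) -> StateRepairTable:
    """Strandless normalized repair per chromatin-state segment.

    Segments with zero simulated count get NaN and are excluded from the
    per-state vectors (counted); states with no usable segment are dropped
    with a warning.
    """
    if not segments:
        raise InputError("chromatin_state_repair: no segments supplied")
    real_total = real_total if real_total is not None else len(real_reads)
    sim_total = sim_total if sim_total is not None else len(sim_reads)
    if real_total == 0 or sim_total == 0:
        raise InputError("chromatin_state_repair: empty library")
    lens = np.array([s.interval.length for s in segments], dtype=float)
    real_c = count_overlaps(segments, real_reads, "ignore")
    sim_c = count_overlaps(segments, sim_reads, "ignore")
    r = np.asarray(rpkm(real_c, lens, real_total))
    s = np.asarray(rpkm(sim_c, lens, sim_total))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(sim_c > 0, r / s, np.nan)
    df = pd.DataFrame(
        {
            "state": [seg.state for seg in segments],
            "chrom": [seg.interval.chrom for seg in segments],
            "start": [seg.interval.start for seg in segments],
            "end": [seg.interval.end for seg in segments],
            "length_bp": lens.astype(np.int64),
            "real_count": real_c,
            "sim_count": sim_c,
            "rpkm_real": r,
            "rpkm_sim": s,
            "normalized": norm,
        }
    )
    n_excl = int(df["normalized"].isna().sum())
    usable = df[df["normalized"].notna()]
    excluded_states = sorted(set(df["state"]) - set(usable["state"]))
    for st in excluded_states:
        logger.warning("state %r has no usable segment; excluded", st)
    return StateRepairTable(df, n_excl, excluded_states)


def star_label(p: float) -> str:
    """Significance stars: ns p>0.05; * p<=0.05; ** p<=0.01; *** p<=0.001;
    **** p<=0.0001."""
    for thr, lab in STAR_THRESHOLDS:
        if p <= thr:
            return lab
    return "ns"


def pairwise_state_tests(
    table: StateRepairTable, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Welch two-sample t-tests between per-state segment repair vectors.

    Raw (uncorrected) two-sided p-values with star labels. Pairs with a
    degenerate vector (n < 2 or zero variance in both) are kept with a
    ``skipped_reason``.
    """
    vecs = table.vectors
    states = sorted(vecs)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(states) for b in states[i + 1 :]]
    rows = []
    for a, b in pairs:
        va, vb = vecs.get(a), vecs.get(b)
        reason = ""
        t = p = np.nan
        if va is None or vb is None:
            reason = "missing state"
        elif len(va) < 2 or len(vb) < 2:
            reason = "fewer than 2 segments"
        elif np.var(va) == 0 and np.var(vb) == 0:
            if np.allclose(va.mean(), vb.mean()):
                t, p = 0.0, 1.0
            else:
                reason = "zero variance"
        else:
            res = stats.ttest_ind(va, vb, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "state_a": a,
                "state_b": b,
                "n_a": 0 if va is None else len(va),
                "n_b": 0 if vb is None else len(vb),
                "t": t,
                "p": p,
                "label": star_label(p) if np.isfinite(p) else "",
                "skipped_reason": reason,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Expression
# --------------------------------------------------------------------------

def select_longest_isoform(transcript_table: pd.DataFrame) -> pd.Series:
    """Gene-level TPM: the TPM of each gene's longest transcript.

    Expects columns transcript_id / gene_id / length / tpm (case-insensitive,
    'TPM' accepted). Length ties break toward the lexicographically smallest
    transcript id.
    """
    df = transcript_table.rename(columns={c: c.lower() for c in transcript_table.columns})
    required = {"transcript_id", "gene_id", "length", "tpm"}
    if not required.issubset(df.columns):
        raise InputError(
            f"transcript table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    picked = (
        df.sort_values(
            ["gene_id", "length", "transcript_id"], ascending=[True, False, True],
            kind="mergesort",
        )
        .groupby("gene_id", sort=True)
        .first()
    )
    return picked["tpm"].rename("tpm")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    table: pd.DataFrame  # gene_id, log2_ts_nts, expression (transformed)
    transform: str


def correlate_expression(
    gene_records: pd.DataFrame,
    gene_tpm: Mapping | pd.Series,
    transform: str = "log10",
    pseudocount: float = 0.1,
) -> CorrelationResult:
    """Pearson correlation between log2 TS/NTS ratios and expression.

    Expression enters as log10(TPM + pseudocount) by default (``transform
    = 'raw'`` uses TPM as-is). Only genes present in both inputs with a
    defined ratio are used.
    """
    if transform not in ("log10", "raw"):
        raise InputError(f"unknown transform {transform!r}")
    tpm = pd.Series(gene_tpm, dtype=float)
    sub = gene_records[gene_records["defined"]].set_index("gene_id")
    common = sub.index.intersection(tpm.index)
    y = sub.loc[common, "log2_ts_nts"].to_numpy(dtype=float)
    x = tpm.loc[common].to_numpy(dtype=float)
    if transform == "log10":
        x = np.log10(x + pseudocount)
    n = len(common)
    if n < 3:
        raise InputError(f"correlate_expression: only {n} usable gene(s), need >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise InputError("correlate_expression: zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame({"gene_id": common, "log2_ts_nts": y, "expression": x})
    return CorrelationResult(float(r), float(p), n, table, transform)
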