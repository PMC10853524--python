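"""Fully specified synthetic datasets for end-to-end testing.

Generates a toy genome, non-overlapping stranded genes with isoforms and
expression, a disjoint chromatin-state segmentation and an excision-repair
read library whose statistical structure mirrors real (6-4)PP XR-seq data:

* bimodal read lengths (primary 25-28 nt peaking at 27; 5'-degraded
  16-21 nt products),
* a damage-site dipyrimidine spectrum at read positions (L-7, L-6),
* strand-asymmetric (transcription-coupled) repair on gene template
  strands scaled with expression rank,
* chromatin-state-dependent repair rates,
* Gaussian repair enrichment bumps at promoter, TSS and TES.

Each read is produced by sampling a lesion site — a genomic dinucleotide
position and strand drawn with weight

    spectrum preference x state multiplier x rho(gene) on template strands
    x positional bump factor

where the spectrum preference for dinucleotide d is q(d) divided by its
genomic availability, so the realized damage spectrum tracks q — then
sampling a read length from the mixture and placing the read so the
lesion occupies positions (L-7, L-6) of its 5'->3' sequence. Reads that
would cross a chromosome end are rejected and resampled.

All quantities needed by parameter-recovery tests (per-gene expected
TS/NTS ratio, pooled body expectation, per-state expected repair) are
computed exactly from the weight arrays and recorded in
:class:`SyntheticTruth`. Output is byte-identical under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .genome_io import (
    DINUCLEOTIDES,
    Genome,
    N_DINUC,
    write_chrom_sizes,
    write_chromatin_states,
    write_fasta,
    write_gff3,
)
from .intervals import ChromatinSegment, GeneModel, GenomicInterval, ReadSet
from .read_qc import DamageSiteSpec
from .repair_profiles import select_longest_isoform

_DEFAULT_SPECTRUM = {"TT": 0.261, "TC": 0.242, "CT": 0.159}
_DEFAULT_STATE_MULT = {"open": 1.5, "genic": 1.0, "hetAT": 0.5, "hetGC": 0.6}
_DEFAULT_PRIMARY_WEIGHTS = {25: 0.15, 26: 0.30, 27: 0.40, 28: 0.15}


@dataclass(frozen=True)
class BumpSpec:
    """A Gaussian repair-enrichment bump anchored to a gene landmark.

    ``amplitude`` is the peak multiplier (1 = no bump), ``width`` the
    Gaussian sigma in bp, ``offset`` the center's displacement from the
    landmark in the gene's 5' direction (negative = upstream).
    """

    amplitude: float = 1.5
    width: float = 200.0
    offset: int = 0


@dataclass(frozen=True)
class SyntheticSpec:
    """All generator parameters; the defaults define the study conditions
    the package is tested under."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc: float = 0.36
    n_genes: int = 200
    gene_len_median: float = 2_000.0
    gene_len_sigma: float = 0.6
    gene_len_min: int = 500
    gene_len_max: int = 8_000
    min_gene_gap: int = 500
    tpm_log_mean: float = 1.5
    tpm_log_sigma: float = 1.2
    n_reads: int = 200_000
    primary_weight: float = 0.8
    primary_length_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_PRIMARY_WEIGHTS)
    )
    degraded_lengths: tuple = (16, 21)
    damage_spectrum: dict = field(default_factory=lambda: dict(_DEFAULT_SPECTRUM))
    tcr_kappa: float = 1.0
    state_multipliers: dict = field(default_factory=lambda: dict(_DEFAULT_STATE_MULT))
    promoter_bump: BumpSpec = field(default_factory=lambda: BumpSpec(1.5, 200.0, -300))
    tss_bump: BumpSpec = field(default_factory=lambda: BumpSpec(1.5, 200.0, 0))
    tes_bump: BumpSpec = field(default_factory=lambda: BumpSpec(1.5, 200.0, 0))
    damage_site: DamageSiteSpec = field(default_factory=DamageSiteSpec)
    segment_len_range: tuple = (1_000, 4_000)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["primary_length_weights"] = {
            str(k): v for k, v in self.primary_length_weights.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("promoter_bump", "tss_bump", "tes_bump"):
            if key in d and isinstance(d[key], dict):
                d[key] = BumpSpec(**d[key])
        if "damage_site" in d and isinstance(d["damage_site"], dict):
            d["damage_site"] = DamageSiteSpec(**d["damage_site"])
        if "primary_length_weights" in d:
            d["primary_length_weights"] = {
                int(k): float(v) for k, v in d["primary_length_weights"].items()
            }
        for key in ("degraded_lengths", "segment_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Generator parameters plus realized per-gene/per-state expectations."""

    spec: dict
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tpm, rank, rho, expected_ts_nts
    expected_pooled_body_ts_nts: float
    expected_state_repair: dict
    state_multipliers: dict
    n_reads: int

    def to_json_file(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec,
            "genes": self.genes.to_dict(orient="list"),
            "expected_pooled_body_ts_nts": self.expected_pooled_body_ts_nts,
            "expected_state_repair": self.expected_state_repair,
            "state_multipliers": self.state_multipliers,
            "n_reads": self.n_reads,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json_file(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            spec=payload["spec"],
            genes=pd.DataFrame(payload["genes"]),
            expected_pooled_body_ts_nts=payload["expected_pooled_body_ts_nts"],
            expected_state_repair=payload["expected_state_repair"],
            state_multipliers=payload["state_multipliers"],
            n_reads=payload["n_reads"],
        )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: Genome
    genes: list[GeneModel]
    transcripts: pd.DataFrame
    states: list[ChromatinSegment]
    gene_tpm: pd.Series
    reads: ReadSet
    truth: SyntheticTruth


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

def generate_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Genome:
    """i.i.d. random genome at the specified GC fraction."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 1])
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(spec.n_chroms):
        codes = rng.choice(4, size=spec.chrom_length, p=p)
        seqs[f"chr{i + 1}"] = bases[codes].tobytes().decode("ascii")
    return Genome(seqs)


# --------------------------------------------------------------------------
# annotation + expression
# --------------------------------------------------------------------------

def generate_annotation(
    spec: SyntheticSpec, genome: Genome, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Non-overlapping stranded genes plus a transcript/TPM table.

    Each gene carries 1-3 isoforms; the longest isoform holds the gene's
    TPM, so gene-level expression recovered via the longest-isoform rule is
    consistent by construction.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 2])
    chroms = genome.names
    per_chrom = [spec.n_genes // len(chroms)] * len(chroms)
    for i in range(spec.n_genes % len(chroms)):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    rows = []
    gidx = 0
    for chrom, n_c in zip(chroms, per_chrom):
        M = len(genome[chrom])
        lens = np.clip(
            rng.lognormal(np.log(spec.gene_len_median), spec.gene_len_sigma, n_c),
            spec.gene_len_min,
            spec.gene_len_max,
        ).astype(np.int64)
        free = M - int(lens.sum()) - (n_c + 1) * spec.min_gene_gap
        if free < 0:
            raise InputError(
                f"chromosome {chrom} too short for {n_c} genes totalling {lens.sum()} bp"
            )
        gaps = spec.min_gene_gap + rng.dirichlet(np.ones(n_c + 1)) * free
        pos = 0.0
        for k in range(n_c):
            pos += gaps[k]
            start = int(round(pos))
            end = start + int(lens[k])
            pos = float(end)
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"SYNG{gidx:05d}"
            gidx += 1
            genes.append(GeneModel(gid, GenomicInterval(chrom, start, end, strand)))
            tpm = float(np.exp(rng.normal(spec.tpm_log_mean, spec.tpm_log_sigma)))
            n_iso = int(rng.integers(1, 4))
            longest = max(int(lens[k] * rng.uniform(0.7, 1.0)), 200)
            rows.append((f"{gid}.1", gid, longest, tpm))
            for j in range(2, n_iso + 1):
                tlen = min(max(int(longest * rng.uniform(0.4, 0.95)), 100), longest - 1)
                rows.append(
                    (f"{gid}.{j}", gid, tlen, tpm * float(rng.uniform(0.05, 0.8)))
                )
    transcripts = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "length", "tpm"]
    )
    return genes, transcripts


# --------------------------------------------------------------------------
# chromatin states
# --------------------------------------------------------------------------

def generate_chromatin_states(
    spec: SyntheticSpec,
    genome: Genome,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[ChromatinSegment]:
    """Disjoint segmentation covering the genome.

    Gene spans become ``genic`` segments; intergenic gaps are tiled into
    segments of random length and labeled by their empirical GC content:
    the lowest tercile ``hetAT``, the highest ``hetGC`` and the middle
    ``open`` — so hetAT segments have lower GC than hetGC by construction.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 3])
    lo, hi = spec.segment_len_range
    genic: list[tuple[str, int, int]] = []
    intergenic: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in genome.names}
    for g in genes:
        by_chrom[g.interval.chrom].append(g)
    for chrom in genome.names:
        M = len(genome[chrom])
        spans = sorted((g.interval.start, g.interval.end) for g in by_chrom[chrom])
        cursor = 0
        for s, e in spans + [(M, M)]:
            gap_s, gap_e = cursor, s
            while gap_e - gap_s > 0:
                seg_len = int(rng.integers(lo, hi + 1))
                if gap_e - gap_s - seg_len < lo:
                    seg_len = gap_e - gap_s  # absorb the remainder
                intergenic.append((chrom, gap_s, gap_s + seg_len))
                gap_s += seg_len
            if e > s:
                genic.append((chrom, s, e))
            cursor = e
    # label intergenic segments by GC terciles
    gcs = []
    for chrom, s, e in intergenic:
        enc = genome.encoded(chrom)[s:e]
        gcs.append(float(((enc == 1) | (enc == 2)).mean()))
    order = np.argsort(np.asarray(gcs), kind="stable")
    n = len(intergenic)
    labels = np.empty(n, dtype=object)
    labels[order[: n // 3]] = "hetAT"
    labels[order[n // 3 : 2 * n // 3]] = "open"
    labels[order[2 * n // 3 :]] = "hetGC"
    segs = [
        ChromatinSegment(GenomicInterval(c, s, e, "."), "genic") for c, s, e in genic
    ] + [
        ChromatinSegment(GenomicInterval(c, s, e, "."), str(lab))
        for (c, s, e), lab in zip(intergenic, labels)
    ]
    segs.sort(key=lambda seg: (seg.interval.chrom, seg.interval.start))
    return segs


# --------------------------------------------------------------------------
# read library
# --------------------------------------------------------------------------

def _spectrum_preferences(spec: SyntheticSpec, genome: Genome) -> np.ndarray:
    """Per-dinucleotide sampling preference q(d)/availability(d) (17 slots,
    N-containing = 0); remaining spectrum mass is spread over unnamed
    dinucleotides proportionally to their genomic availability."""
    counts = np.zeros(16, dtype=np.int64)
    for chrom in genome.names:
        for ids in (genome.dinuc_plus(chrom), genome.dinuc_minus(chrom)):
            counts += np.bincount(ids[ids < N_DINUC], minlength=16)
    q = np.zeros(16)
    named = set()
    for dn, frac in spec.damage_spectrum.items():
        d = DINUCLEOTIDES.index(dn)
        if counts[d] == 0:
            raise InputError(f"spectrum dinucleotide {dn} absent from the genome")
        q[d] = frac
        named.add(d)
    rest = 1.0 - q.sum()
    if rest < -1e-9:
        raise InputError("damage spectrum fractions exceed 1")
    others = np.array([d for d in range(16) if d not in named and counts[d] > 0])
    if others.size and rest > 0:
        q[others] = rest * counts[others] / counts[others].sum()
    pref = np.zeros(17)
    nz = counts > 0
    pref[:16][nz] = q[nz] / counts[nz]
    return pref


def _apply_bump(arr: np.ndarray, center: int, bump: BumpSpec) -> None:
    if bump.amplitude == 1.0:
        return
    sigma = bump.width
    lo = max(int(center - 4 * sigma), 0)
    hi = min(int(center + 4 * sigma) + 1, len(arr))
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] *= 1.0 + (bump.amplitude - 1.0) * np.exp(
        -((x - center) ** 2) / (2 * sigma**2)
    )


def generate_xrseq_library(
    spec: SyntheticSpec,
    genome: Genome,
    genes: list[GeneModel],
    states: list[ChromatinSegment],
    gene_tpm: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[ReadSet, SyntheticTruth]:
    """Sample the read library and record exact recovery expectations."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 4])
    pref = _spectrum_preferences(spec, genome)
    chroms = genome.names

    tpm = gene_tpm.reindex([g.id for g in genes])
    if tpm.isna().any():
        raise InputError("gene_tpm missing entries for some genes")
    ranks = stats.rankdata(tpm.to_numpy())
    rho = 1.0 + spec.tcr_kappa * ranks / len(genes)
    rho_by_gene = dict(zip(tpm.index, rho))

    # weight arrays per chromosome and lesion strand (dinucleotide-start space)
    base = {}
    w = {}
    for chrom in chroms:
        bp = pref[genome.dinuc_plus(chrom)]
        bm = pref[genome.dinuc_minus(chrom)]
        factor = np.ones(len(bp))
        for seg in states:
            if seg.interval.chrom != chrom:
                continue
            mult = spec.state_multipliers.get(seg.state, 1.0)
            if mult != 1.0:
                factor[seg.interval.start : min(seg.interval.end, len(factor))] = mult
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            iv = g.interval
            if iv.strand == "+":
                tss, tes, updir = iv.start, iv.end - 1, -1
            else:
                tss, tes, updir = iv.end - 1, iv.start, 1
            _apply_bump(factor, tss + updir * (-spec.promoter_bump.offset), spec.promoter_bump)
            _apply_bump(factor, tss + updir * (-spec.tss_bump.offset), spec.tss_bump)
            _apply_bump(factor, tes + updir * (-spec.tes_bump.offset), spec.tes_bump)
        wp = bp * factor
        wm = bm * factor
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            span = slice(g.interval.start, min(g.interval.end - 1, len(bp)))
            r = rho_by_gene[g.id]
            if g.interval.strand == "+":
                wm[span] = wm[span] * r  # template strand of a + gene is -
            else:
                wp[span] = wp[span] * r
        base[chrom] = (bp, bm)
        w[chrom] = (wp, wm)

    # flatten for sampling: blocks [(chrom, '+'), (chrom, '-')] in order
    blocks = []
    flat = []
    for chrom in chroms:
        wp, wm = w[chrom]
        blocks.append((chrom, "+", len(wp)))
        flat.append(wp)
        blocks.append((chrom, "-", len(wm)))
        flat.append(wm)
    flat = np.concatenate(flat)
    if flat.sum() <= 0:
        raise InputError("all lesion weights are zero")
    cum = np.cumsum(flat)
    total = cum[-1]
    offsets = np.concatenate([[0], np.cumsum([b[2] for b in blocks])])
    block_chrom = np.array([chroms.index(b[0]) for b in blocks])
    block_plus = np.array([b[1] == "+" for b in blocks])
    clens = np.array([len(genome[c]) for c in chroms], dtype=np.int64)

    # length mixture
    plens = np.array(sorted(spec.primary_length_weights), dtype=np.int64)
    pw = np.array([spec.primary_length_weights[int(l)] for l in plens], dtype=float)
    pw /= pw.sum()
    dlo, dhi = spec.degraded_lengths
    off = spec.damage_site.offset3

    n = spec.n_reads
    j_arr = np.empty(n, dtype=np.int64)
    ci_arr = np.empty(n, dtype=np.int64)
    plus_arr = np.empty(n, dtype=bool)
    len_arr = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        draw = np.searchsorted(cum, rng.random(m) * total, side="right")
        b = np.searchsorted(offsets, draw, side="right") - 1
        j = draw - offsets[b]
        ci = block_chrom[b]
        plus = block_plus[b]
        primary = rng.random(m) < spec.primary_weight
        L = np.where(
            primary,
            rng.choice(plens, size=m, p=pw),
            rng.integers(dlo, dhi + 1, size=m),
        )
        M = clens[ci]
        ok_plus = (j >= L - off - 1) & (j <= M - off - 1)
        ok_minus = (j >= off - 1) & (j <= M + off - 1 - L)
        ok = np.where(plus, ok_plus, ok_minus)
        idx = pending[ok]
        j_arr[idx] = j[ok]
        ci_arr[idx] = ci[ok]
        plus_arr[idx] = plus[ok]
        len_arr[idx] = L[ok]
        pending = pending[~ok]
    starts = np.where(
        plus_arr, j_arr - (len_arr - off - 1), j_arr - off + 1
    )
    reads = ReadSet(
        np.array([chroms[i] for i in ci_arr], dtype=object),
        starts,
        starts + len_arr,
        np.where(plus_arr, "+", "-").astype("<U1"),
        np.array([f"synr_{i}" for i in range(n)], dtype=object),
        np.zeros(n),
    )

    # ---- exact expectations from the weight arrays -----------------------
    gene_rows = []
    sums = {"real_ts": 0.0, "real_nts": 0.0, "sim_ts": 0.0, "sim_nts": 0.0}
    for g_i, g in enumerate(genes):
        chrom = g.interval.chrom
        bp, bm = base[chrom]
        wp, wm = w[chrom]
        span = slice(g.interval.start, min(g.interval.end - 1, len(bp)))
        if g.interval.strand == "+":
            real_ts, sim_ts = wm[span].sum(), bm[span].sum()
            real_nts, sim_nts = wp[span].sum(), bp[span].sum()
        else:
            real_ts, sim_ts = wp[span].sum(), bp[span].sum()
            real_nts, sim_nts = wm[span].sum(), bm[span].sum()
        exp_ratio = np.nan
        if min(sim_ts, sim_nts, real_nts) > 0:
            exp_ratio = (real_ts / sim_ts) / (real_nts / sim_nts)
        for k, v in zip(
            ("real_ts", "real_nts", "sim_ts", "sim_nts"),
            (real_ts, real_nts, sim_ts, sim_nts),
        ):
            sums[k] += v
        gene_rows.append(
            {
                "gene_id": g.id,
                "chrom": chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
                "tpm": float(tpm[g.id]),
                "rank": float(ranks[g_i]),
                "rho": float(rho_by_gene[g.id]),
                "expected_ts_nts": float(exp_ratio),
            }
        )
    pooled = (sums["real_ts"] / sums["sim_ts"]) / (sums["real_nts"] / sums["sim_nts"])

    wtot = total
    btot = sum(bp.sum() + bm.sum() for bp, bm in base.values())
    state_real: dict[str, float] = {}
    state_sim: dict[str, float] = {}
    for seg in states:
        chrom = seg.interval.chrom
        bp, bm = base[chrom]
        wp, wm = w[chrom]
        span = slice(seg.interval.start, min(seg.interval.end, len(bp)))
        state_real[seg.state] = state_real.get(seg.state, 0.0) + wp[span].sum() + wm[span].sum()
        state_sim[seg.state] = state_sim.get(seg.state, 0.0) + bp[span].sum() + bm[span].sum()
    expected_state = {
        st: float((state_real[st] / wtot) / (state_sim[st] / btot))
        for st in state_real
        if state_sim[st] > 0
    }

    truth = SyntheticTruth(
        spec=spec.to_dict(),
        genes=pd.DataFrame(gene_rows),
        expected_pooled_body_ts_nts=float(pooled),
        expected_state_repair=expected_state,
        state_multipliers=dict(spec.state_multipliers),
        n_reads=n,
    )
    return reads, truth


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Genome -> annotation -> states -> expression -> read library."""
    genome = generate_genome(spec)
    genes, transcripts = generate_annotation(spec, genome)
    states = generate_chromatin_states(spec, genome, genes)
    gene_tpm = select_longest_isoform(transcripts)
    reads, truth = generate_xrseq_library(spec, genome, genes, states, gene_tpm)
    return SyntheticDataset(spec, genome, genes, transcripts, states, gene_tpm, reads, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every component as plain-text files; returns the path map."""
    from .genome_io import write_bed6

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "chrom_sizes": outdir / "chrom.sizes",
        "annotation": outdir / "genes.gff3",
        "states": outdir / "states.bed",
        "expression": outdir / "expression.tsv",
        "reads": outdir / "reads.bed",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.genome, paths["genome"])
    write_chrom_sizes(ds.genome.chrom_sizes(), paths["chrom_sizes"])
    write_gff3(ds.genes, paths["annotation"], ds.transcripts)
    write_chromatin_states(ds.states, paths["states"])
    ds.transcripts.to_csv(paths["expression"], sep="\t", index=False)
    write_bed6(ds.reads, paths["reads"])
    ds.truth.to_json_file(paths["truth"])
    return paths
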