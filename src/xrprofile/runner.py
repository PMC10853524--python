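"""End-to-end pipeline orchestration with a serializable run config.

``run_all`` executes dedup -> (optional) simulate -> qc -> profile ->
tsnts -> states -> correlate, writing tidy TSV/JSON outputs, a structured
run log and a manifest with input checksums. Re-running an unchanged
config skips stages whose inputs and parameters are identical
(checksum-based) and marks them ``cached``. Inputs are loaded lazily, so
a malformed file aborts inside — and is reported with the name of — the
first stage that consumes it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import InputError, PipelineStageError
from .genome_io import (
    deduplicate_reads,
    read_bed6,
    read_chromatin_states,
    read_fasta,
    read_gene_annotation,
    write_bed6,
)
from .read_qc import (
    DamageSiteSpec,
    damage_site_composition,
    length_distribution,
    positional_dinucleotide_frequencies,
)
from .repair_profiles import (
    chromatin_state_repair,
    correlate_expression,
    gene_ts_nts,
    metagene_profile,
    pairwise_state_tests,
    select_longest_isoform,
    ts_nts_distribution_summary,
)
from .sim_reads import SimLibraryConfig, simulate_matched_library

logger = logging.getLogger(__name__)

STAGES = ("dedup", "simulate", "qc", "profile", "tsnts", "states", "correlate")


@dataclass
class RunConfig:
    """Every input path and decision flag of one pipeline run."""

    genome: str
    reads: str
    annotation: str
    outdir: str
    annotation_format: str = "gff3"
    states: str | None = None
    expression: str | None = None
    sim_reads: str | None = None  # precomputed background; otherwise simulated
    seed: int = 0
    dedup: bool = True
    n_bins: int = 100
    flank_fraction: float = 0.5
    bin_layout: str = "inclusive"
    damage_offset3: int = 7
    min_read_length: int = 9
    primary_window: tuple = (25, 28)
    biotype_filter: str | None = "protein_coding"
    biotype_key: str | None = None
    tpm_transform: str = "log10"
    tpm_pseudocount: float = 0.1
    max_tries_per_read: int = 10_000
    version: str = __version__

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["primary_window"] = list(self.primary_window)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.pop("version", None)
        if "primary_window" in d:
            d["primary_window"] = tuple(d["primary_window"])
        return cls(**d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _signature(paths: list, params: dict) -> str:
    h = hashlib.sha256()
    for p in paths:
        if p:
            h.update(_sha256(p).encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("xrprofile")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)

    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {
        "version": config.version,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    params = {k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"}
    damage_spec = DamageSiteSpec(config.damage_offset3, config.min_read_length)

    dedup_bed = outdir / "reads.dedup.bed"
    sim_bed = Path(config.sim_reads) if config.sim_reads else outdir / "simulated.bed"
    qc_dir = outdir / "qc"
    profile_tsv = outdir / "metagene.tsv"
    tsnts_tsv = outdir / "gene_ts_nts.tsv"
    tsnts_summary_tsv = outdir / "ts_nts_summary.tsv"
    states_tsv = outdir / "state_repair.tsv"
    states_tests_tsv = outdir / "state_tests.tsv"
    corr_json = outdir / "correlation.json"
    corr_tsv = outdir / "correlation_pairs.tsv"

    # lazy shared inputs: the first stage touching a bad file names itself
    state: dict = {}

    def get_genome():
        if "genome" not in state:
            state["genome"] = read_fasta(config.genome)
        return state["genome"]

    def get_reads():
        if "reads" not in state:
            src = dedup_bed if config.dedup and dedup_bed.exists() else config.reads
            state["reads"] = read_bed6(src)
        return state["reads"]

    def get_sim():
        if "sim" not in state:
            state["sim"] = read_bed6(sim_bed)
        return state["sim"]

    def get_genes():
        if "genes" not in state:
            state["genes"] = read_gene_annotation(
                config.annotation,
                config.annotation_format,
                config.biotype_filter,
                config.biotype_key,
            )
        return state["genes"]

    def get_records():
        if "records" not in state:
            state["records"] = pd.read_csv(tsnts_tsv, sep="\t")
        return state["records"]

    # ---- stage bodies ----------------------------------------------------
    def do_dedup():
        reads = read_bed6(config.reads)
        reads, removed = deduplicate_reads(reads)
        logger.info("dedup: removed %d duplicate(s)", removed)
        write_bed6(reads, dedup_bed)
        state["reads"] = reads

    def do_simulate():
        if config.sim_reads:
            get_sim()
            return
        sim, report = simulate_matched_library(
            get_reads(),
            get_genome(),
            SimLibraryConfig(
                seed=config.seed,
                max_tries_per_read=config.max_tries_per_read,
                damage_site=damage_spec,
            ),
        )
        write_bed6(sim, sim_bed)
        (outdir / "sim_report.json").write_text(report.to_json())
        state["sim"] = sim

    def do_qc():
        reads = get_reads()
        qc_dir.mkdir(exist_ok=True)
        hist = length_distribution(reads, config.primary_window)
        hist.to_frame().to_csv(qc_dir / "length_histogram.tsv", sep="\t", index=False)
        prof = positional_dinucleotide_frequencies(reads, get_genome(), hist.modal_length)
        prof.to_long_frame().to_csv(qc_dir / "dinuc_profile.tsv", sep="\t", index=False)
        comp = damage_site_composition(reads, get_genome(), damage_spec)
        comp.fractions.rename_axis("dinucleotide").reset_index().to_csv(
            qc_dir / "damage_site.tsv", sep="\t", index=False
        )

    def do_profile():
        prof = metagene_profile(
            get_genes(),
            get_reads(),
            get_sim(),
            get_genome(),
            n_bins=config.n_bins,
            flank_fraction=config.flank_fraction,
            bin_layout=config.bin_layout,
        )
        prof.to_frame().to_csv(profile_tsv, sep="\t", index=False)

    def do_tsnts():
        records = gene_ts_nts(get_genes(), get_reads(), get_sim())
        records.to_csv(tsnts_tsv, sep="\t", index=False)
        summary = ts_nts_distribution_summary(records)
        summary.summary.to_csv(tsnts_summary_tsv, sep="\t", index=False)
        state["records"] = records

    def do_states():
        segs = read_chromatin_states(config.states)
        table = chromatin_state_repair(segs, get_reads(), get_sim())
        table.segments.to_csv(states_tsv, sep="\t", index=False)
        pairwise_state_tests(table).to_csv(states_tests_tsv, sep="\t", index=False)

    def do_correlate():
        tx = pd.read_csv(config.expression, sep="\t")
        tpm = select_longest_isoform(tx)
        res = correlate_expression(
            get_records(), tpm, config.tpm_transform, config.tpm_pseudocount
        )
        corr_json.write_text(
            json.dumps({"pearson_r": res.r, "p_value": res.p, "n": res.n}, indent=2)
        )
        res.table.to_csv(corr_tsv, sep="\t", index=False)

    def stage(name: str, inputs: list, outputs: list, fn) -> None:
        sig = _signature([p for p in inputs if p and Path(p).exists()], {**params, "stage": name})
        prev = previous.get(name)
        if (
            prev
            and prev.get("signature") == sig
            and all(Path(o).exists() for o in prev.get("outputs", []))
        ):
            logger.info("stage %s: cached", name)
            manifest["stages"][name] = {**prev, "status": "cached"}
            return
        try:
            fn()
        except InputError as exc:
            raise PipelineStageError(name, str(exc)) from exc
        manifest["stages"][name] = {
            "status": "completed",
            "signature": sig,
            "outputs": [str(o) for o in outputs],
        }
        logger.info("stage %s: completed", name)

    try:
        if config.dedup:
            stage("dedup", [config.reads], [dedup_bed], do_dedup)
        stage(
            "simulate",
            [config.reads, config.genome],
            [] if config.sim_reads else [sim_bed, outdir / "sim_report.json"],
            do_simulate,
        )
        stage(
            "qc",
            [config.reads, config.genome],
            [qc_dir / "length_histogram.tsv", qc_dir / "dinuc_profile.tsv", qc_dir / "damage_site.tsv"],
            do_qc,
        )
        stage(
            "profile",
            [config.reads, config.genome, config.annotation],
            [profile_tsv],
            do_profile,
        )
        stage(
            "tsnts",
            [config.reads, config.genome, config.annotation],
            [tsnts_tsv, tsnts_summary_tsv],
            do_tsnts,
        )
        if config.states:
            stage(
                "states",
                [config.reads, config.states],
                [states_tsv, states_tests_tsv],
                do_states,
            )
        if config.expression:
            stage(
                "correlate",
                [config.reads, config.annotation, config.expression],
                [corr_json, corr_tsv],
                do_correlate,
            )
        config.to_yaml(outdir / "config.used.yaml")
        manifest_path.write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest
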