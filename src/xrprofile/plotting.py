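"""Thin matplotlib convenience wrappers around the tabular outputs."""
from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_length_distribution(hist, ax=None):
    ax = _ax(ax)
    df = hist.to_frame()
    ax.bar(df["length"], df["fraction"], color="#4878d0")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of reads")
    return ax


def plot_dinucleotide_profile(profile, ax=None):
    """Pyrimidine-dinucleotide fractions along reads of one length."""
    ax = _ax(ax)
    sub = profile.pyrimidine_subset
    for dinuc, row in sub.iterrows():
        ax.plot(row.index, row.values, label=dinuc)
    ax.set_xlabel("position along read (5'->3')")
    ax.set_ylabel("fraction")
    ax.legend(frameon=False)
    return ax


def plot_metagene(profile, ax=None):
    """Normalized TS and NTS repair along the binned gene + flanks."""
    ax = _ax(ax)
    for cls, color in (("TS", "#d65f5f"), ("NTS", "#4878d0")):
        tab = profile.tables[cls]
        ax.plot(tab["bin"], tab["normalized"], label=cls, color=color)
    lo, hi = profile.body_slice
    ax.axvline(lo + 1, ls="--", c="grey", lw=0.8)
    ax.axvline(hi, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("bin")
    ax.set_ylabel("normalized repair")
    ax.legend(frameon=False)
    return ax


def plot_state_repair(table, ax=None):
    ax = _ax(ax)
    vecs = table.vectors
    states = sorted(vecs)
    ax.boxplot([vecs[s] for s in states], tick_labels=states, showfliers=False)
    ax.set_ylabel("normalized repair")
    return ax
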