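"""Basic per-stage figures: size histograms, stranded coverage tracks, and
positional nucleotide frequency bars."""

from __future__ import annotations

import numpy as np


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_size_profile(profile, path: str) -> None:
    plt = _axes()
    lengths = list(range(18, 32))
    sense = [profile.counts_sense[k] for k in lengths]
    anti = [profile.counts_antisense[k] for k in lengths]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(lengths, sense, label="sense", color="#4477aa")
    ax.bar(lengths, anti, bottom=sense, label="antisense", color="#ee6677")
    norm21 = profile.norm21
    title = profile.contig_id
    if norm21 is not None:
        title += f"  (21 nt = {norm21:.1f}% of 18-31 nt)"
    ax.set(xlabel="read length (nt)", ylabel="reads", title=title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage(cov, path: str) -> None:
    plt = _axes()
    x = np.arange(len(cov.sense))
    fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.fill_between(x, cov.sense, step="mid", alpha=0.7,
                    label="sense", color="#4477aa")
    ax.fill_between(x, -cov.antisense, step="mid", alpha=0.7,
                    label="antisense", color="#ee6677")
    ax.axhline(0, color="black", lw=0.5)
    ax.set(xlabel="position (nt)", ylabel="depth", title=cov.contig_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_positional_frequencies(matrix, path: str) -> None:
    from .pirna import BASES

    plt = _axes()
    freq = matrix.freq
    positions = np.arange(1, freq.shape[1] + 1)
    colors = {"A": "#228833", "C": "#4477aa", "G": "#ccbb44", "U": "#ee6677"}
    fig, ax = plt.subplots(figsize=(6, 2.5))
    bottom = np.zeros(freq.shape[1])
    for i, base in enumerate(BASES):
        vals = np.nan_to_num(freq[i])
        ax.bar(positions, vals, bottom=bottom, label=base, color=colors[base])
        bottom += vals
    label = matrix.strand or "reads"
    ax.set(xlabel="position (nt from 5' end)", ylabel="frequency",
           title=f"{label} (n={matrix.n_reads})")
    ax.legend(frameon=False, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
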