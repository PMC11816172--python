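"""Minimal Manhattan / QQ / local association plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan_plot", "qq_plot", "local_plot"]


def _cumulative_positions(table: pd.DataFrame):
    offsets = {}
    run = 0
    for chrom, sub in table.groupby("chrom", sort=False):
        offsets[chrom] = run
        run += int(sub["pos"].max()) + 1
    x = table["pos"].to_numpy() + table["chrom"].map(offsets).to_numpy()
    return x, offsets


def manhattan_plot(table: pd.DataFrame, path, q_threshold: float = 0.05):
    """-log10 p against cumulative genome position, significant hits marked."""
    x, _ = _cumulative_positions(table)
    y = -np.log10(table["p"].to_numpy())
    colors = pd.factorize(table["chrom"])[0] % 2
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(x, y, c=np.where(colors == 0, "#1f77b4", "#7f7f7f"), s=4)
    sig = table["q"] < q_threshold
    if sig.any():
        ax.scatter(x[sig.to_numpy()], y[sig.to_numpy()], c="#d62728", s=10)
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(p_values, path):
    p = np.sort(np.asarray(p_values, dtype=float))
    expected = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot(-np.log10(expected), -np.log10(p), ".", ms=3)
    lim = max(-np.log10(expected[0]), -np.log10(p[0])) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def local_plot(gwas_table: pd.DataFrame, eqtl_table: pd.DataFrame, chrom, lo, hi, path):
    """GWAS track above, eQTL track below, for one genomic window."""
    g = gwas_table[
        (gwas_table["chrom"].astype(str) == str(chrom))
        & gwas_table["pos"].between(lo, hi)
    ]
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 4))
    ax1.scatter(g["pos"], -np.log10(g["p"]), s=8)
    ax1.set_ylabel("GWAS -log10 p")
    if not eqtl_table.empty:
        ax2.scatter(
            eqtl_table["pos"], -np.log10(eqtl_table["p"]), s=8, c="#2ca02c"
        )
    ax2.set_ylabel("eQTL -log10 p")
    ax2.set_xlabel(f"chromosome {chrom} position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
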