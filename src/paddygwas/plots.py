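"""Optional matplotlib figures: Manhattan plot, LD-decay curve, LD heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .gwas import AssociationResult  # noqa: E402
from .ld import LDDecayModel  # noqa: E402


def manhattan(result: AssociationResult, out_path: str) -> None:
    """Manhattan plot with the suggestive/significant FDR threshold lines."""
    t = result.table.dropna(subset=["minus_log10_p"]).copy()
    fig, ax = plt.subplots(figsize=(12, 4))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(t.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["minus_log10_p"], s=4, color="C0" if i % 2 == 0 else "C7")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    if np.isfinite(result.sug_line):
        ax.axhline(result.sug_line, color="red", lw=1, label="FDR 0.05")
    if np.isfinite(result.sig_line):
        ax.axhline(result.sig_line, color="blue", lw=1, label="FDR 0.01")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def decay_curve(
    pairs: pd.DataFrame, model: LDDecayModel, out_path: str, n_bins: int = 50
) -> None:
    """Binned mean r² over distance with the fitted hyperbolic curve."""
    d = pairs["d"].to_numpy(float)
    r2 = pairs["r2"].to_numpy(float)
    edges = np.logspace(np.log10(max(d.min(), 1)), np.log10(d.max()), n_bins + 1)
    which = np.digitize(d, edges) - 1
    mids, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            mids.append(np.sqrt(edges[b] * edges[b + 1]))
            means.append(r2[sel].mean())
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mids, means, s=12, label="binned mean $r^2$")
    grid = np.logspace(np.log10(max(d.min(), 1)), np.log10(d.max()), 200)
    ax.plot(grid, model.predict(grid), color="red", label="fitted model")
    ax.axvline(model.d_ld50, color="gray", ls="--", lw=1, label=r"$d_{LD50}$")
    ax.set_xscale("log")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"$r^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def ld_heatmap(r2_matrix: pd.DataFrame, out_path: str) -> None:
    """Local LD block heatmap around a called region."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(r2_matrix.to_numpy(), vmin=0, vmax=1, cmap="Reds")
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    ax.set_xlabel("marker")
    ax.set_ylabel("marker")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
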