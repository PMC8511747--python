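"""Matplotlib helpers mirroring the package's three report figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_h2", "plot_interactions", "plot_correlation_matrix"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_h2(report: pd.DataFrame, ax=None):
    """Bar chart of per-trait H² posterior means with 95 % intervals."""
    ax = _ax(ax)
    x = np.arange(len(report))
    err = np.vstack(
        [report["h2_mean"] - report["h2_q2.5"], report["h2_q97.5"] - report["h2_mean"]]
    )
    ax.bar(x, report["h2_mean"], yerr=err, capsize=3, color="#4878A8")
    ax.set_xticks(x, report["trait"], rotation=60, ha="right")
    ax.set_ylabel("broad-sense heritability $H^2$")
    ax.set_ylim(0, 1)
    return ax


def plot_interactions(reports, ax=None):
    """Relative treatment effects per trait with the additive-null line."""
    ax = _ax(ax)
    traits = [r.trait for r in reports]
    x = np.arange(len(traits))
    w = 0.25
    ax.bar(x - w, [r.delta_temp for r in reports], w, label="high temp", color="#D08770")
    ax.bar(x, [r.delta_pco2 for r in reports], w, label="high pCO2", color="#5E81AC")
    ax.bar(x + w, [r.delta_combined for r in reports], w, label="combined", color="#3B4252")
    for xi, r in zip(x, reports):
        ax.hlines(r.additive_null, xi - 1.6 * w, xi + 1.6 * w, color="black", lw=1.2)
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xticks(x, traits, rotation=60, ha="right")
    ax.set_ylabel("relative difference vs control")
    ax.legend(fontsize=8)
    return ax


def plot_correlation_matrix(entries: pd.DataFrame, context: str, ax=None, alpha: float = 0.05):
    """Heatmap of pairwise r for one context; non-significant cells marked ×."""
    ax = _ax(ax)
    ctx_col = "trait" if "trait" in entries.columns else "treatment"
    sub = entries.loc[entries[ctx_col] == context]
    units = sorted(set(sub["unit_a"]) | set(sub["unit_b"]))
    k = len(units)
    mat = np.eye(k)
    sig = np.ones((k, k), dtype=bool)
    for _, e in sub.iterrows():
        i, j = units.index(e["unit_a"]), units.index(e["unit_b"])
        mat[i, j] = mat[j, i] = e["r"]
        sig[i, j] = sig[j, i] = bool(e["significant"])
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    for i in range(k):
        for j in range(k):
            if i != j and not sig[i, j]:
                ax.text(j, i, "×", ha="center", va="center", color="black")
    ax.set_xticks(range(k), units, rotation=60, ha="right")
    ax.set_yticks(range(k), units)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(str(context))
    return ax
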