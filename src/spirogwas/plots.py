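"""Basic Manhattan and QQ plots for scan summaries (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

__all__ = ["qq_plot", "manhattan_plot"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 5))
    return ax


def qq_plot(p_values, ax=None, label=None):
    """Observed vs expected −log10 p under the uniform null."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(p)
    ax = _axes(ax)
    ax.plot(exp, obs, ".", ms=3, label=label)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected −log10 p")
    ax.set_ylabel("observed −log10 p")
    return ax


def manhattan_plot(results, ax=None, threshold=None):
    """−log10 p by genomic position, alternating chromosome shading."""
    ax = _axes(ax)
    df = results.sort_values(["chromosome", "position"])
    offset = 0
    ticks, ticklabels = [], []
    for i, (chrom, grp) in enumerate(df.groupby("chromosome", sort=True)):
        x = offset + np.arange(len(grp))
        ax.plot(x, -np.log10(grp["p"].to_numpy(dtype=float)), ".",
                ms=2, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + len(grp) / 2)
        ticklabels.append(str(chrom))
        offset += len(grp)
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("−log10 p")
    return ax
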