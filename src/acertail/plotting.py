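"""Matplotlib views: tail extrapolation, merged record, difference clouds."""

from __future__ import annotations

import numpy as np

from .diffplot import DifferenceCloud
from .merge import MergedVector

__all__ = ["plot_tail_fit", "plot_merged", "plot_difference_cloud"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_tail_fit(results, ax=None, percent: bool = True):
    """Log-scale p_k versus lambda: empirical points, fitted tail, dotted
    extrapolated CI, and a star at the predicted return level."""
    ax = _get_ax(ax)
    s = 100.0 if percent else 1.0
    curve, band = results.curve, results.band
    pos = curve.p > 0
    ax.semilogy(curve.lambdas[pos] * s, curve.p[pos], ".", ms=3, color="0.4",
                label=f"empirical $p_{{{results.k}}}$")
    ext = results.band_extrapolation
    lam = ext.lambdas
    ax.semilogy(lam * s, results.predict(lam), "-", color="C0", label="tail fit")
    ax.semilogy(lam * s, ext.lower, ":", color="C0")
    ax.semilogy(lam * s, ext.upper, ":", color="C0",
                label=f"extrapolated {results.conf:.0%} CI")
    ax.axhline(results.p_target, ls="--", color="0.6", lw=0.8)
    ax.plot(results.return_level_ * s, results.p_target, "*", color="C3",
            ms=12, label=f"return level {results.return_level_ * s:.3g}")
    ax.axvline(results.lambda0 * s, ls="-.", color="0.8", lw=0.8)
    ax.set_xlabel("level $\\lambda$" + (" (% of failure limit)" if percent else ""))
    ax.set_ylabel("conditional exceedance rate $p_k(\\lambda)$")
    ax.legend(fontsize=8)
    return ax


def plot_merged(merged: MergedVector, ax=None, percent: bool = True):
    """The pooled vector R/eta against its running index."""
    ax = _get_ax(ax)
    s = 100.0 if percent else 1.0
    ax.plot(np.arange(merged.n), merged.scaled * s, lw=0.5)
    ax.set_xlabel("running index $j$")
    ax.set_ylabel("$R_j/\\eta_j$" + (" (%)" if percent else ""))
    return ax


def plot_difference_cloud(cloud: DifferenceCloud, axes=None):
    """Scatter view: 2-D for order 2, consecutive 2-D projections above."""
    import matplotlib.pyplot as plt

    pairs = [(i, i + 1) for i in range(cloud.order - 1)]
    if axes is None:
        _, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4),
                               squeeze=False)
        axes = axes[0]
    for ax, (i, j) in zip(np.atleast_1d(axes), pairs):
        ax.scatter(cloud.points[:, i], cloud.points[:, j], s=4, alpha=0.5)
        ax.set_xlabel(f"$\\Delta_{{n+{i}}}$")
        ax.set_ylabel(f"$\\Delta_{{n+{j}}}$")
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
    return axes
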