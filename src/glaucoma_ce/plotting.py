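"""Optional figures: tornado diagram, CEAC, and the incremental CE plane."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sensitivity import DSAResult, PSAResult

__all__ = ["plot_tornado", "plot_ceac", "plot_ce_plane"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_tornado(results: Sequence[DSAResult], base_icer: float, ax=None):
    """Horizontal bars of the ICER range per perturbed parameter."""
    finite = [r for r in results if not np.isnan(r.spread)][::-1]
    ax = _axes(ax)
    for i, r in enumerate(finite):
        lo, hi = sorted((r.low_icer, r.high_icer))
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(finite)), [r.parameter for r in finite])
    ax.set_xlabel("ICER (EUR per QALY)")
    return ax


def plot_ceac(curve: pd.DataFrame, wtp: float | None = None, ax=None):
    """Probability of cost-effectiveness against the willingness-to-pay grid."""
    ax = _axes(ax)
    ax.plot(curve["threshold"], curve["probability"])
    if wtp is not None:
        ax.axvline(wtp, color="k", ls="--", lw=1)
    ax.set_xlabel("willingness to pay (EUR per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    return ax


def plot_ce_plane(result: PSAResult, ax=None):
    """Scatter of the PSA incremental cost/QALY cloud with the WTP ray."""
    ax = _axes(ax)
    s = result.samples
    ax.scatter(s["inc_qaly"], s["inc_cost"], s=4, alpha=0.3)
    lim = float(np.abs(s["inc_qaly"]).max())
    x = np.linspace(-lim, lim, 2)
    ax.plot(x, result.config.wtp_threshold * x, "k--", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (EUR)")
    return ax
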