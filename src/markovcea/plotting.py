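"""Diagnostic plots: CE plane, acceptability curves, tornado diagram."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]

_SCEN_LABELS = {"initial": "initial price", "increased": "increased price"}


def plot_ce_plane(psa, ax=None, wtp: float | None = None):
    """Incremental cost vs incremental QALY scatter, one cloud per price level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for scen, dc in psa.delta_cost.items():
        ax.scatter(psa.delta_qaly, dc, s=4, alpha=0.25,
                   label=_SCEN_LABELS.get(scen, scen))
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP {wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (EUR)")
    ax.legend(frameon=False)
    return ax


def plot_ceac(ceac_frame, ax=None):
    """Probability of cost-effectiveness against willingness to pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for scen, sub in ceac_frame.groupby("scenario"):
        ax.plot(sub["wtp"], sub["probability"],
                label=_SCEN_LABELS.get(scen, scen))
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_tornado(entries, ax=None, top: int | None = None):
    """Horizontal bars of one-way ICER ranges, widest on top."""
    entries = entries if top is None else entries[:top]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1))
    names = [e.parameter for e in entries][::-1]
    for i, e in enumerate(entries[::-1]):
        lo = min(e.icer_low_bound, e.icer_high_bound)
        ax.barh(i, e.width, left=lo, height=0.6, color="steelblue")
    base = entries[0].icer_base
    ax.axvline(base, color="k", lw=1, label=f"base case {base:,.0f}")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("ICER (EUR/QALY)")
    ax.legend(frameon=False)
    return ax
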