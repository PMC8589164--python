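"""Simple renderings of the tornado diagram, CE plane and CEAC.

These emit plain matplotlib figures; the underlying data are available as
DataFrames/arrays from the analysis functions themselves.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def tornado_plot(entries, base_inmb: float, top: int = 10, ax=None):
    """Horizontal tornado of INMB swings for the most influential inputs."""
    entries = entries[:top]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(entries) + 1.5))
    labels = [e.pid for e in entries][::-1]
    for k, e in enumerate(entries[::-1]):
        lo, hi = sorted((e.inmb_low, e.inmb_high))
        ax.barh(k, hi - lo, left=lo, color="#4878a8", alpha=0.8)
    ax.axvline(base_inmb, color="k", lw=1)
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    ax.set_xlabel("incremental net monetary benefit (€)")
    ax.figure.tight_layout()
    return ax


def ce_plane_plot(samples, ax=None):
    """PSA cloud on the cost-effectiveness plane with the WTP line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples.d_qaly, samples.d_cost, s=6, alpha=0.4,
               color="#4878a8", edgecolors="none")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    grid = np.linspace(*ax.get_xlim(), 10)
    ax.plot(grid, samples.wtp * grid, "--", color="gray", lw=1,
            label=f"WTP €{samples.wtp:,.0f}/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (€)")
    ax.legend(frameon=False)
    ax.figure.tight_layout()
    return ax


def ceac_plot(wtp_grid, prob, ax=None):
    """Cost-effectiveness acceptability curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.asarray(wtp_grid) / 1000.0, prob, color="#4878a8")
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("willingness-to-pay (€1000/QALY)")
    ax.set_ylabel("P(apixaban cost-effective)")
    ax.figure.tight_layout()
    return ax
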