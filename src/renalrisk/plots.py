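"""Figure helpers: risk-distribution panels and PCF-vs-PNF curves."""

from __future__ import annotations

import numpy as np

from .risk_metrics import RiskDistributionSummary


def plot_risk_distribution(summaries: list[RiskDistributionSummary], title: str = ""):
    """One panel per horizon: predicted-risk densities for progressors (red)
    and non-progressors (blue), with vertical q80 (solid) / q90 (dashed)
    follow-up thresholds."""
    import matplotlib.pyplot as plt

    n = len(summaries)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
    for ax, summ in zip(axes[0], summaries):
        ax.plot(summ.grid, summ.density_nonprogressors, color="tab:blue", label="non-progressors")
        ax.plot(summ.grid, summ.density_progressors, color="tab:red", label="progressors")
        ax.axvline(summ.q80, color="grey", linestyle="-", label="q80")
        ax.axvline(summ.q90, color="grey", linestyle="--", label="q90")
        ax.set_xlabel("predicted ESRD risk")
        ax.set_title(f"{summ.horizon:g}-year horizon")
    axes[0][0].set_ylabel("density")
    axes[0][0].legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_pcf_pnf(curves: dict[str, tuple[np.ndarray, np.ndarray]], title: str = ""):
    """PCF (cases captured) against the followed population fraction.

    ``curves`` maps a label (e.g. a subgroup or horizon) to ``(qs, pcf(qs))``.
    The diagonal marks an uninformative model.
    """
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for label, (qs, vals) in curves.items():
        ax.plot(qs, vals, label=label)
    ax.plot([0, 1], [0, 1], color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("proportion of population followed (PNF)")
    ax.set_ylabel("proportion of cases captured (PCF)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
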