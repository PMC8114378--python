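"""Simple plots of stability and accuracy diagnostics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stability import StabilityReport


def plot_edge_ci(report: StabilityReport, path: str | Path) -> None:
    """Edge-weight accuracy: sample value vs. bootstrap mean with 95% CI."""
    if report.edge_ci is None:
        raise ValueError("report has no edge CIs")
    df = report.edge_ci.sort_values("sample", ascending=True).reset_index(drop=True)
    y = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(6, max(3, len(df) * 0.08)))
    ax.fill_betweenx(y, df["ci_lower"], df["ci_upper"], color="0.8", label="95% CI")
    ax.plot(df["boot_mean"], y, ".", color="k", ms=2, label="bootstrap mean")
    ax.plot(df["sample"], y, "-", color="r", lw=1, label="sample")
    ax.set_yticks([])
    ax.set_xlabel("edge weight")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_casedrop(report: StabilityReport, path: str | Path) -> None:
    """Centrality stability: correlation with full sample vs. cases dropped."""
    if report.casedrop_curves is None:
        raise ValueError("report has no case-dropping curves")
    fig, ax = plt.subplots(figsize=(6, 4))
    for measure, curves in report.casedrop_curves.items():
        qs = sorted(curves)
        med = [np.median(curves[q]) for q in qs]
        lo = [np.quantile(curves[q], 0.025) for q in qs]
        hi = [np.quantile(curves[q], 0.975) for q in qs]
        line, = ax.plot(qs, med, "-o", ms=3, label=measure)
        ax.fill_between(qs, lo, hi, alpha=0.15, color=line.get_color())
    ax.axhline(report.threshold, color="0.5", ls="--", lw=0.8)
    ax.set_xlabel("proportion of cases dropped")
    ax.set_ylabel("correlation with full-sample centrality")
    ax.set_ylim(-1.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
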