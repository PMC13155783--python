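"""Diagnostic plots: funnel and leave-one-out forest."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from mrmediate.estimators import MREstimate

__all__ = ["funnel_plot", "loo_plot"]


def funnel_plot(funnel: pd.DataFrame, estimate: MREstimate, path) -> None:
    """Funnel of per-SNP ratios vs precision with the IVW estimate marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel["ratio"], funnel["precision"], s=18, alpha=0.8)
    ax.axvline(estimate.beta, color="firebrick", lw=1.2, label="IVW")
    ax.set_xlabel("Wald ratio (per-SNP causal estimate)")
    ax.set_ylabel("precision (1 / SE)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loo_plot(loo: pd.DataFrame, full: MREstimate, path) -> None:
    """Forest of leave-one-out IVW estimates with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(loo) + 1.5))
    y = range(len(loo))
    ax.errorbar(
        loo["beta"], list(y), xerr=1.96 * loo["se"], fmt="o", ms=3, lw=1,
        color="steelblue",
    )
    ax.axvline(full.beta, color="firebrick", lw=1.2)
    ax.axvline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_yticks(list(y))
    ax.set_yticklabels(loo["snp_id"], fontsize=6)
    ax.set_xlabel("IVW estimate omitting one SNP")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
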