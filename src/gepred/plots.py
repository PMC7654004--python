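"""Learning-curve and predictive-bias panels from an EvaluationReport."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import EvaluationReport  # noqa: E402

__all__ = ["plot_learning_curves", "plot_bias"]


def _per_method(report, metric):
    sub = report.metrics[report.metrics["metric"] == metric]
    for method, grp in sub.groupby("method"):
        grp = grp.sort_values("fraction")
        yield method, grp["fraction"].to_numpy(), grp["value"].to_numpy()


def plot_learning_curves(report: EvaluationReport, path=None):
    """Two panels: prediction correlation and MSEP vs training fraction."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for metric, ax, label in (("prediction_correlation", axes[0],
                               "Prediction correlation"),
                              ("msep", axes[1], "MSEP")):
        for method, x, y in _per_method(report, metric):
            ax.plot(x, y, marker="o", label=method)
        ax.set_xlabel("Training set used (%)")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bias(report: EvaluationReport, path=None):
    """Regression-slope bias vs training fraction (1 = unbiased)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, x, y in _per_method(report, "bias_slope"):
        ax.plot(x, y, marker="o", label=method)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("Training set used (%)")
    ax.set_ylabel("Slope of observed on predicted")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
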