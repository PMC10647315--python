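"""Report figures for an experiment suite.

All functions take an :class:`~lrtrend.evaluate.ExperimentSuite` and write a
PNG; they return the Figure for embedding elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ExperimentSuite, accuracy_by_fraction_report, consistency_index


def plot_score_boxes(suite: ExperimentSuite, path: str | Path, model: str = "rf"):
    """Box plots of held-out scores per experiment, split by response group."""
    scores = suite.rf_scores if model == "rf" else suite.sw_scores
    resp = suite.labels == 1
    fig, ax = plt.subplots(figsize=(10, 4))
    for grp, color, shift in ((resp, "tab:red", -0.18), (~resp, "tab:blue", 0.18)):
        data = [scores[e, grp][~np.isnan(scores[e, grp])] for e in range(suite.n_experiments)]
        ax.boxplot(
            data,
            positions=suite.ns + shift,
            widths=0.3,
            patch_artist=True,
            boxprops=dict(facecolor=color, alpha=0.5),
            medianprops=dict(color="black"),
            showfliers=False,
        )
    ax.axhline(0.5 if model == "rf" else 0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("fractions used (N)")
    ax.set_ylabel(f"{model.upper()} score")
    ax.set_title(f"{model.upper()} held-out scores (red: responders, blue: non-responders)")
    ax.set_xticks(suite.ns[:: max(1, len(suite.ns) // 14)])
    ax.set_xticklabels(suite.ns[:: max(1, len(suite.ns) // 14)])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_accuracy_bands(suite: ExperimentSuite, path: str | Path, bands=((2, 14), (15, 20), (21, 28))):
    """Accuracy versus fractions used, with fraction-band means overlaid."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(suite.ns, suite.rf_accuracy, "o-", label="RF accuracy")
    ax.plot(suite.ns, suite.sw_accuracy, "s-", label="SW accuracy")
    report = accuracy_by_fraction_report(suite, bands)
    for (lo, hi), (_, row) in zip(bands, report.iterrows()):
        ax.hlines(row["rf_accuracy"], lo, hi, color="tab:blue", ls=":", lw=2)
        ax.hlines(row["sw_accuracy"], lo, hi, color="tab:orange", ls=":", lw=2)
    ax.set_xlabel("fractions used (N)")
    ax.set_ylabel("LOOCV accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_sw_trends(suite: ExperimentSuite, path: str | Path):
    """Per-patient SW score trajectories across N (responders in red)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for j, p in enumerate(suite.patients):
        color = "tab:red" if suite.labels[j] == 1 else "tab:blue"
        ax.plot(suite.ns, suite.sw_scores[:, j], color=color, alpha=0.6, lw=1)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("fractions used (N)")
    ax.set_ylabel("SW score")
    ax.set_title("SW score trajectories (threshold 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_consistency(suite: ExperimentSuite, path: str | Path, model: str = "rf",
                     window_start: int = 15, cut: float = 0.8):
    """Per-patient correctness curves, fit error, and the consistency grouping."""
    ci = consistency_index(suite, model=model, window_start=window_start, cut=cut)
    correct = suite.rf_correct if model == "rf" else suite.sw_correct
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    running = np.cumsum(correct, axis=0) / np.arange(1, suite.n_experiments + 1)[:, None]
    for j, p in enumerate(suite.patients):
        color = "tab:green" if ci.loc[p, "group"] == "high" else "tab:purple"
        ax1.plot(suite.ns, running[:, j], color=color, alpha=0.6, lw=1)
    ax1.axhline(cut, color="black", ls="--", lw=0.8)
    ax1.set_ylabel("running consistency")
    ax1.set_title(f"consistency ({model.upper()}; green: high group, cut {cut})")
    ax2.plot(suite.ns, suite.mean_fit_err, "k.-")
    ax2.set_xlabel("fractions used (N)")
    ax2.set_ylabel("mean fit error (z-units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
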