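"""Cohort-comparison plotting.

A single generic view: where does a submission's score sit relative to a
cohort of other submissions, one panel per metric (e.g. AUROC, AUPR,
Spearman, Pearson).  This generalizes the per-challenge comparison figure
some motif-recognition scorers provide.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_score_vs_cohort"]


def plot_score_vs_cohort(submission: dict, cohort: dict, *, figsize=None):
    """Plot a submission (square) against a cohort (crosses), per metric.

    ``submission`` maps metric name -> value; ``cohort`` maps the same
    names -> sequences of cohort values.  Returns the matplotlib Figure.
    """
    import matplotlib.pyplot as plt

    metrics = [m for m in submission if m in cohort]
    if not metrics:
        raise ValueError("submission and cohort share no metric names")
    n = len(metrics)
    ncols = min(n, 2)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=figsize or (5 * ncols, 3 * nrows), squeeze=False
    )
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for ax, name in zip(axes.ravel(), metrics):
        values = np.asarray(cohort[name], dtype=float)
        jitter = rng.uniform(-0.15, 0.15, size=values.size)
        ax.plot(values, jitter, "k+", label="cohort")
        ax.plot([submission[name]], [0.0], "bs", markersize=9, label="submission")
        ax.set_yticks([])
        ax.set_xlabel(name)
        ax.legend(loc="best", fontsize="small")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig
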