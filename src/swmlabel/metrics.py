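"""Reproducibility and quality reporting for group-wise bundle labels.

The reproducibility of an inter-subject bundle label is the number of cohort
subjects in which it is found; a label present in every subject is maximally
reproducible.  Precision is summarized by the mean MDF between the bundle
centroids of different subjects sharing a label (lower = tighter
correspondence).  Heatmaps of the max-normalized fiber count per
(label, subject) visualize presence and variability at a glance.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry import mdf_distance


def reproducibility_counts(table: pd.DataFrame) -> pd.Series:
    """Distinct-subject count per inter-subject label.

    ``table`` is a :class:`~swmlabel.matching.CohortLabels` table.
    """
    return table.groupby("new_label")["subject"].nunique().sort_index()


def reproducibility_histogram(table: pd.DataFrame, cohort_size: int) -> pd.Series:
    """Number of labels found in exactly k subjects, k = 1..cohort size."""
    counts = reproducibility_counts(table)
    return counts.value_counts().reindex(range(1, cohort_size + 1), fill_value=0)


def intercluster_distance(centroids: list) -> float:
    """Mean MDF over all unordered pairs of one label's per-subject centroids.

    Undefined (NaN) for single-subject labels.
    """
    if len(centroids) < 2:
        return float("nan")
    dists = [mdf_distance(a, b) for a, b in combinations(centroids, 2)]
    return float(np.mean(dists))


def intercluster_distances(cohort_labels) -> pd.Series:
    """Per-label mean cross-subject centroid MDF for a whole cohort result."""
    by_label: dict = {}
    for s, bs in cohort_labels.bundle_sets.items():
        for b in bs.bundles:
            by_label.setdefault(b.label.render(), []).append(b.centroid)
    return pd.Series({lab: intercluster_distance(cents)
                      for lab, cents in sorted(by_label.items())})


def heatmap_matrix(table: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Fiber counts of the top-k most reproducible labels, max-normalized.

    Rows: labels ordered by descending subject count, ties by total fiber
    count descending; columns: subjects; entries in (0, 1], NaN where a
    subject lacks the bundle (absence, not zero).
    """
    counts = table.groupby("new_label").agg(
        subjects=("subject", "nunique"), fibers=("n_fibers", "sum"))
    order = counts.sort_values(["subjects", "fibers"],
                               ascending=[False, False]).index[:top_k]
    mat = table.pivot_table(index="new_label", columns="subject",
                            values="n_fibers", aggfunc="sum")
    mat = mat.reindex(order)
    peak = np.nanmax(mat.to_numpy()) if mat.size else np.nan
    if peak and not math.isnan(peak):
        mat = mat / peak
    return mat


def summary_table(table: pd.DataFrame, cohort_size: int,
                  top_k: int = 20) -> dict:
    """Headline reproducibility summary.

    Returns the maximum subject count among the top-k labels and the number
    of labels reaching at least 50% and 75% of the cohort (thresholds on
    ``ceil(p * S)`` subjects).
    """
    counts = reproducibility_counts(table)
    if counts.empty:
        return {"max_subjects_top": 0, "n_ge_50pct": 0, "n_ge_75pct": 0,
                "n_labels": 0}
    top = counts.sort_values(ascending=False).head(top_k)
    return {
        "max_subjects_top": int(top.max()),
        "n_ge_50pct": int((counts >= math.ceil(0.5 * cohort_size)).sum()),
        "n_ge_75pct": int((counts >= math.ceil(0.75 * cohort_size)).sum()),
        "n_labels": int(len(counts)),
    }


def plot_reproducibility_histogram(table, cohort_size, path):
    """Render the reproducibility histogram to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = reproducibility_histogram(table, cohort_size)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(hist.index, hist.to_numpy(), color="steelblue")
    ax.set_xlabel("subjects containing the bundle")
    ax.set_ylabel("number of bundles")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(table, path, top_k: int = 20):
    """Render the normalized fiber-count heatmap to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = heatmap_matrix(table, top_k=top_k)
    fig, ax = plt.subplots(figsize=(6, 0.3 * max(len(mat), 4) + 1.5))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="hot_r", vmin=0, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized fiber count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
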