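"""Differential composition analysis between peptide classes.

For each feature of a descriptor family the per-peptide values are
contrasted between the positive (anticancer) and negative class with a
two-sided two-sample test — Mann-Whitney rank test by default, chosen for
bounded, zero-inflated composition fractions; Welch's t-test is available.
Features with p below a significance level (default 0.01) are counted
without multiple-testing correction; a Benjamini-Hochberg-corrected count
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import featurize_dataset
from .sequence_io import LabelledDataset

TESTS = ("mannwhitney", "ttest")


@dataclass
class CompositionContrast:
    """Per-feature class contrast for one descriptor scheme."""

    scheme: str
    table: pd.DataFrame  # columns: feature, mean_pos, mean_neg, diff, p_value
    alpha: float
    n_significant: int

    def top_features(self, n: int) -> pd.DataFrame:
        return self.table.reindex(
            self.table["diff"].abs().sort_values(ascending=False).index
        ).head(n)


def _feature_pvalue(pos: np.ndarray, neg: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 1.0  # identical constant feature in both classes: no evidence
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    res = stats.ttest_ind(pos, neg, equal_var=False)
    return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0


def contrast_features(
    dataset: LabelledDataset,
    scheme: str,
    alpha: float = 0.01,
    test: str = "mannwhitney",
    correction: bool = False,
) -> CompositionContrast:
    """Compare every feature of ``scheme`` between the two classes.

    Returns one row per feature with class means, their difference
    (positive minus negative) and the two-sided p-value; ``n_significant``
    counts features with p < alpha (after Benjamini-Hochberg adjustment if
    ``correction`` is on).
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; use one of {TESTS}")
    X, y, names = featurize_dataset(dataset, scheme)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for a composition contrast")

    pvals = np.array([_feature_pvalue(pos[:, j], neg[:, j], test) for j in range(X.shape[1])])
    if correction:
        pvals = stats.false_discovery_control(pvals, method="bh")
    table = pd.DataFrame(
        {
            "feature": list(names),
            "mean_pos": pos.mean(axis=0),
            "mean_neg": neg.mean(axis=0),
            "diff": pos.mean(axis=0) - neg.mean(axis=0),
            "p_value": pvals,
        }
    )
    return CompositionContrast(
        scheme=scheme.upper(),
        table=table,
        alpha=alpha,
        n_significant=int((pvals < alpha).sum()),
    )


def plot_contrasts(
    contrast: CompositionContrast,
    top_n: int = 20,
    figure_path: str | None = None,
    table_path: str | None = None,
):
    """Grouped bar chart of class means for the top features by |difference|.

    Features significant at the contrast's alpha are starred. Writes the
    figure and a TSV of the plotted rows when paths are given; returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if top_n <= 0:
        raise ValueError("top_n must be positive")
    rows = contrast.top_features(top_n)
    x = np.arange(len(rows))
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(rows)), 4))
    ax.bar(x - 0.2, rows["mean_pos"], width=0.4, label="ACP")
    ax.bar(x + 0.2, rows["mean_neg"], width=0.4, label="non-ACP")
    marks = [
        f"{f}*" if p < contrast.alpha else f
        for f, p in zip(rows["feature"], rows["p_value"])
    ]
    ax.set_xticks(x)
    ax.set_xticklabels(marks, rotation=90)
    ax.set_ylabel("mean composition fraction")
    ax.set_title(f"{contrast.scheme}: class means (* p < {contrast.alpha:g})")
    ax.legend()
    fig.tight_layout()
    if figure_path:
        fig.savefig(figure_path, dpi=150)
    if table_path:
        rows.to_csv(table_path, sep="\t", index=False)
    return fig
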