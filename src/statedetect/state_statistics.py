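"""Nonparametric significance testing of features across detected states.

EEG features are non-normal, so state contrasts use rank tests:

* between every unordered pair of states, a two-sided Mann-Whitney U test
  per feature;
* within every state, a one-sample Wilcoxon signed-rank test of the state's
  values against the recording-wide median of the feature.

p-values are Bonferroni-corrected with the family being all features within
one comparison (one state pair, or one state-vs-median sweep); reported per
comparison is the percentage of features significant at the corrected
level.  Windowed synchrony features make adjacent epochs serially
dependent; the tests are computed on the epochs as-is and the caveat is
carried in the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._partition import SegmentPartition
from .features import FeatureTable

__all__ = ["SignificanceMatrix", "pairwise_state_tests", "state_vs_median_tests"]

DEPENDENCY_NOTE = (
    "synchrony features use sliding windows over adjacent epochs; "
    "epochs are serially dependent and the rank tests treat them as exchangeable"
)


@dataclass
class SignificanceMatrix:
    """States x states matrix of % significant features (corrected p < alpha)."""

    matrix: pd.DataFrame
    alpha: float
    n_features: int
    note: str = DEPENDENCY_NOTE

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def _mwu_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per column of (n, f) samples."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
    return np.atleast_1d(res.pvalue)


def pairwise_state_tests(
    features: FeatureTable, partition: SegmentPartition, alpha: float = 0.01
) -> SignificanceMatrix:
    """Mann-Whitney U per feature for every unordered state pair.

    Bonferroni correction multiplies each p-value by the number of features
    (the per-pair family); the matrix entry is the percentage of features
    with corrected p < alpha.  Pairs with a state smaller than two epochs
    are flagged untestable (NaN).
    """
    if partition.n_epochs != features.n_epochs:
        raise ValueError("partition and feature table cover different epoch counts")
    k = partition.n_states
    nf = features.n_features
    mat = np.zeros((k, k))
    segs = partition.segments
    for i in range(k):
        for j in range(i + 1, k):
            a = features.values[segs[i][0]:segs[i][1]]
            b = features.values[segs[j][0]:segs[j][1]]
            if len(a) < 2 or len(b) < 2:
                mat[i, j] = mat[j, i] = np.nan
                continue
            p = _mwu_pvalues(a, b) * nf  # Bonferroni
            mat[i, j] = mat[j, i] = 100.0 * (p < alpha).mean()
    idx = pd.Index([f"St{i + 1}" for i in range(k)])
    return SignificanceMatrix(pd.DataFrame(mat, index=idx, columns=idx), alpha, nf)


def state_vs_median_tests(
    features: FeatureTable,
    partition: SegmentPartition,
    alpha: float = 0.01,
    *,
    groups: tuple[str, ...] = ("band", "kind"),
) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank of each state against feature medians.

    Per state and feature, the within-state values are tested against the
    recording-wide median of that feature (all-tied samples get p = 1 by
    convention, so constant features are never significant).  Bonferroni
    correction is across features.  Returns a per-state frame with the
    overall percentage of significant features and per-group breakdowns.
    """
    if partition.n_epochs != features.n_epochs:
        raise ValueError("partition and feature table cover different epoch counts")
    medians = np.median(features.values, axis=0)
    nf = features.n_features
    rows = []
    for s in range(partition.n_states):
        lo, hi = partition.segments[s]
        diffs = features.values[lo:hi] - medians
        pvals = np.ones(nf)
        testable = (diffs != 0).any(axis=0)
        if testable.any():
            with np.errstate(invalid="ignore"):
                res = stats.wilcoxon(
                    diffs[:, testable], zero_method="zsplit", method="approx", axis=0
                )
            pvals[testable] = np.atleast_1d(res.pvalue)
        sig = (pvals * nf) < alpha
        row = {"pct_significant": 100.0 * sig.mean()}
        for group_col in groups:
            for value in dict.fromkeys(features.meta[group_col].dropna()):
                m = (features.meta[group_col] == value).to_numpy()
                row[f"{group_col}:{value}"] = 100.0 * sig[m].mean()
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(range(1, partition.n_states + 1), name="state"))
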