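"""Weight-of-evidence / information-value feature importance for states.

Detecting which features distinguish one state from the rest of a recording
is a binary-classification feature-importance problem: per state, the event
class is membership in that state.  Per feature, values are binned into
quantile bins of the pooled distribution; each bin's weight of evidence is
WoE = ln(event_share / nonevent_share), and the information value is
IV = sum over bins of (event_share - nonevent_share) * WoE, which is
always >= 0 and zero iff the binned class distributions coincide.

IV is invariant under strictly monotone transforms of the feature (quantile
bins are rank-based).  Interpretation bands used for reporting (thresholds
deliberately higher than the credit-scoring convention because windowed EEG
features are serially dependent): < 0.2 useless, 0.2-0.4 weak, 0.4-0.6
medium, 0.6-1 strong, > 1 very strong / suspicious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._partition import SegmentPartition
from .features import FeatureTable

__all__ = ["woe_iv", "interpret_iv", "iv_report", "IVReport", "iv_values"]

# band edges: < 0.2 useless, [0.2, 0.4) weak, [0.4, 0.6) medium,
# [0.6, 1] strong, > 1 very strong / suspicious
IV_BANDS = (
    (0.2, "useless"),
    (0.4, "weak"),
    (0.6, "medium"),
)


def _bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    return np.unique(qs)


def woe_iv(feature: np.ndarray, event: np.ndarray, n_bins: int = 10):
    """WoE table and information value of one feature for one event class.

    Binning is by quantiles of the pooled distribution; when any bin has a
    zero event or non-event count, 0.5 is added to both counts in every bin
    (Laplace-style smoothing) so the WoE stays finite.

    Returns (table, iv) where ``table`` has per-bin counts, shares, WoE and
    IV contributions.
    """
    feature = np.asarray(feature, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.all() or not event.any():
        raise ValueError("both event and non-event classes must be non-empty")
    edges = _bin_edges(feature, n_bins)
    if len(edges) < 2:  # constant feature: one degenerate bin, no information
        table = pd.DataFrame(
            {"lo": [feature[0]], "hi": [feature[0]],
             "event_count": [event.sum()], "nonevent_count": [(~event).sum()],
             "event_share": [1.0], "nonevent_share": [1.0], "woe": [0.0], "iv": [0.0]}
        )
        return table, 0.0
    bins = np.clip(np.searchsorted(edges, feature, side="right") - 1, 0, len(edges) - 2)
    k = len(edges) - 1
    ev = np.bincount(bins[event], minlength=k).astype(float)
    nv = np.bincount(bins[~event], minlength=k).astype(float)
    if (ev == 0).any() or (nv == 0).any():
        ev = ev + 0.5
        nv = nv + 0.5
    ev_share = ev / ev.sum()
    nv_share = nv / nv.sum()
    woe = np.log(ev_share / nv_share)
    contrib = (ev_share - nv_share) * woe
    table = pd.DataFrame(
        {"lo": edges[:-1], "hi": edges[1:], "event_count": ev, "nonevent_count": nv,
         "event_share": ev_share, "nonevent_share": nv_share, "woe": woe, "iv": contrib}
    )
    return table, float(contrib.sum())


def interpret_iv(iv: float) -> str:
    """Interpretation band of an information value."""
    if iv < 0:
        raise ValueError(f"IV must be non-negative, got {iv}")
    for upper, label in IV_BANDS:
        if iv < upper:
            return label
    return "strong" if iv <= 1.0 else "very strong/suspicious"


def iv_values(features: FeatureTable, event: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Information value of every column for one event indicator."""
    n_bins_eff = n_bins
    if event.sum() < n_bins or (~event).sum() < n_bins:
        import warnings

        n_bins_eff = max(2, int(min(event.sum(), (~event).sum())))
        warnings.warn(f"small class: reducing IV bins from {n_bins} to {n_bins_eff}")
    return np.array(
        [woe_iv(features.values[:, j], event, n_bins_eff)[1] for j in range(features.n_features)]
    )


@dataclass
class IVReport:
    """Per-state IV summary with band/kind group breakdowns.

    ``iv`` is states x features; shares are percentages in [0, 100].
    """

    iv: pd.DataFrame                    # index: state id; columns: feature names
    summary: pd.DataFrame               # per state: % of dataset, average IV, % with IV >= threshold
    group_shares: pd.DataFrame          # per state x group: % of group features with IV >= threshold
    threshold: float

    def to_csv(self, path) -> None:
        pd.concat([self.summary, self.group_shares], axis=1).to_csv(path)


def iv_report(
    features: FeatureTable,
    partition: SegmentPartition,
    *,
    n_bins: int = 10,
    threshold: float = 0.4,
    groups: tuple[str, ...] = ("band", "kind"),
) -> IVReport:
    """IV of every feature for every state, with group summaries.

    Per state the event indicator is membership in that state; reported per
    state are the share of epochs, the average IV over features, and the
    percentage of features at or above ``threshold`` overall and within
    each metadata group (frequency bands and feature kinds by default).
    """
    if partition.n_epochs != features.n_epochs:
        raise ValueError("partition and feature table cover different epoch counts")
    labels = partition.labels()
    states = range(partition.n_states)
    iv_rows = []
    summary_rows = []
    group_rows = []
    for s in states:
        event = labels == s
        iv = iv_values(features, event, n_bins)
        iv_rows.append(iv)
        summary_rows.append(
            {
                "pct_of_dataset": 100.0 * event.mean(),
                "average_iv": iv.mean(),
                "pct_iv_ge_threshold": 100.0 * (iv >= threshold).mean(),
            }
        )
        row = {}
        for group_col in groups:
            for value in dict.fromkeys(features.meta[group_col].dropna()):
                m = (features.meta[group_col] == value).to_numpy()
                row[f"{group_col}:{value}"] = 100.0 * (iv[m] >= threshold).mean()
        group_rows.append(row)
    index = pd.Index([s + 1 for s in states], name="state")
    return IVReport(
        iv=pd.DataFrame(iv_rows, index=index, columns=features.names),
        summary=pd.DataFrame(summary_rows, index=index),
        group_shares=pd.DataFrame(group_rows, index=index),
        threshold=threshold,
    )
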