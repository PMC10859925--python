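"""Artifact-epoch rejection and the feature-space reduction for the detector.

Two steps sit between raw feature tables and the state detector:

1. :class:`ArtifactEpochRejector` drops epochs whose band/region power is an
   outlier (beyond 3 standard deviations in at least one PSD column).
2. :class:`FeatureScalerPCA` log-transforms PSD-like columns, z-scores every
   column and projects onto the leading principal components (15 by default
   for the detector, 20 for classifiers).

Both follow the scikit-learn estimator protocol so they compose with
pipelines; fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .features import FeatureTable

__all__ = ["ArtifactEpochRejector", "FeatureScalerPCA", "reject_artifact_epochs", "fit_transform_features"]


class ArtifactEpochRejector(BaseEstimator):
    """Drop outlier epochs based on band/region PSD columns.

    Per column, mean and SD are computed once over the full (uncleaned)
    table; an epoch is rejected if any PSD column deviates from its mean by
    more than ``n_std`` standard deviations.  Zero-SD columns never flag an
    epoch (zero deviation never exceeds the threshold).  A single pass is
    the default; ``iterate=True`` repeats with recomputed statistics until
    no epoch is flagged.
    """

    def __init__(self, n_std: float = 3.0, iterate: bool = False):
        self.n_std = n_std
        self.iterate = iterate

    def _flag(self, values: np.ndarray) -> np.ndarray:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore"):
            dev = np.abs(values - mean)
        # zero-SD columns: zero deviation never exceeds the threshold
        return (dev > self.n_std * np.where(sd > 0, sd, np.inf)).any(axis=1)

    def fit(self, table: FeatureTable) -> "ArtifactEpochRejector":
        psd = table.select(kind="psd")
        if psd.n_features == 0:
            raise ValueError("rejection requires psd columns")
        n = psd.n_epochs
        keep = np.ones(n, dtype=bool)
        while True:
            bad = self._flag(psd.values[keep])
            if not bad.any():
                break
            idx = np.flatnonzero(keep)[bad]
            keep[idx] = False
            if not keep.any():
                raise ValueError("all epochs rejected as artifacts")
            if not self.iterate:
                break
        self.keep_mask_ = keep
        self.rejected_indices_ = np.flatnonzero(~keep)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return table.take_epochs(self.keep_mask_)

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        return self.fit(table).transform(table)


def reject_artifact_epochs(psd: FeatureTable, n_std: float = 3.0):
    """Functional wrapper: returns (cleaned table, rejected original indices)."""
    rej = ArtifactEpochRejector(n_std=n_std).fit(psd)
    return rej.transform(psd), rej.rejected_indices_


class FeatureScalerPCA(BaseEstimator, TransformerMixin):
    """log -> z-score -> PCA reduction of a feature table.

    PSD and PSD-ratio columns are log-transformed (they are approximately
    log-normal); synchrony-index columns are left on their native scale.
    Every column is then z-scored and the table projected onto the leading
    ``n_components`` principal axes.  Components are sign-fixed so the
    largest-magnitude loading of each is positive, making outputs
    reproducible across platforms.
    """

    LOG_KINDS = ("psd", "psd_ratio")

    def __init__(self, n_components: int = 15):
        self.n_components = n_components

    def _design(self, table: FeatureTable) -> np.ndarray:
        X = table.values.copy()
        logm = table.mask(kind=list(self.LOG_KINDS))
        if logm.any():
            if np.any(X[:, logm] <= 0):
                raise ValueError("log-transformed columns must be strictly positive")
            X[:, logm] = np.log(X[:, logm])
        return X

    def fit(self, table: FeatureTable) -> "FeatureScalerPCA":
        X = self._design(table)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # tolerance absorbs roundoff in the mean of a constant column
        self.keep_cols_ = sd > 1e-10 * np.maximum(1.0, np.abs(self.mean_))
        if not self.keep_cols_.all():
            dropped = [table.names[i] for i in np.flatnonzero(~self.keep_cols_)]
            warnings.warn(f"dropping {len(dropped)} constant column(s): {dropped[:5]}...")
        self.scale_ = np.where(self.keep_cols_, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        Z = Z[:, self.keep_cols_]
        k = min(self.n_components, Z.shape[0], Z.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(Z)
        # orient each axis so its largest-|loading| entry is positive
        flip = np.sign(
            pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
        )
        flip[flip == 0] = 1.0
        self.components_ = pca.components_ * flip[:, None]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.pca_mean_ = pca.mean_
        self.n_components_ = k
        self.feature_names_in_ = np.array(table.names)
        return self

    def transform(self, table: FeatureTable) -> np.ndarray:
        X = self._design(table)
        Z = ((X - self.mean_) / self.scale_)[:, self.keep_cols_]
        return (Z - self.pca_mean_) @ self.components_.T

    def to_dict(self) -> dict:
        """JSON-serializable fitted state (reapply to surrogate variants)."""
        return {
            "n_components": self.n_components_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "keep_cols": self.keep_cols_.tolist(),
            "pca_mean": self.pca_mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "feature_names": self.feature_names_in_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScalerPCA":
        obj = cls(n_components=d["n_components"])
        obj.mean_ = np.array(d["mean"])
        obj.scale_ = np.array(d["scale"])
        obj.keep_cols_ = np.array(d["keep_cols"], dtype=bool)
        obj.pca_mean_ = np.array(d["pca_mean"])
        obj.components_ = np.array(d["components"])
        obj.explained_variance_ratio_ = np.array(d["explained_variance_ratio"])
        obj.n_components_ = d["n_components"]
        obj.feature_names_in_ = np.array(d["feature_names"])
        return obj


def fit_transform_features(table: FeatureTable, n_components: int = 15):
    """Functional wrapper: returns (reduced matrix, fitted transformer)."""
    tf = FeatureScalerPCA(n_components=n_components)
    X = tf.fit(table).transform(table)
    return X, tf
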