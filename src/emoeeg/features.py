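"""Canonical 27-feature indexing and batch extraction to feature tables.

Feature ids are 1-based and fixed: 1-18 linear (alpha 1-6, theta 7-12,
beta 13-18; per band: peak, average value, variance, centre frequency,
maximum power, power sum), 19-27 nonlinear (singular spectral entropy,
K entropy, approximate entropy, maximum Lyapunov exponent, C0 complexity,
sample entropy, spectral entropy, Lempel-Ziv complexity, correlation
dimension).  Tables are pandas DataFrames with columns f01..f27 plus label
and dataset/trial/electrode ids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import features_linear as fl
from . import features_nonlinear as fnl
from .synthetic import DEFAULT_BAND_RANGES, LabeledDataset

FEATURE_NAMES = {
    1: "Alpha peak", 2: "Alpha average value", 3: "Alpha variance",
    4: "Alpha centre frequency", 5: "Alpha maximum power", 6: "Alpha power sum",
    7: "Theta peak", 8: "Theta average value", 9: "Theta variance",
    10: "Theta centre frequency", 11: "Theta maximum power", 12: "Theta power sum",
    13: "Beta peak", 14: "Beta average value", 15: "Beta variance",
    16: "Beta centre frequency", 17: "Beta maximum power", 18: "Beta power sum",
    19: "Singular spectral entropy", 20: "Entropy of K", 21: "Approximate entropy",
    22: "Maximum Lyapunov exponent", 23: "Complexity of C0", 24: "Sample entropy",
    25: "Spectral entropy", 26: "Lempel–Ziv complexity", 27: "Correlation dimension",
}

FEATURE_COLUMNS = [f"f{i:02d}" for i in range(1, 28)]

#: feature ids the study's selection procedures single out (6 linear + 6
#: nonlinear); used as the reference selected subset
SELECTED_12 = (4, 8, 10, 14, 16, 17, 20, 21, 22, 23, 25, 26)


def feature_dictionary() -> pd.DataFrame:
    """Canonical id -> name data dictionary (written next to feature tables)."""
    return pd.DataFrame(
        {"feature_id": list(FEATURE_NAMES), "name": list(FEATURE_NAMES.values())}
    )


def extract_epoch_features(
    epoch: np.ndarray,
    fs: float,
    band_ranges: dict | None = None,
    band_method: str = "butter",
    params: fnl.NonlinearParams | None = None,
) -> np.ndarray:
    """27-vector of one single-channel epoch, canonical order."""
    lin = fl.extract_linear(epoch, fs, band_ranges, band_method=band_method)
    non = fnl.extract_nonlinear(epoch, params)
    return np.concatenate([lin.values(), non.values()])


class EpochFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: (n_epochs, n_samples) -> (n_epochs, 27).

    Composes with sklearn pipelines; `fit` only validates input.  The
    nonlinear estimator settings travel in ``params``.
    """

    def __init__(self, fs=256.0, band_ranges=None, band_method="butter", params=None):
        self.fs = fs
        self.band_ranges = band_ranges
        self.band_method = band_method
        self.params = params

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d array of epochs (n_epochs, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.array([
            extract_epoch_features(
                row, self.fs, self.band_ranges, self.band_method, self.params
            )
            for row in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_COLUMNS)


def extract_features(
    datasets: LabeledDataset | list[LabeledDataset],
    band_ranges: dict | None = None,
    band_method: str = "butter",
    params: fnl.NonlinearParams | None = None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table for one or more labeled datasets.

    One row per (dataset, trial, electrode); columns f01..f27 + label.
    ``channels`` restricts extraction to a subset of electrode names.
    """
    if isinstance(datasets, LabeledDataset):
        datasets = [datasets]
    band_ranges = dict(band_ranges or DEFAULT_BAND_RANGES)
    rows = []
    for ds in datasets:
        ch_idx = [
            i for i, name in enumerate(ds.channel_names)
            if channels is None or name in channels
        ]
        for t in range(ds.data.shape[0]):
            for c in ch_idx:
                feats = extract_epoch_features(
                    ds.data[t, c], ds.fs, band_ranges, band_method, params
                )
                row = {"dataset": ds.dataset_id, "trial": t,
                       "electrode": ds.channel_names[c], "label": ds.labels[t]}
                row.update(dict(zip(FEATURE_COLUMNS, feats)))
                rows.append(row)
    return pd.DataFrame(rows)


def table_matrix(table: pd.DataFrame, electrode: str | None = None,
                 feature_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a feature table, optionally restricted to one
    electrode and a feature-id subset."""
    from .synthetic import EMOTION_CODES

    sub = table if electrode is None else table[table["electrode"] == electrode]
    cols = FEATURE_COLUMNS if feature_ids is None else [f"f{i:02d}" for i in feature_ids]
    X = sub[cols].to_numpy(dtype=float)
    y = sub["label"].map(EMOTION_CODES).to_numpy()
    return X, y
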