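"""Correlation-based feature selection (CFS).

Features and class labels are discretized (equal-frequency bins), their
dependence measured by symmetric uncertainty SU(X, Y) = 2 * IG / (H(X) +
H(Y)) with base-2 plug-in entropies, and candidate subsets scored by the
CFS merit

    Merit(S) = k * su_cf_mean / sqrt(k + k (k - 1) * su_ff_mean)

which trades mean feature-class relevance against mean feature-feature
redundancy.  A greedy forward search grows the subset one feature at a time
(first pick: max class SU, which equals the k=1 merit), emitting a full
ranking with nested prefix subsets.  Two study-level summaries are
provided: the per-feature class-SU average over datasets with a selection
threshold, and top-k selection-frequency counts over many rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin


class CfsError(ValueError):
    pass


@dataclass
class DiscreteFeatureTable:
    """Trials x features bin-index matrix plus discrete labels."""

    bins: np.ndarray
    labels: np.ndarray
    feature_ids: list
    bin_edges: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.bins.shape[1]


@dataclass
class MeritScore:
    subset: tuple
    merit: float
    rcf_bar: float
    rff_bar: float

    @property
    def k(self) -> int:
        return len(self.subset)


@dataclass
class FeatureRanking:
    """Greedy CFS ordering: feature ids in pick order + per-step merit."""

    order: list
    steps: list  # list[MeritScore], one per prefix

    def nested_subsets(self):
        return [tuple(self.order[: i + 1]) for i in range(len(self.order))]

    def top(self, k: int) -> tuple:
        return tuple(self.order[:k])

    @property
    def best(self) -> MeritScore:
        return max(self.steps, key=lambda s: s.merit)


# ---------------------------------------------------------------------------
# discretization

def discretize_column(x: np.ndarray, n_bins: int = 5) -> tuple[np.ndarray, np.ndarray, bool]:
    """Equal-frequency binning of one column.

    Tied values always share a bin (binning by average rank), so constant or
    few-valued columns use fewer bins and are flagged.  With all-distinct
    values bin populations differ by at most 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    avg_rank = pd.Series(x).rank(method="average").to_numpy() - 1.0
    bins = np.floor(avg_rank * n_bins / n).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    # relabel to consecutive ids
    uniq, bins = np.unique(bins, return_inverse=True)
    degenerate = len(uniq) < min(n_bins, n)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    return bins, edges, degenerate


def discretize(features: np.ndarray, n_bins: int = 5, labels=None,
               feature_ids=None) -> DiscreteFeatureTable:
    """Equal-frequency discretization of a trials x features matrix."""
    if n_bins < 2:
        raise CfsError("n_bins must be >= 2")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, p = features.shape
    feature_ids = list(feature_ids) if feature_ids is not None else list(range(1, p + 1))
    out = np.empty((n, p), dtype=int)
    edges, flags = [], {}
    for j in range(p):
        b, e, degenerate = discretize_column(features[:, j], n_bins)
        out[:, j] = b
        edges.append(e)
        if degenerate:
            flags[feature_ids[j]] = "fewer bins than requested (ties/constant)"
    labels = np.asarray(labels) if labels is not None else np.zeros(n, dtype=int)
    return DiscreteFeatureTable(bins=out, labels=labels, feature_ids=feature_ids,
                                bin_edges=edges, flags=flags)


# ---------------------------------------------------------------------------
# information-theoretic correlations (base-2 plug-in estimates)

def entropy(y) -> float:
    """Plug-in Shannon entropy in bits."""
    y = np.asarray(y)
    if y.size == 0:
        raise CfsError("empty sequence")
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(x, y) -> float:
    x = np.asarray(x)
    y = np.asarray(y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = xi.astype(np.int64) * (yi.max() + 1) + yi
    return entropy(joint)


def conditional_entropy(y, x) -> float:
    """H(Y | X) in bits, empirical joint probabilities."""
    y = np.asarray(y)
    x = np.asarray(x)
    if len(x) != len(y):
        raise CfsError("length mismatch between sequences")
    return _joint_entropy(x, y) - entropy(x)


def info_gain(y, x) -> float:
    """IG = H(Y) - H(Y|X) = H(X) + H(Y) - H(X,Y); symmetric, >= 0."""
    y = np.asarray(y)
    x = np.asarray(x)
    if len(x) != len(y):
        raise CfsError("length mismatch between sequences")
    return max(0.0, entropy(x) + entropy(y) - _joint_entropy(x, y))


def symmetric_uncertainty(x, y) -> float:
    """SU = 2 * IG / (H(X) + H(Y)) in [0, 1]; 0 if both entropies vanish."""
    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0.0:
        return 0.0
    return float(np.clip(2.0 * info_gain(y, x) / (hx + hy), 0.0, 1.0))


# ---------------------------------------------------------------------------
# merit and greedy forward search

def _su_matrices(table: DiscreteFeatureTable):
    """Class-SU vector and feature-feature SU matrix (cached per table)."""
    p = table.n_features
    su_c = np.array([
        symmetric_uncertainty(table.bins[:, j], table.labels) for j in range(p)
    ])
    su_ff = np.eye(p)
    for i, j in combinations(range(p), 2):
        su_ff[i, j] = su_ff[j, i] = symmetric_uncertainty(table.bins[:, i], table.bins[:, j])
    return su_c, su_ff


def merit_from_means(k: int, rcf_bar: float, rff_bar: float) -> float:
    return k * rcf_bar / np.sqrt(k + k * (k - 1) * rff_bar)


def merit(subset, table: DiscreteFeatureTable, _cache=None) -> MeritScore:
    """CFS merit of a feature-id subset; the redundancy term vanishes at k=1
    so the singleton merit equals the class SU."""
    subset = tuple(subset)
    if not subset:
        raise CfsError("empty subset")
    idx = []
    for fid in subset:
        if fid not in table.feature_ids:
            raise CfsError(f"unknown feature id {fid}")
        idx.append(table.feature_ids.index(fid))
    su_c, su_ff = _cache if _cache is not None else _su_matrices(table)
    k = len(idx)
    rcf = float(np.mean(su_c[idx]))
    if k == 1:
        rff = 0.0
    else:
        pairs = [(a, b) for a, b in combinations(idx, 2)]
        rff = float(np.mean([su_ff[a, b] for a, b in pairs]))
    return MeritScore(subset=subset, merit=float(merit_from_means(k, rcf, rff)),
                      rcf_bar=rcf, rff_bar=rff)


def greedy_rank(table: DiscreteFeatureTable) -> FeatureRanking:
    """Greedy forward CFS: start from the max class-SU feature, then grow by
    max merit; ties broken by lower canonical feature id."""
    p = table.n_features
    if p < 2:
        raise CfsError("need at least 2 features to rank")
    cache = _su_matrices(table)
    remaining = list(table.feature_ids)
    order: list = []
    steps: list = []
    while remaining:
        best = None
        for fid in remaining:
            sc = merit(tuple(order) + (fid,), table, _cache=cache)
            key = (-sc.merit, fid)
            if best is None or key < best[0]:
                best = (key, fid, sc)
        _, fid, sc = best
        order.append(fid)
        steps.append(sc)
        remaining.remove(fid)
    return FeatureRanking(order=order, steps=steps)


def exhaustive_best_subset(table: DiscreteFeatureTable) -> MeritScore:
    """Brute-force max-merit subset (oracle; only viable for few features)."""
    cache = _su_matrices(table)
    best = None
    ids = table.feature_ids
    for k in range(1, len(ids) + 1):
        for subset in combinations(ids, k):
            sc = merit(subset, table, _cache=cache)
            if best is None or sc.merit > best.merit:
                best = sc
    return best


# ---------------------------------------------------------------------------
# study-level summaries

def class_correlations(table: DiscreteFeatureTable) -> np.ndarray:
    """Per-feature SU with the class labels."""
    su_c = np.array([
        symmetric_uncertainty(table.bins[:, j], table.labels)
        for j in range(table.n_features)
    ])
    return su_c


def average_class_correlation(tables, threshold: float = 0.1):
    """Mean class SU per feature over datasets and the strict-threshold
    selection (mean SU > threshold).

    Returns (mean_su: pd.Series indexed by feature id, selected: list).
    """
    tables = list(tables)
    if not tables:
        raise CfsError("need at least one dataset table")
    ids = tables[0].feature_ids
    sus = np.array([class_correlations(t) for t in tables])
    mean_su = pd.Series(sus.mean(axis=0), index=ids)
    selected = [fid for fid in ids if mean_su[fid] > threshold]
    return mean_su, selected


def threshold_selection(values_by_id: dict, threshold: float = 0.1) -> list:
    """Features whose (already averaged) class-correlation value exceeds the
    threshold strictly; works directly on printed summary columns."""
    return [fid for fid, v in values_by_id.items() if v > threshold]


def selection_frequency(rankings, top_k: int = 10, min_times: int = 20):
    """Chosen-times counts: how often each feature lands in the top-k of a
    ranking; features with count > min_times are labelled High.

    Returns a DataFrame (feature_id, chosen_times, correlation_degree).
    """
    if top_k < 1:
        raise CfsError("top_k must be >= 1")
    rankings = list(rankings)
    counts: dict = {}
    all_ids: set = set()
    for r in rankings:
        all_ids.update(r.order)
        for fid in r.top(top_k):
            counts[fid] = counts.get(fid, 0) + 1
    ids = sorted(all_ids)
    rows = []
    for fid in ids:
        c = counts.get(fid, 0)
        rows.append({"feature_id": fid, "chosen_times": c,
                     "correlation_degree": "High" if c > min_times else "Low"})
    return pd.DataFrame(rows)


def chosen_times_selection(counts_by_id: dict, min_times: int = 20) -> list:
    """Features whose chosen-times count exceeds min_times strictly."""
    return [fid for fid, c in counts_by_id.items() if c > min_times]


# ---------------------------------------------------------------------------
# sklearn estimators

class CfsRanker(BaseEstimator):
    """Greedy CFS ranking as a fit-able estimator.

    Attributes after fit: ranking_ (FeatureRanking), order_ (list of column
    indices in pick order), merits_ (per-step merit values).
    """

    def __init__(self, n_bins: int = 5):
        self.n_bins = n_bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        table = discretize(X, self.n_bins, labels=y,
                           feature_ids=list(range(1, X.shape[1] + 1)))
        self.ranking_ = greedy_rank(table)
        self.order_ = [fid - 1 for fid in self.ranking_.order]
        self.merits_ = [s.merit for s in self.ranking_.steps]
        self.n_features_in_ = X.shape[1]
        return self


class CfsSelector(SelectorMixin, BaseEstimator):
    """CFS feature selector usable in sklearn pipelines.

    mode="merit": keep the greedy prefix with maximal merit.
    mode="threshold": keep features whose class SU exceeds ``threshold``.
    mode="top_k": keep the first ``k`` greedily ranked features.
    """

    def __init__(self, mode: str = "merit", threshold: float = 0.1, k: int = 10,
                 n_bins: int = 5):
        self.mode = mode
        self.threshold = threshold
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        table = discretize(X, self.n_bins, labels=y,
                           feature_ids=list(range(1, X.shape[1] + 1)))
        if self.mode == "threshold":
            su = class_correlations(table)
            self.scores_ = su
            self.support_ = su > self.threshold
            if not self.support_.any():  # never select nothing
                self.support_[int(np.argmax(su))] = True
        elif self.mode in ("merit", "top_k"):
            ranking = greedy_rank(table)
            self.ranking_ = ranking
            keep = (ranking.best.subset if self.mode == "merit"
                    else ranking.top(min(self.k, X.shape[1])))
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[[fid - 1 for fid in keep]] = True
            self.support_ = mask
        else:
            raise CfsError(f"unknown mode {self.mode!r}")
        return self

    def _get_support_mask(self):
        return self.support_


def ranking_to_frame(ranking: FeatureRanking, names: dict | None = None) -> pd.DataFrame:
    """Serializable merit path (step, feature_id, name, merit, means)."""
    rows = []
    for step, sc in enumerate(ranking.steps, start=1):
        fid = ranking.order[step - 1]
        rows.append({
            "step": step, "feature_id": fid,
            "feature_name": (names or {}).get(fid, str(fid)),
            "merit": sc.merit, "rcf_bar": sc.rcf_bar, "rff_bar": sc.rff_bar,
        })
    return pd.DataFrame(rows)
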