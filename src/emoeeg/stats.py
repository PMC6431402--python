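"""Statistical summaries: paired t-test non-rejection counts per electrode,
variance-homogeneity / one-way ANOVA utilities, and per-emotion feature
histograms with shared bin edges.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import FEATURE_COLUMNS
from .synthetic import EMOTIONS


class StatsError(ValueError):
    pass


EMOTION_PAIRS = tuple(combinations(EMOTIONS, 2))


def paired_ttest_counts(feature_tables, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of paired-t-test p-values above alpha (non-rejections).

    For every electrode, emotion pair, dataset and feature, the two
    emotions' per-trial feature values (paired by within-dataset trial rank)
    are compared with a paired t-test; the cell counts p > alpha over
    features x datasets.  A zero-variance difference vector has no defined
    p and is counted as a non-rejection (flagged).  The returned frame has
    one row per emotion pair, one column per electrode, plus a Total row.
    """
    tables = list(feature_tables)
    if not tables:
        raise StatsError("no feature tables")
    electrodes = list(dict.fromkeys(tables[0]["electrode"]))
    counts = pd.DataFrame(0, index=[f"{a}-{b}" for a, b in EMOTION_PAIRS],
                          columns=electrodes)
    n_flagged = 0
    for table in tables:
        for el in electrodes:
            sub = table[table["electrode"] == el]
            by_emo = {
                e: sub[sub["label"] == e].sort_values("trial")[FEATURE_COLUMNS].to_numpy()
                for e in EMOTIONS
            }
            for a, b in EMOTION_PAIRS:
                xa, xb = by_emo[a], by_emo[b]
                if len(xa) != len(xb):
                    raise StatsError("unequal trial counts between emotions")
                diff = xa - xb
                sd = diff.std(axis=0, ddof=1)
                cell = 0
                for j in range(diff.shape[1]):
                    if sd[j] == 0.0:
                        cell += 1  # undefined p, counted as non-rejection
                        n_flagged += 1
                        continue
                    p = sst.ttest_rel(xa[:, j], xb[:, j]).pvalue
                    if p > alpha:
                        cell += 1
                counts.loc[f"{a}-{b}", el] += cell
    counts.loc["Total"] = counts.sum(axis=0)
    counts.attrs["zero_variance_cells"] = n_flagged
    return counts


def levene_test(*groups, center: str = "median"):
    """Brown-Forsythe (median-centred) Levene test; returns (stat, p)."""
    _check_groups(groups)
    res = sst.levene(*groups, center=center)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups):
    """Classical one-way ANOVA F test; returns (F, p)."""
    _check_groups(groups)
    res = sst.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def _check_groups(groups):
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    for g in groups:
        if len(np.asarray(g)) < 2:
            raise StatsError("each group needs at least 2 values")


def feature_histograms(
    feature_table: pd.DataFrame,
    feature_ids,
    electrode: str,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-feature, per-emotion histograms with bin edges shared across
    emotions (so distributions are directly comparable).

    Returns rows (feature_id, emotion, bin_left, bin_right, count).
    """
    sub = feature_table[feature_table["electrode"] == electrode]
    if sub.empty:
        raise StatsError(f"electrode {electrode!r} not present")
    rows = []
    for fid in feature_ids:
        col = f"f{fid:02d}"
        pooled = sub[col].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(pooled, bins=n_bins)
        for emo in EMOTIONS:
            vals = sub[sub["label"] == emo][col].to_numpy(dtype=float)
            hist, _ = np.histogram(vals, bins=edges)
            for b in range(len(hist)):
                rows.append({
                    "feature_id": fid, "emotion": emo,
                    "bin_left": edges[b], "bin_right": edges[b + 1],
                    "count": int(hist[b]),
                })
    return pd.DataFrame(rows)


def plot_feature_histograms(hist_frame: pd.DataFrame, path) -> None:
    """Optional rendering of the histogram table (one panel per feature)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fids = sorted(hist_frame["feature_id"].unique())
    fig, axes = plt.subplots(1, len(fids), figsize=(4 * len(fids), 3), squeeze=False)
    for ax, fid in zip(axes[0], fids):
        sub = hist_frame[hist_frame["feature_id"] == fid]
        for emo in EMOTIONS:
            s = sub[sub["emotion"] == emo]
            centers = 0.5 * (s["bin_left"].to_numpy() + s["bin_right"].to_numpy())
            ax.plot(centers, s["count"].to_numpy(), label=emo)
        ax.set_title(f"feature {fid}")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
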