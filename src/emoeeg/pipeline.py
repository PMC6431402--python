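"""End-to-end study pipeline: simulate -> preprocess -> extract -> select ->
evaluate -> stats, writing a run directory with a config echo and every
table.  Deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfs, evaluate, stats, synthetic
from .config import RunConfig
from .features import FEATURE_NAMES, extract_features, table_matrix
from .features_nonlinear import NonlinearParams
from .io import write_feature_table
from .preprocess import notch_50hz

log = logging.getLogger("emoeeg")


def build_dataset_config(cfg: RunConfig) -> synthetic.DatasetConfig:
    """DatasetConfig from a RunConfig: Pz/T3/T4 are emotion-responsive,
    other requested channels carry emotion-flat background activity."""
    responsive = {"Pz", "T3", "T4"}
    channels = []
    for name in cfg.channels:
        if name in responsive:
            channels.append(synthetic.informative_channel(name))
        else:
            channels.append(synthetic.background_channel(name))
    return synthetic.DatasetConfig(
        n_datasets=cfg.n_datasets,
        trials_per_emotion=cfg.trials_per_emotion,
        channels=channels,
        fs=cfg.fs,
        epoch_s=cfg.epoch_s,
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig, outdir, electrodes=None, classifiers=("c45",)) -> dict:
    """Run the whole study on synthetic data and write all result tables.

    ``electrodes`` restricts feature extraction/evaluation (default: the
    emotion-responsive Pz, T3, T4 plus one background channel if present).
    Returns the main results as a dict of DataFrames / values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cfg.save(outdir / "config.yaml")
    digest = cfg.digest()

    # --- simulate ------------------------------------------------------
    ds_cfg = build_dataset_config(cfg)
    datasets = synthetic.generate_study(ds_cfg)
    log.info("simulated %d datasets in %.1fs", len(datasets), time.time() - t0)

    # --- preprocess (line-noise suppression) ---------------------------
    for ds in datasets:
        for t in range(ds.data.shape[0]):
            for c in range(ds.data.shape[1]):
                ds.data[t, c] = notch_50hz(ds.data[t, c], ds.fs, freq=cfg.notch_hz)

    # --- extract -------------------------------------------------------
    if electrodes is None:
        responsive = [c for c in cfg.channels if c in {"Pz", "T3", "T4"}]
        background = [c for c in cfg.channels if c not in {"Pz", "T3", "T4"}]
        electrodes = responsive + background[:1]
    params = NonlinearParams(**cfg.nonlinear)
    table = extract_features(
        datasets, band_ranges={k: tuple(v) for k, v in cfg.band_ranges.items()},
        band_method=cfg.band_method, params=params, channels=electrodes,
    )
    table.attrs["config_digest"] = digest
    write_feature_table(table, outdir / "features.csv")
    log.info("extracted %d feature rows in %.1fs", len(table), time.time() - t0)

    # --- select --------------------------------------------------------
    best_el = electrodes[0]
    per_dataset_tables = []
    for did in sorted(table["dataset"].unique()):
        X, y = table_matrix(table[table["dataset"] == did], electrode=best_el)
        per_dataset_tables.append(
            cfs.discretize(X, cfg.n_bins, labels=y, feature_ids=list(range(1, 28)))
        )
    mean_su, selected = cfs.average_class_correlation(per_dataset_tables, cfg.su_threshold)
    su_frame = pd.DataFrame({
        "feature_id": mean_su.index,
        "feature_name": [FEATURE_NAMES[i] for i in mean_su.index],
        "mean_su": mean_su.values,
        "selected": [i in selected for i in mean_su.index],
    })
    su_frame.to_csv(outdir / "class_correlations.csv", index=False)

    rankings = []
    for did in sorted(table["dataset"].unique()):
        for el in electrodes:
            X, y = table_matrix(table[table["dataset"] == did], electrode=el)
            dt = cfs.discretize(X, cfg.n_bins, labels=y, feature_ids=list(range(1, 28)))
            rankings.append(cfs.greedy_rank(dt))
    freq = cfs.selection_frequency(rankings, cfg.top_k, cfg.min_times)
    freq["feature_name"] = freq["feature_id"].map(FEATURE_NAMES)
    freq.to_csv(outdir / "selection_frequency.csv", index=False)
    log.info("selection done in %.1fs (selected %s)", time.time() - t0, selected)

    # --- evaluate ------------------------------------------------------
    protocol = evaluate.EvalProtocol(
        k=cfg.cv_folds, total_folds=cfg.cv_total, seed=cfg.seed,
        test_per_emotion=cfg.test_per_emotion, repeats=cfg.repeats,
    )
    report = evaluate.EvalReport()
    for clf in classifiers:
        for el in electrodes:
            X, y = table_matrix(table, electrode=el)
            full = evaluate.crossval_accuracy(X, y, clf, protocol)
            Xs, _ = table_matrix(table, electrode=el, feature_ids=selected or None)
            sel = evaluate.crossval_accuracy(Xs, y, clf, protocol)
            report.add(classifier=clf, electrode=el, feature_set="all27",
                       accuracy=full["mean_accuracy"])
            report.add(classifier=clf, electrode=el, feature_set="selected",
                       accuracy=sel["mean_accuracy"])
    acc_frame = report.frame()
    acc_frame.to_csv(outdir / "accuracy.csv", index=False)

    rep_rows = []
    for did in sorted(table["dataset"].unique()):
        sub = table[table["dataset"] == did]
        X, y = table_matrix(sub, electrode=best_el, feature_ids=selected or None)
        rr = evaluate.repeatability_run(
            X, y, classifiers[0], repeats=cfg.repeats,
            test_per_emotion=cfg.test_per_emotion, seed=cfg.seed + did,
        )
        rep_rows.append({"dataset": did,
                         **{f"rep{i + 1}": a for i, a in enumerate(rr["per_repeat"])},
                         "average": rr["average"]})
    rep_frame = pd.DataFrame(rep_rows)
    rep_frame.to_csv(outdir / "repeatability.csv", index=False)

    # --- stats ---------------------------------------------------------
    per_ds = [table[table["dataset"] == did] for did in sorted(table["dataset"].unique())]
    tt = stats.paired_ttest_counts(per_ds)
    tt.to_csv(outdir / "ttest_counts.csv")
    hist = stats.feature_histograms(table, selected[:6] or [1], best_el)
    hist.to_csv(outdir / "histograms.csv", index=False)

    summary = {
        "config_digest": digest,
        "selected_features": [int(i) for i in selected],
        "high_frequency_features": [int(i) for i in
                                    freq[freq["correlation_degree"] == "High"]["feature_id"]],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline done in %.1fs", time.time() - t0)
    return {
        "table": table, "mean_su": mean_su, "selected": selected, "freq": freq,
        "accuracy": acc_frame, "repeatability": rep_frame, "ttest": tt,
        "summary": summary,
    }
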