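"""End-to-end orchestration: simulate → label → features → train → evaluate.

``run_pipeline`` executes the full study on synthetic sessions (or on spike
tables read from disk), persists every intermediate artifact under the
output directory and writes a manifest recording the configuration hash,
master seed, per-stage row counts and exclusion counts.  All stage
randomness (well holdout, CV folds, under-sampling, label shuffling) is
derived from the single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    FEATURE_NAMES,
    balanced_subsample,
    compare_models,
    crossval_auc,
    evaluate_holdout,
    make_model,
    pca_projection,
    roc_auc,
    split_holdout,
    train_rusboost,
)
from .features import build_feature_table
from .io import write_features, write_labels, write_metrics, write_spike_table
from .labeling import LabelingConfig, label_units, session_deltas
from .stats import compare_feature_by_label
from .synth import SyntheticConfig, generate_study

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: synthesis, labeling, feature and model settings."""

    out_dir: str = "nocilabel_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    n_holdout_wells: int = 2
    cv_folds: int = 10
    models: tuple[str, ...] = ("rusboost", "log", "lda", "knn", "fnn")
    rusboost_params: dict = field(
        default_factory=lambda: {"n_rounds": 150, "max_depth": 3, "learning_rate": 0.5}
    )
    run_cv: bool = True


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory).

    Stage errors abort the run with the stage name; artifacts written up to
    that point remain on disk for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31 - 1))
           for name, s in zip(
               ("simulate", "holdout", "cv", "train", "shuffle"),
               master.spawn(5))}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": sub,
        "config_hash": _config_hash(config),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    stage = "simulate"
    try:
        synth_cfg = SyntheticConfig(
            **{**asdict(config.synthetic),
               "responder": config.synthetic.responder,
               "non_responder": config.synthetic.non_responder,
               "seed": sub["simulate"]}
        )
        treated, untreated, truth = generate_study(synth_cfg, out_dir=out)
        manifest["stages"][stage] = {
            "n_units_treated": treated.n_units,
            "n_units_untreated": untreated.n_units,
            "n_wells_treated": len(treated.wells),
            "n_wells_untreated": len(untreated.wells),
        }

        stage = "label"
        deltas_t = session_deltas(treated, config.labeling.bin_width)
        deltas_u = session_deltas(untreated, config.labeling.bin_width)
        labels, model, threshold = label_units(deltas_t, deltas_u, config.labeling)
        write_labels(labels, out / "labels.csv")
        manifest["stages"][stage] = {
            "n_labeled_nociceptor": int(labels["label"].sum()),
            "n_units": len(labels),
            "labeled_fraction": float(labels["label"].mean()),
            "kde_bandwidth": model.bandwidth,
            "density_threshold": threshold,
        }

        stage = "features"
        features, exclusions = build_feature_table(treated, labels)
        write_features(features, out / "features.csv")
        exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"][stage] = {
            "n_features": len(features),
            "n_excluded": len(exclusions),
        }

        stage = "compare_features"
        comparisons = compare_feature_by_label(features)
        write_metrics(
            {c.feature: {"U": c.u_statistic, "p": c.p_value, "stars": c.stars,
                         "nociceptor_median": c.median_a,
                         "non_nociceptor_median": c.median_b}
             for c in comparisons},
            out / "feature_comparisons.json",
        )

        stage = "train"
        train_df, test_df = split_holdout(
            features, config.n_holdout_wells, seed=sub["holdout"]
        )
        X_tr = train_df[FEATURE_NAMES].to_numpy(float)
        y_tr = train_df["label"].to_numpy(int)
        X_te = test_df[FEATURE_NAMES].to_numpy(float)
        y_te = test_df["label"].to_numpy(int)
        manifest["stages"][stage] = {
            "n_train": len(train_df),
            "n_test": len(test_df),
            "train_prevalence": float(y_tr.mean()),
            "test_prevalence": float(y_te.mean()),
            "test_wells": sorted(test_df["well_id"].unique()),
        }
        cv_summary = None
        if config.run_cv:
            factories = {
                name: (lambda n=name: make_model(
                    n,
                    config.rusboost_params if n == "rusboost" else None,
                    seed=sub["cv"],
                ))
                for name in config.models
            }
            cv = crossval_auc(factories, X_tr, y_tr, k=config.cv_folds,
                              seed=sub["cv"])
            comparison = compare_models(cv)
            cv_summary = {
                "fold_auc": {k: v.tolist() for k, v in cv.fold_auc.items()},
                "kruskal_wallis": comparison,
            }
        tree = train_rusboost(X_tr, y_tr, config.rusboost_params,
                              seed=sub["train"])

        stage = "evaluate"
        report = evaluate_holdout(tree, X_te, y_te)
        bal_idx = balanced_subsample(y_te, seed=sub["holdout"])
        balanced_report = evaluate_holdout(tree, X_te[bal_idx], y_te[bal_idx])
        pc_train, pc_test = pca_projection(X_tr, X_te)
        # chance-level control: mean over a few shuffles (one draw is noisy
        # at typical holdout sizes)
        rng = np.random.default_rng(sub["shuffle"])
        null_aucs = []
        for _ in range(5):
            y_shuf = rng.permutation(y_tr)
            if len(np.unique(y_shuf)) < 2:
                continue
            tree_shuf = train_rusboost(X_tr, y_shuf, config.rusboost_params,
                                       seed=sub["train"])
            null_aucs.append(roc_auc(tree_shuf.predict_proba(X_te)[:, 1], y_te)[1])
        shuffled_auc = float(np.mean(null_aucs)) if null_aucs else float("nan")
        metrics = {
            "holdout": report.to_dict(),
            "holdout_balanced": balanced_report.to_dict(),
            "shuffled_label_auc": shuffled_auc,
            "cross_validation": cv_summary,
            "pca": {"train": pc_train.tolist(), "test": pc_test.tolist()},
        }
        write_metrics(metrics, out / "metrics.json")
        manifest["stages"][stage] = {
            "holdout_auc": report.auc,
            "holdout_accuracy": report.accuracy,
            "balanced_accuracy_metrics": {
                "accuracy": balanced_report.accuracy,
                "f1_negative": balanced_report.f1_negative,
                "f1_positive": balanced_report.f1_positive,
                "auc": balanced_report.auc,
            },
            "shuffled_label_auc": shuffled_auc,
        }
    except Exception as err:
        raise RuntimeError(
            f"pipeline aborted at stage {stage!r} "
            f"(partial outputs under {out}): {err}"
        ) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
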