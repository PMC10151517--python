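"""High-level orchestration: extraction, train/eval, and transfer runs.

These functions wire the modules into the full workflow — resolve pairs,
build the feature matrix, split, cross-validate, refit on the whole
training split, test — and write every artifact (matrix TSV + schema,
resolution report, metrics JSON, model file, run manifest) needed to audit
or exactly reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np

from . import dataset, features, models

logger = logging.getLogger(__name__)


def extract_features(
    pairs_path,
    ccre_bed,
    tss_table,
    chrom_sizes,
    track_paths: dict[str, str],
    out_prefix=None,
    bin_width: int = features.DEFAULT_BIN_WIDTH,
    strand_aware: bool = True,
    tss_one_based: bool = False,
):
    """Pair list + annotations + tracks -> (matrix, labels, schema, pairs, report).

    Applies the duplicate/ambiguity filter before resolution; logs the pair
    counts surviving each stage. If ``out_prefix`` is given the matrix,
    schema and resolution report are written alongside it.
    """
    raw = dataset.load_pairs(pairs_path)
    report_stub = dataset.ResolutionReport()
    filtered = dataset.filter_pairs(raw, report_stub)
    ccres = dataset.load_ccre_bed(ccre_bed)
    tsss = dataset.load_tss_table(tss_table, one_based=tss_one_based)
    sizes = dataset.load_chrom_sizes(chrom_sizes)
    pairs, report = dataset.resolve_pairs(filtered, ccres, tsss, sizes)
    report.ambiguous_removed = report_stub.ambiguous_removed
    logger.info(
        "pairs: %d raw -> %d after filters -> %d resolved (%d dropped)",
        len(raw), len(filtered), report.resolved, report.dropped,
    )
    tracks = [features.SignalTrack(name, path) for name, path in track_paths.items()]
    try:
        matrix, labels, schema = features.build_matrix(
            pairs, tracks, bin_width=bin_width, strand_aware=strand_aware
        )
    finally:
        for t in tracks:
            t.close()
    if out_prefix is not None:
        features.save_matrix(out_prefix, matrix, labels, schema)
        with open(f"{out_prefix}.resolution.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    return matrix, labels, schema, pairs, report


def train_eval(
    matrix: np.ndarray,
    labels: np.ndarray,
    schema: dict,
    split_spec: dataset.SplitSpec | None = None,
    clf_spec: models.ClassifierSpec | None = None,
    k_folds: int = 10,
    threshold: float = 0.5,
    out_dir=None,
    split_mode: str = "split",
) -> dict:
    """Cross-validate on the training split, refit, test independently.

    ``split_mode="split"`` holds out a stratified test fraction;
    ``split_mode="whole"`` trains on everything (cross-validation metrics
    only), the configuration used when the test set is a different cell
    line. Returns a results dict; artifacts are written under ``out_dir``
    when given.
    """
    split_spec = split_spec or dataset.SplitSpec()
    clf_spec = clf_spec or models.ClassifierSpec()
    n = len(labels)
    if split_mode == "split":
        rng = np.random.default_rng(split_spec.seed)
        train_idx: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            n_train = int(np.floor(split_spec.train_fraction * len(idx)))
            train_idx.extend(rng.permutation(idx)[:n_train].tolist())
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
    elif split_mode == "whole":
        train_mask = np.ones(n, dtype=bool)
    else:
        raise ValueError("split_mode must be 'split' or 'whole'")

    X_tr, y_tr = matrix[train_mask], labels[train_mask]
    folds, cv_mean = models.cross_validate(X_tr, y_tr, clf_spec, k=k_folds, threshold=threshold)
    model = models.train(X_tr, y_tr, clf_spec, schema_hash=schema.get("hash"))
    results: dict = {
        "cv_mean": cv_mean.as_dict(),
        "cv_folds": [f.as_dict() for f in folds],
        "n_train": int(train_mask.sum()),
        "n_test": int(n - train_mask.sum()),
        "classifier": dataclasses.asdict(clf_spec),
        "threshold": threshold,
        "schema_hash": schema.get("hash"),
    }
    if split_mode == "split":
        X_te, y_te = matrix[~train_mask], labels[~train_mask]
        test_scores = model.scores(X_te)
        results["test"] = models.compute_metrics(test_scores, y_te, threshold).as_dict()
        results["_test_scores"] = test_scores
        results["_test_labels"] = y_te
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        model.save(os.path.join(out_dir, "model.joblib"))
        public = {k: v for k, v in results.items() if not k.startswith("_")}
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(public, fh, indent=2, sort_keys=True)
        results["model_path"] = os.path.join(out_dir, "model.joblib")
    results["_model"] = model
    return results


def transfer(
    model: models.PairClassifier,
    matrix: np.ndarray,
    labels: np.ndarray,
    schema: dict,
    threshold: float = 0.5,
    out_path=None,
) -> models.MetricsReport:
    """Score a model trained on one cell line against another cell line."""
    report = models.evaluate_transfer(
        model, matrix, labels, schema_hash=schema.get("hash"), threshold=threshold
    )
    if out_path is not None:
        models.write_metrics_json(out_path, report)
    return report
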