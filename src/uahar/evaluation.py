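"""Evaluation metrics and the personalized-vs-generic comparison protocol.

Per-class one-vs-rest precision, recall and F-measure; a leave-one-out
(LOO) harness that, for every cohort subject, trains

* a *personalized* classifier on the subject's own fall-free training
  split (the other subjects' labeled training data contributes only the
  seed centroids of the annotation step), and
* a *generic* classifier whose Gaussians are fitted on the pooled
  labeled training data of all OTHER subjects,

and tests both on the subject's held-out split (which includes falls);
plus Fisher's exact test for 2x2 contingency tables used to check
whether per-subject improvement associates with a binary covariate
(e.g. normal vs abnormal BMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .features import feature_matrix, fit_normalizer
from .mgd_classifier import (
    FALL_LABEL,
    PersonalizedClassifier,
    calibrate_thresholds,
    fit_mgd,
    train_personalized,
)
from .preprocessing import preprocess_stream
from .seeded_kmeans import ACTIVITY_CLASSES
from .synthetic_data import SubjectRecord

ALL_CLASSES = ACTIVITY_CLASSES + (FALL_LABEL,)


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str
) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive`` over equal-length label
    sequences."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label sequences differ in length")
    t = np.array([str(v) == positive for v in y_true])
    p = np.array([str(v) == positive for v in y_pred])
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def f_measure(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F); degenerate 0/0 ratios report 0 with a warning
    so per-subject tables stay aggregable."""
    if c.tp + c.fp == 0 or c.tp + c.fn == 0 or c.tp == 0:
        if c.tp + c.fp == 0 or c.tp + c.fn == 0:
            warnings.warn("degenerate precision/recall (0/0) reported as 0", stacklevel=2)
        precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        return float(precision), float(recall), 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return float(precision), float(recall), float(2 * precision * recall / (precision + recall))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (fixed margins,
    summing hypergeometric probabilities <= the observed table's)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be > 0")
    return float(_scipy_fisher(table, alternative="two-sided")[1])


def ss_is_table(deltas: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """2x2 table of significant/insignificant subjects vs a binary covariate.

    A subject is "significant" (SS) when its improvement delta exceeds the
    cohort mean; rows = (SS, IS), columns = (covariate True, covariate
    False).
    """
    deltas = np.asarray(deltas, dtype=float)
    covariate = np.asarray(covariate, dtype=bool)
    if len(deltas) != len(covariate):
        raise ValueError("delta and covariate vectors differ in length")
    ss = deltas > deltas.mean()
    return np.array(
        [
            [int(np.sum(ss & covariate)), int(np.sum(ss & ~covariate))],
            [int(np.sum(~ss & covariate)), int(np.sum(~ss & ~covariate))],
        ]
    )


@dataclass
class EvaluationReport:
    """Per-subject and cohort-mean F-measures from the LOO protocol."""

    per_subject: pd.DataFrame          # rows subjects; columns model_class F
    mean_personalized: dict[str, float]
    mean_generic: dict[str, float]
    mean_delta: dict[str, float]
    details: dict = field(default_factory=dict)


def _label_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous same-label segments as (start, stop) index pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or str(labels[i]) != str(labels[start]):
            runs.append((start, i))
            start = i
    return runs


def _subject_features(record: SubjectRecord, config) -> tuple:
    """(train_X, train_labels, test_X, test_labels) raw window features.

    Both splits mimic the protocol of per-activity recordings and
    separately captured fall clips: each contiguous same-activity
    segment is preprocessed and windowed on its own, so no evaluated
    window spans an activity change and every fall clip yields windows
    containing the whole transient.  (Continuous-stream classification
    remains available through the library/CLI; the comparison protocol
    is clip-based.)
    """
    length = int(round(config.window_s * config.rate_hz))

    def run(stream):
        parts = []
        for a, b in _label_runs(stream.labels):
            if str(stream.labels[a]) not in ALL_CLASSES:
                continue  # e.g. post-fall stand-up: not an evaluated category
            if b - a < max(length, 3 * (config.butter_order + 1) + 1):
                continue  # clip shorter than one window: nothing to evaluate
            windows = preprocess_stream(
                stream.slice(a, b),
                cutoff_hz=config.gravity_cutoff_hz,
                order=config.butter_order,
                window_s=config.window_s,
                overlap=config.overlap,
            )
            parts.append(feature_matrix(windows))
        X = np.vstack([p[0] for p in parts])
        y = np.concatenate([p[1] for p in parts])
        return X, y

    train_X, train_y = run(record.stream.slice(0, record.train_end))
    test_X, test_y = run(record.stream.slice(record.train_end, None))
    return train_X, train_y, test_X, test_y


def _fit_generic(
    pooled_X: np.ndarray, pooled_y: np.ndarray, config
) -> PersonalizedClassifier:
    """Generic classifier from pooled labeled training data of other subjects."""
    norm = fit_normalizer(pooled_X)
    Z = norm.transform(pooled_X)
    models = []
    for cls in ACTIVITY_CLASSES:
        mask = np.array([str(lab) == cls for lab in pooled_y])
        models.append(fit_mgd(Z[mask], label=cls))
    via_mask = np.array([str(lab) == ACTIVITY_CLASSES[2] for lab in pooled_y])
    log_eps2, eps3 = calibrate_thresholds(
        models[2], Z[via_mask],
        eps2_percentile=config.eps2_percentile, eps3_deg=config.eps3_deg,
    )
    return PersonalizedClassifier(
        models=tuple(models), log_eps2=log_eps2, eps3_deg=eps3,
        normalizer=norm, meta={"mode": "generic"},
    )


def _per_class_f(y_true, y_pred) -> dict[str, float]:
    out = {}
    for cls in ALL_CLASSES:
        if not any(str(v) == cls for v in y_true):
            out[cls] = np.nan  # metrics unavailable (e.g. no fall test windows)
            continue
        out[cls] = f_measure(confusion_counts(y_true, y_pred, cls))[2]
    return out


def loo_generic_vs_personalized(
    cohort: list[SubjectRecord], config=None
) -> EvaluationReport:
    """Run the leave-one-out personalized-vs-generic comparison on a cohort.

    Training splits must be fall-free (they are by the cohort generator's
    construction); falls appear only in the test splits.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    config = config or PipelineConfig()
    if len(cohort) < 3:
        raise ValueError("LOO comparison needs at least 3 subjects")

    feats = [_subject_features(rec, config) for rec in cohort]
    for i, (_, train_y, _, _) in enumerate(feats):
        if train_y is not None and any(str(v) == FALL_LABEL for v in train_y):
            raise ValueError(f"subject {i}: training split contains fall windows")

    rows = []
    for i, rec in enumerate(cohort):
        train_X, _, test_X, test_y = feats[i]
        others = [feats[j] for j in range(len(cohort)) if j != i]
        pooled_X = np.vstack([f[0] for f in others])
        pooled_y = np.concatenate([f[1] for f in others])

        personalized, _ = train_personalized(
            rec.stream.slice(0, rec.train_end),
            pooled_X, pooled_y,
            gravity_cutoff_hz=config.gravity_cutoff_hz,
            butter_order=config.butter_order,
            window_s=config.window_s,
            overlap=config.overlap,
            kmeans_max_iter=config.kmeans_max_iter,
            llof_k=config.llof_k,
            llof_eps1=config.llof_eps1,
            eps2_percentile=config.eps2_percentile,
            eps3_deg=config.eps3_deg,
        )
        generic = _fit_generic(pooled_X, pooled_y, config)

        pred_p = personalized.classify(test_X)
        pred_g = generic.classify(test_X)
        f_p = _per_class_f(test_y, pred_p)
        f_g = _per_class_f(test_y, pred_g)
        row = {"subject": rec.profile.subject_id}
        for cls in ALL_CLASSES:
            row[f"personalized_{cls}"] = f_p[cls]
            row[f"generic_{cls}"] = f_g[cls]
            row[f"delta_{cls}"] = f_p[cls] - f_g[cls]
        rows.append(row)

    per_subject = pd.DataFrame(rows).set_index("subject")
    mean_p = {c: float(np.nanmean(per_subject[f"personalized_{c}"])) for c in ALL_CLASSES}
    mean_g = {c: float(np.nanmean(per_subject[f"generic_{c}"])) for c in ALL_CLASSES}
    delta = {c: mean_p[c] - mean_g[c] for c in ALL_CLASSES}
    return EvaluationReport(
        per_subject=per_subject,
        mean_personalized=mean_p,
        mean_generic=mean_g,
        mean_delta=delta,
        details={"n_subjects": len(cohort)},
    )
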