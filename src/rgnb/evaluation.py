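"""Confusion-matrix metrics, the repeated stratified holdout protocol,
group-stratified evaluation, and a one-way ANOVA helper.

Caveat (inherited from the protocol, not "fixed" here): running a one-way
ANOVA on metrics from repeated random splits of one dataset violates the
independence assumption of the test. The helper implements the protocol as
declared and leaves the interpretation to the caller.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    TrainingConfig,
    fit_nblda,
    fit_radiogenomics_nb,
    predict_nblda,
    predict_radiogenomics_nb,
)
from .data_model import CountMatrix, CovariateMatrix, LabelVector
from .errors import FitError, ValidationError

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "balanced_accuracy",
    "f1",
)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    labels_true: Sequence[str],
    labels_pred: Sequence[str],
    positive_class: str,
    class_set: Sequence[str] | None = None,
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN for a binary evaluation with a declared positive class."""
    if len(labels_true) != len(labels_pred):
        raise ValidationError("true and predicted label vectors differ in length")
    if class_set is not None:
        known = set(class_set)
        bad = [x for x in list(labels_true) + list(labels_pred) if x not in known]
        if bad:
            raise ValidationError(f"labels outside class set: {sorted(set(bad))}")
    tp = fp = fn = tn = 0
    for t, p in zip(labels_true, labels_pred):
        if p == positive_class:
            if t == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    """0/0 -> nan (reported as undefined, excluded from aggregates)."""
    return num / den if den > 0 else math.nan


def metrics_from_confusion(cm: ConfusionCounts) -> dict[str, float]:
    """Standard binary metrics; zero-denominator cases come back as NaN."""
    if cm.total <= 0:
        raise ValidationError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.fp + cm.tn)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.fn + cm.tn),
        "balanced_accuracy": (sens + spec) / 2.0,
        "f1": _ratio(cm.tp, cm.tp + (cm.fp + cm.fn) / 2.0),
    }


def stratified_split(
    labels: LabelVector, train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Random class-stratified train/test split of the sample ids.

    The total train size is round(train_fraction * n); per-class train counts
    use largest-remainder allocation (ties broken by class order), which keeps
    every class's train share within one sample of the global fraction.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = labels.n_samples
    target_total = int(round(train_fraction * n))
    classes = labels.class_set
    sizes = {c: len(labels.class_indices(c)) for c in classes}
    base = {c: int(math.floor(train_fraction * sizes[c])) for c in classes}
    remainder = {c: train_fraction * sizes[c] - base[c] for c in classes}
    leftover = target_total - sum(base.values())
    order = sorted(range(len(classes)), key=lambda i: (-remainder[classes[i]], i))
    take = dict(base)
    for i in order[: max(leftover, 0)]:
        take[classes[i]] += 1

    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in classes:
        idx = labels.class_indices(cls)
        if take[cls] < 2 or take[cls] >= len(idx) or len(idx) - take[cls] < 1:
            raise FitError(
                f"stratification infeasible for class {cls!r}: "
                f"{take[cls]} train of {len(idx)} samples"
            )
        perm = rng.permutation(idx)
        train_ids.extend(labels.sample_ids[i] for i in perm[: take[cls]])
        test_ids.extend(labels.sample_ids[i] for i in perm[take[cls]:])
    # restore the original sample order for determinism of downstream alignment
    pos = {s: i for i, s in enumerate(labels.sample_ids)}
    train_ids.sort(key=pos.__getitem__)
    test_ids.sort(key=pos.__getitem__)
    return train_ids, test_ids


@dataclass
class EvaluationReport:
    """Per-repeat metric rows plus aggregate mean/sd and protocol metadata."""

    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean, sd (ddof=1) and defined-count per metric, NaNs excluded."""
        df = self.to_frame()
        out = {}
        for m in METRIC_NAMES:
            vals = df[m].dropna().to_numpy(dtype=float)
            out[m] = {
                "mean": float(vals.mean()) if len(vals) else math.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
                "n_defined": int(len(vals)),
                "n_undefined": int(len(df) - len(vals)),
            }
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"summary": self.summary(), "metadata": self.metadata},
                indent=1,
                sort_keys=True,
            )
        )


def _run_method(
    method: str,
    train: tuple[CountMatrix, CovariateMatrix | None, LabelVector],
    test: tuple[CountMatrix, CovariateMatrix | None],
    config: TrainingConfig,
):
    counts_tr, covars_tr, labels_tr = train
    counts_te, covars_te = test
    if method == "radiogenomics_nb":
        model = fit_radiogenomics_nb(counts_tr, covars_tr, labels_tr, config)
        return predict_radiogenomics_nb(model, counts_te, covars_te)
    if method == "nblda":
        model = fit_nblda(counts_tr, labels_tr, config)
        return predict_nblda(model, counts_te)
    raise ValueError(f"unknown method {method!r}")


def repeated_holdout(
    counts: CountMatrix,
    covars: CovariateMatrix | None,
    labels: LabelVector,
    method: str = "radiogenomics_nb",
    config: TrainingConfig | None = None,
    repeats: int = 100,
    train_fraction: float = 0.8,
    base_seed: int = 0,
    positive_class: str | None = None,
) -> EvaluationReport:
    """Repeat: stratified split (seed = base_seed + r), fit on train (including
    per-split gene ranking), predict test, tally metrics. Reports per-repeat rows
    and mean +/- sd."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = config or TrainingConfig()
    if method == "radiogenomics_nb" and covars is None:
        raise ValueError("radiogenomics_nb requires covariates")
    if positive_class is None:
        positive_class = labels.class_set[0]
    if positive_class not in labels.class_set:
        raise ValidationError(f"positive class {positive_class!r} not in class set")

    rows = []
    for r in range(repeats):
        rng = np.random.default_rng(base_seed + r)
        train_ids, test_ids = stratified_split(labels, train_fraction, rng)
        counts_tr = counts.subset_samples(train_ids)
        counts_te = counts.subset_samples(test_ids)
        labels_tr = labels.subset_samples(train_ids)
        labels_te = labels.subset_samples(test_ids)
        covars_tr = covars.subset_samples(train_ids) if covars is not None else None
        covars_te = covars.subset_samples(test_ids) if covars is not None else None

        preds = _run_method(
            method, (counts_tr, covars_tr, labels_tr), (counts_te, covars_te), config
        )
        predicted = [p.predicted_class for p in preds]
        cm = confusion(labels_te.labels, predicted, positive_class, labels.class_set)
        row = {"repeat": r, "seed": base_seed + r, "n_train": len(train_ids),
               "n_test": len(test_ids), "tp": cm.tp, "fp": cm.fp, "fn": cm.fn,
               "tn": cm.tn}
        row.update(metrics_from_confusion(cm))
        rows.append(row)

    return EvaluationReport(
        rows=rows,
        metadata={
            "method": method,
            "config": config.to_dict(),
            "repeats": repeats,
            "train_fraction": train_fraction,
            "base_seed": base_seed,
            "positive_class": positive_class,
            "class_set": list(labels.class_set),
            "n_samples": labels.n_samples,
        },
    )


def group_stratified_reports(
    counts: CountMatrix,
    covars: CovariateMatrix | None,
    labels: LabelVector,
    groups: Mapping[str, str],
    min_group_size: int = 10,
    **holdout_kwargs,
) -> dict[str, EvaluationReport]:
    """Run the full repeated-holdout pipeline independently inside each group
    (e.g., one model per gender). Groups too small to stratify are skipped
    with a warning."""
    by_group: dict[str, list[str]] = {}
    for s in labels.sample_ids:
        if s in groups:
            by_group.setdefault(str(groups[s]), []).append(s)
    reports: dict[str, EvaluationReport] = {}
    for name in sorted(by_group):
        ids = by_group[name]
        if len(ids) < min_group_size:
            warnings.warn(f"group {name!r} has only {len(ids)} samples; skipped")
            continue
        sub_labels = labels.subset_samples(ids)
        if min(sub_labels.class_counts().values()) < 3:
            warnings.warn(f"group {name!r} lacks class representation; skipped")
            continue
        reports[name] = repeated_holdout(
            counts.subset_samples(ids),
            covars.subset_samples(ids) if covars is not None else None,
            sub_labels,
            **holdout_kwargs,
        )
        reports[name].metadata["group"] = name
    return reports


def anova_compare(metric_vectors: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across methods' per-repeat metric values.

    Returns (F, p). All-identical input degenerates to (0, 1) with a warning;
    zero within-group variance with distinct group means gives (inf, 0).
    """
    if len(metric_vectors) < 2:
        raise ValueError("need at least two methods to compare")
    arrays = []
    for name, vals in metric_vectors.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            raise ValueError(f"method {name!r} has fewer than 2 defined values")
        arrays.append(arr)
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        warnings.warn("all metric values identical; ANOVA degenerate, returning p=1")
        return 0.0, 1.0
    if all(np.all(a == a[0]) for a in arrays):
        # distinct constant groups: complete separation
        return math.inf, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return math.inf, 0.0
    return float(f), float(p)
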