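"""Accuracy assessment and the early-season time-series-length sweep.

Confusion matrices are laid out rows = predicted class, columns = reference
class, so a row's user's accuracy (UA) is its diagonal count over the row
sum and a column's producer's accuracy (PA) is the diagonal over the column
sum.  ``length_sweep`` retrains the classifier on progressively longer
feature sets — the half-month periods gained as the season advances — and
``saturation_point`` finds the earliest series end at which a crop's PA and
UA both clear a level (the 95 % rule used to call a crop "mappable").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .composites import FeatureCube
from .iain import AntibodyNetwork, IainConfig, classify_cube, train_cube


@dataclass
class ConfusionMatrix:
    """K x K predicted-by-reference count table."""

    classes: list
    counts: np.ndarray  # rows = predicted, columns = reference

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(predicted, reference, classes: Sequence) -> ConfusionMatrix:
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError("label sequences differ in length")
    if not predicted:
        raise ValueError("empty label sequences")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(predicted) | set(reference)) - set(index)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(map(str, unknown))}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, r in zip(predicted, reference):
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(list(classes), counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def class_accuracies(cm: ConfusionMatrix, cls) -> tuple[float, float]:
    """(producer's, user's) accuracy in percent for one class.

    PA = diagonal / reference (column) total; UA = diagonal / predicted
    (row) total.  An empty denominator yields NaN.
    """
    if cls not in cm.classes:
        raise ValueError(f"unknown class {cls!r}")
    i = cm.classes.index(cls)
    diag = float(cm.counts[i, i])
    col = float(cm.counts[:, i].sum())
    row = float(cm.counts[i, :].sum())
    pa = 100.0 * diag / col if col > 0 else float("nan")
    ua = 100.0 * diag / row if row > 0 else float("nan")
    return pa, ua


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (N tr(C) - sum_i row_i col_i) / (N^2 - sum_i row_i col_i)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    chance = float(rows @ cols)
    denom = n * n - chance
    if denom == 0:
        return float("nan")
    return (n * float(np.trace(cm.counts)) - chance) / denom


# ---------------------------------------------------------------------------
# early-season length sweep


@dataclass
class SweepResult:
    """Accuracy metrics for one cumulative time-series length."""

    end_period: str
    feature_names: list[str]
    oa: float
    kappa: float
    per_class: dict = field(default_factory=dict)  # class -> (PA, UA)
    cm: ConfusionMatrix | None = None

    def pa(self, cls) -> float:
        return self.per_class[cls][0]

    def ua(self, cls) -> float:
        return self.per_class[cls][1]


def length_sweep(
    train_cube_: FeatureCube,
    train_labels,
    valid_cube: FeatureCube,
    valid_labels,
    feature_plan: Sequence[tuple[str, Sequence[str]]],
    config: IainConfig | None = None,
) -> list[SweepResult]:
    """Accuracy as a function of cumulative time-series length.

    ``feature_plan`` lists, in season order, (end period label, feature
    names gained at that length) — the features accumulate.  For each
    length the classifier is retrained on the training cube restricted to
    the accumulated features and evaluated on the validation cube;
    training uses complete rows only, validation keeps missing values.
    """
    train_labels = np.asarray(list(train_labels), dtype=object)
    valid_labels = np.asarray(list(valid_labels), dtype=object)
    classes = sorted(set(train_labels) | set(valid_labels), key=str)
    name_to_col_train = {n: j for j, n in enumerate(train_cube_.feature_labels())}
    name_to_col_valid = {n: j for j, n in enumerate(valid_cube.feature_labels())}

    results: list[SweepResult] = []
    accumulated: list[str] = []
    for end_period, gained in feature_plan:
        accumulated = accumulated + [g for g in gained if g not in accumulated]
        names = [n for n in accumulated if n in name_to_col_train]
        if not names:
            warnings.warn(f"no features available at length {end_period}; skipped")
            continue
        tr = train_cube_.select_features([name_to_col_train[n] for n in names])
        va = valid_cube.select_features(
            [name_to_col_valid[n] for n in names if n in name_to_col_valid]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = train_cube(tr, train_labels, config=config)
        pred, bad = classify_cube(net, va)
        ok = ~bad
        cm = confusion(pred[ok], valid_labels[ok], classes)
        results.append(
            SweepResult(
                end_period=end_period,
                feature_names=names,
                oa=overall_accuracy(cm),
                kappa=kappa(cm),
                per_class={c: class_accuracies(cm, c) for c in classes},
                cm=cm,
            )
        )
    return results


def saturation_point(
    sweep: Sequence[SweepResult], cls, level: float = 95.0
) -> str | None:
    """Earliest series end where PA and UA both reach ``level`` percent.

    First crossing wins even if accuracy later dips; ``None`` when the
    level is never reached.
    """
    if not sweep:
        raise ValueError("empty sweep")
    for res in sweep:
        pa, ua = res.per_class.get(cls, (float("nan"), float("nan")))
        if np.isfinite(pa) and np.isfinite(ua) and pa >= level and ua >= level:
            return res.end_period
    return None


def sweep_table(sweep: Sequence[SweepResult]) -> pd.DataFrame:
    """Flatten a sweep into a tidy frame (one row per length and class)."""
    rows = []
    for res in sweep:
        for cls, (pa, ua) in res.per_class.items():
            rows.append(
                {
                    "end_period": res.end_period,
                    "class": cls,
                    "pa": pa,
                    "ua": ua,
                    "oa": res.oa,
                    "kappa": res.kappa,
                    "n_features": len(res.feature_names),
                }
            )
    return pd.DataFrame(rows)
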