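"""Repeated decision-tree classification of fall vs. nonfall trials.

A CART decision tree (Gini impurity, binary splits) is trained on the
10 feature codes of one decomposition level ({x, y} x 5 features at
level 0 for the raw signal or 1-6 for an IMF), under one condition view.
The data are split 80:20 into training and testing partitions
(stratified by group by default), the tree is fitted on the training
partition and confusion counts are accumulated on both partitions; the
whole procedure is repeated (default 20 times) with fresh seeded splits
and the metrics are reported as mean and SD over repeats.

Fall is the positive class:

    accuracy    = (TP + TN) / (TP + FN + TN + FP) * 100
    sensitivity =  TP / (TP + FN) * 100
    specificity =  TN / (TN + FP) * 100

The classification unit is the trial record, so different trials of one
subject can land in both partitions; a ``group_by_subject`` split mode
keeps each subject's trials in a single partition and is the
recommended choice when subject-level generalisation is the question.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import level_codes
from .io import POOLED, VIEWS

__all__ = [
    "ConfusionCounts",
    "TreeModel",
    "ClassifierReport",
    "metrics",
    "train_tree",
    "evaluate_repeated",
]

POSITIVE = "fall"
NEGATIVE = "nonfall"

DEFAULT_TREE_PARAMS = dict(max_depth=5, min_samples_leaf=3)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics(counts: ConfusionCounts):
    """Accuracy, sensitivity, specificity in percent.

    A metric whose denominator is zero is returned as None ("not
    defined") without affecting the others; all-zero counts are a usage
    error.
    """
    if counts.total == 0:
        raise ValueError("no evaluated records: metrics undefined")
    accuracy = (counts.tp + counts.tn) / counts.total * 100.0
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos * 100.0 if pos else None
    specificity = counts.tn / neg * 100.0 if neg else None
    return accuracy, sensitivity, specificity


@dataclass
class TreeModel:
    """A fitted CART tree plus the training-column medians used for
    missing-value imputation."""

    tree: DecisionTreeClassifier
    codes: tuple
    medians: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        mat = self._impute(X)
        return self.tree.predict(mat)

    def _impute(self, X: pd.DataFrame) -> np.ndarray:
        mat = X[list(self.codes)].to_numpy(float)
        for j in range(mat.shape[1]):
            col = mat[:, j]
            col[~np.isfinite(col)] = self.medians[j]
        return mat

    def confusion(self, X: pd.DataFrame, y: Sequence[str]) -> ConfusionCounts:
        pred = self.predict(X)
        y = np.asarray(y)
        return ConfusionCounts(
            tp=int(np.sum((pred == POSITIVE) & (y == POSITIVE))),
            fp=int(np.sum((pred == POSITIVE) & (y == NEGATIVE))),
            fn=int(np.sum((pred == NEGATIVE) & (y == POSITIVE))),
            tn=int(np.sum((pred == NEGATIVE) & (y == NEGATIVE))),
        )


def train_tree(
    X: pd.DataFrame,
    y: Sequence[str],
    codes: Optional[Sequence[str]] = None,
    random_state: int = 0,
    **tree_params,
) -> TreeModel:
    """Fit a CART tree on the given feature columns.

    Missing values are imputed by the training-column median before
    fitting (a median that is itself undefined falls back to 0).  A
    single-class input yields a trivial single-leaf model with a
    warning.
    """
    codes = tuple(codes) if codes is not None else tuple(X.columns)
    y = np.asarray(y)
    if X[list(codes)].isna().all(axis=1).any():
        raise ValueError("a row with all features missing cannot be classified")
    params = {**DEFAULT_TREE_PARAMS, **tree_params}
    mat = X[list(codes)].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(mat, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    model = TreeModel(
        tree=DecisionTreeClassifier(
            criterion="gini", random_state=random_state, **params
        ),
        codes=codes,
        medians=medians,
    )
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training data: trivial model", RuntimeWarning)
    model.tree.fit(model._impute(X), y)
    return model


def _summary(values: list) -> dict:
    """Mean/SD over repeats; None metrics are dropped pairwise."""
    arr = np.array([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


@dataclass
class ClassifierReport:
    """Per-repeat confusion counts and Eq.-style metric summaries."""

    level: int
    condition_view: str
    split_ratio: float
    n_repeats: int
    seed: int
    rows: pd.DataFrame = field(repr=False)
    single_repeat: bool = False

    def summary(self, partition: str = "test") -> dict:
        sub = self.rows[self.rows["partition"] == partition]
        return {
            metric: _summary(list(sub[metric]))
            for metric in ("accuracy", "sensitivity", "specificity")
        }

    def to_frame(self, include_summary: bool = False) -> pd.DataFrame:
        """Per-repeat rows; optionally append mean/SD summary rows."""
        out = self.rows.copy()
        if include_summary:
            extra = []
            for partition in ("train", "test"):
                s = self.summary(partition)
                for stat in ("mean", "sd"):
                    extra.append(
                        {
                            "repeat": stat,
                            "partition": partition,
                            **{m: s[m][stat] for m in s},
                        }
                    )
            out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
        return out


def evaluate_repeated(
    table: pd.DataFrame,
    level: int,
    condition: str = POOLED,
    split: float = 0.8,
    repeats: int = 20,
    seed: int = 0,
    stratify: bool = True,
    group_by_subject: bool = False,
    **tree_params,
) -> ClassifierReport:
    """Repeated stratified holdout evaluation of one decomposition level.

    ``table`` is a feature table (see :func:`copsway.features.feature_table`);
    ``condition`` selects a view (C4 keeps all trials).  One master seed
    drives a per-repeat seed sequence, so identical inputs and seed give
    a bit-identical report.
    """
    if condition not in VIEWS:
        raise ValueError(f"unknown condition view {condition!r}")
    if not 0.0 < split < 1.0:
        raise ValueError("split must be a fraction in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    sub = table if condition == POOLED else table[table["condition"] == condition]
    codes = level_codes(level)
    empty = sub[codes].isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} trial(s) with no level-{level} features",
            RuntimeWarning,
        )
        sub = sub[~empty]
    y = sub["group"].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need >= 2 records")
    X = sub[codes]
    groups = sub["subject_id"].to_numpy()

    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    rows = []
    for rep, rs in enumerate(repeat_seeds):
        rs = int(rs)
        idx = np.arange(len(sub))
        if group_by_subject:
            splitter = GroupShuffleSplit(
                n_splits=1, train_size=split, random_state=rs
            )
            train_idx, test_idx = next(splitter.split(idx, y, groups))
        else:
            train_idx, test_idx = train_test_split(
                idx,
                train_size=split,
                random_state=rs,
                stratify=y if stratify else None,
            )
        model = train_tree(
            X.iloc[train_idx], y[train_idx], codes=codes,
            random_state=rs, **tree_params,
        )
        for partition, part_idx in (("train", train_idx), ("test", test_idx)):
            cc = model.confusion(X.iloc[part_idx], y[part_idx])
            acc, sen, spe = metrics(cc)
            rows.append(
                dict(
                    repeat=rep,
                    partition=partition,
                    tp=cc.tp, fp=cc.fp, fn=cc.fn, tn=cc.tn,
                    accuracy=acc, sensitivity=sen, specificity=spe,
                )
            )
    report = ClassifierReport(
        level=level,
        condition_view=condition,
        split_ratio=split,
        n_repeats=repeats,
        seed=seed,
        rows=pd.DataFrame(rows),
        single_repeat=repeats == 1,
    )
    return report
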