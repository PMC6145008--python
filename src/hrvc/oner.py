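"""One-R rule induction, Zero-R baseline, cross-validation, and metrics.

One-R builds a one-level decision tree: each candidate attribute is
discretized into bins by a greedy sweep of the sorted values (a bin
closes once its majority class holds at least ``min_bucket`` members and
the next value differs from the bin's last value; adjacent bins with the
same majority label are merged), and the attribute whose binning makes
the fewest training errors supplies the single rule.  With CI_l as the
winning attribute the fitted rule takes the familiar form
``CI_l < threshold -> UWS, CI_l >= threshold -> MCS``.

Metrics treat MCS as the positive condition throughout: a false positive
is a UWS patient classified as MCS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multiscale_entropy import MCS_LABEL, UWS_LABEL

__all__ = [
    "SubjectRecord",
    "CohortTable",
    "OneRModel",
    "ClassificationReport",
    "ClassifierError",
    "discretize_attribute",
    "fit_oner",
    "fit_zeror",
    "predict",
    "evaluate",
    "cross_validate",
    "stratified_folds",
]

DEFAULT_MIN_BUCKET = 6
DEFAULT_FEATURES = ("ci_s", "ci_l")


class ClassifierError(ValueError):
    """Invalid input to rule induction or evaluation."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: diagnosis, behavioural score, and complexity indices."""

    subject_id: str
    diagnosis: str
    crs_r_total: int | None = None
    ci_s: float = float("nan")
    ci_l: float = float("nan")
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in (UWS_LABEL, MCS_LABEL):
            raise ClassifierError(f"diagnosis must be UWS or MCS, got {self.diagnosis!r}")

    def feature(self, name: str) -> float:
        if name == "ci_s":
            return self.ci_s
        if name == "ci_l":
            return self.ci_l
        if name in self.covariates:
            return self.covariates[name]
        raise ClassifierError(f"record {self.subject_id} has no attribute {name!r}")


@dataclass(frozen=True)
class CohortTable:
    """An ordered collection of subject records with unique ids."""

    records: tuple
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ClassifierError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def diagnoses(self) -> np.ndarray:
        return np.array([r.diagnosis for r in self.records], dtype=object)

    def values(self, feature: str) -> np.ndarray:
        return np.array([r.feature(feature) for r in self.records], dtype=float)

    def subset(self, indices) -> "CohortTable":
        return CohortTable(tuple(self.records[i] for i in indices), name=self.name)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "cohort") -> "CohortTable":
        required = {"subject_id", "diagnosis", "ci_s", "ci_l"}
        missing = required - set(df.columns)
        if missing:
            raise ClassifierError(f"cohort table missing columns: {sorted(missing)}")
        recs = []
        for row in df.itertuples(index=False):
            crs = getattr(row, "crs_r_total", None)
            recs.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    diagnosis=str(row.diagnosis),
                    crs_r_total=None if crs is None or pd.isna(crs) else int(crs),
                    ci_s=float(row.ci_s),
                    ci_l=float(row.ci_l),
                )
            )
        return cls(tuple(recs), name=name)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path), name=name or str(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "diagnosis": [r.diagnosis for r in self.records],
                "crs_r_total": [r.crs_r_total for r in self.records],
                "ci_s": [r.ci_s for r in self.records],
                "ci_l": [r.ci_l for r in self.records],
            }
        )


@dataclass(frozen=True)
class OneRModel:
    """A single-attribute binned rule (one-level decision tree)."""

    attribute: str
    boundaries: tuple
    bin_labels: tuple
    training_error: int
    min_bucket: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.bin_labels) != len(self.boundaries) + 1:
            raise ClassifierError("need exactly one more bin label than boundaries")
        if len(self.boundaries) > 1 and not np.all(np.diff(self.boundaries) > 0):
            raise ClassifierError("boundaries must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "attribute": self.attribute,
                "boundaries": list(self.boundaries),
                "bin_labels": list(self.bin_labels),
                "min_bucket": self.min_bucket,
                "training_error": self.training_error,
            }
        )

    def rule_text(self) -> str:
        if not self.boundaries:
            return f"always -> {self.bin_labels[0]}"
        parts = [f"{self.attribute} < {self.boundaries[0]:.3f} -> {self.bin_labels[0]}"]
        for lo, lab in zip(self.boundaries, self.bin_labels[1:]):
            parts.append(f"{self.attribute} >= {lo:.3f} -> {lab}")
        return "; ".join(parts)


def _majority(counts: dict) -> str:
    """Majority label; ties break toward the lexicographically smallest
    label, which for the UWS/MCS pair favours MCS (documented tie rule)."""
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def discretize_attribute(values, labels, min_bucket: int = DEFAULT_MIN_BUCKET):
    """Greedy One-R discretization of one attribute.

    Returns ``(boundaries, bin_labels, error)``: strictly increasing split
    points at midpoints between adjacent distinct values across bin
    edges, the majority label per bin (adjacent equal-label bins merged),
    and the count of training misclassifications.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.size != labels.size:
        raise ClassifierError("values and labels must have equal length")
    if min_bucket < 1:
        raise ClassifierError("min_bucket must be >= 1")
    if values.size < min_bucket:
        raise ClassifierError(
            f"need at least min_bucket={min_bucket} values, got {values.size}"
        )
    order = np.argsort(values, kind="stable")
    vs, ls = values[order], labels[order]
    n = vs.size

    bins = []  # (start, stop, counts)
    i = 0
    while i < n:
        counts: dict = {}
        j = i
        while j < n:
            counts[ls[j]] = counts.get(ls[j], 0) + 1
            j += 1
            if max(counts.values()) >= min_bucket:
                # the bucket is full: keep absorbing examples of the
                # majority class, and never split identical values
                # across a boundary
                maj = _majority(counts)
                while j < n and (ls[j] == maj or vs[j] == vs[j - 1]):
                    counts[ls[j]] = counts.get(ls[j], 0) + 1
                    j += 1
                break
        bins.append([i, j, counts])
        i = j

    # merge adjacent bins sharing a majority label
    merged = [bins[0]]
    for start, stop, counts in bins[1:]:
        if _majority(counts) == _majority(merged[-1][2]):
            merged[-1][1] = stop
            for lab, c in counts.items():
                merged[-1][2][lab] = merged[-1][2].get(lab, 0) + c
        else:
            merged.append([start, stop, counts])

    boundaries = tuple((vs[stop - 1] + vs[stop]) / 2.0 for _, stop, _ in merged[:-1])
    bin_labels = tuple(_majority(c) for _, _, c in merged)
    error = int(sum(sum(c.values()) - max(c.values()) for _, _, c in merged))
    return boundaries, bin_labels, error


def fit_oner(
    cohort: CohortTable,
    features=DEFAULT_FEATURES,
    min_bucket: int = DEFAULT_MIN_BUCKET,
) -> OneRModel:
    """Fit One-R: discretize every feature, keep the minimum-error rule.

    Ties between features break toward the earlier feature in
    ``features``.  A single-class cohort yields a degenerate constant
    model, flagged as such.
    """
    if not features:
        raise ClassifierError("need at least one feature")
    labels = cohort.diagnoses
    if len(set(labels)) < 2:
        lab = labels[0] if len(labels) else MCS_LABEL
        return OneRModel(features[0], (), (lab,), 0, min_bucket, degenerate=True)
    best = None
    for feat in features:
        boundaries, bin_labels, error = discretize_attribute(
            cohort.values(feat), labels, min_bucket=min_bucket
        )
        if best is None or error < best[1]:
            best = ((feat, boundaries, bin_labels), error)
    (feat, boundaries, bin_labels), error = best
    return OneRModel(feat, boundaries, bin_labels, error, min_bucket)


def fit_zeror(cohort: CohortTable) -> OneRModel:
    """Zero-R baseline: always predict the majority class (ties -> MCS)."""
    if len(cohort) == 0:
        raise ClassifierError("empty cohort")
    labels = cohort.diagnoses
    counts: dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    majority = _majority(counts)
    error = len(cohort) - counts[majority]
    return OneRModel("zero_r", (), (majority,), error, min_bucket=len(cohort), degenerate=True)


def predict(model: OneRModel, record) -> str:
    """Predicted label for a record (or a bare attribute value).

    Values equal to a boundary fall in the upper bin, matching the
    ``>= threshold -> MCS`` reading of the fitted rule.
    """
    if isinstance(record, SubjectRecord):
        value = record.feature(model.attribute) if model.boundaries else None
    else:
        value = record
    if not model.boundaries:
        return model.bin_labels[0]
    value = float(value)
    if math.isnan(value):
        raise ClassifierError(f"missing {model.attribute} value")
    idx = int(np.searchsorted(np.asarray(model.boundaries), value, side="right"))
    return model.bin_labels[idx]


@dataclass(frozen=True)
class ClassificationReport:
    """2x2 confusion matrix (MCS positive) and its derived rates."""

    tp: int
    fn: int
    fp: int
    tn: int
    mcc_undefined: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _rate(self.tn, self.tn + self.fp)

    @property
    def fpr(self) -> float:
        return _rate(self.fp, self.fp + self.tn)

    @property
    def fnr(self) -> float:
        return _rate(self.fn, self.fn + self.tp)

    @property
    def precision_mcs(self) -> float:
        return _rate(self.tp, self.tp + self.fp)

    @property
    def precision_uws(self) -> float:
        return _rate(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return _rate(self.tp + self.tn, self.n)

    @property
    def f1(self) -> float:
        return _rate(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    @property
    def mcc(self) -> float:
        denom = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)

    def as_dict(self, rounded: bool = False) -> dict:
        """All counts and rates; ``rounded=True`` renders the display
        convention (integer percentages, MCC to two decimals)."""
        d = {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "precision_mcs": self.precision_mcs,
            "precision_uws": self.precision_uws,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if rounded:
            for key in (
                "sensitivity",
                "specificity",
                "fnr",
                "fpr",
                "precision_mcs",
                "precision_uws",
                "accuracy",
                "f1",
            ):
                d[key] = None if math.isnan(d[key]) else int(round(d[key] * 100))
            d["mcc"] = round(d["mcc"], 2)
        return d


def _rate(num: float, denom: float) -> float:
    return num / denom if denom else float("nan")


def evaluate(predicted, truth, positive: str = MCS_LABEL) -> ClassificationReport:
    """Confusion matrix and the full metric panel, MCS positive.

    MCC is defined as 0 (and flagged) when any confusion-matrix marginal
    is zero.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ClassifierError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ClassifierError("need at least one prediction")
    known = {UWS_LABEL, MCS_LABEL}
    unknown = (set(predicted) | set(truth)) - known
    if unknown:
        raise ClassifierError(f"unknown labels: {sorted(unknown)}")
    tp = sum(1 for p, t in zip(predicted, truth) if t == positive and p == positive)
    fn = sum(1 for p, t in zip(predicted, truth) if t == positive and p != positive)
    fp = sum(1 for p, t in zip(predicted, truth) if t != positive and p == positive)
    tn = sum(1 for p, t in zip(predicted, truth) if t != positive and p != positive)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return ClassificationReport(tp=tp, fn=fn, fp=fp, tn=tn, mcc_undefined=(denom == 0))


def stratified_folds(labels, k: int, seed: int, stratified: bool = True) -> list:
    """Deterministic fold assignment: a list of k index arrays of equal
    size (+-1), each record appearing exactly once."""
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if k < 2:
        raise ClassifierError(f"k must be >= 2, got {k}")
    if k > n:
        raise ClassifierError(f"k={k} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    folds: list = [[] for _ in range(k)]
    if stratified:
        start = 0
        for lab in sorted(set(labels)):
            idx = np.nonzero(labels == lab)[0]
            rng.shuffle(idx)
            for offset, i in enumerate(idx):
                folds[(start + offset) % k].append(int(i))
            start += idx.size
    else:
        idx = rng.permutation(n)
        for offset, i in enumerate(idx):
            folds[offset % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(
    cohort: CohortTable,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    features=DEFAULT_FEATURES,
    min_bucket: int = DEFAULT_MIN_BUCKET,
):
    """k-fold cross-validation of One-R with a pooled confusion matrix.

    Folds are of equal size (+-1), stratified by diagnosis by default,
    and fully determined by ``seed``.  Returns ``(pooled_report,
    fold_reports)`` where the pooled report accumulates the test-fold
    confusion matrices (micro-averaged metrics).
    """
    labels = cohort.diagnoses
    folds = stratified_folds(labels, k=k, seed=seed, stratified=stratified)
    all_idx = np.arange(len(cohort))
    preds = np.empty(len(cohort), dtype=object)
    fold_reports = []
    for fold in folds:
        train = np.setdiff1d(all_idx, fold)
        model = fit_oner(cohort.subset(train), features=features, min_bucket=min_bucket)
        for i in fold:
            preds[i] = predict(model, cohort.records[i])
        fold_reports.append(evaluate(preds[fold], labels[fold]))
    pooled = evaluate(list(preds), list(labels))
    return pooled, fold_reports
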