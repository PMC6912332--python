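"""Confusion counting, metrics and patient-level cross-validation.

Malign is the positive class throughout: sensitivity = TP/(TP+FN) is the
fraction of malign cases called malign, specificity = TN/(TN+FP) the
fraction of benign cases called benign, accuracy = (TP+TN)/m. A metric
whose denominator is empty (class absent from the test set) is reported as
NaN rather than raising.

Splitting is by patient — all images of a patient stay on one side. The
default scheme mirrors a fixed-size test draw repeated independently per
fold (11 benign + 50 malign test patients out of 52/246 in the reference
cohort); a disjoint stratified partition is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import BENIGN, MALIGN, Cohort

__all__ = ["ConfusionCounts", "EvalReport", "SplitScheme",
           "confusion", "metrics", "split_cohort", "cross_validate"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_positive(self) -> int:  # malign sample count
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:  # benign sample count
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class FoldResult:
    counts: ConfusionCounts
    accuracy: float
    specificity: float
    sensitivity: float


@dataclass
class EvalReport:
    per_fold: list[FoldResult] = field(default_factory=list)

    def _mean(self, attr: str) -> float:
        vals = [getattr(f, attr) for f in self.per_fold]
        return float(np.mean(vals))

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {"tp": f.counts.tp, "tn": f.counts.tn,
                 "fp": f.counts.fp, "fn": f.counts.fn,
                 "accuracy": round(f.accuracy, 3),
                 "specificity": round(f.specificity, 3),
                 "sensitivity": round(f.sensitivity, 3)}
                for f in self.per_fold
            ],
            "mean_accuracy": round(self.mean_accuracy, 3),
            "mean_specificity": round(self.mean_specificity, 3),
            "mean_sensitivity": round(self.mean_sensitivity, 3),
        }


@dataclass
class SplitScheme:
    n_folds: int = 5
    test_benign: int = 11
    test_malign: int = 50
    mode: str = "repeated_random"   # or "stratified_partition"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.mode not in ("repeated_random", "stratified_partition"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def confusion(predicted, truth) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over paired label lists (malign = positive)."""
    predicted, truth = list(predicted), list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if not predicted:
        raise ValueError("empty label lists")
    c = ConfusionCounts()
    for p, t in zip(predicted, truth):
        if t == MALIGN:
            if p == MALIGN:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == BENIGN:
                c.tn += 1
            else:
                c.fp += 1
    return c


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, specificity, sensitivity); empty denominators give NaN."""
    if counts.total == 0:
        raise ValueError("no samples in confusion counts")
    accuracy = (counts.tp + counts.tn) / counts.total
    specificity = (counts.tn / counts.n_negative
                   if counts.n_negative else float("nan"))
    sensitivity = (counts.tp / counts.n_positive
                   if counts.n_positive else float("nan"))
    return accuracy, specificity, sensitivity


def split_cohort(cohort: Cohort, scheme: SplitScheme):
    """Patient-level folds as (train_ids, test_ids) pairs.

    repeated_random: each fold independently draws test_benign +
    test_malign patients without replacement; stratified_partition:
    disjoint near-equal test folds covering the cohort. Reproducible given
    scheme.seed.
    """
    benign_ids = [r.patient_id for r in cohort.records if r.label == BENIGN]
    malign_ids = [r.patient_id for r in cohort.records if r.label == MALIGN]
    rng = np.random.default_rng(scheme.seed)
    folds = []
    if scheme.mode == "repeated_random":
        if scheme.test_benign > len(benign_ids) or \
                scheme.test_malign > len(malign_ids):
            raise ValueError("test counts exceed class totals")
        for _ in range(scheme.n_folds):
            tb = rng.choice(benign_ids, scheme.test_benign, replace=False)
            tm = rng.choice(malign_ids, scheme.test_malign, replace=False)
            test = set(tb) | set(tm)
            train = [r.patient_id for r in cohort.records
                     if r.patient_id not in test]
            folds.append((train, sorted(test)))
    else:
        b = rng.permutation(benign_ids)
        m = rng.permutation(malign_ids)
        b_chunks = np.array_split(b, scheme.n_folds)
        m_chunks = np.array_split(m, scheme.n_folds)
        for k in range(scheme.n_folds):
            test = set(b_chunks[k]) | set(m_chunks[k])
            train = [r.patient_id for r in cohort.records
                     if r.patient_id not in test]
            folds.append((train, sorted(test)))
    return folds


def cross_validate(cohort: Cohort, scheme: SplitScheme, pipeline_factory,
                   aggregate: str = "image") -> EvalReport:
    """K-fold evaluation of a full train-and-classify pipeline.

    ``pipeline_factory(train_cohort)`` must fit fresh models on the
    training patients only and return a predictor mapping an image path to
    a benign/malign label. ``aggregate``: ``image`` scores every image
    against its patient's label; ``patient`` calls a patient malign if any
    of their images is called malign.
    """
    if aggregate not in ("image", "patient"):
        raise ValueError("aggregate must be 'image' or 'patient'")
    by_id = cohort.by_id()
    report = EvalReport()
    for k, (train_ids, test_ids) in enumerate(split_cohort(cohort, scheme)):
        if set(train_ids) & set(test_ids):
            raise AssertionError(f"fold {k}: train/test patient overlap")
        train_cohort = Cohort([by_id[i] for i in train_ids])
        try:
            predictor = pipeline_factory(train_cohort)
        except Exception as exc:
            raise RuntimeError(f"training failed on fold {k}: {exc}") from exc
        predicted, truth = [], []
        for pid in test_ids:
            rec = by_id[pid]
            img_labels = [predictor(path) for path in rec.image_paths]
            if aggregate == "patient":
                predicted.append(MALIGN if MALIGN in img_labels else BENIGN)
                truth.append(rec.label)
            else:
                predicted.extend(img_labels)
                truth.extend([rec.label] * len(img_labels))
        counts = confusion(predicted, truth)
        acc, spec, sens = metrics(counts)
        report.per_fold.append(FoldResult(counts, acc, spec, sens))
    return report
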