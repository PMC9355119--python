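"""Model validation: binary and multiclass statistics, 5-fold external
cross-validation and Y-randomization.

All eight binary statistics are computed from the confusion counts:

    Se  = TP/(TP+FN)            Sp  = TN/(TN+FP)
    CCR = (Se+Sp)/2             PPV = TP/(TP+FP)
    NPV = TN/(TN+FN)            F1  = 2TP/(2TP+FP+FN)
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    Coverage = in-domain predictions / total predictions

A metric whose denominator is zero is reported as undefined (NaN), never
silently as 0. Multiclass performance is the unweighted mean of one-vs-all
binary reports over the three GHS super-classes (corrosive, irritant,
not-classified).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ad import fit_ad, in_domain_batch
from .descriptors import DescriptorBlock, filter_features
from .models import ClassifierSpec, MudraClassifier, RandomForestModel

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CvResult",
    "binary_metrics",
    "ccr_from_se_sp",
    "confusion_from_labels",
    "five_fold_external_cv",
    "y_randomization",
    "multiclass_metrics",
    "acceptability_check",
]

BINARY_METRIC_NAMES = ("Se", "Sp", "CCR", "PPV", "NPV", "F1", "MCC", "Coverage")

#: metrics checked against the model-acceptability threshold
ACCEPTABILITY_METRICS = ("Se", "Sp", "CCR", "PPV", "NPV")

GHS3_CLASSES = ("CORROSIVE", "IRRITANT", "NC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class MetricsReport:
    Se: float
    Sp: float
    CCR: float
    PPV: float
    NPV: float
    F1: float
    MCC: float
    Coverage: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in BINARY_METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation-layer rounding; internal values stay full precision."""
        return {m: (round(v, ndigits) if not math.isnan(v) else float("nan"))
                for m, v in self.as_dict().items()}

    def summary_row(self, name: str = "") -> str:
        vals = self.rounded()
        cells = "\t".join(
            f"{vals[m]:.2f}" if not math.isnan(vals[m]) else "-"
            for m in ("CCR", "Se", "PPV", "Sp", "NPV", "F1", "MCC", "Coverage"))
        return f"{name}\t{cells}"


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def ccr_from_se_sp(se: float, sp: float) -> float:
    """Correct classification rate: the arithmetic mean of Se and Sp."""
    return (se + sp) / 2.0


def binary_metrics(counts: ConfusionCounts,
                   in_ad_flags=None) -> MetricsReport:
    """All eight binary statistics from confusion counts.

    ``in_ad_flags``, when given, provides the coverage numerator/denominator;
    otherwise Coverage is reported as 1 (no AD restriction applied).
    """
    if counts.total == 0:
        raise ValueError("no evaluated predictions")
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    se = _ratio(TP, TP + FN)
    sp = _ratio(TN, TN + FP)
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = ((TP * TN - FP * FN) / math.sqrt(denom)) if denom > 0 else float("nan")
    if in_ad_flags is not None:
        flags = list(in_ad_flags)
        cov = (sum(1 for f in flags if f in (True, "IN")) / len(flags)
               if flags else float("nan"))
    else:
        cov = 1.0
    return MetricsReport(
        Se=se, Sp=sp, CCR=ccr_from_se_sp(se, sp),
        PPV=_ratio(TP, TP + FP), NPV=_ratio(TN, TN + FN),
        F1=_ratio(2 * TP, 2 * TP + FP + FN), MCC=mcc,
        Coverage=cov, counts=counts,
    )


def confusion_from_labels(y_true, y_pred, positive: str = "POS") -> ConfusionCounts:
    TP = TN = FP = FN = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t == positive:
            TP, FN = (TP + 1, FN) if p == positive else (TP, FN + 1)
        else:
            TN, FP = (TN, FP + 1) if p == positive else (TN + 1, FP)
    return ConfusionCounts(TP=TP, TN=TN, FP=FP, FN=FN)


@dataclass
class CvResult:
    fold_assignments: dict  # compound_id -> fold index (1-based)
    y_true: list
    y_pred: list
    compound_ids: list
    metrics: MetricsReport
    fold_metrics: list = field(default_factory=list)
    rng_seed: int = 0


def _fit_predict(spec: ClassifierSpec, blocks: dict, labels,
                 train_idx, test_idx, assess_ad: bool):
    """Train on one fold's modeling portion, predict its test portion.

    Feature filtering (continuous spaces) and AD fitting use the training
    rows only, so no test information leaks into model construction.
    """
    labels = np.asarray(labels)
    if spec.algorithm == "RF":
        space = spec.spaces[0]
        train_block = blocks[space].subset_rows(train_idx)
        test_block = blocks[space].subset_rows(test_idx)
        if train_block.kind == "CONTINUOUS":
            train_block, report = filter_features(train_block)
            keep = [test_block.feature_names.index(n)
                    for n in train_block.feature_names]
            test_block = DescriptorBlock(
                space=test_block.space, matrix=test_block.matrix[:, keep],
                feature_names=list(train_block.feature_names),
                kind=test_block.kind, compound_ids=test_block.compound_ids)
        model = RandomForestModel(spec).fit(train_block, labels[train_idx])
        preds = model.predict(test_block.matrix)
        if assess_ad:
            ad = fit_ad(train_block)
            flags = in_domain_batch(test_block.matrix, ad)
        else:
            flags = None
        return preds, flags
    if spec.algorithm == "MUDRA":
        mudra = MudraClassifier(spec).fit(
            {s: blocks[s].subset_rows(train_idx) for s in spec.spaces},
            labels[train_idx])
        out = mudra.predict({s: blocks[s].subset_rows(test_idx)
                             for s in spec.spaces})
        return [p.predicted_label for p in out], None
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def five_fold_external_cv(blocks: dict, labels, spec: ClassifierSpec,
                          seed: int = 0, positive: str = "POS",
                          assess_ad: bool = False,
                          n_folds: int = 5) -> CvResult:
    """External cross-validation with an 80%/20% modeling/test split.

    The set is partitioned into five near-equal stratified parts; each part
    serves once as the test set while the model is built on the other four.
    Test compounds play no role whatsoever in model construction. Headline
    metrics are computed on the pooled out-of-fold predictions.
    """
    labels = list(labels)
    any_block = next(iter(blocks.values()))
    ids = any_block.compound_ids
    n = len(labels)
    multiclass = len(set(labels)) > 2

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignments: dict = {}
    y_true_all, y_pred_all, ids_all, flags_all = [], [], [], []
    fold_metrics = []
    for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(n), labels), start=1):
        if len(set(np.asarray(labels)[train_idx])) < 2:
            raise ValueError(f"fold {fold}: a class is absent from training")
        preds, flags = _fit_predict(spec, blocks, labels, train_idx, test_idx,
                                    assess_ad)
        y_t = [labels[i] for i in test_idx]
        for i in test_idx:
            fold_assignments[ids[i]] = fold
        y_true_all.extend(y_t)
        y_pred_all.extend(preds)
        ids_all.extend(ids[i] for i in test_idx)
        if flags is not None:
            flags_all.extend(flags)
        if not multiclass:
            fold_metrics.append(binary_metrics(
                confusion_from_labels(y_t, preds, positive)))

    if multiclass:
        _, overall = multiclass_metrics(y_true_all, y_pred_all)
        metrics = overall
    else:
        metrics = binary_metrics(
            confusion_from_labels(y_true_all, y_pred_all, positive),
            in_ad_flags=flags_all if flags_all else None)
    return CvResult(fold_assignments=fold_assignments, y_true=y_true_all,
                    y_pred=y_pred_all, compound_ids=ids_all, metrics=metrics,
                    fold_metrics=fold_metrics, rng_seed=seed)


def y_randomization(blocks: dict, labels, spec: ClassifierSpec,
                    n_rounds: int = 10, seed: int = 0,
                    positive: str = "POS") -> list[MetricsReport]:
    """Label-shuffling control: n_rounds of CV on permuted labels.

    A real structure–activity signal cannot survive the permutation, so the
    shuffled models should perform at chance (CCR ≈ 0.5, MCC ≈ 0); a real
    model clearly exceeding the shuffled distribution was not fitted by
    chance.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    reports = []
    for r in range(n_rounds):
        shuffled = labels[rng.permutation(len(labels))]
        cv = five_fold_external_cv(blocks, list(shuffled), spec,
                                   seed=seed + r + 1, positive=positive)
        reports.append(cv.metrics)
    return reports


def multiclass_metrics(y_true, y_pred,
                       classes=GHS3_CLASSES) -> tuple[dict, MetricsReport]:
    """One-vs-all binary reports per class plus their unweighted mean.

    Undefined entries (zero denominators) are skipped in the average with a
    warning rather than biasing it toward zero.
    """
    for lab in list(y_true) + list(y_pred):
        if lab not in classes:
            raise ValueError(f"unknown class label {lab!r}")
    per_class = {}
    for cls in classes:
        t = ["POS" if y == cls else "NEG" for y in y_true]
        p = ["POS" if y == cls else "NEG" for y in y_pred]
        per_class[cls] = binary_metrics(confusion_from_labels(t, p))

    averaged = {}
    for m in BINARY_METRIC_NAMES:
        vals = [getattr(per_class[c], m) for c in classes]
        defined = [v for v in vals if not math.isnan(v)]
        if len(defined) < len(vals):
            warnings.warn(f"metric {m}: averaging over {len(defined)} of "
                          f"{len(vals)} classes (others undefined)")
        averaged[m] = (sum(defined) / len(defined)) if defined else float("nan")
    return per_class, MetricsReport(**averaged)


def acceptability_check(report: MetricsReport,
                        threshold: float = 0.6) -> tuple[bool, list[str]]:
    """Model-selection gate: Se, Sp, CCR, PPV and NPV must all reach the
    acceptable threshold (inclusive). Returns (passed, failing metrics)."""
    failing = [m for m in ACCEPTABILITY_METRICS
               if math.isnan(getattr(report, m)) or getattr(report, m) < threshold]
    return (len(failing) == 0, failing)
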