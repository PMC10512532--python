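"""Classification metrics and the cross-validation / independent-test protocol.

Six metrics are reported for every model: accuracy (ACC), balanced accuracy
(BACC = (Sn+Sp)/2), sensitivity (Sn), specificity (Sp), Matthews correlation
coefficient (MCC) and the area under the ROC curve (AUC, midrank-tied).
Degenerate denominators (e.g. a model predicting a single class) score 0
rather than raising, so broken models rank poorly instead of crashing a
sweep. Cross-validation pools out-of-fold predictions into a single report;
per-fold averaging is available as an alternative aggregation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from peptidestack.peptide_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    acc: float
    bacc: float
    sn: float
    sp: float
    mcc: float
    auc: float
    counts: ConfusionCounts
    protocol: str = "independent"  # or "cross-validation"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_row(self) -> pd.DataFrame:
        """One-row frame in the conventional column order."""
        return pd.DataFrame(
            [[self.acc, self.bacc, self.sn, self.sp, self.mcc, self.auc]],
            columns=["ACC", "BACC", "Sn", "Sp", "MCC", "AUC"],
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def mcc_from_counts(c: ConfusionCounts) -> float:
    """MCC with the zero-denominator convention MCC=0."""
    den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return _safe_div(c.tp * c.tn - c.fp * c.fn, den)


def auc_score(y_true: np.ndarray, confidence: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with midranks for ties.

    Returns 0.5 when one class is absent (AUC undefined).
    """
    y_true = np.asarray(y_true)
    confidence = np.asarray(confidence, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(confidence, method="average")
    r_pos = ranks[y_true == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def score(
    y_true,
    confidence,
    threshold: float = 0.5,
    protocol: str = "independent",
) -> EvalReport:
    """Score confidences against binary labels at a decision threshold.

    Ties at the threshold go to the positive class (confidence >= threshold).
    """
    y_true = np.asarray(y_true, dtype=int)
    confidence = np.asarray(confidence, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    if y_true.shape != confidence.shape:
        raise ValueError("labels and confidences must have equal length")
    if not np.isfinite(confidence).all():
        raise ValueError("non-finite confidences")
    y_pred = (confidence >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )
    sn = _safe_div(counts.tp, counts.tp + counts.fn)
    sp = _safe_div(counts.tn, counts.tn + counts.fp)
    return EvalReport(
        acc=_safe_div(counts.tp + counts.tn, counts.total),
        bacc=(sn + sp) / 2.0,
        sn=sn,
        sp=sp,
        mcc=mcc_from_counts(counts),
        auc=auc_score(y_true, confidence),
        counts=counts,
        protocol=protocol,
    )


def cross_validate(
    pipeline_factory,
    ds: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    aggregate: str = "pooled",
) -> EvalReport:
    """Stratified k-fold cross-validation of a full pipeline.

    ``pipeline_factory()`` must return a fresh object with
    ``fit(dataset)`` and ``predict_confidence(dataset) -> array`` methods.
    With ``aggregate="pooled"`` (default) out-of-fold confidences are
    concatenated and scored once; ``"averaged"`` scores each fold and
    averages the metrics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ds.require_both_classes()
    y = ds.y
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if aggregate == "pooled":
        oof = np.full(len(ds), np.nan)
        for train_idx, test_idx in skf.split(np.zeros(len(ds)), y):
            pipe = pipeline_factory()
            pipe.fit(ds.subset(train_idx))
            oof[test_idx] = np.asarray(pipe.predict_confidence(ds.subset(test_idx)))
        report = score(y, oof, threshold=threshold, protocol="cross-validation")
        return report
    if aggregate == "averaged":
        reports = []
        for train_idx, test_idx in skf.split(np.zeros(len(ds)), y):
            pipe = pipeline_factory()
            pipe.fit(ds.subset(train_idx))
            conf = np.asarray(pipe.predict_confidence(ds.subset(test_idx)))
            reports.append(score(y[test_idx], conf, threshold=threshold))
        counts = ConfusionCounts(
            tp=sum(r.counts.tp for r in reports),
            tn=sum(r.counts.tn for r in reports),
            fp=sum(r.counts.fp for r in reports),
            fn=sum(r.counts.fn for r in reports),
        )
        mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
        return EvalReport(
            acc=mean("acc"), bacc=mean("bacc"), sn=mean("sn"), sp=mean("sp"),
            mcc=mean("mcc"), auc=mean("auc"), counts=counts,
            protocol="cross-validation",
        )
    raise ValueError(f"unknown aggregation {aggregate!r}")


def roc_points(y_true, confidence) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) from confidences."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_true, int), np.asarray(confidence, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
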