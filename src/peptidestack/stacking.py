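"""Out-of-fold probabilistic-feature stacking and the PLS meta-classifier.

Every (encoder, algorithm) pair defines one baseline model; the default
architecture crosses 10 encoders with 13 algorithms into 130 baselines.
For the training set, each baseline's positive-class confidence is produced
out-of-fold: a single stratified k-fold partition is shared by all
baselines, the learner is tuned and fitted on each in-fold portion, and its
confidence fills the held-out rows. Stacked side by side these confidences
form the probabilistic feature vector (PFV), one column per baseline, on
which a partial-least-squares meta-classifier is trained. External data is
scored by baselines refitted on the full training set, keeping column order
identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from peptidestack.chem.fingerprints import FINGERPRINT_DIMENSIONS, encode_fingerprint_dataset
from peptidestack.evaluation import ConfusionCounts, mcc_from_counts
from peptidestack.features import FeatureMatrix
from peptidestack.learners import (
    ALGORITHMS,
    LearnerSpec,
    PLSClassifier,
    TrainedLearner,
    tune_and_fit,
)
from peptidestack.peptide_io import LabeledDataset
from peptidestack.seq_encoders import SEQ_ENCODERS, PseudoCompositionConfig, encode_dataset

#: Default encoder order (sequence descriptors first, then fingerprints).
ENCODERS = ("AAC", "APAAC", "DDE", "DPC", "PCP", "PAAC", "Estate", "FP4", "MACCS", "PubChem")

ENCODER_DIMENSIONS = {
    "AAC": 20, "APAAC": 22, "DDE": 400, "DPC": 400, "PCP": 11, "PAAC": 21,
    **FINGERPRINT_DIMENSIONS,
}


def encode(ds: LabeledDataset, encoder: str, paac_cfg: PseudoCompositionConfig | None = None) -> FeatureMatrix:
    """Encode a dataset with any of the 10 encoders by name."""
    if encoder in SEQ_ENCODERS:
        return encode_dataset(ds, encoder, paac_cfg=paac_cfg)
    if encoder in FINGERPRINT_DIMENSIONS:
        return encode_fingerprint_dataset(ds, encoder)
    raise KeyError(f"unknown encoder {encoder!r}")


@dataclass(frozen=True)
class StackingArchitecture:
    """The cross-product of encoders and algorithms defining the baselines."""

    encoders: tuple[str, ...] = ENCODERS
    algorithms: tuple[str, ...] = ALGORITHMS

    def __post_init__(self) -> None:
        unknown = set(self.encoders) - set(ENCODER_DIMENSIONS)
        if unknown:
            raise KeyError(f"unknown encoders: {sorted(unknown)}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise KeyError(f"unknown algorithms: {sorted(unknown)}")

    @property
    def baseline_names(self) -> list[str]:
        """Column names '<algorithm>-<encoder>' in fixed architecture order."""
        return [f"{alg}-{enc}" for enc in self.encoders for alg in self.algorithms]

    @property
    def n_baselines(self) -> int:
        return len(self.encoders) * len(self.algorithms)


@dataclass
class PFVMatrix:
    """Samples x baseline-confidence matrix with provenance."""

    frame: pd.DataFrame  # index: sample ids, columns: baseline names
    provenance: str  # "out-of-fold" or "full-model"
    fold_of_sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(float)
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("PFV confidences must lie in [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _encoded_views(arch: StackingArchitecture, ds: LabeledDataset) -> dict[str, FeatureMatrix]:
    return {enc: encode(ds, enc) for enc in arch.encoders}


def build_training_pfv(
    arch: StackingArchitecture,
    ds: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    tune_folds: int = 10,
) -> PFVMatrix:
    """Build the out-of-fold PFV for a labeled training set.

    One stratified k-fold partition is fixed up front and shared by every
    baseline, so each row of the PFV is consistently out-of-fold across all
    columns. Hyperparameters are re-tuned inside each training fold to keep
    tuning information from leaking across the fold boundary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ds.require_both_classes()
    y = ds.y
    views = _encoded_views(arch, ds)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(ds)), y))
    fold_of_sample = np.empty(len(ds), dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_of_sample[test_idx] = f
    data = np.empty((len(ds), arch.n_baselines))
    col = 0
    for enc in arch.encoders:
        X = views[enc].values
        for alg in arch.algorithms:
            for train_idx, test_idx in folds:
                try:
                    model = tune_and_fit(
                        LearnerSpec(alg), X[train_idx], y[train_idx],
                        k=tune_folds, seed=seed,
                    )
                except Exception as exc:  # noqa: BLE001 - annotate origin
                    raise RuntimeError(
                        f"baseline ({enc}, {alg}) failed during OOF fit: {exc}"
                    ) from exc
                data[test_idx, col] = model.predict_confidence(X[test_idx])
            col += 1
    frame = pd.DataFrame(data, index=pd.Index(ds.ids, name="id"),
                         columns=arch.baseline_names)
    return PFVMatrix(frame, provenance="out-of-fold", fold_of_sample=fold_of_sample)


@dataclass
class FittedBaselines:
    """All baselines tuned and refitted on the full training set."""

    arch: StackingArchitecture
    models: dict[str, TrainedLearner]  # keyed by baseline name

    def manifest(self) -> dict:
        return {name: m.manifest() for name, m in self.models.items()}


def fit_full_baselines(
    arch: StackingArchitecture,
    ds: LabeledDataset,
    seed: int = 0,
    tune_folds: int = 10,
) -> FittedBaselines:
    """Tune and fit every baseline on the complete training set (the models
    used to score external/independent data)."""
    ds.require_both_classes()
    y = ds.y
    views = _encoded_views(arch, ds)
    models: dict[str, TrainedLearner] = {}
    for enc in arch.encoders:
        X = views[enc].values
        for alg in arch.algorithms:
            try:
                models[f"{alg}-{enc}"] = tune_and_fit(
                    LearnerSpec(alg), X, y, k=tune_folds, seed=seed
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"baseline ({enc}, {alg}) failed to fit: {exc}") from exc
    return FittedBaselines(arch, models)


def build_external_pfv(baselines: FittedBaselines, ds: LabeledDataset) -> PFVMatrix:
    """Score an external (test or unlabeled) dataset with full-data baselines.

    Column order matches the training PFV exactly.
    """
    arch = baselines.arch
    views = _encoded_views(arch, ds)
    data = np.empty((len(ds), arch.n_baselines))
    for j, name in enumerate(arch.baseline_names):
        alg, enc = name.split("-", 1)
        data[:, j] = baselines.models[name].predict_confidence(views[enc].values)
    frame = pd.DataFrame(data, index=pd.Index(ds.ids, name="id"),
                         columns=arch.baseline_names)
    return PFVMatrix(frame, provenance="full-model")


@dataclass
class MetaModel:
    """PLS meta-classifier over a selected subset of PFV columns."""

    classifier: PLSClassifier
    columns: list[str]  # selected PFV columns, in order
    n_components: int
    threshold: float = 0.5

    def _matrix(self, pfv: PFVMatrix | pd.DataFrame) -> np.ndarray:
        frame = pfv.frame if isinstance(pfv, PFVMatrix) else pfv
        missing = [c for c in self.columns if c not in frame.columns]
        if missing:
            raise ValueError(f"PFV is missing meta-model columns: {missing[:5]}")
        return frame[self.columns].to_numpy(float)

    def predict(self, pfv: PFVMatrix | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (confidence in [0,1], class) per sample; ties at the
        threshold go to the positive class."""
        conf = np.clip(self.classifier.decision_function(self._matrix(pfv)), 0.0, 1.0)
        return conf, (conf >= self.threshold).astype(int)

    def manifest(self) -> dict:
        return {
            "meta": "PLS",
            "n_components": self.n_components,
            "threshold": self.threshold,
            "columns": self.columns,
        }


def _pooled_mcc_of_pls(X: np.ndarray, y: np.ndarray, n_components: int,
                       k: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        clf = PLSClassifier(n_components=n_components).fit(X[train_idx], y[train_idx])
        oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
    pred = (oof >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(((y == 1) & (pred == 1)).sum()),
        tn=int(((y == 0) & (pred == 0)).sum()),
        fp=int(((y == 0) & (pred == 1)).sum()),
        fn=int(((y == 1) & (pred == 0)).sum()),
    )
    return mcc_from_counts(counts)


def fit_meta(
    pfv: PFVMatrix,
    y,
    mask=None,
    components: int | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetaModel:
    """Fit the PLS meta-classifier on (selected columns of) a training PFV.

    ``mask`` may be a boolean array over columns or a list of column names;
    ``None`` selects all columns. When ``components`` is not given it is
    chosen from {1..min(8, m)} by stratified k-fold CV MCC.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("meta-model training labels contain a single class")
    all_cols = pfv.columns
    if mask is None:
        columns = all_cols
    elif isinstance(mask, (list, tuple)) and mask and isinstance(mask[0], str):
        columns = list(mask)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(all_cols),):
            raise ValueError("mask length must equal PFV column count")
        columns = [c for c, keep in zip(all_cols, mask) if keep]
    if not columns:
        raise ValueError("mask selects no columns")
    X = pfv.frame[columns].to_numpy(float)
    if components is None:
        k_eff = min(k, int(np.bincount(y).min()))
        best, best_mcc = 1, -np.inf
        for c in range(1, min(8, len(columns)) + 1):
            mcc = _pooled_mcc_of_pls(X, y, c, k_eff, seed)
            if mcc > best_mcc:
                best, best_mcc = c, mcc
        components = best
    if components > len(columns):
        raise ValueError("component count exceeds selected column count")
    clf = PLSClassifier(n_components=components, threshold=threshold).fit(X, y)
    return MetaModel(clf, columns, components, threshold)


# ---------------------------------------------------------------------------
# pipeline bundle persistence (directory artifact + JSON manifest)

@dataclass
class PipelineBundle:
    """A trained end-to-end pipeline: full-data baselines + meta-model."""

    baselines: FittedBaselines
    meta: MetaModel
    config: dict = field(default_factory=dict)

    def predict(self, ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
        pfv = build_external_pfv(self.baselines, ds)
        return self.meta.predict(pfv)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.baselines, directory / "baselines.joblib")
        joblib.dump(self.meta, directory / "meta.joblib")
        manifest = {
            "encoders": list(self.baselines.arch.encoders),
            "algorithms": list(self.baselines.arch.algorithms),
            "baselines": self.baselines.manifest(),
            "meta": self.meta.manifest(),
            "config": self.config,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "PipelineBundle":
        directory = Path(directory)
        baselines = joblib.load(directory / "baselines.joblib")
        meta = joblib.load(directory / "meta.joblib")
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(baselines, meta, manifest.get("config", {}))
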