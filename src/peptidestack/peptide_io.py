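"""Peptide sequence I/O, validation, and labeled-dataset management.

Sequences are restricted to the 20 standard amino acids; every downstream
encoder assumes this alphabet. Datasets carry parallel peptide/label lists
and support exact-duplicate removal and seeded, per-class stratified
train/test splitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = 1
NEGATIVE = 0
_LABEL_NAMES = {POSITIVE: "positive", NEGATIVE: "negative"}
_LABEL_CODES = {"positive": POSITIVE, "negative": NEGATIVE, "1": POSITIVE, "0": NEGATIVE}


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the 20-letter alphabet."""


class EmptyDatasetError(ValueError):
    """Raised when parsing yields no valid records."""


@dataclass(frozen=True)
class Peptide:
    """A peptide with a text identifier and a validated sequence.

    The sequence is upper-cased before validation; non-standard residue
    codes (B, J, O, U, X, Z) are rejected.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidSequenceError(f"peptide {self.id!r}: empty sequence")
        bad = sorted(set(seq) - _AA_SET)
        if bad:
            raise InvalidSequenceError(
                f"peptide {self.id!r}: invalid residue(s) {','.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of peptides with parallel binary labels.

    Labels are stored as integers (1 = positive class, 0 = negative).
    Unlabeled collections (e.g. screening input) use label -1.
    """

    peptides: list[Peptide]
    labels: list[int]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.labels):
            raise ValueError("peptides and labels must have equal length")
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate peptide ids in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(zip(self.peptides, self.labels))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def class_counts(self) -> dict[str, int]:
        y = self.y
        return {"positive": int((y == POSITIVE).sum()), "negative": int((y == NEGATIVE).sum())}

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.peptides[i] for i in indices],
            [self.labels[i] for i in indices],
            name or self.name,
        )

    def require_both_classes(self) -> None:
        counts = self.class_counts()
        if counts["positive"] == 0 or counts["negative"] == 0:
            raise ValueError(
                f"dataset {self.name!r} needs samples from both classes "
                f"(got {counts})"
            )

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "n_samples": len(self),
            "class_counts": self.class_counts(),
            "length_range": [min(map(len, self.peptides)), max(map(len, self.peptides))]
            if self.peptides
            else None,
        }


def _coerce_label(label) -> int:
    if label is None:
        return -1
    if isinstance(label, int) and label in (-1, 0, 1):
        return label
    key = str(label).strip().lower()
    if key not in _LABEL_CODES:
        raise ValueError(f"unknown class label {label!r}; expected positive/negative")
    return _LABEL_CODES[key]


def read_fasta(path, label=None, strict: bool = True, name: str | None = None) -> LabeledDataset:
    """Read a FASTA file into a :class:`LabeledDataset`.

    Parameters
    ----------
    path:
        FASTA file of peptide sequences.
    label:
        Class tag applied to every record ("positive"/"negative"/1/0), or
        ``None`` for an unlabeled dataset.
    strict:
        If True (default), any record with characters outside the 20-letter
        alphabet raises :class:`InvalidSequenceError`. If False, such
        records are dropped with a logged warning.
    """
    path = Path(path)
    code = _coerce_label(label)
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            peptides.append(Peptide(rec.id, str(rec.seq)))
        except InvalidSequenceError:
            if strict:
                raise
            logger.warning("dropping invalid record %s from %s", rec.id, path)
    if not peptides:
        raise EmptyDatasetError(f"no valid peptide records in {path}")
    return LabeledDataset(peptides, [code] * len(peptides), name or path.stem)


def write_fasta(ds: LabeledDataset, path) -> None:
    """Write dataset sequences to FASTA, preserving ids and order."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in ds.peptides
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_tsv(path, label=None, name: str | None = None, strict: bool = True) -> LabeledDataset:
    """Read a 2-column TSV (id, sequence) into a dataset with a single label."""
    path = Path(path)
    code = _coerce_label(label)
    peptides = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            try:
                peptides.append(Peptide(parts[0], parts[1]))
            except InvalidSequenceError:
                if strict:
                    raise
                logger.warning("dropping invalid record %s from %s", parts[0], path)
    if not peptides:
        raise EmptyDatasetError(f"no valid peptide records in {path}")
    return LabeledDataset(peptides, [code] * len(peptides), name or path.stem)


def concat(datasets: Iterable[LabeledDataset], name: str = "combined") -> LabeledDataset:
    """Concatenate datasets (ids must stay unique across the union)."""
    peptides, labels = [], []
    for ds in datasets:
        peptides.extend(ds.peptides)
        labels.extend(ds.labels)
    return LabeledDataset(peptides, labels, name)


def deduplicate(ds: LabeledDataset) -> LabeledDataset:
    """Remove exact-sequence duplicates, keeping the first occurrence.

    A sequence that occurs with conflicting labels is removed entirely and
    the conflict is logged: such samples are uninformative for training and
    keeping either copy would silently pick a side.
    """
    first_label: dict[str, int] = {}
    conflicted: set[str] = set()
    for p, lab in ds:
        if p.sequence in first_label and first_label[p.sequence] != lab:
            conflicted.add(p.sequence)
        first_label.setdefault(p.sequence, lab)
    for seq in conflicted:
        logger.warning(
            "dedup: sequence %s... occurs with conflicting labels; removed", seq[:12]
        )
    seen: set[str] = set()
    keep: list[int] = []
    for i, (p, _) in enumerate(ds):
        if p.sequence in conflicted or p.sequence in seen:
            continue
        seen.add(p.sequence)
        keep.append(i)
    return ds.subset(keep, ds.name)


def split(
    ds: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded per-class stratified split into (train, test).

    Within each class, ``round(n_class * train_fraction)`` samples (nearest
    integer, at least 1 on each side) go to the training set. The two
    outputs partition the input exactly and preserve input order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    ds.require_both_classes()
    rng = np.random.default_rng(seed)
    y = ds.y
    train_idx: list[int] = []
    for cls in (POSITIVE, NEGATIVE):
        cls_idx = np.flatnonzero(y == cls)
        n = len(cls_idx)
        n_train = int(np.floor(n * train_fraction + 0.5))
        if not 1 <= n_train <= n - 1:
            raise ValueError(
                f"train_fraction={train_fraction} leaves class "
                f"{_LABEL_NAMES[cls]} empty on one side (n={n})"
            )
        chosen = rng.permutation(cls_idx)[:n_train]
        train_idx.extend(chosen.tolist())
    train_set = set(train_idx)
    test_idx = [i for i in range(len(ds)) if i not in train_set]
    return (
        ds.subset(sorted(train_idx), f"{ds.name}-train"),
        ds.subset(test_idx, f"{ds.name}-test"),
    )


def save_manifest(ds: LabeledDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(ds.manifest(), fh, indent=2)
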