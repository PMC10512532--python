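"""Keyed binary substructure fingerprints over peptide SMILES.

Four fingerprint families with fixed dimensions:

=========  ====  ========================================================
name        dim  backend
=========  ====  ========================================================
Estate       79  electrotopological-state atom types (RDKit EState)
FP4         307  functional-group SMARTS dictionary (Open Babel ``obabel``)
MACCS       166  MACCS structural keys (RDKit; key 0 is unused upstream)
PubChem     881  PubChem-style keyed dictionary shipped with the package
                 (element counts, ring counts, SMARTS patterns; the key
                 definitions are original, see the data file header)
=========  ====  ========================================================

All bits are presence/absence (0/1) of a named, dictionary-defined feature:
no hashing or folding, so bit positions are stable and interpretable.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.EState import AtomTypes as EStateAtomTypes
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from peptidestack.features import FeatureMatrix
from peptidestack.peptide_io import LabeledDataset
from peptidestack.chem.smiles import PeptideSmiles, dataset_to_smiles

FINGERPRINT_DIMENSIONS = {"Estate": 79, "FP4": 307, "MACCS": 166, "PubChem": 881}


@dataclass(frozen=True)
class FingerprintSpec:
    name: str

    def __post_init__(self) -> None:
        if self.name not in FINGERPRINT_DIMENSIONS:
            raise KeyError(
                f"unsupported fingerprint {self.name!r}; "
                f"choose from {sorted(FINGERPRINT_DIMENSIONS)}"
            )

    @property
    def dimension(self) -> int:
        return FINGERPRINT_DIMENSIONS[self.name]


def _as_mol(s: PeptideSmiles | str) -> Chem.Mol:
    smiles = s.smiles if isinstance(s, PeptideSmiles) else s
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# Estate (79 atom types)

@lru_cache(maxsize=1)
def estate_feature_names() -> tuple[str, ...]:
    EStateAtomTypes.BuildPatts()
    return tuple(f"Estate_{name}" for name, _ in EStateAtomTypes.esPatterns)


def _estate_bits(mol: Chem.Mol) -> np.ndarray:
    counts, _sums = EStateFingerprinter.FingerprintMol(mol)
    return (np.asarray(counts) > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# MACCS (166 keys; RDKit emits 167 bits with bit 0 always unset)

def _maccs_bits(mol: Chem.Mol) -> np.ndarray:
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(167, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr[1:]


# ---------------------------------------------------------------------------
# FP4 (307 functional-group patterns, computed by the Open Babel CLI)

_FP4_WORDS = 16  # 512-bit field; patterns occupy bits 0..306


def _require_obabel() -> str:
    exe = shutil.which("obabel")
    if exe is None:
        raise RuntimeError(
            "the FP4 fingerprint requires the Open Babel `obabel` executable on PATH"
        )
    return exe


def _fp4_batch(smiles_list: list[str]) -> np.ndarray:
    """Run one obabel invocation over a batch of SMILES and decode the hex
    fingerprint dump into a (n, 307) bit matrix."""
    exe = _require_obabel()
    out = np.zeros((len(smiles_list), 307), dtype=np.uint8)
    if not smiles_list:
        return out
    with tempfile.TemporaryDirectory() as tmp:
        smi = Path(tmp) / "batch.smi"
        with open(smi, "w") as fh:
            for i, s in enumerate(smiles_list):
                fh.write(f"{s} m{i}\n")
        res = subprocess.run(
            [exe, str(smi), "-ofpt", "-xfFP4", "-xh"],
            capture_output=True, text=True, check=True,
        )
    mol_idx, words = -1, []

    def flush():
        if mol_idx < 0:
            return
        if len(words) != _FP4_WORDS:
            raise RuntimeError(
                f"unexpected obabel FP4 output: {len(words)} words for molecule {mol_idx}"
            )
        # words are printed most-significant first; bit 0 is the LSB of the
        # last word
        for w, word in enumerate(reversed(words)):
            v = int(word, 16)
            while v:
                bit = (v & -v).bit_length() - 1
                idx = 32 * w + bit
                if idx < 307:
                    out[mol_idx, idx] = 1
                v &= v - 1

    for line in res.stdout.splitlines():
        line = line.strip()
        if line.startswith(">"):
            flush()
            mol_idx += 1
            words = []
        elif line and not line.startswith("Possible"):
            tokens = line.split()
            if all(len(t) == 8 for t in tokens):
                words.extend(tokens)
    flush()
    if mol_idx + 1 != len(smiles_list):
        raise RuntimeError(
            f"obabel returned {mol_idx + 1} fingerprints for {len(smiles_list)} molecules"
        )
    return out


# ---------------------------------------------------------------------------
# PubChem-style (881 keys from the shipped synthetic dictionary)

@lru_cache(maxsize=1)
def _pubchem_keys():
    """Load and compile the shipped 881-key dictionary.

    Returns (names, element_count keys, ring keys, compiled smarts keys),
    where each key carries its output index.
    """
    names: list[str] = []
    counts: list[tuple[int, str, int]] = []
    rings: list[tuple[int, int, str, int]] = []
    smarts: list[tuple[int, Chem.Mol]] = []
    path = resources.files("peptidestack.chem.data").joinpath(
        "pubchem_style_keys_synthetic.tsv"
    )
    with path.open() as fh:
        header_seen = False
        for line in fh:
            if line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            idx_s, name, kind, param, thr, sm = line.rstrip("\n").split("\t")
            idx = int(idx_s)
            names.append(f"PubChem_{name}")
            if kind == "element_count":
                counts.append((idx, param, int(thr)))
            elif kind == "ring":
                size, cat = param.split(":")
                rings.append((idx, int(size), cat, int(thr)))
            elif kind == "smarts":
                patt = Chem.MolFromSmarts(sm)
                if patt is None:
                    raise RuntimeError(f"bad SMARTS in key table: {name}")
                smarts.append((idx, patt))
            else:
                raise RuntimeError(f"unknown key kind {kind!r}")
    if len(names) != 881:
        raise RuntimeError(f"key table has {len(names)} entries, expected 881")
    return tuple(names), tuple(counts), tuple(rings), tuple(smarts)


def pubchem_feature_names() -> list[str]:
    return list(_pubchem_keys()[0])


def _ring_matches(ring_atoms, mol: Chem.Mol, cat: str) -> bool:
    atoms = [mol.GetAtomWithIdx(i) for i in ring_atoms]
    if cat == "any":
        return True
    if cat == "aromatic":
        return all(a.GetIsAromatic() for a in atoms)
    if cat == "nonaromatic":
        return not all(a.GetIsAromatic() for a in atoms)
    if cat == "hetero":
        return any(a.GetAtomicNum() != 6 for a in atoms)
    if cat == "carbon_only":
        return all(a.GetAtomicNum() == 6 for a in atoms)
    if cat == "nitrogen":
        return any(a.GetAtomicNum() == 7 for a in atoms)
    if cat == "oxygen":
        return any(a.GetAtomicNum() == 8 for a in atoms)
    raise RuntimeError(f"unknown ring category {cat!r}")


def _pubchem_bits(mol: Chem.Mol) -> np.ndarray:
    _names, counts, rings, smarts = _pubchem_keys()
    out = np.zeros(881, dtype=np.uint8)
    elem_counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        elem_counts[sym] = elem_counts.get(sym, 0) + 1
        elem_counts["H"] = elem_counts.get("H", 0) + atom.GetTotalNumHs()
    for idx, sym, thr in counts:
        if elem_counts.get(sym, 0) >= thr:
            out[idx] = 1
    ring_sets = mol.GetRingInfo().AtomRings()
    for idx, size, cat, thr in rings:
        n = sum(
            1 for ring in ring_sets
            if len(ring) == size and _ring_matches(ring, mol, cat)
        )
        if n >= thr:
            out[idx] = 1
    for idx, patt in smarts:
        if mol.HasSubstructMatch(patt):
            out[idx] = 1
    return out


# ---------------------------------------------------------------------------
# public API

def encode_fingerprint(s: PeptideSmiles | str, spec: FingerprintSpec | str) -> np.ndarray:
    """Encode one molecule; returns a 0/1 vector of the spec's dimension."""
    if isinstance(spec, str):
        spec = FingerprintSpec(spec)
    if spec.name == "FP4":
        smiles = s.smiles if isinstance(s, PeptideSmiles) else s
        _as_mol(smiles)  # surface parse errors eagerly
        return _fp4_batch([smiles])[0]
    mol = _as_mol(s)
    if spec.name == "Estate":
        return _estate_bits(mol)
    if spec.name == "MACCS":
        return _maccs_bits(mol)
    return _pubchem_bits(mol)


def fingerprint_feature_names(spec: FingerprintSpec | str) -> list[str]:
    if isinstance(spec, str):
        spec = FingerprintSpec(spec)
    if spec.name == "Estate":
        return list(estate_feature_names())
    if spec.name == "MACCS":
        return [f"MACCS_{k}" for k in range(1, 167)]
    if spec.name == "FP4":
        return [f"FP4_{k}" for k in range(1, 308)]
    return pubchem_feature_names()


def encode_fingerprint_dataset(
    ds: LabeledDataset, spec: FingerprintSpec | str, stereo: bool = True
) -> FeatureMatrix:
    """Encode a dataset: sequence -> SMILES -> fingerprint matrix."""
    if isinstance(spec, str):
        spec = FingerprintSpec(spec)
    entries = dataset_to_smiles(ds, stereo=stereo)
    if spec.name == "FP4":
        values = _fp4_batch([e.smiles for e in entries])
    else:
        values = (
            np.vstack([encode_fingerprint(e, spec) for e in entries])
            if entries
            else np.empty((0, spec.dimension), dtype=np.uint8)
        )
    return FeatureMatrix(values, fingerprint_feature_names(spec), spec.name, ds.ids)
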