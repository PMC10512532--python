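"""Sequence-based peptide descriptors.

Six fixed-length encodings computed directly from the residue string:

========  ====  =====================================================
encoder   dim   description
========  ====  =====================================================
AAC        20   amino acid composition (residue frequencies)
DPC       400   dipeptide composition (overlapping pair frequencies)
DDE       400   dipeptide deviation from expected mean, standardized
                against a codon-usage null model
PAAC     20+λ   pseudo amino acid composition (Chou): composition plus
                λ sequence-order correlation factors built from
                hydrophobicity, hydrophilicity and side-chain mass
APAAC    20+2λ  amphiphilic pseudo amino acid composition: composition
                plus per-scale correlation factors for hydrophobicity
                and hydrophilicity
PCP        11   per-sequence means of 11 physicochemical scales
========  ====  =====================================================

Feature order is alphabetical in the residue letters (A..Y; dipeptides in
nested alphabetical order AA, AC, .., YY) so column names are reproducible
across runs and installations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from peptidestack.features import FeatureMatrix
from peptidestack.peptide_io import AMINO_ACIDS, LabeledDataset, Peptide

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
_DP_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}

#: Number of standard-genetic-code codons per residue (61 sense codons).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}
TOTAL_CODONS = 61


def _read_scale_table(resource_name: str) -> pd.DataFrame:
    with resources.files("peptidestack.data").joinpath(resource_name).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="residue")
    return df.loc[list(AMINO_ACIDS)]


def _znorm(values: np.ndarray) -> np.ndarray:
    # population standard deviation over the 20 residues, the convention of
    # the pseudo-composition descriptor family
    return (values - values.mean()) / values.std()


@dataclass
class PseudoCompositionConfig:
    """Settings for PAAC/APAAC: correlation rank λ, weight w, and the raw
    (unnormalized) per-residue scales. λ=0 is permitted as the degenerate
    limit in which both encoders reduce to plain composition."""

    lambda_: int = 1
    weight: float = 0.05
    scales: pd.DataFrame | None = None  # columns: hydrophobicity, hydrophilicity, side_chain_mass

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.scales is None:
            self.scales = _read_scale_table("paac_scales.tsv")

    @property
    def normalized(self) -> np.ndarray:
        """(3, 20) array of z-scored H1, H2, M in alphabetical residue order."""
        return np.stack([
            _znorm(self.scales["hydrophobicity"].to_numpy(float)),
            _znorm(self.scales["hydrophilicity"].to_numpy(float)),
            _znorm(self.scales["side_chain_mass"].to_numpy(float)),
        ])


def load_property_table(path=None) -> pd.DataFrame:
    """Load a physicochemical property table (residue rows x scale columns).

    With no argument, returns the shipped default of 11 standard scales.
    """
    if path is None:
        return _read_scale_table("pcp_scales.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", index_col="residue")
    missing = set(AMINO_ACIDS) - set(df.index)
    if missing:
        raise ValueError(f"property table missing residues: {sorted(missing)}")
    return df.loc[list(AMINO_ACIDS)]


def _counts(seq: str) -> np.ndarray:
    out = np.zeros(20)
    for ch in seq:
        out[_AA_INDEX[ch]] += 1
    return out


def encode_aac(p: Peptide) -> np.ndarray:
    """Amino acid composition: residue frequency vector of length 20."""
    return _counts(p.sequence) / len(p)


def _dipeptide_counts(seq: str) -> np.ndarray:
    out = np.zeros(400)
    for i in range(len(seq) - 1):
        out[_DP_INDEX[seq[i : i + 2]]] += 1
    return out


def encode_dpc(p: Peptide) -> np.ndarray:
    """Dipeptide composition: overlapping-pair frequencies, length 400."""
    if len(p) < 2:
        raise ValueError(f"DPC needs length >= 2 (peptide {p.id!r} has {len(p)})")
    return _dipeptide_counts(p.sequence) / (len(p) - 1)


@lru_cache(maxsize=1)
def _dde_null() -> tuple[np.ndarray, np.ndarray]:
    """Theoretical mean TM_ab = (C_a/61)(C_b/61) for all 400 dipeptides."""
    ca = np.array([CODON_COUNTS[a] for a in AMINO_ACIDS]) / TOTAL_CODONS
    tm = np.outer(ca, ca).ravel()
    return tm, tm * (1.0 - tm)


def encode_dde(p: Peptide) -> np.ndarray:
    """Dipeptide deviation from expected mean, length 400.

    For each dipeptide ab: DC = observed frequency; TM = codon-usage
    expectation (C_a/61)(C_b/61); TV = TM(1-TM)/(L-1);
    DDE = (DC - TM) / sqrt(TV).
    """
    if len(p) < 2:
        raise ValueError(f"DDE needs length >= 2 (peptide {p.id!r} has {len(p)})")
    dc = _dipeptide_counts(p.sequence) / (len(p) - 1)
    tm, tm_var = _dde_null()
    tv = tm_var / (len(p) - 1)
    return (dc - tm) / np.sqrt(tv)


def encode_paac(p: Peptide, cfg: PseudoCompositionConfig | None = None) -> np.ndarray:
    """Pseudo amino acid composition, length 20+λ.

    θ_j averages the correlation function Θ(x, y) — the mean squared
    difference of the three normalized scales — over all residue pairs at
    sequence distance j. The composition and the weighted θ terms are
    jointly normalized so the full vector sums to 1.
    """
    cfg = cfg or PseudoCompositionConfig()
    lam, L = cfg.lambda_, len(p)
    if L <= lam:
        raise ValueError(f"PAAC with lambda={lam} needs length > {lam}")
    scales = cfg.normalized
    idx = np.array([_AA_INDEX[ch] for ch in p.sequence])
    vals = scales[:, idx]  # (3, L)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = vals[:, j:] - vals[:, :-j]  # (3, L-j)
        thetas[j - 1] = np.mean(diffs**2, axis=0).sum() / (L - j)
    freqs = _counts(p.sequence) / L
    denom = freqs.sum() + cfg.weight * thetas.sum()
    return np.concatenate([freqs, cfg.weight * thetas]) / denom


def encode_apaac(p: Peptide, cfg: PseudoCompositionConfig | None = None) -> np.ndarray:
    """Amphiphilic pseudo amino acid composition, length 20+2λ.

    τ_{2j-1} and τ_{2j} average the products H1(R_i)H1(R_{i+j}) and
    H2(R_i)H2(R_{i+j}) respectively. Because the normalized scales have
    zero mean, τ terms (and hence components) may be negative; the full
    vector still sums to 1.
    """
    cfg = cfg or PseudoCompositionConfig()
    lam, L = cfg.lambda_, len(p)
    if L <= lam:
        raise ValueError(f"APAAC with lambda={lam} needs length > {lam}")
    h1, h2 = cfg.normalized[0], cfg.normalized[1]
    idx = np.array([_AA_INDEX[ch] for ch in p.sequence])
    taus = np.empty(2 * lam)
    for j in range(1, lam + 1):
        taus[2 * j - 2] = np.mean(h1[idx[:-j]] * h1[idx[j:]])
        taus[2 * j - 1] = np.mean(h2[idx[:-j]] * h2[idx[j:]])
    freqs = _counts(p.sequence) / L
    denom = freqs.sum() + cfg.weight * taus.sum()
    return np.concatenate([freqs, cfg.weight * taus]) / denom


def encode_pcp(p: Peptide, props: pd.DataFrame | None = None) -> np.ndarray:
    """Physicochemical-property encoding: per-scale sequence means (11-D
    with the default table). Order-invariant by construction."""
    if props is None:
        props = load_property_table()
    idx = [_AA_INDEX[ch] for ch in p.sequence]
    return props.to_numpy(float)[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# dataset-level encoding

def _names_aac() -> list[str]:
    return [f"AAC_{a}" for a in AMINO_ACIDS]


def _encoder_table(paac_cfg: PseudoCompositionConfig, props: pd.DataFrame):
    lam = paac_cfg.lambda_
    return {
        "AAC": (encode_aac, _names_aac()),
        "DPC": (encode_dpc, [f"DPC_{d}" for d in DIPEPTIDES]),
        "DDE": (encode_dde, [f"DDE_{d}" for d in DIPEPTIDES]),
        "PAAC": (
            lambda p: encode_paac(p, paac_cfg),
            [f"PAAC_{a}" for a in AMINO_ACIDS] + [f"PAAC_theta{j}" for j in range(1, lam + 1)],
        ),
        "APAAC": (
            lambda p: encode_apaac(p, paac_cfg),
            [f"APAAC_{a}" for a in AMINO_ACIDS]
            + [f"APAAC_tau{k}" for k in range(1, 2 * lam + 1)],
        ),
        "PCP": (lambda p: encode_pcp(p, props), [f"PCP_{c}" for c in props.columns]),
    }


SEQ_ENCODERS = ("AAC", "DPC", "DDE", "PAAC", "APAAC", "PCP")


def encode_dataset(
    ds: LabeledDataset,
    encoder: str,
    paac_cfg: PseudoCompositionConfig | None = None,
    props: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Encode every peptide of a dataset with one sequence encoder."""
    if encoder not in SEQ_ENCODERS:
        raise KeyError(f"unknown sequence encoder {encoder!r}")
    paac_cfg = paac_cfg or PseudoCompositionConfig()
    if props is None:
        props = load_property_table()
    fn, names = _encoder_table(paac_cfg, props)[encoder]
    rows = np.vstack([fn(p) for p in ds.peptides]) if len(ds) else np.empty((0, len(names)))
    return FeatureMatrix(rows, names, encoder, ds.ids)
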