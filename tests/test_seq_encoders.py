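"""Unit and oracle tests for the six sequence descriptors.

The DDE, PAAC and APAAC oracles below re-derive each descriptor from its
published formulas with plain Python loops, independently of the vectorized
implementations they check.
"""

import math

import numpy as np
import pytest

from peptidestack.peptide_io import AMINO_ACIDS, LabeledDataset, Peptide
from peptidestack.seq_encoders import (
    CODON_COUNTS,
    DIPEPTIDES,
    TOTAL_CODONS,
    PseudoCompositionConfig,
    encode_aac,
    encode_apaac,
    encode_dataset,
    encode_dde,
    encode_dpc,
    encode_paac,
    encode_pcp,
    load_property_table,
)
from tests.conftest import random_peptide


# ---------------------------------------------------------------------------
# independent oracles

def oracle_dde(seq):
    L = len(seq)
    out = []
    for ab in DIPEPTIDES:
        dc = sum(seq[i : i + 2] == ab for i in range(L - 1)) / (L - 1)
        tm = (CODON_COUNTS[ab[0]] / TOTAL_CODONS) * (CODON_COUNTS[ab[1]] / TOTAL_CODONS)
        tv = tm * (1 - tm) / (L - 1)
        out.append((dc - tm) / math.sqrt(tv))
    return np.array(out)


def _oracle_norm_scales(cfg):
    scales = []
    for col in ("hydrophobicity", "hydrophilicity", "side_chain_mass"):
        raw = [float(cfg.scales.loc[a, col]) for a in AMINO_ACIDS]
        mu = sum(raw) / 20
        sd = math.sqrt(sum((x - mu) ** 2 for x in raw) / 20)
        scales.append({a: (x - mu) / sd for a, x in zip(AMINO_ACIDS, raw)})
    return scales


def oracle_paac(seq, cfg):
    h1, h2, m = _oracle_norm_scales(cfg)
    L = len(seq)

    def theta_fn(x, y):
        return (
            (h1[y] - h1[x]) ** 2 + (h2[y] - h2[x]) ** 2 + (m[y] - m[x]) ** 2
        ) / 3.0

    thetas = []
    for j in range(1, cfg.lambda_ + 1):
        thetas.append(
            sum(theta_fn(seq[i], seq[i + j]) for i in range(L - j)) / (L - j)
        )
    freqs = [seq.count(a) / L for a in AMINO_ACIDS]
    denom = sum(freqs) + cfg.weight * sum(thetas)
    return np.array([f / denom for f in freqs] + [cfg.weight * t / denom for t in thetas])


def oracle_apaac(seq, cfg):
    h1, h2, _ = _oracle_norm_scales(cfg)
    L = len(seq)
    taus = []
    for j in range(1, cfg.lambda_ + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + j]] for i in range(L - j)) / (L - j))
        taus.append(sum(h2[seq[i]] * h2[seq[i + j]] for i in range(L - j)) / (L - j))
    freqs = [seq.count(a) / L for a in AMINO_ACIDS]
    denom = sum(freqs) + cfg.weight * sum(taus)
    return np.array([f / denom for f in freqs] + [cfg.weight * t / denom for t in taus])


# ---------------------------------------------------------------------------

class TestAAC:
    def test_homopolymer(self):
        v = encode_aac(Peptide("x", "AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_composition(self):
        v = encode_aac(Peptide("x", "ACDE"))
        assert np.allclose(sorted(v)[-4:], 0.25) and np.isclose(v.sum(), 1.0)

    def test_dimension_and_sum(self, random_peptides):
        for p in random_peptides:
            v = encode_aac(p)
            assert v.shape == (20,)
            assert (v >= 0).all() and abs(v.sum() - 1.0) < 1e-12


class TestDPC:
    def test_homopolymer(self):
        v = encode_dpc(Peptide("x", "AAAA"))
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_overlapping_hand_count(self):
        v = encode_dpc(Peptide("x", "ACAC"))
        names = dict(zip(DIPEPTIDES, v))
        assert np.isclose(names["AC"], 2 / 3) and np.isclose(names["CA"], 1 / 3)

    def test_requires_length_two(self):
        with pytest.raises(ValueError):
            encode_dpc(Peptide("x", "A"))

    def test_dimension_and_sum(self, random_peptides):
        for p in random_peptides:
            v = encode_dpc(p)
            assert v.shape == (400,)
            assert (v >= 0).all() and abs(v.sum() - 1.0) < 1e-12


class TestDDE:
    def test_dipeptide_aa_closed_form(self):
        tm = (4 / 61) ** 2
        expected = (1 - tm) / math.sqrt(tm * (1 - tm))
        v = encode_dde(Peptide("x", "AA"))
        assert np.isclose(v[0], expected)

    def test_absent_dipeptides_strictly_negative(self):
        v = encode_dde(Peptide("x", "AAAA"))
        absent = [i for i, d in enumerate(DIPEPTIDES) if d != "AA"]
        assert (v[absent] < 0).all()

    def test_matches_bruteforce_oracle(self, random_peptides):
        for p in random_peptides:
            np.testing.assert_allclose(encode_dde(p), oracle_dde(p.sequence), atol=1e-10)


class TestPAAC:
    def test_homopolymer_reduces_to_composition(self):
        v = encode_paac(Peptide("x", "AAAA"))
        assert v.shape == (21,)
        assert np.isclose(v[0], 1.0) and np.isclose(v[20], 0.0)

    def test_matches_stepwise_oracle(self, random_peptides):
        cfg = PseudoCompositionConfig(lambda_=1, weight=0.05)
        for p in random_peptides:
            np.testing.assert_allclose(
                encode_paac(p, cfg), oracle_paac(p.sequence, cfg), atol=1e-10
            )

    def test_acac_example(self):
        cfg = PseudoCompositionConfig(lambda_=1, weight=0.05)
        np.testing.assert_allclose(
            encode_paac(Peptide("x", "ACAC"), cfg), oracle_paac("ACAC", cfg), atol=1e-12
        )

    def test_length_must_exceed_lambda(self):
        with pytest.raises(ValueError):
            encode_paac(Peptide("x", "AC"), PseudoCompositionConfig(lambda_=2))

    def test_lambda_zero_equals_aac(self, random_peptides):
        cfg = PseudoCompositionConfig(lambda_=0)
        for p in random_peptides[:10]:
            np.testing.assert_allclose(encode_paac(p, cfg), encode_aac(p), atol=1e-14)


class TestAPAAC:
    def test_dimension_and_unit_sum(self, random_peptides):
        for p in random_peptides:
            v = encode_apaac(p)
            assert v.shape == (22,)
            assert abs(v.sum() - 1.0) < 1e-10

    def test_homopolymer_taus_are_squared_scale_values(self):
        cfg = PseudoCompositionConfig()
        h = cfg.normalized
        a = 0  # index of residue A
        v = encode_apaac(Peptide("x", "AAAA"), cfg)
        denom = 1.0 + cfg.weight * (h[0, a] ** 2 + h[1, a] ** 2)
        assert np.isclose(v[20], cfg.weight * h[0, a] ** 2 / denom)
        assert np.isclose(v[21], cfg.weight * h[1, a] ** 2 / denom)

    def test_matches_stepwise_oracle(self, random_peptides):
        cfg = PseudoCompositionConfig(lambda_=1, weight=0.05)
        for p in random_peptides:
            np.testing.assert_allclose(
                encode_apaac(p, cfg), oracle_apaac(p.sequence, cfg), atol=1e-10
            )

    def test_lambda_zero_equals_aac(self, random_peptides):
        cfg = PseudoCompositionConfig(lambda_=0)
        for p in random_peptides[:10]:
            np.testing.assert_allclose(encode_apaac(p, cfg), encode_aac(p), atol=1e-14)


class TestPCP:
    def test_homopolymer_gives_scale_values(self):
        props = load_property_table()
        v = encode_pcp(Peptide("x", "GGGG"), props)
        np.testing.assert_allclose(v, props.loc["G"].to_numpy(float))

    def test_permutation_invariance(self):
        assert np.allclose(
            encode_pcp(Peptide("x", "ACDE")), encode_pcp(Peptide("y", "EDCA"))
        )

    def test_dimension(self, random_peptides):
        assert encode_pcp(random_peptides[0]).shape == (11,)


class TestDatasetEncoding:
    def test_rowwise_equals_individual(self, tiny_dataset):
        fm = encode_dataset(tiny_dataset, "DDE")
        for i, p in enumerate(tiny_dataset.peptides):
            np.testing.assert_array_equal(fm.values[i], encode_dde(p))

    def test_feature_names_are_ordered_and_match_dimension(self, tiny_dataset):
        fm = encode_dataset(tiny_dataset, "DPC")
        assert fm.feature_names[:2] == ["DPC_AA", "DPC_AC"]
        assert fm.shape == (len(tiny_dataset), 400)

    def test_csv_roundtrip(self, tiny_dataset, tmp_path):
        fm = encode_dataset(tiny_dataset, "AAC")
        path = tmp_path / "aac.csv"
        fm.to_csv(path)
        from peptidestack.features import FeatureMatrix

        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values)
        assert back.feature_names == fm.feature_names
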