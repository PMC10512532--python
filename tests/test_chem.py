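"""Peptide SMILES construction and fingerprint encodings."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from peptidestack.chem.fingerprints import (
    FINGERPRINT_DIMENSIONS,
    FingerprintSpec,
    encode_fingerprint,
    encode_fingerprint_dataset,
    fingerprint_feature_names,
)
from peptidestack.chem.smiles import (
    RESIDUE_FRAGMENTS,
    WATER_MASS,
    peptide_to_smiles,
)
from peptidestack.peptide_io import AMINO_ACIDS, LabeledDataset, Peptide
from tests.conftest import random_peptide


def independent_expected_mass(sequence):
    """Mass-balance oracle: free-residue weights summed directly with RDKit,
    minus one water per peptide bond."""
    total = 0.0
    for ch in sequence:
        total += Descriptors.MolWt(Chem.MolFromSmiles(RESIDUE_FRAGMENTS[ch] + "O"))
    return total - (len(sequence) - 1) * WATER_MASS


class TestPeptideToSmiles:
    def test_glycine_is_glycine(self):
        ps = peptide_to_smiles(Peptide("g", "G"))
        assert Chem.CanonSmiles(ps.smiles) == Chem.CanonSmiles("NCC(=O)O")

    def test_diglycine_structure_and_mass(self):
        ps = peptide_to_smiles(Peptide("gg", "GG"))
        assert Chem.CanonSmiles(ps.smiles) == Chem.CanonSmiles("NCC(=O)NCC(=O)O")
        assert ps.mol_weight == pytest.approx(2 * 75.07 - 18.02, abs=0.02)

    def test_deterministic_output(self):
        a = peptide_to_smiles(Peptide("x", "ACDEFG"))
        b = peptide_to_smiles(Peptide("x", "ACDEFG"))
        assert a.smiles == b.smiles

    def test_l_alpha_stereocenters(self):
        # all standard residues except glycine carry an alpha stereocenter;
        # cysteine is CIP-R (sulfur priority), the rest CIP-S
        for ch in "ASTWCP":
            mol = peptide_to_smiles(Peptide(ch, ch)).mol()
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
            codes = [a.GetPropsAsDict().get("_CIPCode") for a in mol.GetAtoms()
                     if a.HasProp("_CIPCode")]
            expected = "R" if ch == "C" else "S"
            assert codes[0] == expected, ch

    def test_stereo_strip_flag(self):
        ps = peptide_to_smiles(Peptide("x", "ACD"), stereo=False)
        assert "@" not in ps.smiles

    def test_mass_balance_invariant(self, rng):
        for i in range(100):
            p = random_peptide(rng, min_len=1, max_len=30, pid=f"m{i}")
            ps = peptide_to_smiles(p)
            assert ps.mol_weight == pytest.approx(
                independent_expected_mass(p.sequence), abs=0.01
            )


class TestFingerprints:
    @pytest.mark.parametrize("name,dim", sorted(FINGERPRINT_DIMENSIONS.items()))
    def test_dimension_and_binary_range(self, name, dim):
        ps = peptide_to_smiles(Peptide("x", "ACDEFGHIKLMNPQRSTVWY"))
        fp = encode_fingerprint(ps, name)
        assert fp.shape == (dim,)
        assert set(np.unique(fp)) <= {0, 1}
        assert len(fingerprint_feature_names(name)) == dim

    @pytest.mark.parametrize("name", sorted(FINGERPRINT_DIMENSIONS))
    def test_invariant_to_smiles_writing_order(self, name):
        ps = peptide_to_smiles(Peptide("x", "CWYR"))
        rewritten = Chem.MolToSmiles(Chem.MolFromSmiles(ps.smiles))
        assert rewritten != ps.smiles  # genuinely different text
        a = encode_fingerprint(ps.smiles, name)
        b = encode_fingerprint(rewritten, name)
        np.testing.assert_array_equal(a, b)

    def test_identical_sequences_identical_bits(self):
        a = encode_fingerprint(peptide_to_smiles(Peptide("x", "ACW")), "MACCS")
        b = encode_fingerprint(peptide_to_smiles(Peptide("y", "ACW")), "MACCS")
        np.testing.assert_array_equal(a, b)

    def test_fp4_thiol_distinguishes_cysteine_from_glycine(self):
        gly = encode_fingerprint(peptide_to_smiles(Peptide("g", "G")), "FP4")
        cys = encode_fingerprint(peptide_to_smiles(Peptide("c", "C")), "FP4")
        # glycine's functional groups (amine, acid) are a subset of
        # cysteine's, which adds thiol-related bits
        assert ((gly == 1) & (cys == 0)).sum() == 0
        assert ((cys == 1) & (gly == 0)).sum() >= 1

    def test_unknown_spec_rejected(self):
        with pytest.raises(KeyError):
            FingerprintSpec("ECFP4")

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(ValueError):
            encode_fingerprint("not-a-smiles", "MACCS")

    def test_dataset_encoding_shapes_and_names(self, tiny_dataset):
        fm = encode_fingerprint_dataset(tiny_dataset, "Estate")
        assert fm.shape == (len(tiny_dataset), 79)
        assert fm.sample_ids == tiny_dataset.ids
        fm4 = encode_fingerprint_dataset(tiny_dataset, "FP4")
        assert fm4.shape == (len(tiny_dataset), 307)
        # batch path agrees with the single-molecule path
        single = encode_fingerprint(
            peptide_to_smiles(tiny_dataset.peptides[0]), "FP4"
        )
        np.testing.assert_array_equal(fm4.values[0], single)
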