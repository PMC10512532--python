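"""Deterministic peptide-sequence to SMILES conversion.

Each residue contributes a backbone fragment ``N[C@@H](side chain)C(=O)``;
fragments are concatenated so each carbonyl bonds directly to the next
backbone nitrogen (amide bond), and a terminal ``O`` completes the free
C-terminal carboxylic acid. The N-terminus stays a free amine. Residues are
emitted as L-amino acids with explicit alpha-carbon stereocenters (2S
everywhere; threonine 3R and isoleucine 3S on the side chain); a flag strips
all stereo annotations for backends that ignore them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem
from rdkit.Chem import Descriptors

from peptidestack.peptide_io import LabeledDataset, Peptide

#: Water lost per amide bond formed (average molecular weight, Da).
WATER_MASS = 18.01528

# Ring-closure digits are local to each fragment, so repeats are safe.
RESIDUE_FRAGMENTS = {
    "A": "N[C@@H](C)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "G": "NCC(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@H](O)C)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
}


@dataclass(frozen=True)
class PeptideSmiles:
    """A peptide's chemical structure in SMILES notation."""

    id: str
    smiles: str
    heavy_atoms: int
    mol_weight: float

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # cannot happen for template-built SMILES
            raise ValueError(f"unparseable SMILES for {self.id!r}")
        return mol


def _strip_stereo(smiles: str) -> str:
    return smiles.replace("[C@@H]", "C").replace("[C@H]", "C")


def peptide_to_smiles(p: Peptide, stereo: bool = True) -> PeptideSmiles:
    """Build the linear-peptide SMILES for a sequence.

    The output string is a deterministic function of the sequence (and the
    ``stereo`` flag), so identical sequences always yield byte-identical
    SMILES.
    """
    smiles = "".join(RESIDUE_FRAGMENTS[ch] for ch in p.sequence) + "O"
    if not stereo:
        smiles = _strip_stereo(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"internal error: template SMILES unparseable for {p.id!r}")
    return PeptideSmiles(p.id, smiles, mol.GetNumHeavyAtoms(), Descriptors.MolWt(mol))


@lru_cache(maxsize=32)
def residue_mass(residue: str) -> float:
    """Average molecular weight of the free amino acid (fragment + OH)."""
    mol = Chem.MolFromSmiles(RESIDUE_FRAGMENTS[residue] + "O")
    return Descriptors.MolWt(mol)


def expected_peptide_mass(sequence: str) -> float:
    """Mass-balance prediction: sum of free-residue masses minus one water
    per amide bond formed."""
    return sum(residue_mass(ch) for ch in sequence) - (len(sequence) - 1) * WATER_MASS


def dataset_to_smiles(ds: LabeledDataset, stereo: bool = True) -> list[PeptideSmiles]:
    return [peptide_to_smiles(p, stereo=stereo) for p in ds.peptides]


def write_smiles_tsv(entries: list[PeptideSmiles], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsmiles\n")
        for e in entries:
            fh.write(f"{e.id}\t{e.smiles}\n")
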