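"""Regenerate the synthetic PubChem-style 881-key definition table.

The genuine PubChem/CACTVS substructure key definitions are not
redistributable here, so the package ships its own keyed dictionary with
the same dimension (881), the same bit semantics (bit k set iff keyed
feature k present), and the same broad section structure: hierarchical
element counts, ring counts by size/character, and SMARTS substructure
patterns. The table is versioned data; this script exists so the
enumeration scheme is reproducible and auditable.

Usage: python scripts/generate_pubchem_style_keys.py
Writes src/peptidestack/chem/data/pubchem_style_keys_synthetic.tsv
"""

from itertools import combinations_with_replacement, product
from pathlib import Path

from rdkit import Chem

OUT = Path(__file__).resolve().parents[1] / "src/peptidestack/chem/data/pubchem_style_keys_synthetic.tsv"

TOTAL_KEYS = 881

ELEMENTS = [
    "H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se",
    "Li", "Na", "K", "Mg", "Ca", "Fe", "Zn", "Cu", "Mn", "Al",
]
COUNT_THRESHOLDS = [1, 2, 4, 8, 16]

RING_SIZES = range(3, 11)
RING_CATEGORIES = ["any", "aromatic", "nonaromatic", "hetero", "carbon_only", "nitrogen", "oxygen"]
RING_THRESHOLDS = [1, 2]

ATOM = {"C": "[#6]", "N": "[#7]", "O": "[#8]", "S": "[#16]", "P": "[#15]"}
ORG = ["C", "N", "O", "S"]

FUNCTIONAL_GROUPS = [
    ("amide", "[CX3](=O)[NX3]"),
    ("primary_amide", "[CX3](=O)[NX3H2]"),
    ("secondary_amide", "[CX3](=O)[NX3H1]"),
    ("tertiary_amide", "[CX3](=O)[NX3H0]"),
    ("peptide_bond", "[CX3](=O)[NX3H1][CX4]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("carboxylate", "[CX3](=O)[O-]"),
    ("ester", "[CX3](=O)[OX2][#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("aldehyde", "[CX3H1](=O)"),
    ("primary_amine", "[NX3H2][CX4]"),
    ("secondary_amine", "[NX3H1]([CX4])[CX4]"),
    ("tertiary_amine", "[NX3]([CX4])([CX4])[CX4]"),
    ("quaternary_ammonium", "[NX4+]"),
    ("aromatic_amine", "[NX3][c]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("amidine", "[NX3][CX3]=[NX2]"),
    ("urea", "[NX3][CX3](=O)[NX3]"),
    ("carbamate", "[NX3][CX3](=O)[OX2]"),
    ("hydroxyl", "[OX2H]"),
    ("phenol", "[OX2H][c]"),
    ("hydroxymethyl", "[OX2H][CH2]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[#6][SX2][#6]"),
    ("disulfide", "[SX2][SX2]"),
    ("methylthioether", "[CH3][SX2][CH2]"),
    ("sulfoxide", "[SX3]=[OX1]"),
    ("sulfone", "[SX4](=[OX1])=[OX1]"),
    ("alpha_amino_acid", "[NX3][CX4H1][CX3](=O)"),
    ("n_terminal_amine", "[NX3H2][CX4H1][CX3](=O)"),
    ("c_terminal_acid", "[CX4][CX3](=O)[OX2H1]"),
    ("glycine_unit", "[NX3][CH2][CX3](=O)"),
    ("benzene_ring", "c1ccccc1"),
    ("imidazole_ring", "c1cnc[nH]1"),
    ("indole_ring", "c1ccc2c(c1)cc[nH]2"),
    ("pyrrole_nh", "[nH]"),
    ("aromatic_n_basic", "[nX2]"),
    ("aromatic_o", "[o]"),
    ("aromatic_s", "[s]"),
    ("methyl", "[CH3]"),
    ("isopropyl", "[CH]([CH3])[CH3]"),
    ("gem_dimethyl", "[CX4]([CH3])[CH3]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("nitro", "[N+](=O)[O-]"),
    ("nitrile", "[CX2]#[NX1]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("imine", "[CX3]=[NX2]"),
    ("phosphoryl", "[PX4]=[OX1]"),
]


def smarts_keys():
    keys = []

    def add(name, smarts):
        if Chem.MolFromSmarts(smarts) is None:
            raise ValueError(f"bad SMARTS for {name}: {smarts}")
        keys.append((name, smarts))

    # bonded element pairs, all bond orders
    for (a, b) in combinations_with_replacement(ATOM, 2):
        for bond, bname in [("-", "single"), ("=", "double"), ("#", "triple")]:
            add(f"pair_{a}{bond}{b}", f"{ATOM[a]}{bond}{ATOM[b]}")
    # aromatic pairs
    arom = {"C": "c", "N": "n", "O": "o", "S": "s"}
    for (a, b) in combinations_with_replacement(ORG, 2):
        add(f"aropair_{a}:{b}", f"[{arom[a]}]:[{arom[b]}]")
    # bonded triples over {C,N,O,S} with single/double/triple bonds,
    # deduplicated under reversal
    seen = set()
    for e1, b1, e2, b2, e3 in product(ORG, "-=#", ORG, "-=#", ORG):
        fwd = (e1, b1, e2, b2, e3)
        if fwd in seen or (e3, b2, e2, b1, e1) in seen:
            continue
        seen.add(fwd)
        add(f"triple_{e1}{b1}{e2}{b2}{e3}",
            f"{ATOM[e1]}{b1}{ATOM[e2]}{b2}{ATOM[e3]}")
    # first-sphere environments: centre with 3 neighbours (any bonds)
    for centre in ("C", "N"):
        for nbrs in combinations_with_replacement(ORG, 3):
            nb = "".join(f"(~{ATOM[x]})" for x in nbrs)
            add(f"env_{centre}_{''.join(nbrs)}", f"{ATOM[centre]}{nb}")
    # explicit hydrogen-count atoms
    for s in ["CH3", "CH2", "CH1", "CH0", "NH2", "NH1", "NH0", "OH1", "OH0",
              "SH1", "SH0", "cH1", "cH0", "nH1", "nH0"]:
        add(f"hcount_{s}", f"[{s}]")
    # charged atoms
    for s in ["C+", "C-", "N+", "N-", "O+", "O-", "S+", "S-"]:
        add(f"charge_{s}", f"[{s}]")
    # named functional groups
    for name, sm in FUNCTIONAL_GROUPS:
        add(f"fg_{name}", sm)
    # saturated carbon chains of increasing length
    for n in range(3, 9):
        add(f"chain_C{n}", "-".join(["[#6]"] * n))
    # heteroatom pairs at topological distances 2-5
    for (a, b) in combinations_with_replacement(["N", "O", "S"], 2):
        for d in range(2, 6):
            path = "~*" * (d - 1)
            add(f"path_{a}{d}{b}", f"{ATOM[a]}{path}~{ATOM[b]}")
    # ring attachment points
    for e in ORG:
        for bond in "-=":
            add(f"ringattach_{e}{bond}", f"[R]{bond}{ATOM[e]}")
    # single-bonded element quadruples (reversal-deduplicated) pad the
    # dictionary to its fixed size
    seen = set()
    for quad in product(ORG, repeat=4):
        if quad in seen or quad[::-1] in seen:
            continue
        seen.add(quad)
        add(f"quad_{''.join(quad)}", "-".join(ATOM[x] for x in quad))
    return keys


def main():
    rows = []
    for el in ELEMENTS:
        for t in COUNT_THRESHOLDS:
            rows.append((f"count_{el}>={t}", "element_count", el, str(t), ""))
    for size in RING_SIZES:
        for cat in RING_CATEGORIES:
            for t in RING_THRESHOLDS:
                rows.append((f"ring{size}_{cat}>={t}", "ring", f"{size}:{cat}", str(t), ""))
    budget = TOTAL_KEYS - len(rows)
    sk = smarts_keys()
    if len(sk) < budget:
        raise SystemExit(f"only {len(sk)} SMARTS keys for a budget of {budget}")
    for name, sm in sk[:budget]:
        rows.append((name, "smarts", "", "", sm))
    assert len(rows) == TOTAL_KEYS, len(rows)
    with open(OUT, "w") as fh:
        fh.write(
            "# Synthetic PubChem-style substructure key dictionary (881 keys).\n"
            "# These definitions are original to this package: they mirror the\n"
            "# section structure of the public PubChem fingerprint (element\n"
            "# counts, ring counts, substructure patterns) but are NOT the\n"
            "# CACTVS definitions. Regenerate with\n"
            "# scripts/generate_pubchem_style_keys.py.\n"
            "index\tname\tkind\tparam\tthreshold\tsmarts\n"
        )
        for i, (name, kind, param, thr, sm) in enumerate(rows):
            fh.write(f"{i}\t{name}\t{kind}\t{param}\t{thr}\t{sm}\n")
    print(f"wrote {len(rows)} keys to {OUT}")


if __name__ == "__main__":
    main()
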