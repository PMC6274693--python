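"""Molecular-graph descriptors: triple-bond count, second-order complementary
information content, and the maximum equalization partial charge on carbon.

The three descriptors feed the mixture toxicity models:

NTB
    Number of triple bonds in the (kekulized) molecular graph — nitrile and
    alkyne groups.

ACIC2
    Complementary information content of order 2, ``log2(n) − IC_2`` bits,
    where ``IC_2`` is the Shannon entropy of the distribution of atoms
    (hydrogens included) over order-2 topological equivalence classes.
    It grows with molecular size and symmetry and shrinks with structural
    diversity.

QMaxC
    The maximum partial charge over carbon atoms under a one-shot Sanderson
    electronegativity-equalization (Zefirov-type) scheme: the molecular
    electronegativity is the geometric mean of the atomic values and each
    atom receives ``q_i = (S_mol − S_i) / (2.08·sqrt(S_i))``, followed by a
    uniform correction so the charges sum to the net molecular charge.

Hydrogens are always made explicit: the information-content partitions and
the charge scheme both operate on the hydrogen-complete graph. Aromatic
bonds enter neighborhood signatures as bond order 1.5 so that equivalence
classes do not depend on an arbitrary Kekulé structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import DescriptorError, ParseError

DESCRIPTOR_NAMES = ("ntb", "acic2", "qmaxc")

# Denominator constant of the Zefirov/Sanderson one-shot equalization charge.
_CHARGE_SCALE = 2.08


@dataclass(frozen=True)
class DescriptorVector:
    """The (NTB, ACIC2, QMaxC) triple for a compound or a mixture."""

    ntb: float
    acic2: float
    qmaxc: float

    def as_array(self) -> np.ndarray:
        return np.array([self.ntb, self.acic2, self.qmaxc], dtype=float)


def load_electronegativity_table(path: str | Path | None = None) -> dict[str, float]:
    """Sanderson electronegativities per element symbol (bundled JSON config)."""
    if path is None:
        text = resources.files("mixtox.data").joinpath(
            "sanderson_electronegativity.json"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


_DEFAULT_EN_TABLE = load_electronegativity_table()


def parse_smiles(text: str) -> Chem.Mol:
    """Parse SMILES into an RDKit molecule with explicit hydrogens.

    Raises :class:`ParseError` on syntax/valence failure or a disconnected
    graph (counter-ions and multi-fragment inputs are not meaningful here).
    """
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise ParseError(f"invalid SMILES: {text!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ParseError(f"SMILES is not a connected graph: {text!r}")
    return Chem.AddHs(mol)


def _as_mol(molecule: Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, str):
        return parse_smiles(molecule)
    if molecule.GetNumAtoms() != Chem.AddHs(molecule).GetNumAtoms():
        return Chem.AddHs(molecule)
    return molecule


def count_triple_bonds(molecule: Chem.Mol | str) -> int:
    """NTB: number of order-3 bonds after kekulization."""
    mol = Chem.Mol(_as_mol(molecule))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE)


def atom_equivalence_classes(
    molecule: Chem.Mol | str, order: int
) -> list[frozenset[int]]:
    """Partition all atoms (hydrogens included) by iteratively refined
    neighborhood signatures.

    Order 0 groups atoms by element; order k refines order k−1 by the
    multiset of (bond order, neighbor class) pairs. Signatures are sorted
    tuples, so the partition does not depend on atom numbering, and each
    order refines the previous one.
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    mol = _as_mol(molecule)
    labels: list = [atom.GetSymbol() for atom in mol.GetAtoms()]
    for _ in range(order):
        labels = [
            (
                labels[atom.GetIdx()],
                tuple(sorted(
                    (bond.GetBondTypeAsDouble(),
                     labels[bond.GetOtherAtom(atom).GetIdx()])
                    for bond in atom.GetBonds()
                )),
            )
            for atom in mol.GetAtoms()
        ]
    groups: dict = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return [frozenset(groups[lab]) for lab in sorted(groups, key=repr)]


def information_content(molecule: Chem.Mol | str, order: int) -> float:
    """IC_k in bits: Shannon entropy of the equivalence-class size distribution."""
    classes = atom_equivalence_classes(molecule, order)
    n = sum(len(c) for c in classes)
    return -sum(
        (len(c) / n) * math.log2(len(c) / n) for c in classes if len(c) > 0
    )


def acic2(molecule: Chem.Mol | str) -> float:
    """ACIC2 = log2(n) − IC_2 over the hydrogen-complete graph (bits)."""
    mol = _as_mol(molecule)
    n = mol.GetNumAtoms()
    return math.log2(n) - information_content(mol, 2)


def sanderson_equalization_charges(
    molecule: Chem.Mol | str,
    electronegativity_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom equalization charges (elementary-charge units).

    Geometric-mean molecular electronegativity, one-shot transfer
    ``(S_mol − S_i)/(2.08·sqrt(S_i))``, then a uniform shift so the total
    equals the net formal charge (the raw scheme conserves charge only in
    symmetric special cases).
    """
    mol = _as_mol(molecule)
    table = _DEFAULT_EN_TABLE if electronegativity_table is None else electronegativity_table
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    missing = sorted({s for s in symbols if s not in table})
    if missing:
        raise DescriptorError(
            f"no Sanderson electronegativity configured for element(s): {missing}"
        )
    s = np.array([table[sym] for sym in symbols], dtype=float)
    s_mol = float(np.exp(np.mean(np.log(s))))
    q = (s_mol - s) / (_CHARGE_SCALE * np.sqrt(s))
    net = float(sum(atom.GetFormalCharge() for atom in mol.GetAtoms()))
    return q - (q.sum() - net) / len(q)


def qmaxc(
    molecule: Chem.Mol | str,
    electronegativity_table: dict[str, float] | None = None,
) -> float:
    """Maximum equalization charge over carbon atoms."""
    mol = _as_mol(molecule)
    carbons = [atom.GetIdx() for atom in mol.GetAtoms() if atom.GetSymbol() == "C"]
    if not carbons:
        raise DescriptorError("QMaxC is undefined: molecule has no carbon atom")
    charges = sanderson_equalization_charges(mol, electronegativity_table)
    return float(charges[carbons].max())


def compute_descriptors(
    smiles: str, electronegativity_table: dict[str, float] | None = None
) -> DescriptorVector:
    """All three descriptors for one SMILES string."""
    mol = parse_smiles(smiles)
    return DescriptorVector(
        ntb=float(count_triple_bonds(mol)),
        acic2=acic2(mol),
        qmaxc=qmaxc(mol, electronegativity_table),
    )


def compute_descriptor_table(
    compounds: pd.DataFrame,
    electronegativity_table: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Descriptor rows (id, ntb, acic2, qmaxc) for a compound table."""
    rows = []
    for rec in compounds.itertuples():
        d = compute_descriptors(rec.smiles, electronegativity_table)
        rows.append({"id": rec.id, "ntb": d.ntb, "acic2": d.acic2, "qmaxc": d.qmaxc})
    return pd.DataFrame(rows)
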