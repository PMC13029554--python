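"""SMILES to featurized 2D heavy-atom graphs.

A molecule is represented as ``G = (V, E)``: an atom feature matrix
``V`` of shape ``(N, d_n)`` and a dense symmetric bond feature tensor
``E`` of shape ``(N, N, d_e)`` that is zero wherever no bond exists.
Hydrogens are implicit; every node is a heavy atom.

Atom features (in fixed block order):

1.  atom type — one-hot over a configurable vocabulary, with a reserved
    trailing "other" slot for elements outside it;
2.  topological position — scaffold atom vs. side-chain atom, where the
    scaffold is the Murcko scaffold (ring systems plus linkers); acyclic
    molecules have an empty scaffold and mark every atom side-chain;
3.  scaffold type — whether the scaffold atom itself is aromatic or
    aliphatic (both bits zero off-scaffold);
4.  aromaticity;
5.  ring membership;
6.  pharmacophoric flags — H-bond donor, H-bond acceptor, aromatic ring,
    hydrophobic site.

Pharmacophore definitions are Lipinski-style SMARTS patterns:

* donor      ``[#7,#8;!H0]``      — N or O bearing at least one H
* acceptor   ``[#7,#8]``          — any N or O
* hydrophobic ``[#6;!$([#6]~[!#6;!#1])]`` — carbon with no heteroatom
  neighbour

Bond features: bond-type one-hot over {single, double, triple,
aromatic}, plus aromatic, conjugated (RDKit conjugation perception) and
in-ring flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

__all__ = [
    "FeatureSchema",
    "MolGraph",
    "AtomDescriptor",
    "BondDescriptor",
    "SmilesParseError",
    "smiles_to_graph",
    "encode_atom_features",
    "encode_bond_features",
]

DONOR_SMARTS = "[#7,#8;!H0]"
ACCEPTOR_SMARTS = "[#7,#8]"
HYDROPHOBIC_SMARTS = "[#6;!$([#6]~[!#6;!#1])]"

_DONOR = Chem.MolFromSmarts(DONOR_SMARTS)
_ACCEPTOR = Chem.MolFromSmarts(ACCEPTOR_SMARTS)
_HYDROPHOBIC = Chem.MolFromSmarts(HYDROPHOBIC_SMARTS)

DEFAULT_ATOM_TYPES = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
BOND_TYPES = ["single", "double", "triple", "aromatic"]

_RDKIT_BOND_TYPE = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a heavy-atom graph."""

    def __init__(self, smiles: str, reason: str = "RDKit failed to parse"):
        self.smiles = smiles
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


@dataclass(frozen=True)
class FeatureSchema:
    """Defines the encoded feature layout; fixes d_n and d_e for a run."""

    atom_types: tuple[str, ...] = tuple(DEFAULT_ATOM_TYPES)
    bond_types: tuple[str, ...] = tuple(BOND_TYPES)

    @property
    def d_n(self) -> int:
        # type one-hot (+other) | scaffold/side-chain | scaffold arom/aliph
        # | aromatic | ring | donor, acceptor, aromatic-ring, hydrophobic
        return len(self.atom_types) + 1 + 2 + 2 + 1 + 1 + 4

    @property
    def d_e(self) -> int:
        return len(self.bond_types) + 3  # aromatic, conjugated, in-ring

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"atom_types": list(self.atom_types), "bond_types": list(self.bond_types)},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(atom_types=tuple(raw["atom_types"]), bond_types=tuple(raw["bond_types"]))

    def to_dict(self) -> dict:
        return {"atom_types": list(self.atom_types), "bond_types": list(self.bond_types)}

    @classmethod
    def from_dict(cls, raw: dict) -> "FeatureSchema":
        return cls(atom_types=tuple(raw["atom_types"]), bond_types=tuple(raw["bond_types"]))


@dataclass(frozen=True)
class AtomDescriptor:
    element: str
    on_scaffold: bool
    aromatic: bool
    in_ring: bool
    donor: bool
    acceptor: bool
    hydrophobic: bool


@dataclass(frozen=True)
class BondDescriptor:
    bond_type: str
    aromatic: bool
    conjugated: bool
    in_ring: bool


@dataclass
class MolGraph:
    """One molecule as a featurized heavy-atom graph."""

    atom_features: np.ndarray  # (N, d_n)
    bond_features: np.ndarray  # (N, N, d_e), symmetric, zero off-bond
    adjacency: np.ndarray      # (N, N) binary symmetric, zero diagonal
    num_atoms: int
    mol_id: str = ""
    canonical_smiles: str = ""
    bonds: list = field(default_factory=list)  # (i, j) with i < j

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)


def encode_atom_features(desc: AtomDescriptor, schema: FeatureSchema) -> np.ndarray:
    """Concatenated one-hot/binary blocks; unknown elements map to 'other'."""
    v = np.zeros(schema.d_n)
    types = schema.atom_types
    try:
        v[types.index(desc.element)] = 1.0
    except ValueError:
        v[len(types)] = 1.0  # reserved "other" slot
    off = len(types) + 1
    v[off + (0 if desc.on_scaffold else 1)] = 1.0  # scaffold vs side chain
    off += 2
    if desc.on_scaffold:
        v[off + (0 if desc.aromatic else 1)] = 1.0  # scaffold type
    off += 2
    v[off] = float(desc.aromatic)
    v[off + 1] = float(desc.in_ring)
    off += 2
    v[off] = float(desc.donor)
    v[off + 1] = float(desc.acceptor)
    v[off + 2] = float(desc.aromatic)  # pharmacophoric aromatic-ring flag
    v[off + 3] = float(desc.hydrophobic)
    return v


def encode_bond_features(desc: BondDescriptor, schema: FeatureSchema) -> np.ndarray:
    v = np.zeros(schema.d_e)
    types = schema.bond_types
    try:
        v[types.index(desc.bond_type)] = 1.0
    except ValueError:
        pass  # unknown bond order: type block stays zero
    off = len(types)
    v[off] = float(desc.aromatic)
    v[off + 1] = float(desc.conjugated)
    v[off + 2] = float(desc.in_ring)
    return v


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def _scaffold_atom_indices(mol: Chem.Mol) -> set[int]:
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return set()
    match = mol.GetSubstructMatch(scaffold)
    if match:
        return set(match)
    # rare perception mismatch: fall back to ring atoms
    return {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}


def smiles_to_graph(smiles: str, schema: FeatureSchema | None = None,
                    mol_id: str = "") -> MolGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Multi-fragment inputs (salts) keep only the largest fragment.
    Raises :class:`SmilesParseError` for unparsable or atom-free input.
    """
    if schema is None:
        schema = FeatureSchema()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if mol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(smiles, "no heavy atoms")
    mol = _largest_fragment(mol)
    n = mol.GetNumAtoms()

    scaffold_atoms = _scaffold_atom_indices(mol)
    donors = {m[0] for m in mol.GetSubstructMatches(_DONOR)}
    acceptors = {m[0] for m in mol.GetSubstructMatches(_ACCEPTOR)}
    hydrophobes = {m[0] for m in mol.GetSubstructMatches(_HYDROPHOBIC)}

    V = np.zeros((n, schema.d_n))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        desc = AtomDescriptor(
            element=atom.GetSymbol(),
            on_scaffold=i in scaffold_atoms,
            aromatic=atom.GetIsAromatic(),
            in_ring=atom.IsInRing(),
            donor=i in donors,
            acceptor=i in acceptors,
            hydrophobic=i in hydrophobes,
        )
        V[i] = encode_atom_features(desc, schema)

    E = np.zeros((n, n, schema.d_e))
    A = np.zeros((n, n), dtype=np.int8)
    bonds: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        desc = BondDescriptor(
            bond_type=_RDKIT_BOND_TYPE.get(bond.GetBondType(), "other"),
            aromatic=bond.GetIsAromatic(),
            conjugated=bond.GetIsConjugated(),
            in_ring=bond.IsInRing(),
        )
        e = encode_bond_features(desc, schema)
        E[i, j] = e
        E[j, i] = e
        A[i, j] = A[j, i] = 1
        bonds.append((min(i, j), max(i, j)))

    return MolGraph(
        atom_features=V,
        bond_features=E,
        adjacency=A,
        num_atoms=n,
        mol_id=mol_id,
        canonical_smiles=Chem.MolToSmiles(mol),
        bonds=sorted(bonds),
    )
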