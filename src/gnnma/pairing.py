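"""Target-wise splitting, leakage-free pair construction and batching.

Screening libraries are organized per target: a set of known actives and
a (usually much larger) set of decoys/inactives.  Molecules are split
8:1:1 into train/validation/test *at the molecule level*, independently
for actives and decoys so every subset contains both classes when
possible.  Pairs never cross subset boundaries: positives pair two
distinct same-subset actives, negatives pair a same-subset active with a
same-subset decoy.  Mini-batches contain pairs from a single target.

Split rule: per class, the validation and test subsets each receive
``floor(n/10)`` molecules and the remainder stays in train.  Two guards
apply to small classes: a class with at least 5 molecules places at
least 2 in test (a lone test active has no same-subset query once
self-pairs are excluded, which would leave within-test ranking
undefined), and a class with at least 10 places at least 2 in
validation (so validation-based model selection stays operative).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molgraph import MolGraph

__all__ = [
    "TargetLibrary",
    "PairSample",
    "GraphBatch",
    "PairBatch",
    "split_target",
    "split_library",
    "build_pairs",
    "make_batches",
    "pack_graphs",
    "manifest_frame",
]

SUBSETS = ("train", "val", "test")


@dataclass
class TargetLibrary:
    target_id: str
    actives: list[str]
    decoys: list[str]
    split_assignment: dict[str, str] = field(default_factory=dict)
    usable: bool = True

    def subset_ids(self, subset: str, label: int | None = None) -> list[str]:
        pools = {1: self.actives, 0: self.decoys}
        ids = self.actives + self.decoys if label is None else pools[label]
        return [m for m in ids if self.split_assignment.get(m) == subset]


@dataclass(frozen=True)
class PairSample:
    query_id: str
    candidate_id: str
    label: int
    target_id: str
    subset: str


def _target_rng(seed: int, target_id: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32((target_id + salt).encode())])


def _class_counts(n: int) -> tuple[int, int, int]:
    n_val = n // 10
    n_test = n // 10
    if n >= 5 and n_test < 2:
        n_test = 2
    if n >= 10 and n_val < 2:
        n_val = 2
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_target(library: TargetLibrary, seed: int) -> TargetLibrary:
    """Assign each molecule of one target to train/val/test.

    Deterministic given ``(target_id, seed)`` only — independent of the
    order molecules are listed in.  Actives and decoys are split
    independently.  Targets with fewer than 3 actives are flagged
    unusable for pair evaluation (with a warning) but still split.
    """
    n_mols = len(library.actives) + len(library.decoys)
    if n_mols < 10:
        raise ValueError(
            f"target {library.target_id!r} has {n_mols} molecules; need >= 10 to split"
        )
    if len(library.actives) < 3:
        warnings.warn(
            f"target {library.target_id!r} has <3 actives; unusable for pair evaluation"
        )
        library.usable = False

    rng = _target_rng(seed, library.target_id)
    assignment: dict[str, str] = {}
    for ids in (library.actives, library.decoys):
        ordered = sorted(ids)
        rng.shuffle(ordered)
        n_train, n_val, n_test = _class_counts(len(ordered))
        for m in ordered[:n_train]:
            assignment[m] = "train"
        for m in ordered[n_train:n_train + n_val]:
            assignment[m] = "val"
        for m in ordered[n_train + n_val:]:
            assignment[m] = "test"
    library.split_assignment = assignment
    return library


def split_library(frame: pd.DataFrame, seed: int) -> dict[str, TargetLibrary]:
    """Split every target of a library frame (mol_id, smiles, target, label)."""
    libraries: dict[str, TargetLibrary] = {}
    for target_id, group in frame.groupby("target", sort=True):
        lib = TargetLibrary(
            target_id=str(target_id),
            actives=group.loc[group["label"] == 1, "mol_id"].tolist(),
            decoys=group.loc[group["label"] == 0, "mol_id"].tolist(),
        )
        libraries[str(target_id)] = split_target(lib, seed)
    return libraries


def manifest_frame(libraries: dict[str, TargetLibrary]) -> pd.DataFrame:
    """Split manifest (mol_id, target, subset, label) shared by all models."""
    rows = []
    for lib in libraries.values():
        for mol_id in lib.actives:
            rows.append((mol_id, lib.target_id, lib.split_assignment[mol_id], 1))
        for mol_id in lib.decoys:
            rows.append((mol_id, lib.target_id, lib.split_assignment[mol_id], 0))
    return pd.DataFrame(rows, columns=["mol_id", "target", "subset", "label"])


def build_pairs(library: TargetLibrary, subset: str, negative_ratio: float = 3.0,
                seed: int = 0) -> list[PairSample]:
    """Construct leakage-free pairs within one subset of one target.

    Positives pair two distinct subset actives (unordered construction,
    emitted in fixed (query, candidate) role order); negatives pair a
    subset active with a subset decoy, subsampled to
    ``negative_ratio x n_positives``.
    """
    actives = sorted(library.subset_ids(subset, label=1))
    decoys = sorted(library.subset_ids(subset, label=0))
    if len(actives) < 2:
        warnings.warn(
            f"target {library.target_id!r} subset {subset!r} has <2 actives; no pairs"
        )
        return []
    pairs: list[PairSample] = []
    for i, a in enumerate(actives):
        for b in actives[i + 1:]:
            pairs.append(PairSample(a, b, 1, library.target_id, subset))
    n_pos = len(pairs)
    all_neg = [(a, d) for a in actives for d in decoys]
    rng = _target_rng(seed, library.target_id, salt=f"|neg|{subset}")
    if np.isinf(negative_ratio):
        n_neg = len(all_neg)
    else:
        n_neg = min(len(all_neg), int(round(negative_ratio * n_pos)))
    if n_neg > 0:
        chosen = rng.choice(len(all_neg), size=n_neg, replace=False)
        for k in sorted(chosen):
            a, d = all_neg[k]
            pairs.append(PairSample(a, d, 0, library.target_id, subset))
    return pairs


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Padded/masked arrays for one side (query or candidate) of a pair batch.

    Edge arrays come in two layouts: *directed* (each bond twice, for
    message passing into its destination atom) and *undirected bond
    tokens* (each bond once, for bond-level attention and edge fusion).
    Index arrays are flat into ``(B * max_atoms)`` rows.
    """

    atom_features: np.ndarray   # (B, N, d_n)
    atom_mask: np.ndarray       # (B, N)
    n_atoms: np.ndarray         # (B,)
    edge_src: np.ndarray        # (B*2E,) flat source-node rows
    edge_dst: np.ndarray        # (B*2E,) flat destination-node rows
    edge_features: np.ndarray   # (B*2E, d_e)
    edge_mask: np.ndarray       # (B*2E,)
    bond_i: np.ndarray          # (B*E,) flat endpoint rows
    bond_j: np.ndarray          # (B*E,)
    bond_features: np.ndarray   # (B*E, d_e)
    bond_mask: np.ndarray       # (B, E)
    max_atoms: int
    max_bonds: int

    @property
    def batch_size(self) -> int:
        return self.atom_features.shape[0]


@dataclass
class PairBatch:
    query: GraphBatch
    candidate: GraphBatch
    labels: np.ndarray          # (B,) in {0,1}
    target_id: str
    query_ids: list[str]
    candidate_ids: list[str]


def pack_graphs(graphs: list[MolGraph]) -> GraphBatch:
    """Pad a list of molecular graphs into one masked batch side."""
    B = len(graphs)
    N = max(g.num_atoms for g in graphs)
    E = max(max(g.num_bonds for g in graphs), 1)
    d_n = graphs[0].atom_features.shape[1]
    d_e = graphs[0].bond_features.shape[2]

    atom_features = np.zeros((B, N, d_n))
    atom_mask = np.zeros((B, N))
    n_atoms = np.zeros(B, dtype=np.intp)
    edge_src = np.zeros(B * 2 * E, dtype=np.intp)
    edge_dst = np.zeros(B * 2 * E, dtype=np.intp)
    edge_features = np.zeros((B * 2 * E, d_e))
    edge_mask = np.zeros(B * 2 * E)
    bond_i = np.zeros(B * E, dtype=np.intp)
    bond_j = np.zeros(B * E, dtype=np.intp)
    bond_features = np.zeros((B * E, d_e))
    bond_mask = np.zeros((B, E))

    for b, g in enumerate(graphs):
        n = g.num_atoms
        atom_features[b, :n] = g.atom_features
        atom_mask[b, :n] = 1.0
        n_atoms[b] = n
        base = b * N
        for k, (i, j) in enumerate(g.bonds):
            feat = g.bond_features[i, j]
            # directed copies i->j and j->i
            for d, (src, dst) in enumerate(((i, j), (j, i))):
                row = b * 2 * E + 2 * k + d
                edge_src[row] = base + src
                edge_dst[row] = base + dst
                edge_features[row] = feat
                edge_mask[row] = 1.0
            row = b * E + k
            bond_i[row] = base + i
            bond_j[row] = base + j
            bond_features[row] = feat
            bond_mask[b, k] = 1.0

    return GraphBatch(atom_features, atom_mask, n_atoms, edge_src, edge_dst,
                      edge_features, edge_mask, bond_i, bond_j, bond_features,
                      bond_mask, N, E)


def make_batches(pairs: list[PairSample], graphs: dict[str, MolGraph],
                 batch_size: int = 32, seed: int = 0,
                 shuffle: bool = True) -> list[PairBatch]:
    """Group pairs into single-target mini-batches of at most ``batch_size``.

    Shuffling (within targets and of the final batch order) is
    deterministic given ``seed``.
    """
    rng = np.random.default_rng([seed, 0x5e0d])
    by_target: dict[str, list[PairSample]] = {}
    for p in pairs:
        by_target.setdefault(p.target_id, []).append(p)

    batches: list[PairBatch] = []
    for target_id in sorted(by_target):
        tpairs = list(by_target[target_id])
        if shuffle:
            order = rng.permutation(len(tpairs))
            tpairs = [tpairs[k] for k in order]
        for start in range(0, len(tpairs), batch_size):
            chunk = tpairs[start:start + batch_size]
            q = pack_graphs([graphs[p.query_id] for p in chunk])
            c = pack_graphs([graphs[p.candidate_id] for p in chunk])
            batches.append(PairBatch(
                query=q, candidate=c,
                labels=np.array([p.label for p in chunk], dtype=np.float64),
                target_id=target_id,
                query_ids=[p.query_id for p in chunk],
                candidate_ids=[p.candidate_id for p in chunk],
            ))
    if shuffle:
        order = rng.permutation(len(batches))
        batches = [batches[k] for k in order]
    return batches
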