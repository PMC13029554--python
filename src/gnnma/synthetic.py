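"""Synthetic screening-library generator and the ECFP4 similarity baseline.

Emulates the structure of target-organized screening benchmarks: each
synthetic target owns a scaffold motif; its actives are that scaffold
decorated with 1-3 random substituents, while its decoys are decorated
molecules built on *other* scaffolds (and verified not to contain the
target scaffold as a substructure).  All molecules are assembled by
zipping dummy-labelled attachment points of curated templates, so every
emitted SMILES is chemically valid by construction.

This emulates the shape of real active/decoy libraries (shared actives
scaffold, much larger decoy set, per-target organization) but not their
chemistry: decoys are not property-matched to actives, and the scaffold
signal is far cleaner than real bioactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

from .metrics import SCORE_COLUMNS
from .pairing import TargetLibrary

__all__ = ["SyntheticSpec", "default_pools", "generate_library",
           "ecfp4_tanimoto_baseline", "tanimoto_ecfp4"]

_ZIP_PARAMS = Chem.MolzipParams()
_ZIP_PARAMS.label = Chem.MolzipLabel.Isotope

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def default_pools() -> tuple[dict[str, str], list[str]]:
    """Scaffold templates and decoration fragments shipped with the package."""
    ref = resources.files("gnnma").joinpath("data/synthetic_pools.yaml")
    raw = yaml.safe_load(ref.read_text())
    return dict(raw["scaffolds"]), list(raw["decorations"])


@dataclass
class SyntheticSpec:
    """Study conditions for one generated library."""

    n_targets: int = 3
    actives_per_target: int = 15
    decoys_per_target: int = 150
    scaffold_pool: dict[str, str] = field(default_factory=lambda: default_pools()[0])
    decoration_pool: list[str] = field(default_factory=lambda: default_pools()[1])
    noise_rate: float = 0.0
    seed: int = 0
    max_decorations: int = 3

    def __post_init__(self):
        if self.n_targets > len(self.scaffold_pool):
            raise ValueError("need at least one scaffold per target")
        for name, template in self.scaffold_pool.items():
            mol = Chem.MolFromSmiles(template)
            if mol is None:
                raise ValueError(f"invalid scaffold template {name!r}: {template}")
            if not _dummy_sites(mol):
                raise ValueError(f"scaffold template {name!r} has no attachment points")


def _dummy_sites(mol: Chem.Mol) -> list[int]:
    return sorted(a.GetIsotope() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol:
    """Remove remaining attachment dummies, re-protonating aromatic N."""
    ed = Chem.RWMol(mol)
    ed.BeginBatchEdit()
    for atom in ed.GetAtoms():
        if atom.GetAtomicNum() == 0:
            for nb in atom.GetNeighbors():
                if nb.GetIsAromatic() and nb.GetSymbol() == "N" and nb.GetTotalNumHs() == 0:
                    nb.SetNumExplicitHs(1)
            ed.RemoveAtom(atom.GetIdx())
    ed.CommitBatchEdit()
    out = ed.GetMol()
    Chem.SanitizeMol(out)
    return out


def bare_scaffold(template: str) -> str:
    """Canonical SMILES of a scaffold template with all sites H-capped."""
    return Chem.MolToSmiles(_strip_dummies(Chem.MolFromSmiles(template)))


def decorate(template: str, site_decorations: dict[int, str]) -> str:
    """Attach decoration fragments at the given sites; returns canonical SMILES."""
    scaffold = Chem.MolFromSmiles(template)
    keep = set(site_decorations)
    # drop unused sites first so molzip sees only matched labels
    ed = Chem.RWMol(scaffold)
    ed.BeginBatchEdit()
    for atom in ed.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() not in keep:
            for nb in atom.GetNeighbors():
                if nb.GetIsAromatic() and nb.GetSymbol() == "N" and nb.GetTotalNumHs() == 0:
                    nb.SetNumExplicitHs(1)
            ed.RemoveAtom(atom.GetIdx())
    ed.CommitBatchEdit()
    combined = ed.GetMol()
    for site, dec_smiles in site_decorations.items():
        dec = Chem.MolFromSmiles(dec_smiles)
        for atom in dec.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetIsotope(site)
        combined = Chem.CombineMols(combined, dec)
    mol = Chem.molzip(combined, _ZIP_PARAMS) if site_decorations else combined
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _random_molecule(template: str, decorations: list[str], max_dec: int,
                     rng: np.random.Generator) -> str:
    sites = _dummy_sites(Chem.MolFromSmiles(template))
    n_dec = int(rng.integers(1, min(max_dec, len(sites)) + 1))
    chosen = rng.choice(len(sites), size=n_dec, replace=False)
    assignment = {sites[k]: decorations[int(rng.integers(len(decorations)))]
                  for k in sorted(chosen)}
    return decorate(template, assignment)


def generate_library(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a per-target active/decoy library.

    Returns a frame with columns ``mol_id, smiles, target, label`` plus a
    ``scaffold`` attribute mapping targets to their scaffold names.
    Deterministic given ``spec.seed``; every SMILES re-parses; molecule
    counts are exactly as specified.
    """
    rng = np.random.default_rng([spec.seed, 0x5f11])
    names = sorted(spec.scaffold_pool)
    target_scaffolds = {f"T{k + 1:03d}": names[k % len(names)]
                        for k in range(spec.n_targets)}
    rows = []
    for target_id, scaffold_name in target_scaffolds.items():
        template = spec.scaffold_pool[scaffold_name]
        bare = Chem.MolFromSmiles(bare_scaffold(template))
        seen: set[str] = set()

        def draw(from_template: str, forbid_target_scaffold: bool) -> str:
            for _ in range(500):
                smi = _random_molecule(from_template, spec.decoration_pool,
                                       spec.max_decorations, rng)
                if smi in seen:
                    continue
                if forbid_target_scaffold and Chem.MolFromSmiles(smi).HasSubstructMatch(bare):
                    continue
                seen.add(smi)
                return smi
            raise RuntimeError(
                f"could not draw a fresh molecule for {target_id} "
                f"(pool too small for requested counts)")

        for i in range(spec.actives_per_target):
            rows.append((f"{target_id}_A{i + 1:03d}", draw(template, False),
                         target_id, 1))
        other_names = [n for n in names if n != scaffold_name]
        for i in range(spec.decoys_per_target):
            pick = other_names[int(rng.integers(len(other_names)))]
            rows.append((f"{target_id}_D{i + 1:03d}",
                         draw(spec.scaffold_pool[pick], True), target_id, 0))

    frame = pd.DataFrame(rows, columns=["mol_id", "smiles", "target", "label"])
    if spec.noise_rate > 0:
        flip = rng.random(len(frame)) < spec.noise_rate
        frame.loc[flip, "label"] = 1 - frame.loc[flip, "label"]
    frame.attrs["scaffold"] = target_scaffolds
    return frame


# ---------------------------------------------------------------------------
# fingerprint baseline
# ---------------------------------------------------------------------------

def tanimoto_ecfp4(smiles_a: str, smiles_b: str) -> float:
    """ECFP4 (Morgan radius-2, 2048 bit) Tanimoto similarity."""
    fa = _MORGAN.GetFingerprint(Chem.MolFromSmiles(smiles_a))
    fb = _MORGAN.GetFingerprint(Chem.MolFromSmiles(smiles_b))
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def ecfp4_tanimoto_baseline(frame: pd.DataFrame,
                            libraries: dict[str, TargetLibrary]) -> pd.DataFrame:
    """Classical fingerprint screening baseline on the test splits.

    Each test molecule's score is its maximum ECFP4 Tanimoto similarity
    to any test-split active of the same target, excluding itself.
    Feeds the same metrics pipeline as the learned scorer.
    """
    smiles = dict(zip(frame["mol_id"], frame["smiles"]))
    rows = []
    for target_id in sorted(libraries):
        lib = libraries[target_id]
        if not lib.usable:
            continue
        queries = lib.subset_ids("test", label=1)
        candidates = lib.subset_ids("test")
        if not queries:
            continue
        fps = {m: _MORGAN.GetFingerprint(Chem.MolFromSmiles(smiles[m]))
               for m in set(queries) | set(candidates)}
        labels = dict.fromkeys(lib.decoys, 0) | dict.fromkeys(lib.actives, 1)
        for cand in candidates:
            others = [q for q in queries if q != cand]
            if not others:
                continue
            sims = DataStructs.BulkTanimotoSimilarity(fps[cand],
                                                      [fps[q] for q in others])
            rows.append((target_id, cand, float(max(sims)), labels[cand]))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
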