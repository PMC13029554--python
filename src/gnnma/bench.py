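"""Throughput benchmark harness for deployment-cost estimates.

Two pipeline scopes are timed:

* ``forward_only`` — model forward passes over pre-built graph batches;
  the upper bound of model compute efficiency.
* ``e2e`` — disk-to-score: reading SMILES, graph construction/feature
  encoding (or cache loading) plus the forward pass.

Compound preparation for ``e2e`` is either ``online`` (featurize on the
fly) or ``cache`` (graphs precomputed into an on-disk store keyed by
canonical SMILES + schema hash).  Reported quantities: throughput in
pairs/s, per-pair latency ms/pair = 1000/(pairs/s), and extrapolated
screening times T(N) = N / throughput for N = 1e5 and 1e6 pairs.  The
first ``warmup_batches`` batches are excluded from timing.

Only CPU execution is available; requesting another device falls back to
CPU with a notice in the report.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np

from .model import GNNMAScorer
from .molgraph import FeatureSchema, MolGraph, smiles_to_graph
from .pairing import PairBatch, pack_graphs

__all__ = ["GraphCache", "run_benchmark"]


class GraphCache:
    """On-disk store of featurized graphs, keyed by canonical SMILES + schema.

    Each graph is flat-packed into a single ``.npy`` record (header, atom
    feature matrix, bond index pairs, per-bond feature rows); the dense
    bond tensor and adjacency are rebuilt on load.  Loaded graphs are
    memoized in process memory, so a molecule that appears in many pairs
    touches the disk once per run — the behaviour a deployment cache has.
    """

    def __init__(self, directory, schema: FeatureSchema):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.schema = schema
        schema_key = ",".join(schema.atom_types) + "|" + ",".join(schema.bond_types)
        self._schema_hash = hashlib.sha1(schema_key.encode()).hexdigest()[:12]
        self._memo: dict[str, MolGraph] = {}

    def _path(self, smiles: str) -> Path:
        key = hashlib.sha1(f"{smiles}|{self._schema_hash}".encode()).hexdigest()
        return self.directory / f"{key}.npy"

    def put(self, smiles: str, graph: MolGraph) -> None:
        n, nb = graph.num_atoms, graph.num_bonds
        d_n, d_e = self.schema.d_n, self.schema.d_e
        bond_rows = np.array([graph.bond_features[i, j] for i, j in graph.bonds],
                             dtype=np.float64).reshape(nb, d_e)
        bond_idx = np.array(graph.bonds, dtype=np.float64).reshape(nb * 2)
        packed = np.concatenate([
            np.array([n, nb, d_n, d_e], dtype=np.float64),
            graph.atom_features.ravel(), bond_idx, bond_rows.ravel(),
        ])
        np.save(self._path(smiles), packed)

    def get(self, smiles: str) -> MolGraph | None:
        hit = self._memo.get(smiles)
        if hit is not None:
            return hit
        path = self._path(smiles)
        if not path.exists():
            return None
        packed = np.load(path)
        n, nb, d_n, d_e = (int(x) for x in packed[:4])
        off = 4
        atom_features = packed[off:off + n * d_n].reshape(n, d_n)
        off += n * d_n
        bonds = [(int(a), int(b)) for a, b in
                 packed[off:off + 2 * nb].reshape(nb, 2)]
        off += 2 * nb
        bond_rows = packed[off:off + nb * d_e].reshape(nb, d_e)
        E = np.zeros((n, n, d_e))
        A = np.zeros((n, n), dtype=np.int8)
        for (i, j), row in zip(bonds, bond_rows):
            E[i, j] = E[j, i] = row
            A[i, j] = A[j, i] = 1
        graph = MolGraph(atom_features, E, A, n, canonical_smiles=smiles,
                         bonds=bonds)
        self._memo[smiles] = graph
        return graph

    def warm(self, smiles_list: list[str]) -> None:
        for smi in smiles_list:
            if not self._path(smi).exists():
                self.put(smi, smiles_to_graph(smi, self.schema))


def _resolve_device(device: str) -> tuple[str, str | None]:
    if device.lower() in ("cpu", ""):
        return "cpu", None
    return "cpu", f"device {device!r} unavailable; fell back to cpu"


def run_benchmark(scorer: GNNMAScorer, smiles_pairs: list[tuple[str, str]],
                  mode: str = "forward_only", prep: str = "online",
                  device: str = "cpu", batch_size: int = 32,
                  warmup_batches: int = 10,
                  cache_dir=None) -> dict:
    """Time pair scoring and report throughput, latency and T(1e5)/T(1e6)."""
    if mode not in ("forward_only", "e2e"):
        raise ValueError("mode must be 'forward_only' or 'e2e'")
    if prep not in ("online", "cache"):
        raise ValueError("prep must be 'online' or 'cache'")
    device, notice = _resolve_device(device)
    schema = scorer.schema

    cache = None
    if mode == "e2e" and prep == "cache":
        if cache_dir is None:
            raise ValueError("cache prep requires cache_dir")
        cache = GraphCache(cache_dir, schema)
        unique = sorted({s for pair in smiles_pairs for s in pair})
        cache.warm(unique)

    def fetch(smiles: str) -> MolGraph:
        if cache is not None:
            return cache.get(smiles)
        return smiles_to_graph(smiles, schema)

    chunks = [smiles_pairs[k:k + batch_size]
              for k in range(0, len(smiles_pairs), batch_size)]
    if mode == "forward_only":
        # graph construction excluded from scope: prebuild all batches
        prebuilt = []
        for chunk in chunks:
            prebuilt.append(PairBatch(
                query=pack_graphs([smiles_to_graph(a, schema) for a, _ in chunk]),
                candidate=pack_graphs([smiles_to_graph(b, schema) for _, b in chunk]),
                labels=np.zeros(len(chunk)), target_id="",
                query_ids=[""] * len(chunk), candidate_ids=[""] * len(chunk)))

    timed_pairs = 0
    elapsed = 0.0
    for k, chunk in enumerate(chunks):
        t0 = time.perf_counter()
        if mode == "forward_only":
            batch = prebuilt[k]
        else:
            batch = PairBatch(
                query=pack_graphs([fetch(a) for a, _ in chunk]),
                candidate=pack_graphs([fetch(b) for _, b in chunk]),
                labels=np.zeros(len(chunk)), target_id="",
                query_ids=[""] * len(chunk), candidate_ids=[""] * len(chunk))
        scorer.forward_batch(batch)
        dt = time.perf_counter() - t0
        if k >= warmup_batches:
            elapsed += dt
            timed_pairs += len(chunk)
    if timed_pairs == 0:
        raise ValueError(
            f"no timed batches: {len(chunks)} batches <= {warmup_batches} warm-up; "
            "provide more pairs or fewer warm-up batches")

    pairs_per_s = timed_pairs / elapsed
    report = {
        "mode": mode,
        "prep": prep if mode == "e2e" else None,
        "device": device,
        "batch_size": batch_size,
        "n_pairs_timed": timed_pairs,
        "warmup_batches": warmup_batches,
        "pairs_per_s": pairs_per_s,
        "ms_per_pair": 1000.0 / pairs_per_s,
        "t_1e5_s": 1e5 / pairs_per_s,
        "t_1e6_s": 1e6 / pairs_per_s,
    }
    if notice:
        report["notice"] = notice
    return report
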