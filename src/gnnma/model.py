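"""The GNN-MA pairwise molecular scorer.

Four stages, applied to a (query, candidate) molecule pair:

1. **Intra-molecular message passing** — per layer, atom ``i`` collects
   messages ``m_i = sum_{j in N(i)} psi(v_i, v_j, e_ij)`` and updates
   ``v_i <- v_i + LayerNorm(phi([v_i || m_i]))`` (residual + norm).
2. **Bidirectional cross-graph attention** — scaled dot-product logits
   ``alpha_ij = (W_q v_qi)^T (W_c v_cj) / sqrt(d)``; a softmax over the
   candidate axis yields the row-stochastic soft alignment ``A_q2c``,
   and the contextual embedding ``V~_qi = sum_j A_q2c(i,j) v_cj``.  The
   reverse direction uses its own projection pair.  The same machinery
   runs at the bond level with undirected bond tokens.
3. **Edge fusion and bond-to-atom aggregation** — each bond token is a
   symmetrized learnable map of its two (cross-updated) incident atoms
   and the raw bond feature; the fused edge, concatenated with its
   bond-level cross context, is mapped to an enhanced edge vector that
   is summed over incident edges per atom (``g_i``) and transformed
   (``eta``) into a per-atom bond-aggregation vector.
4. **Pooling and scoring** — ``Z = pool(V_intra + V~ + V_e2v)`` over
   unmasked atoms (masked mean by default), and the pair score is
   ``S = MLP(Z_q || Z_c)``, an unbounded logit.

Setting ``use_cross_attention=False`` gives the intra-only ablation:
both cross-attention stages are removed, each molecule is embedded
independently, and only the joint MLP head sees both molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, gather_rows, masked_softmax, scatter_rows
from .molgraph import FeatureSchema, MolGraph
from .nn import MLP, Adam, LayerNorm, Linear, Module
from .pairing import GraphBatch, PairBatch, pack_graphs

__all__ = ["ModelConfig", "PairEmbedding", "AlignmentResult", "GNNMAScorer",
           "score_id_pairs"]

CHECKPOINT_VERSION = "gnnma-checkpoint-1"


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 64
    num_mp_layers: int = 3
    dropout: float = 0.2
    use_cross_attention: bool = True  # False => intra-only ablation
    pooling: str = "mean"             # "mean" | "sum"
    mlp_hidden: tuple[int, ...] = (128, 64)

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.num_mp_layers < 1:
            raise ValueError("num_mp_layers must be >= 1")
        if self.pooling not in ("mean", "sum"):
            raise ValueError("pooling must be 'mean' or 'sum'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        raw = dict(raw)
        if "mlp_hidden" in raw:
            raw["mlp_hidden"] = tuple(raw["mlp_hidden"])
        return cls(**raw)


@dataclass
class PairEmbedding:
    """Intermediate representations of one scored pair (true-size arrays)."""

    V_intra_q: np.ndarray
    V_intra_c: np.ndarray
    V_ctx_q: np.ndarray
    V_ctx_c: np.ndarray
    V_e2v_q: np.ndarray
    V_e2v_c: np.ndarray
    Z_q: np.ndarray
    Z_c: np.ndarray
    score: float


@dataclass
class AlignmentResult:
    """Atom-level soft alignment between a query and a candidate."""

    A_q2c: np.ndarray  # (n, m), rows sum to 1
    A_c2q: np.ndarray  # (m, n), rows sum to 1
    top_links: list[tuple[int, int, float]] = field(default_factory=list)

    @classmethod
    def from_matrices(cls, A_q2c: np.ndarray, A_c2q: np.ndarray,
                      top_k: int | None = None) -> "AlignmentResult":
        n, m = A_q2c.shape
        links = [(i, j, float(A_q2c[i, j])) for i in range(n) for j in range(m)]
        links.sort(key=lambda t: (-t[2], t[0], t[1]))
        if top_k is not None:
            links = links[:top_k]
        return cls(A_q2c=A_q2c, A_c2q=A_c2q, top_links=links)


class GNNMAScorer(Module):
    """Pairwise scorer over featurized molecular graphs."""

    def __init__(self, config: ModelConfig | None = None,
                 schema: FeatureSchema | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.schema = schema or FeatureSchema()
        self.seed = seed
        rng = np.random.default_rng([seed, 0x6d0de1])
        h, d_n, d_e = self.config.hidden_dim, self.schema.d_n, self.schema.d_e

        self.input_proj = Linear(d_n, h, rng)
        self.psi = [MLP([2 * h + d_e, h, h], rng) for _ in range(self.config.num_mp_layers)]
        self.phi = [Linear(2 * h, h, rng) for _ in range(self.config.num_mp_layers)]
        self.norms = [LayerNorm(h) for _ in range(self.config.num_mp_layers)]

        if self.config.use_cross_attention:
            # separate projections per attention direction (atom level)
            self.W_q = Linear(h, h, rng, bias=False)
            self.W_c = Linear(h, h, rng, bias=False)
            self.W_q_rev = Linear(h, h, rng, bias=False)
            self.W_c_rev = Linear(h, h, rng, bias=False)
            # bond-level attention projections
            self.Wb_q = Linear(h, h, rng, bias=False)
            self.Wb_c = Linear(h, h, rng, bias=False)
            self.Wb_q_rev = Linear(h, h, rng, bias=False)
            self.Wb_c_rev = Linear(h, h, rng, bias=False)

        self.edge_fuse1 = MLP([2 * h + d_e, h, h], rng)
        self.edge_fuse2 = Linear(2 * h, h, rng)
        self.eta = Linear(h, h, rng)
        # keeps the bond-aggregation residual term on the same scale as the
        # layer-normalized atom embeddings it is summed with before pooling
        self.eta_norm = LayerNorm(h)
        head_dims = [2 * h, *self.config.mlp_hidden, 1]
        self.head = MLP(head_dims, rng, drop=self.config.dropout)

    # ------------------------------------------------------------------
    # forward stages
    # ------------------------------------------------------------------
    def _encode_intra(self, side: GraphBatch) -> Tensor:
        """Input projection + message-passing stack; returns (B*N, h) flat."""
        B, N, _ = side.atom_features.shape
        mask = Tensor(side.atom_mask.reshape(B * N, 1))
        x = Tensor(side.atom_features.reshape(B * N, -1))
        H = self.input_proj(x) * mask
        e = Tensor(side.edge_features)
        emask = Tensor(side.edge_mask[:, None])
        for layer in range(self.config.num_mp_layers):
            h_i = gather_rows(H, side.edge_dst)  # receiving atom v_i
            h_j = gather_rows(H, side.edge_src)  # neighbour v_j
            msg = self.psi[layer](concat([h_i, h_j, e])) * emask
            m = scatter_rows(msg, side.edge_dst, B * N)
            # residual add, then layer norm between layers: keeps node
            # embeddings unit-scale so downstream attention logits stay soft
            H = self.norms[layer](H + self.phi[layer](concat([H, m]))) * mask
        return H

    def _atom_cross(self, Vq: Tensor, Vc: Tensor, side_q: GraphBatch,
                    side_c: GraphBatch) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Bidirectional atom-level attention; returns A_q2c, A_c2q, V~_q, V~_c."""
        scale = 1.0 / np.sqrt(self.config.hidden_dim)
        alpha = (self.W_q(Vq) @ self.W_c(Vc).swap_last()) * scale
        A_q2c = masked_softmax(alpha, side_c.atom_mask[:, None, :])
        Vt_q = (A_q2c @ Vc) * Tensor(side_q.atom_mask[:, :, None])

        alpha_r = (self.W_q_rev(Vc) @ self.W_c_rev(Vq).swap_last()) * scale
        A_c2q = masked_softmax(alpha_r, side_q.atom_mask[:, None, :])
        Vt_c = (A_c2q @ Vq) * Tensor(side_c.atom_mask[:, :, None])
        return A_q2c, A_c2q, Vt_q, Vt_c

    def _bond_tokens(self, U_flat: Tensor, side: GraphBatch) -> Tensor:
        """Stage-1 edge fusion: symmetric fused bond token per undirected bond."""
        u_i = gather_rows(U_flat, side.bond_i)
        u_j = gather_rows(U_flat, side.bond_j)
        e = Tensor(side.bond_features)
        fwd = self.edge_fuse1(concat([u_i, u_j, e]))
        rev = self.edge_fuse1(concat([u_j, u_i, e]))
        B = side.batch_size
        b = ((fwd + rev) * 0.5) * Tensor(side.bond_mask.reshape(-1, 1))
        return b.reshape(B, side.max_bonds, self.config.hidden_dim)

    def _bond_cross(self, Bq: Tensor, Bc: Tensor, side_q: GraphBatch,
                    side_c: GraphBatch) -> tuple[Tensor, Tensor]:
        """Bond-level cross context (zero rows for molecules without bonds)."""
        scale = 1.0 / np.sqrt(self.config.hidden_dim)
        logits = (self.Wb_q(Bq) @ self.Wb_c(Bc).swap_last()) * scale
        Ab_q2c = masked_softmax(logits, side_c.bond_mask[:, None, :])
        Bt_q = (Ab_q2c @ Bc) * Tensor(side_q.bond_mask[:, :, None])

        logits_r = (self.Wb_q_rev(Bc) @ self.Wb_c_rev(Bq).swap_last()) * scale
        Ab_c2q = masked_softmax(logits_r, side_q.bond_mask[:, None, :])
        Bt_c = (Ab_c2q @ Bq) * Tensor(side_c.bond_mask[:, :, None])
        return Bt_q, Bt_c

    def _edge_to_atom(self, Btok: Tensor, Bctx: Tensor | None,
                      side: GraphBatch) -> Tensor:
        """Stage-2 fusion then incident-edge aggregation g_i and eta(g_i)."""
        B, E, h = Btok.shape
        if Bctx is None:
            Bctx = Tensor(np.zeros((B, E, h)))
        fused = self.edge_fuse2(concat([Btok, Bctx])).relu()
        fused = fused * Tensor(side.bond_mask[:, :, None])
        flat = fused.reshape(B * E, h)
        n_rows = side.batch_size * side.max_atoms
        g = scatter_rows(flat, side.bond_i, n_rows) + scatter_rows(flat, side.bond_j, n_rows)
        mask = Tensor(side.atom_mask.reshape(-1, 1))
        return self.eta_norm(self.eta(g)) * mask

    def _pool(self, combined_flat: Tensor, side: GraphBatch) -> Tensor:
        B, N = side.batch_size, side.max_atoms
        Z = combined_flat.reshape(B, N, self.config.hidden_dim).sum(axis=1)
        if self.config.pooling == "mean":
            Z = Z * Tensor(1.0 / side.n_atoms[:, None])
        return Z

    # ------------------------------------------------------------------
    # public API
    # ------------------------------------------------------------------
    def forward_batch(self, batch: PairBatch, training: bool = False,
                      rng: np.random.Generator | None = None) -> dict:
        """Score a padded pair batch; returns tensors keyed by stage."""
        q, c = batch.query, batch.candidate
        h = self.config.hidden_dim
        Hq = self._encode_intra(q)
        Hc = self._encode_intra(c)
        Vq = Hq.reshape(q.batch_size, q.max_atoms, h)
        Vc = Hc.reshape(c.batch_size, c.max_atoms, h)

        out: dict = {}
        if self.config.use_cross_attention:
            A_q2c, A_c2q, Vt_q, Vt_c = self._atom_cross(Vq, Vc, q, c)
            out["A_q2c"], out["A_c2q"] = A_q2c, A_c2q
            Uq = (Vq + Vt_q).reshape(-1, h)
            Uc = (Vc + Vt_c).reshape(-1, h)
        else:
            Vt_q = Tensor(np.zeros(Vq.shape))
            Vt_c = Tensor(np.zeros(Vc.shape))
            Uq, Uc = Hq, Hc

        Btok_q = self._bond_tokens(Uq, q)
        Btok_c = self._bond_tokens(Uc, c)
        if self.config.use_cross_attention:
            Bt_q, Bt_c = self._bond_cross(Btok_q, Btok_c, q, c)
        else:
            Bt_q = Bt_c = None
        E2v_q = self._edge_to_atom(Btok_q, Bt_q, q)
        E2v_c = self._edge_to_atom(Btok_c, Bt_c, c)

        comb_q = Hq + Vt_q.reshape(-1, h) + E2v_q
        comb_c = Hc + Vt_c.reshape(-1, h) + E2v_c
        Z_q = self._pool(comb_q, q)
        Z_c = self._pool(comb_c, c)
        score = self.head(concat([Z_q, Z_c]), training=training, rng=rng)
        out.update({
            "score": score.reshape(-1),
            "Z_q": Z_q, "Z_c": Z_c,
            "V_intra_q": Hq, "V_intra_c": Hc,
            "V_ctx_q": Vt_q, "V_ctx_c": Vt_c,
            "V_e2v_q": E2v_q, "V_e2v_c": E2v_c,
        })
        return out

    def forward_pair(self, graph_q: MolGraph, graph_c: MolGraph
                     ) -> tuple[float, AlignmentResult | None, PairEmbedding]:
        """Score a single pair; also return alignment and stage embeddings."""
        batch = PairBatch(
            query=pack_graphs([graph_q]), candidate=pack_graphs([graph_c]),
            labels=np.zeros(1), target_id="", query_ids=[graph_q.mol_id],
            candidate_ids=[graph_c.mol_id],
        )
        out = self.forward_batch(batch)
        n, m = graph_q.num_atoms, graph_c.num_atoms
        h = self.config.hidden_dim
        score = float(out["score"].data[0])
        alignment = None
        if self.config.use_cross_attention:
            alignment = AlignmentResult.from_matrices(
                out["A_q2c"].data[0, :n, :m].copy(),
                out["A_c2q"].data[0, :m, :n].copy(),
            )
        emb = PairEmbedding(
            V_intra_q=out["V_intra_q"].data.reshape(1, -1, h)[0, :n].copy(),
            V_intra_c=out["V_intra_c"].data.reshape(1, -1, h)[0, :m].copy(),
            V_ctx_q=out["V_ctx_q"].data.reshape(1, -1, h)[0, :n].copy(),
            V_ctx_c=out["V_ctx_c"].data.reshape(1, -1, h)[0, :m].copy(),
            V_e2v_q=out["V_e2v_q"].data.reshape(1, -1, h)[0, :n].copy(),
            V_e2v_c=out["V_e2v_c"].data.reshape(1, -1, h)[0, :m].copy(),
            Z_q=out["Z_q"].data[0].copy(), Z_c=out["Z_c"].data[0].copy(),
            score=score,
        )
        return score, alignment, emb

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: parameter arrays + embedded config and feature schema."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "schema": self.schema.to_dict(),
            "seed": self.seed,
        }
        arrays = {name: p.data for name, p in self.named_parameters()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "GNNMAScorer":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            scorer = cls(
                config=ModelConfig.from_dict(meta["config"]),
                schema=FeatureSchema.from_dict(meta["schema"]),
                seed=meta.get("seed", 0),
            )
            for name, p in scorer.named_parameters():
                p.data[...] = archive[name]
        return scorer

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]


def score_id_pairs(scorer: GNNMAScorer, id_pairs: list[tuple[str, str]],
                   graphs: dict[str, MolGraph], batch_size: int = 64) -> np.ndarray:
    """Inference scores for explicit (query_id, candidate_id) pairs."""
    scores = np.empty(len(id_pairs))
    for start in range(0, len(id_pairs), batch_size):
        chunk = id_pairs[start:start + batch_size]
        batch = PairBatch(
            query=pack_graphs([graphs[a] for a, _ in chunk]),
            candidate=pack_graphs([graphs[b] for _, b in chunk]),
            labels=np.zeros(len(chunk)), target_id="",
            query_ids=[a for a, _ in chunk], candidate_ids=[b for _, b in chunk],
        )
        scores[start:start + len(chunk)] = scorer.forward_batch(batch)["score"].data
    return scores
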