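"""High-level modelling surface: fit a pairwise scorer to a screening library.

Follows the model/results idiom: :class:`VirtualScreeningModel` is
constructed from the data (a per-target library of actives and decoys)
plus configuration; :meth:`VirtualScreeningModel.fit` trains the
pairwise scorer and returns a :class:`VirtualScreeningResults` carrying
the fitted parameters, the training history, per-target test metrics
with all four aggregation views, and a ``summary()`` table.  Paired
comparison against another fitted model or a score table (bootstrap CI,
Wilcoxon, win/loss/tie) hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .model import GNNMAScorer, ModelConfig, score_id_pairs
from .molgraph import FeatureSchema, MolGraph, smiles_to_graph
from .pairing import TargetLibrary, manifest_frame, split_library
from .training import LossConfig, TrainResult, train

__all__ = ["VirtualScreeningModel", "VirtualScreeningResults"]

REQUIRED_COLUMNS = ("mol_id", "smiles", "target", "label")


def featurize_frame(frame: pd.DataFrame,
                    schema: FeatureSchema) -> dict[str, MolGraph]:
    return {row.mol_id: smiles_to_graph(row.smiles, schema, mol_id=row.mol_id)
            for row in frame.itertuples()}


def test_pair_table(scorer: GNNMAScorer, libraries: dict[str, TargetLibrary],
                    graphs: dict[str, MolGraph],
                    batch_size: int = 64) -> pd.DataFrame:
    """Score every (test active, test molecule) pair, self-pairs excluded."""
    rows = []
    id_pairs = []
    for target_id in sorted(libraries):
        lib = libraries[target_id]
        if not lib.usable:
            continue
        queries = lib.subset_ids("test", label=1)
        candidates = lib.subset_ids("test")
        labels = dict.fromkeys(lib.decoys, 0) | dict.fromkeys(lib.actives, 1)
        for q in queries:
            for cand in candidates:
                if q == cand:
                    continue
                id_pairs.append((q, cand))
                rows.append((target_id, q, cand, labels[cand]))
    scores = score_id_pairs(scorer, id_pairs, graphs, batch_size)
    out = pd.DataFrame(rows, columns=["target", "query_id", "candidate_id",
                                      "candidate_label"])
    out["score"] = scores
    return out[["target", "query_id", "candidate_id", "score", "candidate_label"]]


class VirtualScreeningModel:
    """A pairwise graph-matching screening model bound to one library.

    Parameters
    ----------
    library : DataFrame with columns mol_id, smiles, target, label (0/1).
    model_config, loss_config : architecture and objective settings.
    schema : feature schema fixing the atom/bond encodings (default schema
        if omitted).
    """

    def __init__(self, library: pd.DataFrame,
                 model_config: ModelConfig | None = None,
                 loss_config: LossConfig | None = None,
                 schema: FeatureSchema | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in library.columns]
        if missing:
            raise ValueError(f"library frame is missing columns: {missing}")
        if not set(library["label"].unique()) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if library["mol_id"].duplicated().any():
            raise ValueError("mol_id values must be unique")
        self.library = library.reset_index(drop=True)
        self.model_config = model_config or ModelConfig()
        self.loss_config = loss_config or LossConfig()
        self.schema = schema or FeatureSchema()
        self._graphs: dict[str, MolGraph] | None = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VirtualScreeningModel":
        return cls(pd.read_csv(path), **kwargs)

    @property
    def graphs(self) -> dict[str, MolGraph]:
        if self._graphs is None:
            self._graphs = featurize_frame(self.library, self.schema)
        return self._graphs

    def fit(self, seed: int = 0, ef_cutoffs=_metrics.DEFAULT_EF_CUTOFFS,
            aggregator: str = "max", verbose: bool = False
            ) -> "VirtualScreeningResults":
        """Split, train, score the test split and compute all metrics."""
        libraries = split_library(self.library, seed)
        scorer = GNNMAScorer(self.model_config, self.schema, seed=seed)
        fit_log = train(scorer, libraries, self.graphs, self.loss_config,
                        seed=seed, verbose=verbose)
        scorer.load_state_arrays(fit_log.best_state)

        pair_table = test_pair_table(scorer, libraries, self.graphs,
                                     batch_size=self.loss_config.batch_size)
        score_table = _metrics.candidate_scores(pair_table, aggregator)
        per_target = _metrics.per_target_metrics(score_table, tuple(ef_cutoffs))
        views = _metrics.aggregate(score_table, tuple(ef_cutoffs), per_target)
        return VirtualScreeningResults(
            model=self, scorer=scorer, libraries=libraries, seed=seed,
            fit_log=fit_log, pair_table=pair_table, score_table=score_table,
            per_target=per_target, views=views, ef_cutoffs=tuple(ef_cutoffs),
        )


@dataclass
class VirtualScreeningResults:
    """Fitted scorer plus everything measured on the held-out test split."""

    model: VirtualScreeningModel
    scorer: GNNMAScorer
    libraries: dict[str, TargetLibrary]
    seed: int
    fit_log: TrainResult
    pair_table: pd.DataFrame
    score_table: pd.DataFrame
    per_target: pd.DataFrame
    views: dict
    ef_cutoffs: tuple[float, ...] = field(default_factory=tuple)

    @property
    def history(self) -> pd.DataFrame:
        return self.fit_log.history

    @property
    def split_manifest(self) -> pd.DataFrame:
        return manifest_frame(self.libraries)

    def save_checkpoint(self, path) -> None:
        self.scorer.save(path)

    def summary(self) -> str:
        cfg = self.model.model_config
        variant = "GNN-MA" if cfg.use_cross_attention else "GNN-MA-intra"
        lines = [
            "Pairwise virtual-screening results",
            "=" * 62,
            f"variant: {variant}   hidden_dim={cfg.hidden_dim} "
            f"layers={cfg.num_mp_layers} pooling={cfg.pooling}",
            f"seed: {self.seed}   best epoch: {self.fit_log.best_epoch} "
            f"(val pair AUC {self._best_val_auc():.4f})",
            f"targets evaluated: {len(self.per_target)}   "
            f"test molecules: {int(self.per_target['n_molecules'].sum())}",
            "",
            "Per-target test metrics",
            "-" * 62,
            self.per_target.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Aggregation views",
            "-" * 62,
        ]
        metric_cols = ["roc_auc"] + [f"ef_{k:g}" for k in self.ef_cutoffs]
        header = f"{'view':<16}" + "".join(f"{c:>10}" for c in metric_cols)
        lines.append(header)
        for view in ("pooled", "macro", "weighted_macro"):
            vals = self.views[view]
            lines.append(f"{view:<16}" + "".join(f"{vals[c]:>10.4f}"
                                                 for c in metric_cols))
        return "\n".join(lines)

    def _best_val_auc(self) -> float:
        hist = self.fit_log.history
        row = hist.loc[hist["epoch"] == self.fit_log.best_epoch]
        return float(row["val_auc"].iloc[0]) if len(row) else float("nan")

    def compare(self, other, metric: str = "roc_auc", n_boot: int = 20000,
                seed: int = 0) -> dict:
        """Paired per-target comparison against another result/score table.

        ``other`` may be a :class:`VirtualScreeningResults` or a
        per-target metrics frame.  Returns deltas, bootstrap CI of the
        mean delta, Wilcoxon p and win/loss/tie counts.
        """
        if isinstance(other, VirtualScreeningResults):
            other_pt = other.per_target
        else:
            other_pt = other
        deltas = _metrics.per_target_delta(self.per_target, other_pt, metric)
        low, high, mean = _metrics.bootstrap_ci(deltas.to_numpy(), n_boot,
                                                seed=seed)
        test = _metrics.wilcoxon_signed_rank(deltas.to_numpy())
        return {
            "metric": metric,
            "deltas": deltas.to_dict(),
            "mean_delta": mean,
            "ci95": (low, high),
            **test,
        }
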