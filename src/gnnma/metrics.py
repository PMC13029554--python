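"""Screening metrics: ROC-AUC, EF@k%, aggregation views and statistics.

A *score table* is a DataFrame with columns ``target, mol_id, score,
label`` — one ranked candidate per row, per target.  From per-target
metrics we report four aggregation views:

* **pooled** — predictions of all targets concatenated before computing
  the metric (pooled EF sums per-target top-n counts: caution, raw
  scores are not calibrated across targets, so this view can differ
  sharply from macro averages);
* **macro** — unweighted mean of per-target values;
* **weighted_macro** — mean weighted by per-target molecule counts;
* **macro_target** — the per-target distribution itself, summarized and
  compared between methods via paired statistics: bootstrap percentile
  confidence intervals over targets, a two-sided Wilcoxon signed-rank
  test, and win/loss/tie counts.

EF@k% uses the top-``n`` cutoff ``n = max(1, round_half_up(k/100 * N))``
with ties broken by a stable sort on (-score, mol_id); then
``EF = (a/n) / (A/N)`` where ``a`` counts actives in the top ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "SCORE_COLUMNS", "TargetMetrics", "candidate_scores", "roc_auc",
    "enrichment_factor", "per_target_metrics", "aggregate",
    "per_target_delta", "bootstrap_ci", "wilcoxon_signed_rank",
    "DEFAULT_EF_CUTOFFS",
]

SCORE_COLUMNS = ["target", "mol_id", "score", "label"]
DEFAULT_EF_CUTOFFS = (1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass
class TargetMetrics:
    target_id: str
    roc_auc: float
    ef: dict[float, float] = field(default_factory=dict)
    n_molecules: int = 0
    n_actives: int = 0


def candidate_scores(pair_scores: pd.DataFrame, aggregator: str = "max") -> pd.DataFrame:
    """Collapse query-candidate pair scores into one score per candidate.

    ``pair_scores`` columns: target, query_id, candidate_id, score,
    candidate_label.  Self-pairs (query == candidate) are excluded; each
    candidate's screening score is the max (default) or mean of its pair
    scores over the remaining queries.
    """
    if aggregator not in ("max", "mean"):
        raise ValueError("aggregator must be 'max' or 'mean'")
    df = pair_scores[pair_scores["query_id"] != pair_scores["candidate_id"]]
    grouped = (
        df.groupby(["target", "candidate_id"], sort=True)
        .agg(score=("score", aggregator), label=("candidate_label", "first"))
        .reset_index()
        .rename(columns={"candidate_id": "mol_id"})
    )
    return grouped[SCORE_COLUMNS]


def roc_auc(table: pd.DataFrame) -> float:
    """Probability a random active outranks a random inactive (ties 0.5)."""
    labels = table["label"].to_numpy()
    if labels.min() == labels.max():
        raise ValueError("ROC-AUC needs both an active and an inactive")
    return float(roc_auc_score(labels, table["score"].to_numpy()))


def _top_n(k_percent: float, n_total: int) -> int:
    return max(1, int(np.floor(k_percent / 100.0 * n_total + 0.5)))


def enrichment_factor(table: pd.DataFrame, k_percent: float) -> float:
    """EF@k% = (a/n) / (A/N) for the top n = max(1, round(k/100 * N))."""
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must lie in (0, 100]")
    N = len(table)
    A = int(table["label"].sum())
    if A == 0:
        raise ValueError("enrichment factor undefined with zero actives")
    ranked = table.sort_values(["score", "mol_id"], ascending=[False, True],
                               kind="stable")
    n = _top_n(k_percent, N)
    a = int(ranked["label"].head(n).sum())
    return (a / n) / (A / N)


def per_target_metrics(score_table: pd.DataFrame,
                       ef_cutoffs: tuple[float, ...] = DEFAULT_EF_CUTOFFS
                       ) -> pd.DataFrame:
    """Per-target ROC-AUC and EF@k for each cutoff; one row per target."""
    rows = []
    for target_id, group in score_table.groupby("target", sort=True):
        row = {
            "target": target_id,
            "n_molecules": len(group),
            "n_actives": int(group["label"].sum()),
            "roc_auc": roc_auc(group),
        }
        for k in ef_cutoffs:
            row[f"ef_{k:g}"] = enrichment_factor(group, k)
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_ef(score_table: pd.DataFrame, k_percent: float) -> float:
    """Pooled EF: per-target top-n and active counts summed before the ratio."""
    a_sum = n_sum = A_sum = N_sum = 0
    for _, group in score_table.groupby("target", sort=True):
        N = len(group)
        n = _top_n(k_percent, N)
        ranked = group.sort_values(["score", "mol_id"], ascending=[False, True],
                                   kind="stable")
        a_sum += int(ranked["label"].head(n).sum())
        n_sum += n
        A_sum += int(group["label"].sum())
        N_sum += N
    return (a_sum / n_sum) / (A_sum / N_sum)


def aggregate(score_table: pd.DataFrame,
              ef_cutoffs: tuple[float, ...] = DEFAULT_EF_CUTOFFS,
              per_target: pd.DataFrame | None = None) -> dict:
    """All four aggregation views over one score table."""
    if per_target is None:
        per_target = per_target_metrics(score_table, ef_cutoffs)
    metric_cols = ["roc_auc"] + [f"ef_{k:g}" for k in ef_cutoffs]
    weights = per_target["n_molecules"].to_numpy(dtype=float)

    pooled = {"roc_auc": roc_auc(score_table)}
    for k in ef_cutoffs:
        pooled[f"ef_{k:g}"] = _pooled_ef(score_table, k)

    macro = {c: float(per_target[c].mean()) for c in metric_cols}
    weighted = {c: float(np.average(per_target[c], weights=weights))
                for c in metric_cols}
    macro_target = {
        c: {
            "per_target": dict(zip(per_target["target"], per_target[c])),
            "mean": float(per_target[c].mean()),
            "median": float(per_target[c].median()),
            "std": float(per_target[c].std(ddof=1)) if len(per_target) > 1 else 0.0,
            "min": float(per_target[c].min()),
            "max": float(per_target[c].max()),
        }
        for c in metric_cols
    }
    return {
        "pooled": pooled,
        "macro": macro,
        "weighted_macro": weighted,
        "macro_target": macro_target,
        "note": "pooled view concatenates uncalibrated per-target scores; "
                "compare with macro views before drawing conclusions",
    }


def per_target_delta(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                     metric: str = "roc_auc") -> pd.Series:
    """Delta_t = M_t(A) - M_t(B) over the common target set (indexed by target)."""
    a = metrics_a.set_index("target")[metric]
    b = metrics_b.set_index("target")[metric]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common targets between the two metric tables")
    return (a.loc[common] - b.loc[common]).sort_index()


def bootstrap_ci(deltas, n_boot: int = 20000, confidence: float = 0.95,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean delta, resampling targets."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("no deltas to bootstrap")
    rng = np.random.default_rng([seed, 0xb007])
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    means = d[idx].mean(axis=1)
    alpha = (1.0 - confidence) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high), float(d.mean())


def wilcoxon_signed_rank(deltas) -> dict:
    """Two-sided Wilcoxon signed-rank test on nonzero per-target deltas.

    Returns p-value (NaN when every delta is zero) plus win/loss/tie
    counts (win: delta > 0; loss: delta < 0; tie: delta == 0).
    """
    d = np.asarray(deltas, dtype=float)
    wins = int((d > 0).sum())
    losses = int((d < 0).sum())
    ties = int((d == 0).sum())
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return {"p_value": float("nan"), "statistic": float("nan"),
                "wins": wins, "losses": losses, "ties": ties}
    stat, p = stats.wilcoxon(nonzero, alternative="two-sided")
    return {"p_value": float(p), "statistic": float(stat),
            "wins": wins, "losses": losses, "ties": ties}
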