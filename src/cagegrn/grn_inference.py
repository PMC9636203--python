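"""TF -> gene interaction scores and GRN assembly.

An edge's interaction score is the mean of four components, each rank-scaled
to [0, 1] across all candidate (TF, gene) pairs:

* TF expression (log(1+TPM) of the TF's own gene),
* target-gene expression,
* distance-weighted binding: sum over enhancers within the horizon of the
  gene's TSS of p(TF binds enhancer) * w(distance),
* genome-wide motif activity of the TF.

The distance weight is 1 within 5 kb of the TSS, decays exponentially with
constant 25 kb out to 100 kb, and is 0 beyond. Pairs with weighted binding 0
are excluded before scaling. Each piece is an isolated configurable function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import Ridge

__all__ = [
    "GrnEdge",
    "distance_weight",
    "weighted_binding",
    "weighted_binding_table",
    "motif_activity",
    "interaction_scores",
    "build_grn",
    "rank_scale",
]

FULL_WEIGHT_RADIUS = 5_000
MAX_RADIUS = 100_000
DECAY = 25_000


def distance_weight(
    d: float,
    full_radius: int = FULL_WEIGHT_RADIUS,
    max_radius: int = MAX_RADIUS,
    decay: float = DECAY,
) -> float:
    """Non-increasing weight in |d|: 1 inside full_radius, exp decay to
    max_radius, 0 beyond."""
    ad = abs(d)
    if ad <= full_radius:
        return 1.0
    if ad > max_radius:
        return 0.0
    return math.exp(-(ad - full_radius) / decay)


def weighted_binding(
    probs: Sequence[float],
    distances: Sequence[float],
    max_radius: int = MAX_RADIUS,
) -> float:
    """Sum of p_l * w(d_l) over enhancers within the horizon; 0 if none."""
    total = 0.0
    for p, d in zip(probs, distances):
        if abs(d) <= max_radius:
            total += p * distance_weight(d, max_radius=max_radius)
    return total


def weighted_binding_table(
    binding: pd.DataFrame,
    enhancer_mid: Mapping[str, Tuple[str, int]],
    gene_tss: Mapping[str, Tuple[str, int]],
    max_radius: int = MAX_RADIUS,
) -> pd.DataFrame:
    """Aggregate per-(TF, enhancer) probabilities into per-(TF, gene) weighted
    binding.

    binding: columns [tf, region_id, prob]; enhancer_mid: region_id ->
    (chrom, midpoint); gene_tss: gene -> (chrom, tss).
    """
    rows = []
    regions = [(rid,) + enhancer_mid[rid] for rid in binding["region_id"].unique()]
    probs_by_tf = {
        tf: dict(zip(sub["region_id"], sub["prob"]))
        for tf, sub in binding.groupby("tf")
    }
    for gene, (gchrom, tss) in gene_tss.items():
        near = [
            (rid, abs(mid - tss))
            for rid, chrom, mid in regions
            if chrom == gchrom and abs(mid - tss) <= max_radius
        ]
        if not near:
            continue
        for tf, probs in probs_by_tf.items():
            wb = sum(
                probs.get(rid, 0.0) * distance_weight(d, max_radius=max_radius)
                for rid, d in near
            )
            if wb > 0:
                rows.append((tf, gene, wb))
    return pd.DataFrame(rows, columns=["tf", "gene", "weighted_binding"])


def motif_activity(
    enhancer_intensity: np.ndarray,
    motif_zscores: np.ndarray,
    motif_ids: Sequence[str],
    motif2tf: Mapping[str, Sequence[str]],
    alpha: float = 1.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Ridge-regress log(1+intensity) on the enhancer x motif z-score matrix;
    a TF's activity is the coefficient of its motif with max |coefficient|."""
    y = np.log1p(np.asarray(enhancer_intensity, dtype=float))
    Z = np.asarray(motif_zscores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] < 2:
        raise ValueError("motif activity is underdetermined with < 2 enhancers")
    model = Ridge(alpha=alpha, random_state=seed)
    model.fit(Z, y)
    coef = dict(zip(motif_ids, model.coef_))
    activity: Dict[str, float] = {}
    for motif_id, tfs in motif2tf.items():
        c = coef.get(motif_id)
        if c is None:
            continue
        for tf in tfs:
            if tf not in activity or abs(c) > abs(activity[tf]):
                activity[tf] = float(c)
    return activity


def rank_scale(values: np.ndarray) -> np.ndarray:
    """Ranks scaled to [0, 1]; tied values share the lowest rank of the tie
    group so a raw 0 (the minimum of a non-negative component) maps to 0."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return v
    if n == 1:
        return np.ones(1)
    r = rankdata(v, method="min")
    return (r - 1) / (n - 1)


@dataclass
class GrnEdge:
    tf: str
    gene: str
    score: float
    components: Dict[str, float] = field(default_factory=dict)
    self_edge: bool = False


def interaction_scores(
    expression: Mapping[str, float],
    binding: pd.DataFrame,
    activity: Mapping[str, float],
) -> List[GrnEdge]:
    """Mean of four rank-scaled components per candidate (TF, gene) pair.

    expression: gene -> pooled TPM (must contain every TF's own gene for the
    TF to be considered expressed); binding: columns [tf, gene,
    weighted_binding] with zero-binding pairs already excluded or excluded
    here; activity: tf -> motif activity.
    """
    df = binding[binding["weighted_binding"] > 0].copy()
    df = df[df["tf"].isin(expression.keys())]  # TF must be in the expression table
    if df.empty:
        return []
    tf_expr = np.log1p(df["tf"].map(lambda t: expression.get(t, 0.0)).to_numpy())
    tg_expr = np.log1p(df["gene"].map(lambda g: expression.get(g, 0.0)).to_numpy())
    wb = df["weighted_binding"].to_numpy(dtype=float)
    act = df["tf"].map(lambda t: activity.get(t, 0.0)).to_numpy(dtype=float)

    comps = {
        "tf_expression": rank_scale(tf_expr),
        "target_expression": rank_scale(tg_expr),
        "weighted_binding": rank_scale(wb),
        "activity": rank_scale(act),
    }
    score = np.mean(np.column_stack(list(comps.values())), axis=1)
    edges = []
    for i, (tf, gene) in enumerate(zip(df["tf"], df["gene"])):
        edges.append(
            GrnEdge(
                tf,
                gene,
                float(score[i]),
                {k: float(v[i]) for k, v in comps.items()},
                self_edge=(tf == gene),
            )
        )
    return edges


def build_grn(edges: Sequence[GrnEdge], top_n: int = 500_000) -> List[GrnEdge]:
    """Top-n edges by interaction score, ties broken by (tf, gene) lexically."""
    ordered = sorted(edges, key=lambda e: (-e.score, e.tf, e.gene))
    return ordered[:top_n]
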