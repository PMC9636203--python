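"""TF influence scoring over a differential GRN, plus time-course clustering.

The differential network keeps, per (TF, gene) pair, diff = max(0, target
interaction - source interaction); missing edges score 0. For each TF a
breadth-limited traversal (depth <= max_depth) finds, per reachable gene, the
best path (max product of edge diff scores); the gene contributes

    bestpath(g) * max(0, log2FC_g) / 2**(depth - 1)

to the TF's raw score, which is then min-max scaled to [0, 1] across TFs.
Only positive fold changes contribute (the framework models activation only);
a TF's own fold change does not enter its score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grn_inference import GrnEdge

__all__ = [
    "DifferentialGrn",
    "InfluenceResult",
    "TemporalClusters",
    "differential_grn",
    "influence_scores",
    "rank_and_plot_data",
    "timecourse_cluster",
    "simple_log2fc",
]

EdgeTable = Mapping[Tuple[str, str], float]  # (tf, gene) -> interaction score


def _as_edge_dict(grn) -> Dict[Tuple[str, str], float]:
    if isinstance(grn, Mapping):
        return dict(grn)
    out = {}
    for e in grn:
        if isinstance(e, GrnEdge):
            out[(e.tf, e.gene)] = e.score
        else:
            tf, gene, score = e
            out[(tf, gene)] = float(score)
    return out


@dataclass
class DifferentialGrn:
    edges: List[Tuple[str, str, float]]  # (tf, gene, diff), sorted desc
    top_n: int
    n_before_truncation: int = 0


def differential_grn(source_grn, target_grn, top_n: int = 500_000) -> DifferentialGrn:
    """Per pair diff = max(0, target - source), zero-diff edges dropped, top_n
    kept with deterministic (tf, gene) tie-break."""
    src = _as_edge_dict(source_grn)
    tgt = _as_edge_dict(target_grn)
    diffs = []
    for pair in set(src) | set(tgt):
        d = max(0.0, tgt.get(pair, 0.0) - src.get(pair, 0.0))
        if d > 0:
            diffs.append((pair[0], pair[1], d))
    diffs.sort(key=lambda r: (-r[2], r[0], r[1]))
    return DifferentialGrn(diffs[:top_n], top_n, n_before_truncation=len(diffs))


@dataclass
class InfluenceResult:
    influence: Dict[str, float]  # scaled to [0, 1] across TFs
    raw: Dict[str, float]
    log2fc: Dict[str, float]  # the TF's own gene
    out_degree: Dict[str, int]  # distinct targets within the depth horizon


def _best_paths(
    adj: Mapping[str, List[Tuple[str, float]]], tf: str, max_depth: int
) -> Dict[str, Tuple[float, int]]:
    """gene -> (best path score, depth of that best path), excluding the TF
    itself. Best = max product of edge diffs; shallower depth wins ties."""
    best: Dict[str, Tuple[float, int]] = {}
    frontier = {tf: 1.0}
    for depth in range(1, max_depth + 1):
        nxt: Dict[str, float] = {}
        for node, pscore in frontier.items():
            for child, w in adj.get(node, []):
                s = pscore * w
                if child == tf:
                    continue
                cur = best.get(child)
                if cur is None or s > cur[0]:
                    best[child] = (s, depth)
                if s > nxt.get(child, 0.0):
                    nxt[child] = s
        frontier = nxt
        if not frontier:
            break
    return best


def influence_scores(
    diff_grn: DifferentialGrn,
    de_table: Mapping[str, float],
    max_depth: int = 2,
) -> InfluenceResult:
    """Depth-discounted best-path aggregation of positive fold changes."""
    if not diff_grn.edges:
        raise ValueError("differential GRN is empty")
    if not de_table:
        warnings.warn("empty DE table: all influence scores are 0", stacklevel=2)
    adj: Dict[str, List[Tuple[str, float]]] = {}
    for tf, gene, d in diff_grn.edges:
        adj.setdefault(tf, []).append((gene, d))
    tfs = sorted({tf for tf, _, _ in diff_grn.edges})

    raw: Dict[str, float] = {}
    out_degree: Dict[str, int] = {}
    for tf in tfs:
        paths = _best_paths(adj, tf, max_depth)
        out_degree[tf] = len(paths)
        total = 0.0
        for gene, (pscore, depth) in paths.items():
            fc = max(0.0, float(de_table.get(gene, 0.0)))
            if fc > 0:
                total += pscore * fc / (2 ** (depth - 1))
        raw[tf] = total

    values = np.array([raw[tf] for tf in tfs])
    lo, hi = values.min(), values.max()
    if hi > lo:
        scaled = (values - lo) / (hi - lo)
    elif hi > 0:
        scaled = np.ones_like(values)
    else:
        scaled = np.zeros_like(values)
    influence = {tf: float(s) for tf, s in zip(tfs, scaled)}
    log2fc = {tf: float(de_table.get(tf, 0.0)) for tf in tfs}
    return InfluenceResult(influence, raw, log2fc, out_degree)


def rank_and_plot_data(result: InfluenceResult) -> pd.DataFrame:
    """Per-TF influence / own log2FC / out-degree table, influence-descending.

    This is the data surface behind the influence-vs-fold-change scatterplots.
    """
    df = pd.DataFrame(
        {
            "tf": list(result.influence),
            "influence": [result.influence[t] for t in result.influence],
            "log2fc": [result.log2fc[t] for t in result.influence],
            "out_degree": [result.out_degree[t] for t in result.influence],
        }
    )
    df = df.sort_values(
        ["influence", "tf"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class TemporalClusters:
    k: int
    assignments: Dict[str, int]
    cluster_means: pd.DataFrame  # cluster x timepoint mean influence
    elbow: pd.DataFrame  # columns k, wss


def timecourse_cluster(
    influence_matrix: pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 25,
    k_override: Optional[int] = None,
) -> TemporalClusters:
    """Seeded k-means on the TF x timepoint influence matrix.

    The elbow k is the k with the largest second difference of the
    within-cluster sum of squares curve (overridable via ``k_override``).
    Euclidean on raw influence values, no row scaling.
    """
    X = influence_matrix.to_numpy(dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    wss = {}
    fits = {}
    for k in ks:
        if k > len(X):
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        wss[k] = float(km.inertia_)
        fits[k] = km
    ks = [k for k in ks if k in wss]
    elbow = pd.DataFrame({"k": ks, "wss": [wss[k] for k in ks]})
    if k_override is not None:
        best_k = k_override
    elif len(ks) >= 3:
        curve = np.array([wss[k] for k in ks])
        second_diff = curve[:-2] - 2 * curve[1:-1] + curve[2:]
        best_k = ks[1 + int(np.argmax(second_diff))]
    else:
        best_k = ks[-1]
    km = fits[best_k]
    labels = km.predict(X)
    assignments = dict(zip(influence_matrix.index, (int(l) for l in labels)))
    means = (
        influence_matrix.assign(_cluster=labels).groupby("_cluster").mean()
    )
    means.index.name = "cluster"
    return TemporalClusters(best_k, assignments, means, elbow)


def simple_log2fc(
    expr_source: Mapping[str, float],
    expr_target: Mapping[str, float],
    pseudocount: float = 1.0,
) -> Dict[str, float]:
    """Fallback DE table: log2((target + pc) / (source + pc)) on pooled TPM."""
    genes = set(expr_source) | set(expr_target)
    return {
        g: math.log2(
            (expr_target.get(g, 0.0) + pseudocount)
            / (expr_source.get(g, 0.0) + pseudocount)
        )
        for g in genes
    }


def read_de_table(path: str) -> Dict[str, float]:
    """TSV with columns gene, log2fc[, padj]; genes absent read as 0 downstream."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    fc_col = cols.get("log2fc", cols.get("log2foldchange", df.columns[1]))
    out = dict(zip(df[gene_col].astype(str), df[fc_col].astype(float)))
    if any(not np.isfinite(v) for v in out.values()):
        raise ValueError(f"{path}: non-finite log2FC values")
    return out
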