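"""End-to-end orchestration shared by the CLI, the tests, and the acceptance
report: CTSS -> enhancers -> features -> binding -> GRN -> influence."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bidirectional import (
    BidirectionalRegion,
    call_bidirectional,
    filter_bidirectional,
    normalize_width,
)
from .binding_model import (
    BindingModel,
    best_motif_scores,
    encode_sequence,
    fit_quantile_reference,
    markov_background,
    normalize_cage_feature,
    pfm_to_logodds,
    train_general_model,
)
from .ctss_clustering import (
    CtssProfile,
    GeneExpressionTable,
    filter_tcs,
    pool_profiles,
    prefilter_positions,
    quantify_genes,
    slice_unidirectional,
    tpm_normalize,
)
from .fixtures import TwoStateFixture
from .formats_io import AnnotationRecord, CoverageTrack, CtssRecord, GenomeIndex, MotifRecord
from .grn_inference import (
    GrnEdge,
    build_grn,
    interaction_scores,
    motif_activity,
    weighted_binding_table,
)
from .influence import InfluenceResult, differential_grn, influence_scores, simple_log2fc


@dataclass
class StateData:
    pooled: CtssProfile
    sample_profiles: List[CtssProfile]
    regions: List[BidirectionalRegion]
    expression: GeneExpressionTable


def process_state(
    replicate_records: Sequence[Sequence[CtssRecord]],
    annotation: Sequence[AnnotationRecord],
    *,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    position_floor_tpm: float = 0.1,
    max_gap: int = 20,
    min_support: int = 2,
    min_pooled_tpm: float = 1.0,
    window: int = 201,
    balance_threshold: float = 0.95,
    assignment_window: int = 500,
    sample_ids: Optional[Sequence[str]] = None,
) -> StateData:
    """Normalize, pool, call and filter enhancers, and quantify genes."""
    profiles = []
    for i, recs in enumerate(replicate_records):
        sid = sample_ids[i] if sample_ids else (recs[0].sample if recs else f"s{i}")
        profiles.append(tpm_normalize(CtssProfile.from_records(recs, sample_id=sid)))
    pooled = prefilter_positions(pool_profiles(profiles), position_floor_tpm)
    regions = call_bidirectional(
        pooled, window=window, balance_threshold=balance_threshold, max_gap=max_gap
    )
    regions = filter_bidirectional(regions, profiles, min_support=min_support)
    regions = normalize_width(regions, chrom_lengths=chrom_lengths)
    clusters = filter_tcs(
        slice_unidirectional(pooled, max_gap=max_gap),
        min_support=min_support,
        min_pooled_tpm=min_pooled_tpm,
    )
    expression = quantify_genes(
        clusters, annotation, assignment_window=assignment_window,
        per_sample_profiles=profiles,
    )
    return StateData(pooled, profiles, regions, expression)


def compute_features(
    regions: Sequence[BidirectionalRegion],
    genome: GenomeIndex,
    motifs: Sequence[MotifRecord],
    motif2tf: Mapping[str, Sequence[str]],
    coverage: Optional[CoverageTrack] = None,
    cage_reference: Optional[np.ndarray] = None,
    n_background: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(TF, region) feature rows: S, E_CAGE, E_ChIP (+ per-motif z)."""
    tpm_vec = np.array([r.tpm for r in regions])
    ref = cage_reference if cage_reference is not None else fit_quantile_reference(tpm_vec)
    e_cage = normalize_cage_feature(tpm_vec, ref)

    zmat = np.zeros((len(regions), len(motifs)))
    rng = np.random.default_rng(seed)
    for i, r in enumerate(regions):
        start, end = r.interval
        encoded = encode_sequence(genome.fetch(r.chrom, start, end))
        bg = markov_background(encoded, n_background, rng)
        for j, m in enumerate(motifs):
            lo = pfm_to_logodds(m.pfm)
            obs = float(best_motif_scores(lo, encoded)[0])
            bgs = best_motif_scores(lo, bg)
            zmat[i, j] = (obs - float(bgs.mean())) / max(float(bgs.std()), 1e-8)

    tf_motifs: Dict[str, List[int]] = {}
    for j, m in enumerate(motifs):
        for tf in motif2tf.get(m.motif_id, m.tfs):
            tf_motifs.setdefault(tf, []).append(j)

    rows = []
    for i, r in enumerate(regions):
        start, end = r.interval
        chip = (
            np.log1p(coverage.mean(r.chrom, start, end)) if coverage is not None else 0.0
        )
        for tf, cols in sorted(tf_motifs.items()):
            rows.append(
                (tf, r.region_id, r.chrom, float(zmat[i, cols].max()),
                 float(e_cage[i]), float(chip))
            )
    df = pd.DataFrame(
        rows, columns=["tf", "region_id", "chrom", "S", "E_CAGE", "E_ChIP"]
    )
    df.attrs["zmat"] = zmat
    df.attrs["motif_ids"] = [m.motif_id for m in motifs]
    return df


def state_grn(
    state: StateData,
    features: pd.DataFrame,
    model: BindingModel,
    annotation: Sequence[AnnotationRecord],
    motif2tf: Mapping[str, Sequence[str]],
    top_n: int = 500_000,
    activity_alpha: float = 1.0,
    seed: int = 0,
) -> List[GrnEdge]:
    """Binding probabilities -> weighted binding -> interaction scores -> GRN."""
    probs = model.predict(features[["S", "E_CAGE", "E_ChIP"]].to_numpy(dtype=float))
    binding = features[["tf", "region_id"]].copy()
    binding["prob"] = probs

    region_mid = {r.region_id: (r.chrom, r.mid) for r in state.regions}
    gene_tss = {a.gene: (a.chrom, a.tss) for a in annotation}
    wb = weighted_binding_table(binding, region_mid, gene_tss)

    zmat = features.attrs["zmat"]
    motif_ids = features.attrs["motif_ids"]
    intensity = np.array([r.tpm for r in state.regions])
    activity = motif_activity(
        intensity, zmat, motif_ids, motif2tf, alpha=activity_alpha, seed=seed
    )
    edges = interaction_scores(state.expression.pooled_tpm, wb, activity)
    return build_grn(edges, top_n=top_n)


def two_state_influence(
    fix: TwoStateFixture,
    seed: int = 0,
    n_background: int = 100,
    max_depth: int = 2,
    top_n: int = 500_000,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full A->B and B->A influence rankings on a two-state fixture.

    The binding model is a general model trained on state A's called regions
    with planted-ownership labels from the fixture truth.
    """
    from .influence import rank_and_plot_data

    chrom_lengths = fix.genome.chrom_lengths
    state_a = process_state(fix.records_a, fix.annotation, chrom_lengths=chrom_lengths)
    state_b = process_state(fix.records_b, fix.annotation, chrom_lengths=chrom_lengths)

    motif2tf = dict(fix.motif2tf)
    feats_a = compute_features(
        state_a.regions, fix.genome, fix.motifs, motif2tf,
        coverage=fix.coverage, n_background=n_background, seed=seed,
    )
    feats_b = compute_features(
        state_b.regions, fix.genome, fix.motifs, motif2tf,
        coverage=fix.coverage, n_background=n_background, seed=seed + 1,
    )
    labels = _planted_labels(feats_a, state_a.regions, fix)
    train = feats_a.merge(labels, on=["tf", "region_id"])
    model = train_general_model(train, seed=seed)

    grn_a = state_grn(
        state_a, feats_a, model, fix.annotation, motif2tf, top_n=top_n, seed=seed
    )
    grn_b = state_grn(
        state_b, feats_b, model, fix.annotation, motif2tf, top_n=top_n, seed=seed
    )

    de_ab = simple_log2fc(state_a.expression.pooled_tpm, state_b.expression.pooled_tpm)
    de_ba = simple_log2fc(state_b.expression.pooled_tpm, state_a.expression.pooled_tpm)

    res_ab = influence_scores(
        differential_grn(grn_a, grn_b, top_n=top_n), de_ab, max_depth=max_depth
    )
    res_ba = influence_scores(
        differential_grn(grn_b, grn_a, top_n=top_n), de_ba, max_depth=max_depth
    )
    return rank_and_plot_data(res_ab), rank_and_plot_data(res_ba)


def _planted_labels(
    features: pd.DataFrame, regions: Sequence[BidirectionalRegion], fix: TwoStateFixture
) -> pd.DataFrame:
    """Label (tf, region) = 1 iff the region sits at a planted enhancer owned
    by that TF (truth table lookup, tolerance 100 bp)."""
    owner_of = {}
    for r in regions:
        best = None
        for t in fix.enhancer_truth:
            if t["chrom"] != r.chrom:
                continue
            d = abs(r.mid - t["mid"])
            if d <= 100 and (best is None or d < best[0]):
                best = (d, t["owner"])
        owner_of[r.region_id] = best[1] if best else None
    rows = [
        (tf, rid, int(owner_of.get(rid) == tf))
        for tf, rid in zip(features["tf"], features["region_id"])
    ]
    return pd.DataFrame(rows, columns=["tf", "region_id", "label"]).drop_duplicates()
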