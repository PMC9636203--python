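"""Deterministic synthetic genomes, CTSS tags, motifs, labels and coverage.

Everything here is a pure function of (spec, seed): identical inputs give
byte-identical outputs, and each generator emits a truth table sufficient to
compute exact precision/recall for the pipeline stage it feeds.

Geometry: genes sit on a regular grid of slots; each planted enhancer sits
3.5 kb downstream of a gene TSS, with divergent tag arms at +/- ``arm_offset``
around its midpoint. A balance fraction of 0.5 gives perfectly balanced arms
(balance score 1.0 at the midpoint); 1.0 puts all tags on the plus arm
(score sqrt(0.5), rejected at the 0.95 threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats_io import (
    AnnotationRecord,
    CoverageTrack,
    CtssRecord,
    GenomeIndex,
    MotifRecord,
)

__all__ = [
    "FixtureSpec",
    "TwoStateFixture",
    "make_genome",
    "make_motifs",
    "make_ctss",
    "make_binding_truth",
    "make_logistic_dataset",
    "make_feature_suite",
    "make_timecourse",
    "make_two_state",
]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc: float = 0.5
    n_genes: int = 60
    gene_length: int = 2_000
    n_enhancers: int = 40
    arm_offset: int = 60
    arm_tags: int = 50
    balance_fraction: float = 0.5  # fraction of enhancer tags on the plus arm
    n_tfs: int = 8
    motif_width: int = 10
    motif_plant_prob: float = 1.0
    n_replicates: int = 3
    poisson_noise: bool = False
    beta: Tuple[float, float, float] = (1.5, 0.8, 2.0)
    intercept: float = -1.0
    # two-state design
    n_driver_tfs: int = 2
    n_targets_per_tf: int = 2
    unit_spacing: int = 7_000


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _tf_name(i: int) -> str:
    return f"TF{i:02d}"


def _consensus_pfm(consensus: str, strength: float = 0.91) -> np.ndarray:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(consensus)
    pfm = np.full((4, w), (1 - strength) / 3 * 100)
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = strength * 100
    return pfm


def make_motifs(spec: FixtureSpec, n_tfs: Optional[int] = None) -> Tuple[
    List[MotifRecord], Dict[str, List[str]], Dict[str, str]
]:
    """One strong motif per TF; returns (motifs, motif2tf, tf->consensus)."""
    rng = np.random.default_rng([spec.seed, 11])
    n = n_tfs if n_tfs is not None else spec.n_tfs
    motifs, motif2tf, consensus = [], {}, {}
    for i in range(n):
        tf = _tf_name(i)
        cons = "".join(_BASES[rng.integers(0, 4, size=spec.motif_width)])
        mid = f"M{i:02d}"
        motifs.append(MotifRecord(mid, [tf], _consensus_pfm(cons)))
        motif2tf[mid] = [tf]
        consensus[tf] = cons
    return motifs, motif2tf, consensus


@dataclass
class _Layout:
    genes: List[AnnotationRecord]
    enhancers: List[Tuple[str, int, str, bool]]  # (chrom, mid, owner TF, planted)


def _build_layout(spec: FixtureSpec, rng: np.random.Generator) -> _Layout:
    genes: List[AnnotationRecord] = []
    per_chrom = -(-spec.n_genes // spec.n_chroms)
    for i in range(spec.n_genes):
        chrom = f"chr{i % spec.n_chroms + 1}"
        slot = 10_000 + (i // spec.n_chroms) * spec.unit_spacing
        strand = "+" if i % 3 else "-"
        if strand == "+":
            start, end, tss = slot, slot + spec.gene_length, slot
        else:
            start, end, tss = slot - spec.gene_length + 1, slot + 1, slot
        # the first n_tfs genes are the TF-coding genes (gene id == TF name)
        gene = _tf_name(i) if i < spec.n_tfs else f"G{i:03d}"
        genes.append(AnnotationRecord(gene, chrom, strand, tss, start, end))
    if spec.n_enhancers > spec.n_genes:
        raise ValueError("layout requires n_enhancers <= n_genes")
    enhancers = []
    for j in range(spec.n_enhancers):
        g = genes[j]
        mid = g.tss + 3_500
        owner = _tf_name(j % spec.n_tfs)
        planted = bool(rng.random() < spec.motif_plant_prob)
        enhancers.append((g.chrom, mid, owner, planted))
    return _Layout(genes, enhancers)


def make_genome(spec: FixtureSpec) -> Tuple[GenomeIndex, List[AnnotationRecord], Dict]:
    """Random genome with planted motif consensus at enhancer midpoints."""
    rng = np.random.default_rng([spec.seed, 1])
    seqs = {
        f"chr{c + 1}": _random_sequence(rng, spec.chrom_length, spec.gc)
        for c in range(spec.n_chroms)
    }
    layout = _build_layout(spec, np.random.default_rng([spec.seed, 2]))
    _, _, consensus = make_motifs(spec)
    for chrom, mid, owner, planted in layout.enhancers:
        if planted:
            cons = consensus[owner]
            lo = mid - len(cons) // 2
            seqs[chrom] = seqs[chrom][:lo] + cons + seqs[chrom][lo + len(cons) :]
    genome = GenomeIndex(seqs)
    truth = {
        "genes": [(a.gene, a.chrom, a.tss, a.strand) for a in layout.genes],
        "enhancers": [
            {"chrom": c, "mid": m, "owner": o, "planted": p}
            for c, m, o, p in layout.enhancers
        ],
    }
    return genome, layout.genes, truth


def _emit_tss_tags(
    out: List[CtssRecord],
    gene: AnnotationRecord,
    level: float,
    sample: str,
    rng: np.random.Generator,
    noise: bool,
) -> None:
    offsets = [0, 2, 5, 9]
    weights = [4, 3, 2, 1]
    sign = 1 if gene.strand == "+" else -1
    for off, w in zip(offsets, weights):
        mean = level * w
        count = int(rng.poisson(mean)) if noise else int(round(mean))
        if count > 0:
            out.append(
                CtssRecord(gene.chrom, gene.tss + sign * off, gene.strand, count, sample)
            )


def _emit_enhancer_tags(
    out: List[CtssRecord],
    chrom: str,
    mid: int,
    spec: FixtureSpec,
    sample: str,
    rng: np.random.Generator,
    noise: bool,
    level: float = 1.0,
) -> None:
    total = 2 * int(round(spec.arm_tags * level))  # even, so 0.5 splits exactly
    plus_total = int(round(total * spec.balance_fraction))
    minus_total = total - plus_total
    placements = [
        (mid - spec.arm_offset, "-", minus_total - minus_total // 2),
        (mid - spec.arm_offset - 4, "-", minus_total // 2),
        (mid + spec.arm_offset, "+", plus_total - plus_total // 2),
        (mid + spec.arm_offset + 4, "+", plus_total // 2),
    ]
    for pos, strand, mean in placements:
        count = int(rng.poisson(mean)) if noise else int(mean)
        if count > 0:
            out.append(CtssRecord(chrom, pos, strand, count, sample))


def make_ctss(spec: FixtureSpec, state: str = "A") -> Tuple[List[List[CtssRecord]], Dict]:
    """Per-replicate CTSS records: TSS clusters for every gene, divergent arms
    at every planted enhancer."""
    layout = _build_layout(spec, np.random.default_rng([spec.seed, 2]))
    rng = np.random.default_rng([spec.seed, 3, sum(map(ord, state))])
    replicates: List[List[CtssRecord]] = []
    for rep in range(spec.n_replicates):
        sample = f"{state}_rep{rep + 1}"
        records: List[CtssRecord] = []
        for g in layout.genes:
            _emit_tss_tags(records, g, 10.0, sample, rng, spec.poisson_noise)
        for j, (chrom, mid, _owner, _planted) in enumerate(layout.enhancers):
            _emit_enhancer_tags(
                records, chrom, mid, spec, sample, rng, spec.poisson_noise,
                level=1.0 + (j % 4) * 0.25,
            )
        replicates.append(records)
    truth = {
        "tss": [(g.chrom, g.tss, g.strand) for g in layout.genes],
        "enhancer_mids": [(c, m) for c, m, _, _ in layout.enhancers],
    }
    return replicates, truth


def make_binding_truth(
    spec: FixtureSpec, regions: Sequence, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, CoverageTrack]:
    """Labels drawn from the logistic model applied to true features.

    Per (TF, region): S ~ N(4, 0.5) when the TF's motif is planted there else
    N(0, 1); E_CAGE = standardized log(1+region TPM); E_ChIP ~ N(0, 1) latent
    written out as a coverage track over the region.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    layout = _build_layout(spec, np.random.default_rng([spec.seed, 2]))
    owner_at = {(c, m): (o, p) for c, m, o, p in layout.enhancers}
    b1, b2, b3 = spec.beta
    tpms = np.log1p([r.tpm for r in regions])
    e_cage_all = (tpms - tpms.mean()) / (tpms.std() or 1.0)
    rows = []
    cov_rows = []
    for idx, r in enumerate(regions):
        nearest = min(
            (abs(r.mid - m), (c, m))
            for c, m, _, _ in layout.enhancers
            if c == r.chrom
        ) if any(c == r.chrom for c, _, _, _ in layout.enhancers) else (10**9, None)
        owner = None
        if nearest[0] <= 100:
            owner, planted = owner_at[nearest[1]]
            if not planted:
                owner = None
        e_chip = float(rng.normal())
        start, end = r.interval
        cov_rows.append((r.chrom, start, end, float(np.exp(e_chip))))
        for i in range(spec.n_tfs):
            tf = _tf_name(i)
            s = float(rng.normal(4.0, 0.5)) if tf == owner else float(rng.normal())
            logit = b1 * s + b2 * e_cage_all[idx] + b3 * e_chip + spec.intercept
            p = 1.0 / (1.0 + np.exp(-logit))
            rows.append(
                (tf, r.region_id, s, float(e_cage_all[idx]), e_chip, p,
                 int(rng.random() < p))
            )
    labels = pd.DataFrame(
        rows, columns=["tf", "region_id", "S", "E_CAGE", "E_ChIP", "p_true", "label"]
    )
    return labels, CoverageTrack.from_intervals(cov_rows)


def make_logistic_dataset(
    beta: Sequence[float] = (1.5, 0.8, 2.0),
    intercept: float = -1.0,
    n: int = 5000,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Standard-normal features, Bernoulli labels from the logistic model."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta) + intercept)))
    y = (rng.random(n) < p).astype(int)
    return X, y


def make_feature_suite(
    n_tfs: int = 20,
    n_per_cell: int = 400,
    n_chroms: int = 5,
    n_cell_types: int = 3,
    beta: Sequence[float] = (1.5, 0.8, 2.0),
    intercept: float = -1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy (tf, cell_type, chrom) feature/label table from the logistic
    generative model, for the cross-validation harness."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_tfs):
        tf = _tf_name(i)
        for ct in range(n_cell_types):
            X = rng.normal(size=(n_per_cell, 3))
            p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta) + intercept)))
            y = (rng.random(n_per_cell) < p).astype(int)
            chroms = [f"chr{j % n_chroms + 1}" for j in range(n_per_cell)]
            for j in range(n_per_cell):
                rows.append(
                    (tf, f"ct{ct}", chroms[j], X[j, 0], X[j, 1], X[j, 2], y[j])
                )
    return pd.DataFrame(
        rows, columns=["tf", "cell_type", "chrom", "S", "E_CAGE", "E_ChIP", "label"]
    )


def make_timecourse(
    n_per_group: int = 15,
    seed: int = 0,
    noise_sd: float = 0.03,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Two well-separated temporal influence profiles (planted partition)."""
    rng = np.random.default_rng(seed)
    profiles = {0: np.array([0.9, 0.5, 0.1]), 1: np.array([0.05, 0.45, 0.95])}
    rows, truth = [], {}
    for grp, base in profiles.items():
        for i in range(n_per_group):
            tf = f"{_tf_name(grp * n_per_group + i)}"
            rows.append(base + rng.normal(0, noise_sd, size=len(base)))
            truth[tf] = grp
    df = pd.DataFrame(
        rows,
        index=list(truth),
        columns=[f"t{j}" for j in range(len(profiles[0]))],
    )
    return df, truth


# -- two-state design ------------------------------------------------------


@dataclass
class TwoStateFixture:
    genome: GenomeIndex
    annotation: List[AnnotationRecord]
    motifs: List[MotifRecord]
    motif2tf: Dict[str, List[str]]
    records_a: List[List[CtssRecord]]
    records_b: List[List[CtssRecord]]
    drivers: List[str]
    tfs: List[str]
    coverage: CoverageTrack
    enhancer_truth: List[Dict]  # chrom, mid, owner, state


def make_two_state(spec: Optional[FixtureSpec] = None) -> TwoStateFixture:
    """Two cell states sharing a genome.

    State A transcribes the enhancers and target genes of the 12 background
    TFs; state B silences those and instead transcribes driver-TF enhancers
    (carrying the drivers' motifs) next to driver target genes, which are
    strongly upregulated. Drivers' own genes are also upregulated in B.
    """
    spec = spec or FixtureSpec()
    n_tfs = max(spec.n_tfs, 14)
    n_drv = spec.n_driver_tfs
    tfs = [_tf_name(i) for i in range(n_tfs)]
    drivers = tfs[:n_drv]
    motifs, motif2tf, consensus = make_motifs(spec, n_tfs=n_tfs)

    rng = np.random.default_rng([spec.seed, 21])
    seqs = {
        "chr1": _random_sequence(rng, spec.chrom_length, spec.gc),
        "chr2": _random_sequence(rng, spec.chrom_length, spec.gc),
    }

    annotation: List[AnnotationRecord] = []
    for i, tf in enumerate(tfs):  # TF genes on chr1, gene id == TF name
        tss = 10_000 + i * 12_000
        annotation.append(
            AnnotationRecord(tf, "chr1", "+", tss, tss, tss + spec.gene_length)
        )
    targets: Dict[str, List[AnnotationRecord]] = {tf: [] for tf in tfs}
    enhancers: List[Tuple[str, int, str]] = []  # (chrom, mid, owner)
    slot = 0
    for i, tf in enumerate(tfs):
        for j in range(spec.n_targets_per_tf):
            tss = 10_000 + slot * 10_000
            slot += 1
            gene = f"TG{i:02d}_{j}"
            rec = AnnotationRecord(gene, "chr2", "+", tss, tss, tss + spec.gene_length)
            annotation.append(rec)
            targets[tf].append(rec)
            mid = tss + 3_000
            cons = consensus[tf]
            lo = mid - len(cons) // 2
            seqs["chr2"] = seqs["chr2"][:lo] + cons + seqs["chr2"][lo + len(cons) :]
            enhancers.append(("chr2", mid, tf))
    genome = GenomeIndex(seqs)

    def build_state(state: str) -> List[List[CtssRecord]]:
        srng = np.random.default_rng([spec.seed, 22, sum(map(ord, state))])
        reps = []
        for rep in range(spec.n_replicates):
            sample = f"{state}_rep{rep + 1}"
            records: List[CtssRecord] = []
            for i, tf in enumerate(tfs):
                is_driver = tf in drivers
                level = (
                    40.0 if (is_driver and state == "B") else 10.0
                )  # driver TF genes up in B
                _emit_tss_tags(
                    records, annotation[i], level, sample, srng, spec.poisson_noise
                )
            for tf in tfs:
                is_driver = tf in drivers
                active_state = "B" if is_driver else "A"
                target_level = 40.0 if state == active_state else 2.0
                for rec in targets[tf]:
                    _emit_tss_tags(
                        records, rec, target_level, sample, srng, spec.poisson_noise
                    )
            for j, (chrom, mid, owner) in enumerate(enhancers):
                active_state = "B" if owner in drivers else "A"
                if state == active_state:
                    _emit_enhancer_tags(
                        records, chrom, mid, spec, sample, srng, spec.poisson_noise,
                        level=1.0 + (j % 4) * 0.25,
                    )
            reps.append(records)
        return reps

    cov_rows = [(c, m - 100, m + 100, 5.0) for c, m, _ in enhancers]
    truth = [
        {
            "chrom": c,
            "mid": m,
            "owner": o,
            "state": "B" if o in drivers else "A",
        }
        for c, m, o in enhancers
    ]
    return TwoStateFixture(
        genome=genome,
        annotation=annotation,
        motifs=motifs,
        motif2tf=motif2tf,
        records_a=build_state("A"),
        records_b=build_state("B"),
        drivers=drivers,
        tfs=tfs,
        coverage=CoverageTrack.from_intervals(cov_rows),
        enhancer_truth=truth,
    )
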