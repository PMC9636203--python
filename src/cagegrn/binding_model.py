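"""Per-(TF, enhancer) feature construction and logistic binding models.

Features, one row per (TF, enhancer):

* ``S`` — highest motif z-score over the TF's motifs. A motif's score on a
  sequence is the best log-odds sum over all offsets and both strands; the
  z-score standardizes it against best scores on GC-matched background
  sequences sampled from a first-order Markov chain fitted on the sequence.
* ``E_CAGE`` — log(1+TPM) of the bidirectional region, quantile-mapped onto a
  persisted reference distribution.
* ``E_ChIP`` — log(1+mean curated ChIP coverage) over the 200-bp region.

The model is a standard L2 logistic regression on standardized features:
log p/(1-p) = b1*S + b2*E_CAGE + b3*E_ChIP (+ intercept). PR AUC is the
average-precision estimator; a constant predictor scores the positive
prevalence by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .bidirectional import BidirectionalRegion
from .formats_io import IntervalSet, MotifRecord

__all__ = [
    "BindingModel",
    "encode_sequence",
    "pfm_to_logodds",
    "best_motif_scores",
    "markov_background",
    "motif_zscore",
    "fit_quantile_reference",
    "normalize_cage_feature",
    "quantile_normalize",
    "label_enhancers",
    "train_tf_model",
    "train_general_model",
    "predict_binding",
    "pr_auc",
    "crossval_pr_auc",
    "wilcoxon_vs_baseline",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3 as int8; ambiguous bases map to A (fixtures emit none)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def pfm_to_logodds(
    pfm: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.1,
) -> np.ndarray:
    pfm = np.asarray(pfm, dtype=float)
    col = pfm.sum(axis=0)
    freqs = (pfm + pseudocount) / (col + 4 * pseudocount)
    return np.log2(freqs / np.asarray(background)[:, None])


def _revcomp_logodds(lo: np.ndarray) -> np.ndarray:
    return lo[::-1, ::-1]


def best_motif_scores(logodds: np.ndarray, seq_matrix: np.ndarray) -> np.ndarray:
    """Best log-odds score per row of an (n, L) encoded-sequence matrix,
    maximized over all offsets and both strands."""
    w = logodds.shape[1]
    if seq_matrix.ndim == 1:
        seq_matrix = seq_matrix[None, :]
    n, L = seq_matrix.shape
    if L < w:
        raise ValueError(f"sequence length {L} shorter than motif width {w}")
    windows = np.lib.stride_tricks.sliding_window_view(seq_matrix, w, axis=1)
    cols = np.arange(w)
    best = np.full(n, -np.inf)
    for lo in (logodds, _revcomp_logodds(logodds)):
        scores = lo[windows, cols].sum(axis=-1)
        best = np.maximum(best, scores.max(axis=1))
    return best


def markov_background(
    encoded: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n sequences of equal length from a first-order Markov chain
    fitted on ``encoded`` (preserves GC and dinucleotide statistics in
    expectation)."""
    L = len(encoded)
    counts = np.full((4, 4), 0.1)  # small smoothing keeps the chain ergodic
    np.add.at(counts, (encoded[:-1], encoded[1:]), 1)
    trans = counts / counts.sum(axis=1, keepdims=True)
    cum = np.cumsum(trans, axis=1)
    out = np.empty((n, L), dtype=np.int8)
    start_freq = np.bincount(encoded, minlength=4) / L
    out[:, 0] = rng.choice(4, size=n, p=start_freq)
    u = rng.random((n, L - 1))
    for j in range(1, L):
        out[:, j] = (cum[out[:, j - 1]] < u[:, j - 1 : j]).sum(axis=1)
    return out


def motif_zscore(
    sequence: str,
    motifs_for_tf: Sequence[MotifRecord],
    n_background: int = 1000,
    seed: int = 0,
    background_matrix: Optional[np.ndarray] = None,
) -> float:
    """S_f,l: max over the TF's motifs of the standardized best motif score.

    ``background_matrix`` lets callers share one sampled background batch per
    sequence across many motifs.
    """
    if not motifs_for_tf:
        raise ValueError("TF has no mapped motifs")
    encoded = encode_sequence(sequence)
    if background_matrix is None:
        rng = np.random.default_rng(seed)
        background_matrix = markov_background(encoded, n_background, rng)
    best_z = -np.inf
    for m in motifs_for_tf:
        if m.width > len(encoded):
            raise ValueError(
                f"motif {m.motif_id} wider ({m.width}) than sequence ({len(encoded)})"
            )
        lo = pfm_to_logodds(m.pfm)
        obs = float(best_motif_scores(lo, encoded)[0])
        bg = best_motif_scores(lo, background_matrix)
        sd = float(bg.std())
        z = (obs - float(bg.mean())) / max(sd, 1e-8)
        best_z = max(best_z, z)
    return best_z


# -- E_CAGE quantile normalization ---------------------------------------


def fit_quantile_reference(tpm_matrix: np.ndarray) -> np.ndarray:
    """Reference distribution = mean across columns of sorted log(1+TPM)."""
    x = np.log1p(np.asarray(tpm_matrix, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    return np.sort(x, axis=0).mean(axis=1)


def normalize_cage_feature(
    tpm_vector: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """log(1+x), then map each value by rank quantile onto the reference.

    Monotone within a sample; a vector whose length matches the reference is
    mapped exactly to the reference order statistics (classic quantile
    normalization), ties receiving the mean of their reference slots.
    """
    x = np.log1p(np.asarray(tpm_vector, dtype=float))
    m = len(x)
    ref = np.asarray(reference, dtype=float)
    order = np.argsort(x, kind="stable")
    # average ranks over ties so equal inputs map to equal outputs
    _, inv = np.unique(x[order], return_inverse=True)
    mean_rank_per_value = np.bincount(inv, weights=np.arange(m)) / np.bincount(inv)
    ranks = np.empty(m)
    ranks[order] = mean_rank_per_value[inv]
    if m == len(ref):
        return np.interp(ranks, np.arange(len(ref)), ref)
    q = (ranks + 0.5) / m
    ref_q = (np.arange(len(ref)) + 0.5) / len(ref)
    return np.interp(q, ref_q, ref)


def quantile_normalize(tpm_matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Columnwise quantile normalization of log(1+TPM); returns (matrix, ref)."""
    x = np.asarray(tpm_matrix, dtype=float)
    ref = fit_quantile_reference(x)
    out = np.column_stack(
        [normalize_cage_feature(x[:, j], ref) for j in range(x.shape[1])]
    )
    return out, ref


# -- labels ---------------------------------------------------------------


def label_enhancers(
    regions: Sequence[BidirectionalRegion],
    chip_peaks: Mapping[str, IntervalSet],
) -> pd.DataFrame:
    """Binary labels: 1 iff the normalized region overlaps (>= 1 bp) any peak
    of that TF. Raises KeyError for a TF with no peak set — callers route such
    TFs to the general model."""
    rows = []
    for tf in sorted(chip_peaks):
        peaks = chip_peaks[tf]
        if peaks is None:
            raise KeyError(f"no peak file for TF {tf}")
        for r in regions:
            start, end = r.interval
            ivs = peaks.get(r.chrom)
            hit = bool(
                ivs is not None
                and len(ivs)
                and ((ivs[:, 0] < end) & (ivs[:, 1] > start)).any()
            )
            rows.append((tf, r.region_id, int(hit)))
    return pd.DataFrame(rows, columns=["tf", "region_id", "label"])


# -- model ----------------------------------------------------------------


@dataclass
class BindingModel:
    """Logistic binding model with its feature standardization state."""

    tf: str
    feature_names: List[str]
    coef: np.ndarray  # on the standardized scale
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cage_reference: Optional[np.ndarray] = None
    assembly: str = ""
    metadata: Dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        z = (X - self.scaler_mean) / self.scaler_scale
        logit = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def to_dict(self) -> Dict:
        return {
            "tf": self.tf,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "cage_reference": (
                self.cage_reference.tolist() if self.cage_reference is not None else None
            ),
            "assembly": self.assembly,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "BindingModel":
        return cls(
            tf=d["tf"],
            feature_names=list(d["feature_names"]),
            coef=np.array(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            scaler_mean=np.array(d["scaler_mean"], dtype=float),
            scaler_scale=np.array(d["scaler_scale"], dtype=float),
            cage_reference=(
                np.array(d["cage_reference"], dtype=float)
                if d.get("cage_reference") is not None
                else None
            ),
            assembly=d.get("assembly", ""),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "BindingModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_tf_model(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] = ("S", "E_CAGE", "E_ChIP"),
    tf: str = "",
    C: float = 1.0,
    seed: int = 0,
) -> BindingModel:
    """L2 logistic regression on standardized features; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels are single-class ({classes.tolist()})")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    # guard against effectively-constant features (float noise around 0 sd)
    scale[scale <= 1e-8 * np.maximum(1.0, np.abs(mean))] = 1.0
    Xs = (X - mean) / scale
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(Xs, y)
    return BindingModel(
        tf=tf or "general",
        feature_names=list(feature_names),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
    )


def train_general_model(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = ("S", "E_CAGE", "E_ChIP"),
    label_col: str = "label",
    C: float = 1.0,
    seed: int = 0,
) -> BindingModel:
    """One model over pooled (TF, enhancer) rows; applied to any TF lacking
    its own trained model."""
    X = features[list(feature_cols)].to_numpy(dtype=float)
    y = features[label_col].to_numpy()
    return train_tf_model(X, y, feature_names=feature_cols, tf="general", C=C, seed=seed)


def predict_binding(model: BindingModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def pr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    return float(average_precision_score(y_true, scores))


def crossval_pr_auc(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = ("S", "E_CAGE", "E_ChIP"),
    scheme: str = "chromosome",
    label_col: str = "label",
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out cross-validated PR AUC per TF.

    scheme="chromosome": per-TF models, folds = chromosomes (train on the
    others, evaluate on the held-out chromosome).
    scheme="celltype": one general model per fold, trained on all rows from
    the other cell types and evaluated per TF on the held-out cell type.

    Returns columns: tf, fold, pr_auc, baseline (positive prevalence of the
    evaluation set). Folds whose evaluation set is single-class, or whose
    training set is single-class, are skipped.
    """
    rows = []
    if scheme == "chromosome":
        for tf, sub in features.groupby("tf", sort=True):
            for chrom in sorted(sub["chrom"].unique()):
                train = sub[sub["chrom"] != chrom]
                test = sub[sub["chrom"] == chrom]
                ytr = train[label_col].to_numpy()
                yte = test[label_col].to_numpy()
                if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
                    continue
                model = train_tf_model(
                    train[list(feature_cols)].to_numpy(dtype=float),
                    ytr,
                    feature_names=feature_cols,
                    tf=str(tf),
                    C=C,
                    seed=seed,
                )
                p = model.predict(test[list(feature_cols)].to_numpy(dtype=float))
                rows.append((tf, chrom, pr_auc(yte, p), float(yte.mean())))
    elif scheme == "celltype":
        for ct in sorted(features["cell_type"].unique()):
            train = features[features["cell_type"] != ct]
            test = features[features["cell_type"] == ct]
            ytr = train[label_col].to_numpy()
            if len(np.unique(ytr)) < 2:
                continue
            model = train_general_model(
                train, feature_cols=feature_cols, label_col=label_col, C=C, seed=seed
            )
            for tf, sub in test.groupby("tf", sort=True):
                yte = sub[label_col].to_numpy()
                if len(np.unique(yte)) < 2:
                    continue
                p = model.predict(sub[list(feature_cols)].to_numpy(dtype=float))
                rows.append((tf, ct, pr_auc(yte, p), float(yte.mean())))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(rows, columns=["tf", "fold", "pr_auc", "baseline"])


def wilcoxon_vs_baseline(prauc_table: pd.DataFrame) -> Tuple[float, float]:
    """Paired two-sided signed-rank test of per-TF mean PR AUC vs baseline."""
    per_tf = prauc_table.groupby("tf")[["pr_auc", "baseline"]].mean()
    stat, p = wilcoxon(per_tf["pr_auc"], per_tf["baseline"])
    return float(stat), float(p)
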