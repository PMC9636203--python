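import math

import numpy as np
import pandas as pd
import pytest

from cagegrn.binding_model import (
    BindingModel,
    best_motif_scores,
    crossval_pr_auc,
    encode_sequence,
    fit_quantile_reference,
    label_enhancers,
    markov_background,
    motif_zscore,
    normalize_cage_feature,
    pfm_to_logodds,
    pr_auc,
    predict_binding,
    quantile_normalize,
    train_general_model,
    train_tf_model,
    wilcoxon_vs_baseline,
)
from cagegrn.bidirectional import BidirectionalRegion
from cagegrn.fixtures import make_logistic_dataset
from cagegrn.formats_io import MotifRecord, intervals_from_tuples


def _consensus_motif(consensus, motif_id="M1", tf="TFX"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pfm = np.full((4, len(consensus)), 3.0)
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = 91.0
    return MotifRecord(motif_id, [tf], pfm)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# -- motif z-scores -------------------------------------------------------


def test_planted_consensus_scores_high():
    rng = np.random.default_rng(5)
    cons = "ACGTGACGTGAC"  # 12-bp motif
    motif = _consensus_motif(cons)
    seq = _random_seq(rng, 94) + cons + _random_seq(rng, 94)
    z = motif_zscore(seq, [motif], n_background=300, seed=1)
    assert z > 3


def test_background_sequence_scores_near_zero():
    rng = np.random.default_rng(6)
    motif = _consensus_motif("ACGTGACGTGAC")
    zs = [
        motif_zscore(_random_seq(rng, 200), [motif], n_background=200, seed=i)
        for i in range(20)
    ]
    assert np.mean(np.abs(np.array(zs) < 3)) >= 0.9


def test_motif_wider_than_region_errors():
    motif = _consensus_motif("ACGTACGTACGTACGT")
    with pytest.raises(ValueError, match="wider"):
        motif_zscore("ACGTACG", [motif])


def test_no_motifs_errors():
    with pytest.raises(ValueError, match="no mapped motifs"):
        motif_zscore("ACGTACGT", [])


def test_reverse_strand_scanning():
    cons = "AAACCCGGGTTT"
    motif = _consensus_motif(cons)
    lo = pfm_to_logodds(motif.pfm)
    fwd = best_motif_scores(lo, encode_sequence(cons))[0]
    rc = cons[::-1].translate(str.maketrans("ACGT", "TGCA"))
    rev = best_motif_scores(lo, encode_sequence(rc))[0]
    assert fwd == pytest.approx(rev)


def test_markov_background_preserves_gc():
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGT"))
    seq = encode_sequence(
        "".join(rng.choice(bases, size=500, p=[0.15, 0.35, 0.35, 0.15]))
    )
    bg = markov_background(seq, 200, rng)
    gc_in = float(np.isin(seq, [1, 2]).mean())
    gc_bg = float(np.isin(bg, [1, 2]).mean())
    assert abs(gc_in - gc_bg) < 0.05


# -- quantile normalization -----------------------------------------------


def test_qn_identical_inputs_identical_outputs():
    ref = fit_quantile_reference(np.column_stack([[1, 2, 3], [4, 5, 6]]))
    a = normalize_cage_feature(np.array([2.0, 7.0, 1.0]), ref)
    b = normalize_cage_feature(np.array([2.0, 7.0, 1.0]), ref)
    np.testing.assert_array_equal(a, b)


def test_qn_rank_order_preserved():
    ref = fit_quantile_reference(np.random.default_rng(0).gamma(2, size=(50, 3)))
    x = np.array([0.5, 9.0, 2.0, 2.0, 0.1])
    out = normalize_cage_feature(x, ref)
    assert np.all(np.argsort(out, kind="stable") == np.argsort(x, kind="stable"))
    assert out[2] == out[3]  # ties map together


def test_qn_toy_vectors_hand_worked():
    # columns (1,2,3) and (4,5,6): after log1p, each rank maps to the mean of
    # the two sorted log columns — hand-computed oracle
    mat = np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    out, ref = quantile_normalize(mat)
    expected = np.array(
        [
            (math.log1p(1) + math.log1p(4)) / 2,
            (math.log1p(2) + math.log1p(5)) / 2,
            (math.log1p(3) + math.log1p(6)) / 2,
        ]
    )
    np.testing.assert_allclose(ref, expected)
    np.testing.assert_allclose(out[:, 0], expected)
    np.testing.assert_allclose(out[:, 1], expected)


# -- labels ---------------------------------------------------------------


def _region(mid, rid):
    r = BidirectionalRegion("chr1", mid, mid - 5, mid + 5, 1.0, 10.0, 3)
    r.norm_start, r.norm_end = mid - 100, mid + 100
    r.region_id = rid
    return r


def test_label_one_bp_overlap():
    regions = [_region(1000, "r1")]  # normalized [900, 1100)
    peaks = {"TFX": intervals_from_tuples({"chr1": [(1099, 1200)]})}
    df = label_enhancers(regions, peaks)
    assert df["label"].tolist() == [1]


def test_label_half_open_boundary():
    regions = [_region(1000, "r1")]
    peaks = {"TFX": intervals_from_tuples({"chr1": [(1100, 1200)]})}
    df = label_enhancers(regions, peaks)
    assert df["label"].tolist() == [0]


def test_label_missing_tf_errors():
    with pytest.raises(KeyError):
        label_enhancers([_region(1000, "r1")], {"TFX": None})


# -- training / prediction ------------------------------------------------


def test_beta_recovery():
    beta = (1.5, 0.8, 2.0)
    X, y = make_logistic_dataset(beta=beta, intercept=-1.0, n=5000, seed=11)
    model = train_tf_model(X, y, tf="synthetic")
    # features are standard normal, so standardized coefficients ~ beta
    np.testing.assert_allclose(model.coef, beta, atol=0.15)


def test_null_labels_flat_model():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(4000, 3))
    y = (rng.random(4000) < 0.2).astype(int)
    model = train_tf_model(X, y)
    assert np.all(np.abs(model.coef) < 0.1)
    p = model.predict(X)
    assert pr_auc(y, p) == pytest.approx(y.mean(), abs=0.03)


def test_single_class_errors():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError, match="single-class"):
        train_tf_model(X, np.ones(10))


def test_nan_features_error():
    X = np.full((10, 3), np.nan)
    y = np.array([0, 1] * 5)
    with pytest.raises(ValueError, match="non-finite"):
        train_tf_model(X, y)


def _identity_model(coef, intercept=0.0):
    k = len(coef)
    return BindingModel(
        "t", ["x"] * k, np.array(coef, dtype=float), intercept,
        np.zeros(k), np.ones(k),
    )


def test_predict_zero_model_is_half():
    m = _identity_model([0.0, 0.0, 0.0])
    assert predict_binding(m, np.array([[5.0, -3.0, 2.0]]))[0] == pytest.approx(0.5)


def test_predict_origin_is_half():
    m = _identity_model([1.0, 1.0, 1.0])
    assert predict_binding(m, np.zeros((1, 3)))[0] == pytest.approx(0.5)


def test_predict_log3_gives_three_quarters():
    m = _identity_model([1.0, 0.0, 0.0])
    x = np.array([[math.log(3), 0.0, 0.0]])
    assert predict_binding(m, x)[0] == pytest.approx(0.75)


def test_predict_monotone_in_positive_coef():
    m = _identity_model([2.0, 0.0, 0.0])
    xs = np.column_stack([np.linspace(-3, 3, 50), np.zeros(50), np.zeros(50)])
    p = predict_binding(m, xs)
    assert np.all(np.diff(p) > 0)
    assert np.all((p > 0) & (p < 1))


def test_model_json_roundtrip(tmp_path):
    X, y = make_logistic_dataset(n=500, seed=4)
    model = train_tf_model(X, y, tf="TFZ")
    path = tmp_path / "model.json"
    model.save(str(path))
    back = BindingModel.load(str(path))
    np.testing.assert_array_equal(model.coef, back.coef)
    assert model.intercept == back.intercept
    X2 = np.random.default_rng(0).normal(size=(20, 3))
    np.testing.assert_array_equal(model.predict(X2), back.predict(X2))


def test_duplicating_rows_leaves_coef_nearly_unchanged():
    X, y = make_logistic_dataset(n=2000, seed=9)
    m1 = train_tf_model(X, y)
    m2 = train_tf_model(np.vstack([X, X]), np.concatenate([y, y]))
    np.testing.assert_allclose(m1.coef, m2.coef, atol=0.02)


# -- PR AUC / cross-validation --------------------------------------------


def test_pr_auc_perfect_separation():
    y = np.array([0] * 50 + [1] * 50)
    assert pr_auc(y, y.astype(float)) == 1.0


def test_pr_auc_constant_score_is_prevalence():
    y = np.array([0] * 80 + [1] * 20)
    assert pr_auc(y, np.zeros(100)) == pytest.approx(0.2)


def test_pr_auc_random_scores_near_prevalence():
    rng = np.random.default_rng(12)
    y = (rng.random(2000) < 0.2).astype(int)
    scores = rng.random(2000)
    assert pr_auc(y, scores) == pytest.approx(0.20, abs=0.03)


def _cv_frame(seed=0, n=600):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    p = 1 / (1 + np.exp(-(X @ np.array([2.0, 1.0, 1.5]) - 1)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "tf": "TFA",
            "cell_type": [f"ct{i % 3}" for i in range(n)],
            "chrom": [f"chr{i % 4}" for i in range(n)],
            "S": X[:, 0],
            "E_CAGE": X[:, 1],
            "E_ChIP": X[:, 2],
            "label": y,
        }
    )


def test_crossval_chromosome_scheme_beats_baseline():
    table = crossval_pr_auc(_cv_frame(), scheme="chromosome")
    assert len(table) == 4
    assert (table["pr_auc"] > table["baseline"]).all()


def test_crossval_celltype_scheme_runs():
    table = crossval_pr_auc(_cv_frame(), scheme="celltype")
    assert len(table) == 3
    assert (table["pr_auc"] > table["baseline"]).all()


def test_crossval_unknown_scheme():
    with pytest.raises(ValueError):
        crossval_pr_auc(_cv_frame(), scheme="bogus")


def test_model_beats_constant_over_seeds():
    # informative model's PR AUC >= prevalence baseline, in expectation
    wins = 0
    for seed in range(20):
        df = _cv_frame(seed=seed, n=400)
        table = crossval_pr_auc(df, scheme="chromosome")
        wins += (table["pr_auc"].mean() >= table["baseline"].mean())
    assert wins >= 18


def test_general_model_degenerate_pooling_equals_tf_model():
    df = _cv_frame(seed=1)
    m_tf = train_tf_model(
        df[["S", "E_CAGE", "E_ChIP"]].to_numpy(), df["label"].to_numpy(), seed=0
    )
    m_gen = train_general_model(df, seed=0)
    np.testing.assert_allclose(m_tf.coef, m_gen.coef)


def test_wilcoxon_utility():
    rng = np.random.default_rng(7)
    table = pd.DataFrame(
        {
            "tf": [f"T{i}" for i in range(30)],
            "fold": "chr1",
            "pr_auc": rng.uniform(0.4, 0.8, 30),
            "baseline": rng.uniform(0.1, 0.2, 30),
        }
    )
    stat, p = wilcoxon_vs_baseline(table)
    assert p < 1e-4
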