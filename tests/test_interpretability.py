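"""Attribution math, PR/AUPRC enrichment, and the permutation null."""

import numpy as np
import pytest
from scipy import stats

import proteobridge as pb
from proteobridge.interpretability import (
    ImportanceMatrix,
    ReferenceEdgeSet,
    attribute,
    completeness_gap,
    edge_density_enrichment,
    importance_matrix,
    importance_vs_accuracy,
    node_importance,
    pair_importance,
    pair_labels,
    permutation_test,
    pr_curve,
    self_cross_split,
)
from proteobridge.jvae import JointVAE, NetworkConfig

from conftest import affine_imputation_map, linear_toy_config


def _toy_map(d=5):
    return [(f"a{i}", f"b{i}") for i in range(d)]


@pytest.fixture
def toy_model():
    model = JointVAE(linear_toy_config(d_a=5, d_b=5, d_z=3, hidden=6), seed=7)
    model.eval()
    return model


# ---- attribution on the linear toy --------------------------------------


def test_linear_attribution_equals_weight_times_input(toy_model):
    rng = np.random.default_rng(0)
    x = rng.standard_normal((40, 5))
    w_eff, _ = affine_imputation_map(toy_model, "A2B")
    im = importance_matrix(
        toy_model, x, "A2B", _toy_map(), [f"a{i}" for i in range(5)],
        [f"b{i}" for i in range(5)], method="grad_input",
    )
    expected = np.abs(w_eff) * np.abs(x).mean(0)[:, None]
    assert np.allclose(im.values, expected, rtol=0.05)


def test_integrated_gradients_exact_on_linear(toy_model):
    rng = np.random.default_rng(1)
    x = rng.standard_normal((10, 5))
    out_cols = np.arange(5)
    a_gi = attribute(toy_model, x, "A2B", out_cols, method="grad_input")
    a_ig = attribute(toy_model, x, "A2B", out_cols, method="integrated_gradients", n_steps=4)
    assert np.allclose(a_gi, a_ig, atol=1e-10)


def test_completeness_for_integrated_gradients_nonlinear():
    model = JointVAE(
        NetworkConfig(d_a=5, d_b=4, d_z=3, hidden=8, dropout=0.0, use_batchnorm=False),
        seed=3,
    )
    model.eval()
    rng = np.random.default_rng(2)
    x = rng.standard_normal((6, 5))
    out_cols = np.arange(4)
    attr = attribute(model, x, "A2B", out_cols, method="integrated_gradients", n_steps=512)
    gap = completeness_gap(model, x, "A2B", out_cols, attr)
    assert gap.max() < 1e-4


def test_ignored_input_gets_zero_attribution(toy_model):
    # zero the first input's weights in the encoder stem
    toy_model.enc_a.stem.layers[0].weight.data[0, :] = 0.0
    rng = np.random.default_rng(3)
    x = rng.standard_normal((20, 5))
    im = importance_matrix(
        toy_model, x, "A2B", _toy_map(), [f"a{i}" for i in range(5)],
        [f"b{i}" for i in range(5)],
    )
    assert np.allclose(im.values[0, :], 0.0, atol=1e-12)


def test_methods_agree_in_rank_on_linear_toy(toy_model):
    rng = np.random.default_rng(4)
    x = rng.standard_normal((30, 5))
    args = (toy_model, x, "A2B", _toy_map(), [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)])
    mats = {
        m: importance_matrix(*args, method=m).values.ravel()
        for m in ("grad_input", "integrated_gradients", "gradient_shap")
    }
    for m in ("integrated_gradients", "gradient_shap"):
        rho = stats.spearmanr(mats["grad_input"], mats[m]).statistic
        assert rho > 0.8


def test_empty_probe_map_errors(toy_model):
    with pytest.raises(ValueError, match="probe_map"):
        importance_matrix(toy_model, np.zeros((3, 5)), "A2B", [], ["a"], ["b"])


# ---- self/cross split and pair scores ------------------------------------


def test_self_cross_split_diagonal_oracle():
    rng = np.random.default_rng(5)
    vals = rng.random((4, 4))
    im = ImportanceMatrix(vals, ["a"] * 0 + [f"a{i}" for i in range(4)],
                          [f"b{i}" for i in range(4)], "A2B", "grad_input")
    self_imp, cross = self_cross_split(im)
    assert np.array_equal(self_imp, np.diag(vals))
    assert np.all(np.diag(cross) == 0)
    off = vals.copy()
    np.fill_diagonal(off, 0)
    assert np.array_equal(cross, off)


def test_self_cross_split_identity_matrix_has_zero_cross():
    im = ImportanceMatrix(np.eye(3), [f"a{i}" for i in range(3)],
                          [f"b{i}" for i in range(3)], "A2B", "grad_input")
    _, cross = self_cross_split(im)
    assert np.all(cross == 0)


def test_pair_importance_max_oracle_and_symmetry():
    rng = np.random.default_rng(6)
    names = [f"a{i}" for i in range(4)]
    bnames = [f"b{i}" for i in range(4)]
    v1, v2 = rng.random((4, 4)), rng.random((4, 4))
    i_ab = ImportanceMatrix(v1, names, bnames, "A2B", "grad_input")
    i_ba = ImportanceMatrix(v2, bnames, names, "B2A", "grad_input")
    score, out_names = pair_importance(i_ab, i_ba, family_prefix_rule=None)
    assert out_names == names
    assert np.allclose(score, score.T)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            assert score[i, j] == pytest.approx(
                max(v1[i, j], v1[j, i], v2[i, j], v2[j, i])
            )


def test_pair_importance_single_direction():
    names = ["a0", "a1"]
    v = np.array([[0.0, 0.7], [0.0, 0.0]])
    i_ab = ImportanceMatrix(v, names, ["b0", "b1"], "A2B", "g")
    i_ba = ImportanceMatrix(np.zeros((2, 2)), ["b0", "b1"], names, "B2A", "g")
    score, _ = pair_importance(i_ab, i_ba, family_prefix_rule=None)
    assert score[0, 1] == 0.7 and score[1, 0] == 0.7


def test_family_prefix_grouping_merges_members():
    names = ["IL1", "IL2", "TNF1"]
    v = np.zeros((3, 3))
    v[0, 2] = 0.4
    v[1, 2] = 0.9  # IL2-TNF1 is the family maximum
    i_ab = ImportanceMatrix(v, names, names, "A2B", "g")
    i_ba = ImportanceMatrix(np.zeros((3, 3)), names, names, "B2A", "g")
    score, fam = pair_importance(i_ab, i_ba)
    assert fam == ["IL", "TNF"]
    assert score[fam.index("IL"), fam.index("TNF")] == pytest.approx(0.9)


# ---- PR / AUPRC ----------------------------------------------------------


def test_pr_perfect_separation():
    rng = np.random.default_rng(6)
    n_pos, n_neg = 50, 150
    scores = np.concatenate([rng.uniform(0.6, 1.0, n_pos), rng.uniform(0.01, 0.4, n_neg)])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    res = pr_curve(scores, labels)
    # every threshold that has not yet admitted negatives is pure
    assert np.all(res.precision[res.recall < 1] == 1.0)
    assert res.auprc > 0.95


def test_pr_random_scores_auprc_near_prevalence():
    rng = np.random.default_rng(7)
    n = 4000
    scores = rng.random(n)
    labels = rng.random(n) < 0.15
    res = pr_curve(scores, labels)
    assert res.auprc == pytest.approx(0.15, abs=0.04)


def test_pr_two_point_trapezoid_hand_area():
    # 4 pairs; thresholds chosen so the curve has two attained points
    scores = np.array([1.0, 0.5, 0.5, 0.5])
    labels = np.array([True, False, False, True])
    res = pr_curve(scores, labels, n_thresholds=2)
    # t=1.0: predicted={0}, precision 1, recall 0.5
    # t=0.5: predicted=all, precision 0.5, recall 1.0
    assert np.allclose(sorted(res.recall), [0.5, 1.0])
    assert res.auprc == pytest.approx(0.5 * (1.0 + 0.5) * 0.5)


def test_pr_recall_monotone_and_bounded():
    rng = np.random.default_rng(8)
    scores = rng.random(500)
    labels = rng.random(500) < 0.2
    res = pr_curve(scores, labels)
    assert np.all((res.precision >= 0) & (res.precision <= 1))
    assert np.all((res.recall >= 0) & (res.recall <= 1))
    # thresholds loosen along the returned order -> recall nondecreasing
    assert np.all(np.diff(res.recall) >= -1e-12)


def test_pr_requires_positives():
    with pytest.raises(ValueError, match="positive"):
        pr_curve(np.array([0.5, 0.2]), np.array([False, False]))


# ---- permutation test ----------------------------------------------------


def test_permutation_p_formula_when_observed_is_best():
    rng = np.random.default_rng(9)
    n_ent = 40
    m = n_ent * (n_ent - 1) // 2
    scores = rng.permutation(m).astype(float) + 1.0  # distinct positive scores
    labels = np.zeros(m, dtype=bool)
    labels[np.argsort(-scores)[:25]] = True  # positives are exactly the top scores
    res = permutation_test(scores, labels, n=1000, seed=0)
    assert res.k == 0
    assert res.p == pytest.approx(1 / 1001)


def test_permutation_p_is_one_when_observed_is_worst():
    rng = np.random.default_rng(10)
    m = 600
    scores = rng.permutation(m).astype(float) + 1.0
    labels = np.zeros(m, dtype=bool)
    labels[np.argsort(scores)[:30]] = True  # positives are the lowest scores
    res = permutation_test(scores, labels, n=300, seed=1)
    assert res.k == 300
    assert res.p == 1.0


def test_permutation_null_mean_near_prevalence():
    rng = np.random.default_rng(11)
    m = 1000
    scores = rng.random(m)
    labels = rng.random(m) < 0.2
    res = permutation_test(scores, labels, n=200, seed=2)
    assert res.null_auprcs.mean() == pytest.approx(labels.mean(), abs=0.05)


# ---- node importance -----------------------------------------------------


def test_node_importance_dominant_input_rank_one():
    vals = np.ones((5, 6)) * 0.1
    vals[2, :] = 5.0
    im = ImportanceMatrix(vals, [f"a{i}" for i in range(5)],
                          [f"b{j}" for j in range(6)], "A2B", "g")
    scores = node_importance(im)
    assert scores[2] == 1.0
    assert np.argmin(scores) == 2


def test_node_importance_matches_per_column_ranking_oracle():
    rng = np.random.default_rng(12)
    vals = rng.random((6, 4))
    im = ImportanceMatrix(vals, [f"a{i}" for i in range(6)],
                          [f"b{j}" for j in range(4)], "A2B", "g")
    scores = node_importance(im)
    oracle = np.mean(
        [stats.rankdata(-vals[:, j], method="average") for j in range(4)], axis=0
    )
    assert np.allclose(scores, oracle)


def test_edge_density_enrichment_prefers_hub_nodes():
    names = [f"p{i}" for i in range(10)]
    ref = ReferenceEdgeSet.from_pairs([("p0", "p1"), ("p0", "p2"), ("p1", "p2")])
    node_scores = np.arange(10, dtype=float)  # p0..p2 most important
    dens = edge_density_enrichment(node_scores, names, ref, fractions=(0.3, 1.0))
    assert dens[0][1] > dens[1][1]


def test_importance_vs_accuracy_directions():
    rng = np.random.default_rng(13)
    r = rng.random(40)
    out = importance_vs_accuracy(2.0 * r + 0.01 * rng.standard_normal(40), r, rng.random(40))
    assert out["r_vs_imputation_r"] > 0.95
    assert abs(out["r_vs_measured_r"]) < 0.5


def test_reference_edge_set_removes_self_and_restricts_universe():
    ref = ReferenceEdgeSet.from_pairs(
        [("a", "a"), ("a", "b"), ("b", "c"), ("x", "y")], universe=["a", "b", "c"]
    )
    assert frozenset(("a", "b")) in ref.edges
    assert len(ref) == 2
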