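"""Loss arithmetic, kernel math, and model contracts for the joint VAE."""

import itertools

import numpy as np
import pytest

from proteobridge.autodiff import Tensor
from proteobridge.jvae import (
    JointVAE,
    KernelConfig,
    LossWeights,
    NetworkConfig,
    kl_loss,
    median_heuristic,
    mmd_loss,
    rbf_kernel,
    reconstruction_loss,
    reparameterize,
    total_loss,
)

from conftest import linear_toy_config


# ---- reparameterization --------------------------------------------------


def test_reparameterize_zero_noise_returns_mu():
    mu = np.array([[1.0, -2.0]])
    assert np.array_equal(reparameterize(mu, np.zeros((1, 2)), np.zeros((1, 2))), mu)


def test_reparameterize_unit_logvar_shift():
    mu = np.array([[0.5, 0.5]])
    out = reparameterize(mu, np.zeros((1, 2)), np.ones((1, 2)))
    assert np.allclose(out, mu + 1.0)  # sigma = exp(0) = 1


def test_reparameterize_moments_match_posterior():
    rng = np.random.default_rng(0)
    mu, log_var = np.array([[0.7, -1.2]]), np.array([[0.3, -0.8]])
    n = 100_000
    eps = rng.standard_normal((n, 2))
    z = reparameterize(np.repeat(mu, n, 0), np.repeat(log_var, n, 0), eps)
    sigma2 = np.exp(log_var).ravel()
    se_mean = np.sqrt(sigma2 / n)
    se_var = sigma2 * np.sqrt(2.0 / (n - 1))
    assert np.all(np.abs(z.mean(0) - mu.ravel()) < 3 * se_mean)
    assert np.all(np.abs(z.var(0) - sigma2) < 3 * se_var)


# ---- reconstruction losses ----------------------------------------------


def test_reconstruction_perfect_is_zero():
    x = np.ones((3, 4))
    assert reconstruction_loss(x, x, x, x) == 0.0


def test_reconstruction_printed_formula_single_sample():
    xa, xhat_a = np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])
    xb = xhat_b = np.array([[0.0, 0.0]])
    assert reconstruction_loss(xa, xb, xhat_a, xhat_b) == 0.5


def test_reconstruction_matches_elementwise_oracle():
    rng = np.random.default_rng(1)
    xa, xb = rng.standard_normal((6, 3)), rng.standard_normal((6, 5))
    ha, hb = rng.standard_normal((6, 3)), rng.standard_normal((6, 5))
    oracle = (((xa - ha) ** 2).sum() + ((xb - hb) ** 2).sum()) / 12
    assert np.isclose(reconstruction_loss(xa, xb, ha, hb), oracle)


def test_reconstruction_sample_permutation_invariance():
    rng = np.random.default_rng(2)
    xa, xb = rng.standard_normal((8, 3)), rng.standard_normal((8, 4))
    ha, hb = rng.standard_normal((8, 3)), rng.standard_normal((8, 4))
    perm = rng.permutation(8)
    assert np.isclose(
        reconstruction_loss(xa, xb, ha, hb),
        reconstruction_loss(xa[perm], xb[perm], ha[perm], hb[perm]),
    )


# ---- KL ------------------------------------------------------------------


def test_kl_zero_at_prior():
    z = np.zeros((4, 3))
    assert kl_loss(z, z, z, z) == 0.0


def test_kl_hand_value():
    # N=1, d_z=1, mu=1, logvar=0 in A; B at prior: L_A = 0.5, total 0.25
    mu_a, lv_a = np.array([[1.0]]), np.array([[0.0]])
    mu_b, lv_b = np.array([[0.0]]), np.array([[0.0]])
    assert kl_loss(mu_a, lv_a, mu_b, lv_b) == 0.25


def test_kl_nonnegative_random():
    rng = np.random.default_rng(3)
    for _ in range(20):
        mu = rng.standard_normal((5, 4))
        lv = rng.uniform(-2, 2, (5, 4))
        assert kl_loss(mu, lv, rng.standard_normal((5, 4)), rng.uniform(-2, 2, (5, 4))) >= 0


def test_kl_matches_monte_carlo():
    rng = np.random.default_rng(4)
    mu = rng.standard_normal((1, 3))
    lv = rng.uniform(-1, 1, (1, 3))
    prior = np.zeros((1, 3))
    analytic_a = kl_loss(mu, lv, prior, prior) * 2  # isolate platform A term
    n = 100_000
    sigma = np.exp(0.5 * lv)
    z = mu + sigma * rng.standard_normal((n, 3))
    log_q = (-0.5 * ((z - mu) / sigma) ** 2 - 0.5 * np.log(2 * np.pi) - 0.5 * lv).sum(1)
    log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(1)
    samples = log_q - log_p
    se = samples.std(ddof=1) / np.sqrt(n)
    assert abs(analytic_a - samples.mean()) < 3 * se


# ---- kernels and MMD -----------------------------------------------------


def test_rbf_identity_and_scale():
    u = np.array([1.0, 2.0])
    assert rbf_kernel(u, u, gamma=0.7) == 1.0
    gamma = 1.3
    v = u + np.array([gamma * np.sqrt(2.0), 0.0])
    assert np.isclose(rbf_kernel(u, v, gamma), np.exp(-1.0))


def test_rbf_symmetry():
    rng = np.random.default_rng(5)
    for _ in range(10):
        u, v = rng.standard_normal(3), rng.standard_normal(3)
        assert np.isclose(rbf_kernel(u, v, 0.9), rbf_kernel(v, u, 0.9))


def test_median_heuristic_two_points():
    a = np.array([[0.0, 0.0]])
    b = np.array([[3.0, 4.0]])
    assert np.isclose(median_heuristic(a, b), 5.0)


def test_median_heuristic_coincident_floor():
    z = np.zeros((4, 2))
    with pytest.warns(UserWarning):
        g = median_heuristic(z, z)
    assert g == 1e-8


def test_median_heuristic_matches_double_loop():
    rng = np.random.default_rng(6)
    za, zb = rng.standard_normal((7, 3)), rng.standard_normal((5, 3))
    pool = np.vstack([za, zb])
    dists = [
        np.linalg.norm(pool[i] - pool[j])
        for i, j in itertools.combinations(range(len(pool)), 2)
    ]
    assert np.isclose(median_heuristic(za, zb), np.median(dists))


def mmd_double_loop(za, zb, gamma):
    n = za.shape[0]
    k = lambda u, v: np.exp(-((u - v) ** 2).sum() / (2 * gamma**2))
    within = sum(
        k(za[i], za[j]) + k(zb[i], zb[j]) for i in range(n) for j in range(n) if i != j
    ) / (n * (n - 1))
    between = 2.0 / n**2 * sum(k(za[i], zb[j]) for i in range(n) for j in range(n))
    return within - between


def test_mmd_coincident_pairs_cancel():
    z = np.array([[1.0, 2.0], [1.0, 2.0]])
    assert np.isclose(mmd_loss(z, z, 1.0), 0.0)


def test_mmd_two_point_hand_expansion():
    a, b = np.array([0.0, 0.0]), np.array([1.0, 1.0])
    z = np.vstack([a, b])
    gamma = 0.8
    expected = rbf_kernel(a, b, gamma) - 1.0
    assert np.isclose(mmd_loss(z, z, gamma), expected)
    assert mmd_loss(z, z, gamma) <= 0


def test_mmd_matches_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(2, 20))
        d = int(rng.integers(1, 6))
        za, zb = rng.standard_normal((n, d)), rng.standard_normal((n, d))
        gamma = float(rng.uniform(0.3, 2.0))
        assert abs(mmd_loss(za, zb, gamma) - mmd_double_loop(za, zb, gamma)) < 1e-10


def test_mmd_sign_behavior():
    rng = np.random.default_rng(8)
    gamma = 1.0
    # same distribution: near zero (may be slightly negative)
    vals = [
        mmd_loss(rng.standard_normal((64, 3)), rng.standard_normal((64, 3)), gamma)
        for _ in range(10)
    ]
    assert abs(np.mean(vals)) < 0.05
    # well-separated clouds: positive, approaching 2x the within-cloud mean
    za = rng.standard_normal((32, 3))
    zb = rng.standard_normal((32, 3)) + 50.0
    assert mmd_loss(za, zb, gamma) > 0.2
    # tight clouds far apart: within-kernel ~ 1, between ~ 0 -> MMD^2 ~ 2
    za_t = 0.01 * rng.standard_normal((16, 3))
    zb_t = 0.01 * rng.standard_normal((16, 3)) + 50.0
    assert mmd_loss(za_t, zb_t, gamma) == pytest.approx(2.0, abs=0.01)


def test_mmd_requires_two_samples():
    with pytest.raises(ValueError):
        mmd_loss(np.zeros((1, 2)), np.zeros((1, 2)), 1.0)


# ---- total loss ----------------------------------------------------------


def test_total_loss_reference_weights():
    bd = total_loss(1.0, 1.0, 1.0, 1.0, LossWeights())
    assert np.isclose(bd.total, 0.90 + 1.4 + 1.4e-4 + 1.9)


def test_total_loss_zero_weights():
    w = LossWeights(lambda_rec=0, lambda_cross=0, lambda_kl=0, lambda_align=0)
    assert total_loss(3.0, 2.0, 1.0, 0.5, w).total == 0.0


def test_total_loss_dot_product_oracle():
    rng = np.random.default_rng(9)
    comps = rng.uniform(0, 5, 4)
    wts = rng.uniform(0, 3, 4)
    w = LossWeights(lambda_rec=wts[0], lambda_cross=wts[1], lambda_kl=wts[2], lambda_align=wts[3])
    bd = total_loss(*comps, w)
    assert np.isclose(bd.total, comps @ wts)


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        LossWeights(lambda_rec=-0.1)


# ---- network contracts ---------------------------------------------------


def test_encode_decode_shapes_and_determinism():
    cfg = NetworkConfig(d_a=7, d_b=5, d_z=3, hidden=16)
    model = JointVAE(cfg, seed=0)
    model.eval()
    x = np.random.default_rng(0).standard_normal((4, 7))
    post = model.encode(x, "A")
    assert post.mu.shape == (4, 3) and post.log_var.shape == (4, 3)
    post2 = model.encode(x, "A")
    assert np.array_equal(post.mu, post2.mu)
    recon = model.decode(post.mu, "B")
    assert recon.shape == (4, 5)
    with pytest.raises(ValueError, match="width"):
        model.encode(x[:, :5], "A")


def test_single_sample_matches_batch_in_eval_mode():
    cfg = NetworkConfig(d_a=6, d_b=6, d_z=2, hidden=8)
    model = JointVAE(cfg, seed=1)
    model.eval()
    x = np.random.default_rng(1).standard_normal((5, 6))
    full = model.encode(x, "A")
    single = model.encode(x[2:3], "A")
    assert np.allclose(full.mu[2], single.mu[0], atol=1e-6)


def test_linear_toy_decoder_is_affine():
    model = JointVAE(linear_toy_config(), seed=2)
    model.eval()
    dec = model.dec_b
    w = dec.stem.layers[0].weight.data @ dec.out.weight.data
    b = dec.stem.layers[0].bias.data @ dec.out.weight.data + dec.out.bias.data
    z = np.random.default_rng(2).standard_normal((6, 3))
    assert np.allclose(model.decode(z, "B"), z @ w + b)


def test_forward_components_match_standalone_ops():
    cfg = NetworkConfig(d_a=6, d_b=4, d_z=3, hidden=8, dropout=0.0, use_batchnorm=False)
    model = JointVAE(cfg, seed=3)
    model.eval()
    rng = np.random.default_rng(3)
    xa, xb = rng.standard_normal((8, 6)), rng.standard_normal((8, 4))
    eps_a, eps_b = rng.standard_normal((8, 3)), rng.standard_normal((8, 3))
    out, tot, bd = model.forward_joint(xa, xb, eps_a, eps_b)
    pa, pb = out["posterior_a"], out["posterior_b"]
    za = reparameterize(pa.mu, pa.log_var, eps_a)
    zb = reparameterize(pb.mu, pb.log_var, eps_b)
    assert np.isclose(bd.rec, reconstruction_loss(xa, xb, out["xhat_a"].data, out["xhat_b"].data))
    assert np.isclose(bd.kl, kl_loss(pa.mu, pa.log_var, pb.mu, pb.log_var))
    assert np.isclose(bd.align, mmd_loss(za, zb, out["gamma"]))
    assert np.isclose(bd.total, float(tot.data))


def test_forward_gradients_finite():
    cfg = NetworkConfig(d_a=5, d_b=5, d_z=2, hidden=8)
    model = JointVAE(cfg, seed=4)
    model.train()
    rng = np.random.default_rng(4)
    _, tot, _ = model.forward_joint(
        rng.standard_normal((6, 5)), rng.standard_normal((6, 5)),
        rng.standard_normal((6, 2)), rng.standard_normal((6, 2)),
    )
    tot.backward()
    for p in model.parameters():
        assert p.grad is not None and np.all(np.isfinite(p.grad))


def test_one_adamw_step_decreases_loss():
    from proteobridge.nn import AdamW

    cfg = NetworkConfig(d_a=6, d_b=6, d_z=3, hidden=12, dropout=0.0, use_batchnorm=False)
    model = JointVAE(cfg, seed=5)
    model.train()
    rng = np.random.default_rng(5)
    xa, xb = rng.standard_normal((16, 6)), rng.standard_normal((16, 6))
    eps_a, eps_b = rng.standard_normal((16, 3)), rng.standard_normal((16, 3))
    kernel = KernelConfig(heuristic="fixed", gamma=1.0)  # fixed kernel for comparability
    _, tot, before = model.forward_joint(xa, xb, eps_a, eps_b, kernel=kernel)
    opt = AdamW(list(model.parameters()), lr=1e-3, weight_decay=0.0)
    tot.backward()
    opt.step()
    _, _, after = model.forward_joint(xa, xb, eps_a, eps_b, kernel=kernel)
    assert after.total < before.total
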