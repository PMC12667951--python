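"""Joint variational autoencoder over two measurement platforms.

Two encoders map each platform's profile x^A in R^{d_A}, x^B in R^{d_B} to a
Gaussian posterior q(z|x) = N(mu, diag(sigma^2)) in a shared latent space
R^{d_z}; two decoders map latent codes back to either platform, so a latent
code from one platform can be decoded into the other (cross-imputation).

The training objective combines four terms:

    L_total = lambda_rec * L_rec + lambda_KL * L_KL
            + lambda_align * L_align + lambda_cross * L_cross

* ``L_rec``   — squared-error self-reconstruction, (1/2N) sum_i
  (||x_i^A - xhat_i^A||^2 + ||x_i^B - xhat_i^B||^2);
* ``L_cross`` — the same form with each latent code decoded by the *other*
  platform's decoder;
* ``L_KL``    — mean of the per-platform KL divergences to the unit
  Gaussian prior, each (1/2N) sum_i [||mu||^2 + exp(logvar) - 1 - logvar]
  summed over latent dimensions;
* ``L_align`` — the unbiased U-statistic estimator of the squared maximum
  mean discrepancy between the two aggregated posteriors, with an RBF
  kernel k_gamma(u, v) = exp(-||u - v||^2 / (2 gamma^2)) and gamma chosen
  per minibatch by the median heuristic.

Default weights: lambda_rec = 0.90, lambda_cross = 1.4, lambda_KL = 1.4e-4,
lambda_align = 1.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor

LOG_VAR_CLAMP = 15.0  # numerical guard before exponentiation


# --------------------------------------------------------------------------
# configuration and result containers
# --------------------------------------------------------------------------


@dataclass
class LossWeights:
    lambda_rec: float = 0.90
    lambda_cross: float = 1.4
    lambda_kl: float = 1.4e-4
    lambda_align: float = 1.9

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters for both encoder/decoder pairs.

    The default geometry is a three-layer residual MLP: an input projection,
    one dual-head residual block, and an output layer. ``activation``
    'identity' with ``use_batchnorm=False``, ``dropout=0`` and
    ``n_res_blocks=0`` yields a purely affine network (useful as an
    analytically tractable configuration).
    """

    d_a: int
    d_b: int
    d_z: int = 128
    hidden: int = 512
    dropout: float = 0.1
    weight_decay: float = 1e-4
    use_batchnorm: bool = True
    activation: str = "relu"
    n_res_blocks: int = 1

    def __post_init__(self) -> None:
        for name in ("d_a", "d_b", "d_z", "hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class KernelConfig:
    heuristic: str = "median"  # 'median' or 'fixed'
    gamma: Optional[float] = None
    pooled: bool = True  # median over pooled {z_A} U {z_B} pairs
    floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.heuristic not in ("median", "fixed"):
            raise ValueError("heuristic must be 'median' or 'fixed'")
        if self.heuristic == "fixed" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("fixed heuristic requires gamma > 0")


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior parameters for one platform's batch."""

    mu: np.ndarray
    log_var: np.ndarray
    platform: str = "A"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.log_var = np.asarray(self.log_var, dtype=np.float64)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var shapes disagree")
        if not np.all(np.isfinite(self.log_var)):
            raise ValueError("log_var contains non-finite values")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class LossBreakdown:
    rec: float
    cross: float
    kl: float
    align: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# --------------------------------------------------------------------------
# loss primitives (accept Tensors or arrays; return a scalar of same kind)
# --------------------------------------------------------------------------

TensorLike = Union[Tensor, np.ndarray]


def _ret(x: Tensor, tensor_out: bool):
    return x if tensor_out else float(x.data)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def reparameterize(mu: TensorLike, log_var: TensorLike, eps: np.ndarray) -> TensorLike:
    """z = mu + exp(log_var / 2) * eps."""
    tensor_out = _any_tensor(mu, log_var)
    mu_t, lv_t = as_tensor(mu), as_tensor(log_var)
    if mu_t.shape != np.asarray(eps).shape:
        raise ValueError("epsilon shape must match the posterior shape")
    z = mu_t + lv_t.clip(-LOG_VAR_CLAMP, LOG_VAR_CLAMP).exp() ** 0.5 * eps
    return z if tensor_out else z.data


def reconstruction_loss(xa, xb, xhat_a, xhat_b):
    """(1/2N) sum_i (||x_i^A - xhat_i^A||^2 + ||x_i^B - xhat_i^B||^2)."""
    tensor_out = _any_tensor(xa, xb, xhat_a, xhat_b)
    xa, xb, xhat_a, xhat_b = map(as_tensor, (xa, xb, xhat_a, xhat_b))
    if xa.shape != xhat_a.shape or xb.shape != xhat_b.shape or xa.shape[0] != xb.shape[0]:
        raise ValueError("reconstruction shapes disagree")
    n = xa.shape[0]
    loss = (((xa - xhat_a) ** 2).sum() + ((xb - xhat_b) ** 2).sum()) / (2 * n)
    return _ret(loss, tensor_out)


def cross_reconstruction_loss(xa, xb, xtilde_a, xtilde_b):
    """Same arithmetic as the self term, on cross-decoded reconstructions."""
    return reconstruction_loss(xa, xb, xtilde_a, xtilde_b)


def kl_loss(mu_a, log_var_a, mu_b, log_var_b):
    """Mean of per-platform KL terms to the N(0, I) prior.

    L_KL^P = (1/2N) sum_i sum_d [mu^2 + exp(logvar) - 1 - logvar];
    returns (L_KL^A + L_KL^B) / 2.
    """
    tensor_out = _any_tensor(mu_a, log_var_a, mu_b, log_var_b)

    def one(mu, lv):
        mu, lv = as_tensor(mu), as_tensor(lv)
        n = mu.shape[0]
        return (mu**2 + lv.exp() - 1.0 - lv).sum() / (2 * n)

    loss = (one(mu_a, log_var_a) + one(mu_b, log_var_b)) * 0.5
    return _ret(loss, tensor_out)


def rbf_kernel(u, v, gamma: float):
    """k_gamma(u, v) = exp(-||u - v||^2 / (2 gamma^2)) for single vectors."""
    tensor_out = _any_tensor(u, v)
    u, v = as_tensor(u), as_tensor(v)
    k = (((u - v) ** 2).sum() * (-1.0 / (2.0 * gamma**2))).exp()
    return _ret(k, tensor_out)


def median_heuristic(
    z_a: np.ndarray, z_b: np.ndarray, pooled: bool = True, floor: float = 1e-8
) -> float:
    """Bandwidth gamma = median pairwise Euclidean distance.

    By default the median is over all pairs in the pooled minibatch
    {z_A} U {z_B} (including cross-platform pairs); ``pooled=False``
    restricts to within-set pairs. Falls back to ``floor`` when all points
    coincide.
    """
    z_a = np.asarray(z_a.data if isinstance(z_a, Tensor) else z_a, dtype=np.float64)
    z_b = np.asarray(z_b.data if isinstance(z_b, Tensor) else z_b, dtype=np.float64)
    if pooled:
        pool = np.vstack([z_a, z_b])
        if pool.shape[0] < 2:
            raise ValueError("median heuristic needs at least 2 points")
        d = _pairwise_dist(pool)
        vals = d[np.triu_indices_from(d, k=1)]
    else:
        parts = []
        for z in (z_a, z_b):
            if z.shape[0] >= 2:
                d = _pairwise_dist(z)
                parts.append(d[np.triu_indices_from(d, k=1)])
        if not parts:
            raise ValueError("median heuristic needs at least 2 points in a set")
        vals = np.concatenate(parts)
    gamma = float(np.median(vals))
    if gamma <= floor:
        import warnings

        warnings.warn("all points (nearly) coincide; using bandwidth floor")
        return floor
    return gamma


def _pairwise_dist(z: np.ndarray) -> np.ndarray:
    sq = _pairwise_sqdist_np(z, z)
    return np.sqrt(np.maximum(sq, 0.0))


def _pairwise_sqdist_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ra = (a**2).sum(axis=1)[:, None]
    rb = (b**2).sum(axis=1)[None, :]
    return ra + rb - 2.0 * a @ b.T


def _kernel_matrix_t(a: Tensor, b: Tensor, gamma: float) -> Tensor:
    ra = (a**2).sum(axis=1, keepdims=True)
    rb = (b**2).sum(axis=1, keepdims=True)
    sq = ra + rb.T - (a @ b.T) * 2.0
    return (sq * (-1.0 / (2.0 * gamma**2))).exp()


def mmd_loss(z_a, z_b, gamma: float):
    """Unbiased U-statistic estimator of MMD^2 between the two latent clouds.

    L_align = (1/(N(N-1))) sum_{i != j} [k(zA_i, zA_j) + k(zB_i, zB_j)]
            - (2/N^2) sum_{i,j} k(zA_i, zB_j).

    May be negative (unbiased estimator).
    """
    tensor_out = _any_tensor(z_a, z_b)
    z_a, z_b = as_tensor(z_a), as_tensor(z_b)
    n = z_a.shape[0]
    if n < 2 or z_b.shape[0] != n:
        raise ValueError("mmd_loss requires equal batch sizes with N >= 2")
    eye = np.eye(n)
    kaa = _kernel_matrix_t(z_a, z_a, gamma)
    kbb = _kernel_matrix_t(z_b, z_b, gamma)
    kab = _kernel_matrix_t(z_a, z_b, gamma)
    within = ((kaa * (1 - eye)).sum() + (kbb * (1 - eye)).sum()) / (n * (n - 1))
    between = kab.sum() * (2.0 / n**2)
    return _ret(within - between, tensor_out)


def total_loss(rec, cross, kl, align, weights: LossWeights):
    """Weighted sum of components; returns a LossBreakdown (floats) or a
    (Tensor total, LossBreakdown) pair when any component is a Tensor."""
    tensor_out = _any_tensor(rec, cross, kl, align)
    rec_t, cross_t, kl_t, align_t = map(as_tensor, (rec, cross, kl, align))
    tot = (
        weights.lambda_rec * rec_t
        + weights.lambda_kl * kl_t
        + weights.lambda_align * align_t
        + weights.lambda_cross * cross_t
    )
    breakdown = LossBreakdown(
        rec=float(rec_t.data),
        cross=float(cross_t.data),
        kl=float(kl_t.data),
        align=float(align_t.data),
        total=float(tot.data),
    )
    if tensor_out:
        return tot, breakdown
    return breakdown


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------


class _Encoder(nn.Module):
    def __init__(self, d_in: int, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Linear(d_in, cfg.hidden, rng),
            nn.BatchNorm1d(cfg.hidden) if cfg.use_batchnorm else nn.Identity(),
            nn.make_activation(cfg.activation),
            nn.Dropout(cfg.dropout, rng),
        )
        self.blocks = [
            nn.DualHeadResBlock(cfg.hidden, rng, cfg.activation, cfg.dropout, cfg.use_batchnorm)
            for _ in range(cfg.n_res_blocks)
        ]
        self.mu_head = nn.Linear(cfg.hidden, cfg.d_z, rng)
        self.log_var_head = nn.Linear(cfg.hidden, cfg.d_z, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.stem(x)
        for blk in self.blocks:
            h = blk(h)
        return self.mu_head(h), self.log_var_head(h).clip(-LOG_VAR_CLAMP, LOG_VAR_CLAMP)


class _Decoder(nn.Module):
    def __init__(self, d_out: int, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Linear(cfg.d_z, cfg.hidden, rng),
            nn.BatchNorm1d(cfg.hidden) if cfg.use_batchnorm else nn.Identity(),
            nn.make_activation(cfg.activation),
            nn.Dropout(cfg.dropout, rng),
        )
        self.blocks = [
            nn.DualHeadResBlock(cfg.hidden, rng, cfg.activation, cfg.dropout, cfg.use_batchnorm)
            for _ in range(cfg.n_res_blocks)
        ]
        self.out = nn.Linear(cfg.hidden, d_out, rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.stem(z)
        for blk in self.blocks:
            h = blk(h)
        return self.out(h)


class JointVAE(nn.Module):
    """Dual-encoder / dual-decoder VAE with a shared latent space."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.enc_a = _Encoder(config.d_a, config, rng)
        self.enc_b = _Encoder(config.d_b, config, rng)
        self.dec_a = _Decoder(config.d_a, config, rng)
        self.dec_b = _Decoder(config.d_b, config, rng)

    # -- graph-level API (Tensors) --------------------------------------
    def encode_t(self, x: Tensor, platform: str) -> tuple[Tensor, Tensor]:
        enc = {"A": self.enc_a, "B": self.enc_b}.get(platform)
        if enc is None:
            raise ValueError("platform must be 'A' or 'B'")
        d = {"A": self.config.d_a, "B": self.config.d_b}[platform]
        if x.shape[1] != d:
            raise ValueError(f"platform {platform} expects width {d}, got {x.shape[1]}")
        return enc(x)

    def decode_t(self, z: Tensor, platform: str) -> Tensor:
        dec = {"A": self.dec_a, "B": self.dec_b}.get(platform)
        if dec is None:
            raise ValueError("platform must be 'A' or 'B'")
        if z.shape[1] != self.config.d_z:
            raise ValueError(f"latent width {z.shape[1]} != d_z {self.config.d_z}")
        return dec(z)

    # -- array-level API --------------------------------------------------
    def encode(self, x: np.ndarray, platform: str) -> LatentPosterior:
        mu, lv = self.encode_t(as_tensor(np.asarray(x, dtype=np.float64)), platform)
        return LatentPosterior(mu=mu.data, log_var=lv.data, platform=platform)

    def decode(self, z: np.ndarray, platform: str) -> np.ndarray:
        return self.decode_t(as_tensor(np.asarray(z, dtype=np.float64)), platform).data

    def forward_joint(
        self,
        xa: TensorLike,
        xb: TensorLike,
        eps_a: Optional[np.ndarray] = None,
        eps_b: Optional[np.ndarray] = None,
        weights: Optional[LossWeights] = None,
        kernel: Optional[KernelConfig] = None,
    ):
        """One full pass: encode both platforms, one reparameterised draw per
        platform, four decodes (2 self + 2 cross), all losses on the same
        draws. Returns (outputs dict, total-loss Tensor, LossBreakdown)."""
        weights = weights or LossWeights()
        kernel = kernel or KernelConfig()
        xa_t, xb_t = as_tensor(xa), as_tensor(xb)
        n = xa_t.shape[0]
        if eps_a is None:
            eps_a = np.zeros((n, self.config.d_z))
        if eps_b is None:
            eps_b = np.zeros((n, self.config.d_z))
        mu_a, lv_a = self.encode_t(xa_t, "A")
        mu_b, lv_b = self.encode_t(xb_t, "B")
        z_a = reparameterize(mu_a, lv_a, eps_a)
        z_b = reparameterize(mu_b, lv_b, eps_b)
        xhat_a = self.decode_t(z_a, "A")
        xhat_b = self.decode_t(z_b, "B")
        xtilde_a = self.decode_t(z_b, "A")  # cross: B's code through A's decoder
        xtilde_b = self.decode_t(z_a, "B")
        rec = reconstruction_loss(xa_t, xb_t, xhat_a, xhat_b)
        cross = cross_reconstruction_loss(xa_t, xb_t, xtilde_a, xtilde_b)
        kl = kl_loss(mu_a, lv_a, mu_b, lv_b)
        if kernel.heuristic == "median":
            gamma = median_heuristic(z_a.data, z_b.data, pooled=kernel.pooled, floor=kernel.floor)
        else:
            gamma = float(kernel.gamma)
        align = mmd_loss(z_a, z_b, gamma) if n >= 2 else as_tensor(0.0)
        tot, breakdown = total_loss(rec, cross, kl, align, weights)
        outputs = {
            "posterior_a": LatentPosterior(mu_a.data, lv_a.data, "A"),
            "posterior_b": LatentPosterior(mu_b.data, lv_b.data, "B"),
            "xhat_a": xhat_a,
            "xhat_b": xhat_b,
            "xtilde_a": xtilde_a,
            "xtilde_b": xtilde_b,
            "gamma": gamma,
        }
        return outputs, tot, breakdown
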