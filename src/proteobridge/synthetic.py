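"""Synthetic paired-platform cohorts with known ground truth.

The generator emulates the statistical structure cross-platform imputation
assumes: a shared low-dimensional biological state drives both platforms'
measurements. Latent factors Z ~ N(0, I_K) load onto each platform through
sparse loading matrices; each probe has one dominant factor and up to two
minor ones. Factor "module sizes" are Zipf-like (the probability that a
probe's dominant factor is k is proportional to 1/(k+1)), mirroring the
strongly unequal functional-module sizes of real plasma proteomes, so the
data has the decaying covariance spectrum a latent bottleneck exploits.

Concordant probes share identical loadings across platforms, so their
cross-platform correlation is governed purely by per-probe noise (noise SD
is relative to per-probe signal SD; at the default noise level 0.5 the
expected concordant cross-platform r is 1/(1 + 0.25) = 0.8, with per-probe
jitter). Discordant probes get platform-A loadings on factors disjoint from
their platform-B support, emulating probe pairs that nominally target the
same protein but measure different species. Probe correspondence covers a
configurable fraction of probes, as real panels overlap only partially.

Matrices are returned on vendor-like scales: platform A is already on a
log2-like scale (offset +10, NPX-like); platform B is 2**(raw + 10)
(RFU-like), so the pipeline's log2 path is exercised and exactly inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_preprocess import PairedPlatformMatrix

A_OFFSET = 10.0
B_OFFSET = 10.0


@dataclass
class SyntheticGroundTruth:
    z: np.ndarray  # N x K latent factors
    w_a: np.ndarray  # K x d_A loadings
    w_b: np.ndarray  # K x d_B
    noise_sd_a: np.ndarray
    noise_sd_b: np.ndarray
    dominant_a: np.ndarray  # dominant factor per platform-A probe
    dominant_b: np.ndarray
    shared: np.ndarray  # indices of probes with cross-platform correspondence
    discordant: np.ndarray  # subset of shared whose A/B supports are disjoint
    planted_edges: list[tuple[str, str]]  # mapped-entity pairs sharing a dominant factor
    nonlinear: bool
    seed: int
    phenotype_coeffs: Optional[np.ndarray] = None  # K x n_pheno
    phenotype_truth: dict = field(default_factory=dict)


def _nonlin(t: np.ndarray) -> np.ndarray:
    """Mild saturating nonlinearity emulating dynamic-range compression."""
    return 0.7 * t + 0.6 * np.tanh(t / 2.0)


def _sparse_loadings(
    d: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Loadings with Zipf-weighted dominant factors plus 0-2 minor factors."""
    p = 1.0 / (np.arange(k) + 1.0)
    p /= p.sum()
    dominant = rng.choice(k, size=d, p=p)
    w = np.zeros((k, d))
    for j in range(d):
        scale = rng.uniform(0.8, 1.2)
        w[dominant[j], j] = scale
        n_minor = rng.integers(0, 3)
        if n_minor:
            others = [f for f in range(k) if f != dominant[j]]
            minors = rng.choice(others, size=min(n_minor, len(others)), replace=False)
            w[minors, j] = rng.uniform(0.3, 0.5, size=minors.size) * rng.choice([-1, 1], size=minors.size) * scale
    return w, dominant


def probe_names(d: int, platform: str) -> list[str]:
    return [f"{platform}_P{j:04d}" for j in range(d)]


def mapped_pairs(gt: SyntheticGroundTruth) -> list[tuple[str, str]]:
    return [(f"A_P{j:04d}", f"B_P{j:04d}") for j in gt.shared]


def generate_cohort(
    n: int,
    d_a: int,
    d_b: int,
    k: int,
    noise_level: float = 0.5,
    frac_discordant: float = 0.1,
    frac_shared: float = 0.6,
    nonlinear: bool = False,
    seed: int = 0,
) -> tuple[PairedPlatformMatrix, SyntheticGroundTruth]:
    """Draw one paired cohort plus its generating ground truth.

    X_A = g(Z W_A) + eps_A on an NPX-like scale, X_B likewise on an
    RFU-like scale; ``g`` is the identity unless ``nonlinear``. Per-probe
    noise SD is ``noise_level`` (jittered by U(0.6, 1.4)) times the probe's
    signal SD.
    """
    if k > min(d_a, d_b):
        raise ValueError("need K <= min(d_A, d_B)")
    if n < 2 or d_a < 1 or d_b < 1 or k < 1:
        raise ValueError("invalid dimensions")
    rng = np.random.default_rng(seed)
    w_b, dominant_b = _sparse_loadings(d_b, k, rng)

    n_shared = int(round(frac_shared * min(d_a, d_b)))
    shared = np.arange(n_shared)
    n_disc = int(round(frac_discordant * n_shared))
    discordant = rng.choice(shared, size=n_disc, replace=False) if n_disc else np.array([], dtype=int)

    # platform A: shared probes copy B's loadings; discordant and non-shared
    # probes get independent loadings
    w_a_indep, dominant_a_indep = _sparse_loadings(d_a, k, rng)
    w_a = w_a_indep.copy()
    dominant_a = dominant_a_indep.copy()
    for j in shared:
        if j in set(discordant.tolist()):
            # disjoint support: re-draw until no overlap with B's support
            support_b = set(np.flatnonzero(w_b[:, j]))
            for _ in range(100):
                col = np.zeros(k)
                p = 1.0 / (np.arange(k) + 1.0)
                p /= p.sum()
                dom = rng.choice(k, p=p)
                if dom in support_b:
                    continue
                col[dom] = rng.uniform(0.8, 1.2)
                free = [f for f in range(k) if f not in support_b and f != dom]
                n_minor = rng.integers(0, min(3, len(free) + 1))
                if n_minor and free:
                    minors = rng.choice(free, size=min(n_minor, len(free)), replace=False)
                    col[minors] = rng.uniform(0.3, 0.5, size=minors.size) * rng.choice([-1, 1], size=minors.size)
                w_a[:, j] = col
                dominant_a[j] = dom
                break
        else:
            w_a[:, j] = w_b[:, j]
            dominant_a[j] = dominant_b[j]

    noise_mult_a = noise_level * rng.uniform(0.6, 1.4, size=d_a)
    noise_mult_b = noise_level * rng.uniform(0.6, 1.4, size=d_b)
    noise_sd_a = noise_mult_a * np.linalg.norm(w_a, axis=0)
    noise_sd_b = noise_mult_b * np.linalg.norm(w_b, axis=0)

    z = rng.standard_normal((n, k))
    g = _nonlin if nonlinear else (lambda t: t)
    raw_a = g(z @ w_a) + noise_sd_a * rng.standard_normal((n, d_a))
    raw_b = g(z @ w_b) + noise_sd_b * rng.standard_normal((n, d_b))

    concordant = np.setdiff1d(shared, discordant)
    edges: list[tuple[str, str]] = []
    for i_pos, i in enumerate(concordant):
        for j in concordant[i_pos + 1 :]:
            if dominant_b[i] == dominant_b[j]:
                # entity names follow the A-side probe of each mapped pair,
                # matching the pair-importance naming convention
                edges.append((f"A_P{i:04d}", f"A_P{j:04d}"))

    gt = SyntheticGroundTruth(
        z=z, w_a=w_a, w_b=w_b,
        noise_sd_a=noise_sd_a, noise_sd_b=noise_sd_b,
        dominant_a=dominant_a, dominant_b=dominant_b,
        shared=shared, discordant=np.sort(discordant),
        planted_edges=edges, nonlinear=nonlinear, seed=seed,
    )
    paired = PairedPlatformMatrix(
        samples=[f"S{i:05d}" for i in range(n)],
        platform_a=raw_a + A_OFFSET,
        platform_b=np.exp2(raw_b + B_OFFSET),
        probes_a=probe_names(d_a, "A"),
        probes_b=probe_names(d_b, "B"),
        probe_map=mapped_pairs(gt),
    )
    return paired, gt


def expected_feature_r(gt: SyntheticGroundTruth, probe: int) -> float:
    """Closed-form expected cross-platform Pearson r for a shared probe
    under linear g: r = (w_A . w_B) / sqrt((|w_A|^2 + s_A^2)(|w_B|^2 + s_B^2))."""
    if probe not in set(gt.shared.tolist()):
        raise ValueError("expected r is defined for shared probes only")
    wa, wb = gt.w_a[:, probe], gt.w_b[:, probe]
    sa, sb = gt.noise_sd_a[probe], gt.noise_sd_b[probe]
    denom = np.sqrt((wa @ wa + sa**2) * (wb @ wb + sb**2))
    return float(wa @ wb / denom)


def concordant_probes(gt: SyntheticGroundTruth) -> np.ndarray:
    return np.setdiff1d(gt.shared, gt.discordant)


def generate_phenotypes(
    gt: SyntheticGroundTruth,
    n_continuous: int = 3,
    n_binary: int = 3,
    effect_size: float = 1.0,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Latent-factor-driven phenotypes with sex/age covariates.

    Each phenotype is driven by 1-2 factors: continuous
    y = Z c + 0.5*sex + 0.02*age + noise*eps; binary via
    Bernoulli(sigmoid(Z c + 0.5*sex + 0.02*(age - 55))). The truth set per
    phenotype (recorded on ``gt.phenotype_truth``) is the platform-B shared
    probes whose dominant factor drives the phenotype; it is empty when the
    effect size is zero.
    """
    rng = np.random.default_rng(seed)
    n, k = gt.z.shape
    n_pheno = n_continuous + n_binary
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(30, 79, size=n)
    coeffs = np.zeros((k, n_pheno))
    table = {"sex": sex, "age": age}
    types: dict[str, str] = {}
    truth: dict[str, list[str]] = {}
    for j in range(n_pheno):
        name = f"pheno_c{j}" if j < n_continuous else f"pheno_b{j - n_continuous}"
        kind = "continuous" if j < n_continuous else "binary"
        n_drive = int(rng.integers(1, 3))
        drivers = rng.choice(k, size=n_drive, replace=False)
        if effect_size != 0:
            coeffs[drivers, j] = effect_size * rng.choice([-1.0, 1.0], size=n_drive)
        lin = gt.z @ coeffs[:, j] + 0.5 * sex + 0.02 * (age - 55.0)
        if kind == "continuous":
            table[name] = lin + noise * rng.standard_normal(n)
        else:
            table[name] = rng.binomial(1, 1.0 / (1.0 + np.exp(-lin))).astype(float)
        types[name] = kind
        if effect_size != 0:
            drv = set(drivers.tolist())
            truth[name] = [
                f"B_P{p:04d}" for p in gt.shared if gt.dominant_b[p] in drv
            ]
        else:
            truth[name] = []
    gt.phenotype_coeffs = coeffs
    gt.phenotype_truth = truth
    return pd.DataFrame(table), types


def generate_second_cohort(
    gt: SyntheticGroundTruth,
    n2: int,
    mean_shift: float = 0.0,
    scale_shift: float = 0.0,
    seed: int = 1,
) -> PairedPlatformMatrix:
    """A new cohort from the same loadings with fresh latent draws and
    per-probe location (``mean_shift``) and scale (``1 + scale_shift``)
    shifts on the raw (pre-platform-scale) values."""
    rng = np.random.default_rng(seed)
    k, d_a = gt.w_a.shape
    d_b = gt.w_b.shape[1]
    z = rng.standard_normal((n2, k))
    g = _nonlin if gt.nonlinear else (lambda t: t)
    raw_a = g(z @ gt.w_a) + gt.noise_sd_a * rng.standard_normal((n2, d_a))
    raw_b = g(z @ gt.w_b) + gt.noise_sd_b * rng.standard_normal((n2, d_b))
    raw_a = raw_a * (1.0 + scale_shift) + mean_shift
    raw_b = raw_b * (1.0 + scale_shift) + mean_shift
    return PairedPlatformMatrix(
        samples=[f"T{i:05d}" for i in range(n2)],
        platform_a=raw_a + A_OFFSET,
        platform_b=np.exp2(raw_b + B_OFFSET),
        probes_a=probe_names(d_a, "A"),
        probes_b=probe_names(d_b, "B"),
        probe_map=mapped_pairs(gt),
    )


PRESETS = {
    "small": dict(n=600, d_a=60, d_b=60, k=10),
    "medium": dict(n=3000, d_a=300, d_b=300, k=30),
}


def generate_preset(name: str, seed: int = 0, **overrides):
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = {**PRESETS[name], **overrides}
    return generate_cohort(seed=seed, **kwargs)
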