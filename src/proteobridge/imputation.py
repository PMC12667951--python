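"""Cross-platform inference with a trained joint VAE.

The default point estimate decodes the posterior mean: for direction A->B,
xhat^B = f_dec^B(mu_A(x^A)). Sampling mode instead decodes one
reparameterised draw for uncertainty exploration. The external-cohort path
standardises the new cohort on its own distribution, checks that all model
input probes are supplied (no silent zero-fill), and can de-standardise the
output into target-cohort units.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .io_preprocess import PlatformMatrix, StandardizationParams, zscore_apply, zscore_fit, zscore_invert
from .jvae import JointVAE, reparameterize

_DIRECTIONS = {"A2B": ("A", "B"), "B2A": ("B", "A")}


def _parse_direction(direction: str) -> tuple[str, str]:
    key = direction.replace("->", "2").replace("→", "2").upper()
    if key not in _DIRECTIONS:
        raise ValueError("direction must be 'A2B' or 'B2A'")
    return _DIRECTIONS[key]


def impute(
    x_source: np.ndarray,
    direction: str,
    model: JointVAE,
    mode: str = "mean",
    seed: Optional[int] = None,
) -> np.ndarray:
    """Impute the other platform's profiles for standardized source data.

    ``mode='mean'`` (default) decodes the posterior mean and is
    deterministic; ``mode='sample'`` decodes one reparameterised draw using
    ``seed``.
    """
    src, tgt = _parse_direction(direction)
    x_source = np.atleast_2d(np.asarray(x_source, dtype=np.float64))
    d_expected = model.config.d_a if src == "A" else model.config.d_b
    if x_source.shape[1] != d_expected:
        raise ValueError(f"source width {x_source.shape[1]} != model d_{src.lower()} {d_expected}")
    col_means = np.abs(x_source.mean(axis=0))
    if x_source.shape[0] >= 10 and np.median(col_means) > 1.0:
        warnings.warn(
            "input columns are far from zero mean; did you standardize the source cohort?"
        )
    model.eval()
    post = model.encode(x_source, src)
    if mode == "mean":
        z = post.mu
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(post.mu.shape)
        z = reparameterize(post.mu, post.log_var, eps)
    else:
        raise ValueError("mode must be 'mean' or 'sample'")
    return model.decode(z, tgt)


def latent_embed(x: np.ndarray, platform: str, model: JointVAE) -> np.ndarray:
    """Posterior means mu in the shared latent space (N x d_z)."""
    model.eval()
    return model.encode(np.atleast_2d(np.asarray(x, dtype=np.float64)), platform).mu


def apply_external(
    model: JointVAE,
    external: PlatformMatrix,
    model_probes: Sequence[str],
    direction: str,
    cohort: str = "external",
    target_params: Optional[StandardizationParams] = None,
) -> tuple[np.ndarray, StandardizationParams]:
    """Impute an external cohort without fine-tuning.

    The external matrix must supply every model input probe (by ID); it is
    standardised using parameters fit on the external cohort's own
    distribution, imputed, and optionally de-standardised into target-cohort
    units via ``target_params``. Returns (imputed matrix, the external
    standardisation parameters used).
    """
    missing = [p for p in model_probes if p not in set(external.probes)]
    if missing:
        raise ValueError(
            f"external cohort is missing {len(missing)} model input probes: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    order = [external.probes.index(p) for p in model_probes]
    values = external.values[:, order]
    if np.isnan(values).any():
        raise ValueError("external cohort contains missing values; handle missingness first")
    params = zscore_fit(values, list(model_probes), cohort=cohort)
    x_std = zscore_apply(values, params)
    imputed = impute(x_std, direction, model, mode="mean")
    if target_params is not None:
        imputed = zscore_invert(imputed, target_params)
    return imputed, params
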