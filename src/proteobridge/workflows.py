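"""End-to-end convenience pipelines tying the modules together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_preprocess import (
    PairedPlatformMatrix,
    SplitAssignment,
    StandardizationParams,
    log2_transform,
    make_splits,
    zscore_apply,
    zscore_fit,
)
from .jvae import JointVAE, LossWeights, NetworkConfig
from .training import TrainConfig, TrainHistory, train


@dataclass
class PreparedData:
    """Standardized platform matrices plus the parameters that produced them."""

    xa: np.ndarray
    xb: np.ndarray
    params_a: StandardizationParams
    params_b: StandardizationParams
    split: SplitAssignment


def prepare(
    paired: PairedPlatformMatrix,
    split: Optional[SplitAssignment] = None,
    seed: int = 0,
    log2_platform_b: bool = True,
    fit_on: str = "train",
    cohort: str = "train_cohort",
) -> PreparedData:
    """Standard preprocessing: log2 platform B (RFU-like), feature-wise
    Z-score both platforms. By default standardisation parameters are fit on
    the training split only and applied to all splits; ``fit_on='all'``
    mimics fit-on-everything."""
    xa = paired.platform_a.astype(np.float64)
    xb = paired.platform_b.astype(np.float64)
    if log2_platform_b:
        xb = log2_transform(xb, paired.probes_b)
    if split is None:
        split = make_splits(paired.n_samples, seed=seed)
    if fit_on == "train":
        rows = split.train
    elif fit_on == "all":
        rows = np.arange(paired.n_samples)
    else:
        raise ValueError("fit_on must be 'train' or 'all'")
    params_a = zscore_fit(xa[rows], paired.probes_a, cohort=cohort)
    params_b = zscore_fit(xb[rows], paired.probes_b, cohort=cohort)
    return PreparedData(
        xa=zscore_apply(xa, params_a),
        xb=zscore_apply(xb, params_b),
        params_a=params_a,
        params_b=params_b,
        split=split,
    )


def fit_jvae(
    prepared: PreparedData,
    network: Optional[NetworkConfig] = None,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> tuple[JointVAE, TrainHistory]:
    """Build and train a joint VAE on prepared (standardized) data."""
    d_a, d_b = prepared.xa.shape[1], prepared.xb.shape[1]
    if network is None:
        network = NetworkConfig(d_a=d_a, d_b=d_b)
    if config is None:
        config = TrainConfig(seed=seed, network=network)
    model = JointVAE(network, seed=config.seed)
    return train(model, prepared.xa, prepared.xb, prepared.split, config)
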