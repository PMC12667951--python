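"""Shared fixtures: linear toy models, a small trained model, and the
session-level medium-scale training run reused by the acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import proteobridge as pb
from proteobridge.jvae import JointVAE, NetworkConfig
from proteobridge.training import TrainConfig


def linear_toy_config(d_a=6, d_b=5, d_z=3, hidden=8) -> NetworkConfig:
    """Purely affine network: identity activations, no batchnorm/dropout,
    no residual blocks — encode/decode reduce to explicit matrix products."""
    return NetworkConfig(
        d_a=d_a, d_b=d_b, d_z=d_z, hidden=hidden,
        dropout=0.0, use_batchnorm=False, activation="identity", n_res_blocks=0,
    )


def affine_imputation_map(model: JointVAE, direction: str = "A2B"):
    """Closed-form (W, b) of the mean-path imputation for a linear toy."""
    enc = model.enc_a if direction == "A2B" else model.enc_b
    dec = model.dec_b if direction == "A2B" else model.dec_a
    w1, b1 = enc.stem.layers[0].weight.data, enc.stem.layers[0].bias.data
    wmu, bmu = enc.mu_head.weight.data, enc.mu_head.bias.data
    w2, b2 = dec.stem.layers[0].weight.data, dec.stem.layers[0].bias.data
    wout, bout = dec.out.weight.data, dec.out.bias.data
    w_enc = w1 @ wmu
    b_enc = b1 @ wmu + bmu
    w_dec = w2 @ wout
    b_dec = b2 @ wout + bout
    return w_enc @ w_dec, b_enc @ w_dec + b_dec


@pytest.fixture
def linear_toy() -> JointVAE:
    model = JointVAE(linear_toy_config(), seed=11)
    model.eval()
    return model


@dataclass
class SmallRun:
    paired: object
    gt: object
    prep: object
    model: JointVAE


@pytest.fixture(scope="session")
def small_run() -> SmallRun:
    """Quickly trained small-preset model for trained-model properties."""
    paired, gt = pb.generate_preset("small", seed=3)
    prep = pb.prepare(paired, seed=3)
    net = NetworkConfig(d_a=60, d_b=60, d_z=8, hidden=64)
    cfg = TrainConfig(seed=3, network=net, max_epochs=40, patience=40, learning_rate=2e-3)
    model, _ = pb.fit_jvae(prep, network=net, config=cfg)
    return SmallRun(paired=paired, gt=gt, prep=prep, model=model)


@dataclass
class MediumRun:
    paired: object
    gt: object
    prep: object
    model: JointVAE
    history: object


@pytest.fixture(scope="session")
def medium_run() -> MediumRun:
    """The reference synthetic study: medium preset (N=3000, d=300, K=30),
    linear generator at the default noise level, reduced joint VAE
    (d_z=16, hidden 128) trained for up to 60 epochs."""
    paired, gt = pb.generate_preset("medium", seed=5)
    prep = pb.prepare(paired, seed=5)
    net = NetworkConfig(d_a=300, d_b=300, d_z=16, hidden=128)
    cfg = TrainConfig(seed=5, network=net, max_epochs=60, patience=10, learning_rate=3e-3)
    model, history = pb.fit_jvae(prep, network=net, config=cfg)
    return MediumRun(paired=paired, gt=gt, prep=prep, model=model, history=history)
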