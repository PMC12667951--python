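"""Optimisation protocol for the joint VAE.

Training uses AdamW (learning rate 4e-4, decoupled weight decay) on
mini-batches of 256 samples, Xavier/Glorot-initialised weights, a maximum of
200 epochs, and early stopping when the total weighted loss on the dedicated
early-stopping split has not improved for 10 consecutive epochs; the weights
from the best early-stopping epoch are restored on exit.

``tune_hyperparameters`` evaluates candidate configurations on the tuning
split behind a declared search-space contract, using a seeded random-search
sampler (or an exhaustive grid); after tuning, the recommended pipeline is
to retrain from scratch with the selected configuration.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .autodiff import as_tensor
from .io_preprocess import SplitAssignment
from .jvae import (
    JointVAE,
    KernelConfig,
    LossBreakdown,
    LossWeights,
    NetworkConfig,
)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    learning_rate: float = 4e-4
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    network: Optional[NetworkConfig] = None
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning rate, batch size, epochs and patience must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max epochs")


@dataclass
class TrainHistory:
    train: list[LossBreakdown] = field(default_factory=list)
    early_stop: list[LossBreakdown] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, (tr, es) in enumerate(zip(self.train, self.early_stop)):
            row = {"epoch": i}
            row.update({f"train_{k}": v for k, v in tr.as_dict().items()})
            row.update({f"early_stop_{k}": v for k, v in es.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def initialize_weights(model: JointVAE, seed: int) -> JointVAE:
    """Re-initialise: Xavier-uniform weight matrices, zero biases, fresh
    batchnorm statistics. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    for _, mod in model.named_modules():
        if isinstance(mod, nn.Linear):
            mod.weight.data = nn.xavier_uniform(mod.weight.data.shape, rng)
            mod.bias.data = np.zeros_like(mod.bias.data)
        elif isinstance(mod, nn.BatchNorm1d):
            mod.gamma.data = np.ones_like(mod.gamma.data)
            mod.beta.data = np.zeros_like(mod.beta.data)
            mod.running_mean = np.zeros_like(mod.running_mean)
            mod.running_var = np.ones_like(mod.running_var)
    return model


def _check_finite(breakdown: LossBreakdown) -> None:
    bad = [k for k, v in breakdown.as_dict().items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite loss component(s): {bad}")


def evaluate_loss(
    model: JointVAE,
    xa: np.ndarray,
    xb: np.ndarray,
    weights: LossWeights,
    kernel: KernelConfig,
) -> LossBreakdown:
    """Deterministic eval-mode loss with zero-noise latent draws (z = mu)."""
    model.eval()
    _, _, breakdown = model.forward_joint(xa, xb, weights=weights, kernel=kernel)
    return breakdown


def train(
    model: JointVAE,
    xa: np.ndarray,
    xb: np.ndarray,
    split: SplitAssignment,
    config: TrainConfig,
) -> tuple[JointVAE, TrainHistory]:
    """Optimise the joint objective with early stopping.

    ``xa``/``xb`` are the full standardized matrices; the split selects the
    train and early-stop rows. Returns the model carrying the best-epoch
    weights and the per-epoch history.
    """
    xa = np.asarray(xa, dtype=np.float64)
    xb = np.asarray(xb, dtype=np.float64)
    n = xa.shape[0]
    for idx in (split.train, split.early_stop):
        if idx.size and idx.max() >= n:
            raise ValueError("split references rows beyond the data")
    if split.train.size < 2 or split.early_stop.size < 2:
        raise ValueError("train and early-stop splits each need at least 2 samples")
    initialize_weights(model, config.seed)
    batch_size = min(config.batch_size, split.train.size)
    opt = nn.AdamW(
        list(model.parameters()),
        lr=config.learning_rate,
        weight_decay=model.config.weight_decay,
    )
    history = TrainHistory()
    best_state: Optional[dict[str, np.ndarray]] = None
    best_total = np.inf
    stale = 0
    master = np.random.default_rng(config.seed)
    epoch_seeds = master.integers(0, 2**31 - 1, size=config.max_epochs)

    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(split.train)
        model.train()
        comp_sums = np.zeros(5)
        n_seen = 0
        for start in range(0, order.size, batch_size):
            batch = order[start : start + batch_size]
            if batch.size < 2:
                continue  # MMD needs >= 2 samples; a trailing singleton is skipped
            eps_a = rng.standard_normal((batch.size, model.config.d_z))
            eps_b = rng.standard_normal((batch.size, model.config.d_z))
            _, tot, breakdown = model.forward_joint(
                xa[batch], xb[batch], eps_a, eps_b, config.weights, config.kernel
            )
            _check_finite(breakdown)
            opt.zero_grad()
            tot.backward()
            opt.step()
            comp_sums += batch.size * np.array(
                [breakdown.rec, breakdown.cross, breakdown.kl, breakdown.align, breakdown.total]
            )
            n_seen += batch.size
        mean = comp_sums / max(n_seen, 1)
        history.train.append(LossBreakdown(rec=mean[0], cross=mean[1], kl=mean[2], align=mean[3], total=mean[4]))
        es = evaluate_loss(model, xa[split.early_stop], xb[split.early_stop], config.weights, config.kernel)
        _check_finite(es)
        history.early_stop.append(es)
        if es.total < best_total:
            best_total = es.total
            best_state = model.state_dict()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history.stop_reason = f"early stop: no improvement for {config.patience} epochs"
                break
    else:
        history.stop_reason = "reached max epochs"
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# --------------------------------------------------------------------------
# hyperparameter search
# --------------------------------------------------------------------------


def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log_uniform":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "choice":
            out[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown search-space kind {kind!r} for {name!r}")
    return out


_NETWORK_KEYS = {"d_z", "hidden", "dropout", "weight_decay", "use_batchnorm", "n_res_blocks", "activation"}
_WEIGHT_KEYS = {"lambda_rec", "lambda_cross", "lambda_kl", "lambda_align"}


def _apply_params(base: TrainConfig, params: dict) -> TrainConfig:
    cfg = replace(base)
    net = replace(base.network) if base.network else None
    wts = replace(base.weights)
    for k, v in params.items():
        if k == "learning_rate":
            cfg = replace(cfg, learning_rate=float(v))
        elif k in _NETWORK_KEYS:
            if net is None:
                raise ValueError("search over network keys requires TrainConfig.network")
            net = replace(net, **{k: int(v) if k in ("d_z", "hidden", "n_res_blocks") else v})
        elif k in _WEIGHT_KEYS:
            wts = replace(wts, **{k: float(v)})
        else:
            raise ValueError(f"unknown tunable parameter {k!r}")
    return replace(cfg, network=net, weights=wts)


def tune_hyperparameters(
    space: dict,
    xa: np.ndarray,
    xb: np.ndarray,
    split: SplitAssignment,
    budget: int,
    seed: int,
    base_config: TrainConfig,
    objective: str = "total_loss",
    sampler: str = "random",
) -> tuple[TrainConfig, list[dict]]:
    """Search ``space`` for the configuration with the best tuning-split score.

    ``space`` maps parameter names (learning_rate, d_z, hidden, dropout,
    lambda_* ...) to ('uniform', lo, hi), ('log_uniform', lo, hi) or
    ('choice', [values]). ``objective`` is 'total_loss' (minimised) or
    'cross_r' (median feature-wise cross-imputation Pearson r on the tuning
    split, maximised). Returns the winning TrainConfig plus a per-trial log.
    """
    if budget < 1:
        raise ValueError("trial budget must be >= 1")
    if base_config.network is None:
        raise ValueError("base_config.network must be set for tuning")
    if objective not in ("total_loss", "cross_r"):
        raise ValueError("objective must be 'total_loss' or 'cross_r'")
    rng = np.random.default_rng(seed)
    if sampler == "random":
        candidates = [_sample_space(space, rng) for _ in range(budget)]
    elif sampler == "grid":
        for name, spec in space.items():
            if spec[0] != "choice":
                raise ValueError("grid sampler requires 'choice' entries only")
        keys = list(space)
        grids = [space[k][1] for k in keys]
        candidates = [dict(zip(keys, combo)) for combo in itertools.product(*grids)][:budget]
    else:
        raise ValueError("sampler must be 'random' or 'grid'")

    trials: list[dict] = []
    best_score = np.inf
    best_cfg = base_config
    for i, params in enumerate(candidates):
        cfg = _apply_params(base_config, params)
        cfg = replace(cfg, seed=base_config.seed)
        model = JointVAE(cfg.network, seed=cfg.seed)
        model, _ = train(model, xa, xb, split, cfg)
        if objective == "total_loss":
            es = evaluate_loss(model, xa[split.tune], xb[split.tune], cfg.weights, cfg.kernel)
            score = es.total
        else:
            from .evaluation import correlation_report
            from .imputation import impute

            xb_hat = impute(xa[split.tune], "A2B", model)
            rep = correlation_report(xb_hat, xb[split.tune])
            score = -rep.median_feature_r  # maximise r
        trials.append({"trial": i, "params": params, "score": float(score)})
        if score < best_score:
            best_score = score
            best_cfg = cfg
    return best_cfg, trials


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------


def save_checkpoint(
    model: JointVAE,
    path: str | Path,
    weights: Optional[LossWeights] = None,
    probes_a: Optional[Sequence[str]] = None,
    probes_b: Optional[Sequence[str]] = None,
    standardization_provenance: Optional[dict] = None,
) -> None:
    """Write weights (npz) plus a JSON sidecar of all hyperparameters."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "network": asdict(model.config),
        "loss_weights": asdict(weights) if weights else asdict(LossWeights()),
        "probes_a": list(probes_a) if probes_a is not None else None,
        "probes_b": list(probes_b) if probes_b is not None else None,
        "standardization_provenance": standardization_provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> tuple[JointVAE, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(
            f"checkpoint format version {sidecar.get('format_version')} "
            f"!= supported {CHECKPOINT_FORMAT_VERSION}"
        )
    config = NetworkConfig(**sidecar["network"])
    model = JointVAE(config, seed=0)
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.eval()
    return model, sidecar
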