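"""Training loops: pretraining, fine-tuning, and hyperparameter search.

The workflow mirrors a foundation-model strategy for vessel segmentation:
pretrain one network on several chunked stores at once (store selection
weighted, e.g. 5:4:1:1, so small datasets are not over-sampled), then
specialize the checkpoint to a new imaging style by fine-tuning on a single
small labelled subvolume of the new data.

Optimisation is Adam with a continuous exponential-decay learning-rate
schedule ``lr = lr0 * rate^(step / decay_steps)``. An "epoch" is a fixed
number of randomly sampled batches (sampling is random rather than a sweep
over data), after which the monitored validation metric is evaluated on
held-out subvolumes via tiled inference; training stops early when the
metric fails to improve for ``patience`` epochs, and the best checkpoint is
always the one returned. Hyperparameters (initial learning rate, activation,
dropout) can be chosen by uniform random search over a small grid.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .infer import predict_volume
from .losses import LossSpec, get_loss
from .metrics import auroc, average_precision, dice_score
from .nn.unet import CHECKPOINT_FORMAT_VERSION, NetworkConfig, UNet3D
from .patches import AugmentationConfig, SamplerPolicy, make_batch

__all__ = ["TrainConfig", "TrainState", "SearchSpace", "Adam", "lr_at_step",
           "labelled_fraction",
           "pretrain", "finetune", "random_search", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class TrainConfig:
    loss: LossSpec = field(default_factory=LossSpec)
    initial_lr: float = 0.001
    lr_decay_rate: float = 0.96
    lr_decay_steps: int = 1000
    batch_size: int = 6
    steps_per_epoch: int = 100
    max_epochs: int = 10
    patience: int = 10
    monitor: str = "dice"            # dice | auroc | ap | loss
    finetune_lr_scale: float = 0.1
    sampler: SamplerPolicy = field(default_factory=SamplerPolicy)
    augmentation: AugmentationConfig | None = field(
        default_factory=AugmentationConfig)
    validation: list = field(default_factory=list)
    # validation: list of (store_index, origin, shape) held-out regions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if not 0.0 < self.lr_decay_rate <= 1.0:
            raise ValueError("lr_decay_rate must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("dice", "auroc", "ap", "loss"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class TrainState:
    """Outcome of a training run: weights, history, best-checkpoint info."""

    net: UNet3D
    history: list                    # one dict per completed epoch
    best_epoch: int
    best_metric: float
    checkpoint_path: str | None = None
    config: TrainConfig | None = None


@dataclass
class SearchSpace:
    """Grid for uniform random hyperparameter search (without replacement)."""

    learning_rates: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    activations: tuple = (("relu", 0.0), ("leaky_relu", 0.1),
                          ("leaky_relu", 0.2), ("leaky_relu", 0.3))
    dropout_rates: tuple[float, ...] = (0.1, 0.2, 0.3)
    n_iterations: int = 15

    def candidates(self) -> list[dict]:
        return [{"initial_lr": lr, "activation": act[0],
                 "leaky_alpha": act[1], "dropout_rate": dr}
                for lr, act, dr in itertools.product(
                    self.learning_rates, self.activations,
                    self.dropout_rates)]


def labelled_fraction(region_shape, volume_shape) -> float:
    """Fraction of a dataset's voxels covered by a labelled subvolume.

    The budget a user pays for fine-tuning: e.g. a 79 x 500 x 250 labelled
    block of a 1536 x 1536 x 79 two-photon volume is ~5% of the data.
    """
    region = np.prod([int(s) for s in region_shape], dtype=np.int64)
    volume = np.prod([int(s) for s in volume_shape], dtype=np.int64)
    if region <= 0 or volume <= 0 or region > volume:
        raise ValueError("region must be non-empty and within the volume")
    return float(region / volume)


def lr_at_step(config: TrainConfig, step: int) -> float:
    """Continuous (non-staircase) exponential decay."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return config.initial_lr * config.lr_decay_rate ** (
        step / config.lr_decay_steps)


class Adam:
    """Adam optimiser over a network's parameter iterator."""

    def __init__(self, net: UNet3D, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in net.parameters()}
        self.v = {name: np.zeros_like(v) for name, v, _ in net.parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, value, grad in self.net.parameters():
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * grad
            v *= b2
            v += (1.0 - b2) * grad * grad
            value -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(net: UNet3D, path, history: list | None = None) -> None:
    """Write weights (.npz) plus network config and history (JSON sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **net.state_dict())
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "network_config": json.loads(net.config.to_json())}
    (path / "checkpoint.json").write_text(json.dumps(meta, indent=2),
                                          encoding="utf-8")
    if history is not None:
        (path / "history.json").write_text(json.dumps(history, indent=2),
                                           encoding="utf-8")


def load_checkpoint(path) -> UNet3D:
    path = Path(path)
    meta = json.loads((path / "checkpoint.json").read_text(encoding="utf-8"))
    config = NetworkConfig.from_json(json.dumps(meta["network_config"]))
    net = UNet3D(config)
    with np.load(path / "weights.npz") as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net


# -- validation -------------------------------------------------------------

def _one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    out[..., 1] = labels
    out[..., 0] = 1.0 - labels
    return out


def _validate(net: UNet3D, stores, validation, threshold: float = 0.5) -> dict:
    """Predict each held-out region by tiled inference and score it."""
    dices, aurocs, aps = [], [], []
    for store_index, origin, shape in validation:
        store = stores[store_index]
        image = store.read_subvolume(origin, shape, "image")
        truth = store.read_subvolume(origin, shape, "labels")
        prob = predict_volume(net, image, overlap=0)
        dices.append(dice_score(prob >= threshold, truth))
        if truth.any() and not truth.all():
            aurocs.append(auroc(prob, truth))
            aps.append(average_precision(prob, truth))
    return {"dice": float(np.mean(dices)) if dices else float("nan"),
            "auroc": float(np.mean(aurocs)) if aurocs else float("nan"),
            "ap": float(np.mean(aps)) if aps else float("nan")}


# -- training loops ---------------------------------------------------------

def _train_loop(net: UNet3D, stores, config: TrainConfig,
                rng: np.random.Generator, out_dir=None,
                log=None) -> TrainState:
    lossfn = get_loss(config.loss)
    opt = Adam(net)
    higher_better = config.monitor != "loss"
    best_metric = -np.inf if higher_better else np.inf
    best_state = net.state_dict()
    best_epoch = -1
    patience_left = config.patience
    history: list[dict] = []
    step = 0
    for epoch in range(config.max_epochs):
        losses = []
        for _ in range(config.steps_per_epoch):
            batch = make_batch(stores, config.sampler, config.augmentation,
                               config.batch_size, rng)
            x = batch.images[..., None]
            t = _one_hot(batch.labels)
            probs = net.forward(x, train=True, rng=rng)
            loss, dloss = lossfn(probs, t)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at step {step}; aborting")
            net.zero_grad()
            net.backward(dloss.astype(np.float32))
            opt.step(lr_at_step(config, step))
            step += 1
            losses.append(loss)
        val = (_validate(net, stores, config.validation)
               if config.validation else {})
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "lr": lr_at_step(config, step), **val}
        history.append(record)
        if log is not None:
            log(record)
        monitored = (record["train_loss"] if config.monitor == "loss"
                     else val.get(config.monitor, float("nan")))
        record["monitored"] = monitored
        improved = (monitored > best_metric if higher_better
                    else monitored < best_metric)
        if np.isfinite(monitored) and improved:
            best_metric = monitored
            best_epoch = epoch
            best_state = net.state_dict()
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_epoch >= 0:
        net.load_state_dict(best_state)
    checkpoint_path = None
    if out_dir is not None:
        checkpoint_path = str(out_dir)
        save_checkpoint(net, out_dir, history)
    return TrainState(net=net, history=history, best_epoch=best_epoch,
                      best_metric=float(best_metric),
                      checkpoint_path=checkpoint_path, config=config)


def pretrain(stores, config: TrainConfig,
             network_config: NetworkConfig | None = None,
             net: UNet3D | None = None, out_dir=None,
             log=None) -> TrainState:
    """Train a fresh network on one or more labelled stores.

    ``config.sampler.dataset_weights`` must have one weight per store.
    Validation regions (``config.validation``) are evaluated as whole
    subvolumes by tiled inference after every epoch.
    """
    if not stores:
        raise ValueError("pretrain requires at least one labelled store")
    if any(s.labels is None for s in stores):
        raise ValueError("all pretraining stores must carry labels")
    rng = np.random.default_rng(config.seed)
    if net is None:
        network_config = network_config or NetworkConfig()
        net = UNet3D(network_config,
                     np.random.default_rng(network_config.init_seed))
    return _train_loop(net, stores, config, rng, out_dir, log)


def finetune(checkpoint, store, labelled_region, config: TrainConfig,
             out_dir=None, log=None) -> TrainState:
    """Specialize a pretrained checkpoint on one labelled subvolume.

    ``labelled_region`` is an ``(origin, shape)`` box within ``store``;
    patch sampling is restricted to it. Optimiser state is reset and the
    initial learning rate is scaled by ``config.finetune_lr_scale``
    (default 0.1), standard transfer-learning practice.
    """
    net = (checkpoint if isinstance(checkpoint, UNet3D)
           else load_checkpoint(checkpoint))
    origin, shape = labelled_region
    if any(s < p for s, p in zip(shape, config.sampler.patch_shape)):
        raise ValueError(f"labelled region {shape} smaller than patch "
                         f"{config.sampler.patch_shape}")
    if any(o + s > d for o, s, d in zip(origin, shape, store.shape)):
        raise ValueError("labelled region exceeds store bounds")
    ft_config = TrainConfig(**{**asdict_shallow(config),
                               "initial_lr": config.initial_lr
                               * config.finetune_lr_scale})
    ft_config.sampler = SamplerPolicy(
        patch_shape=config.sampler.patch_shape,
        dataset_weights=(1.0,),
        vessel_fraction_threshold=config.sampler.vessel_fraction_threshold,
        background_retain_prob=config.sampler.background_retain_prob,
        regions=((tuple(origin), tuple(shape)),))
    rng = np.random.default_rng(ft_config.seed)
    return _train_loop(net, [store], ft_config, rng, out_dir, log)


def asdict_shallow(config: TrainConfig) -> dict:
    """Shallow field dict of a TrainConfig (nested dataclasses unconverted)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def random_search(space: SearchSpace, train_fn, n_iterations: int | None = None,
                  seed: int = 0):
    """Uniform random search over the hyperparameter grid.

    ``train_fn(candidate: dict) -> score`` trains a model under a fixed
    small budget and returns the validation score (higher is better).
    Candidates are drawn without replacement. Returns ``(best_candidate,
    leaderboard)`` with the leaderboard sorted best-first.
    """
    candidates = space.candidates()
    if not candidates:
        raise ValueError("empty search space")
    n = n_iterations if n_iterations is not None else space.n_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    if n > len(candidates):
        warnings.warn(f"n_iterations {n} exceeds grid size "
                      f"{len(candidates)}; evaluating the full grid")
        n = len(candidates)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    leaderboard = []
    for idx in chosen:
        candidate = candidates[int(idx)]
        score = train_fn(dict(candidate))
        leaderboard.append({"candidate": candidate, "score": float(score)})
    leaderboard.sort(key=lambda r: r["score"], reverse=True)
    return leaderboard[0]["candidate"], leaderboard
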