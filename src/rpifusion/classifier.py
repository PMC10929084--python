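"""Parallel multi-branch convolutional classifier.

Each feature block (sequence, structure, physicochemical, PPI) feeds its
own convolutional branch: three kernel-3 1-D convolutions arranged as two
pooled stages — the first stage holds two convolutions, then ReLU, batch
normalization and max pooling; the second holds one convolution followed
by the same ReLU/BN/pool trio. ReLU is applied before batch normalization
throughout. Branch outputs are flattened and fused — by concatenation
(default) into a single vector, or by stacking, where per-branch networks
produce class probabilities that a second-stage logistic model combines.
The fused vector passes through fully connected layers of 16, 8 and 2
units and a softmax; a pair is called interacting when the positive-class
probability exceeds 0.5 (strictly).

Branches whose input is too short to survive three convolutions and two
poolings fall back to a single convolution + pooling stage (logged);
inputs shorter than 4 are rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import ConfigError, DimensionError, SingleClassError, StrategyError
from .io import InteractionPair
from . import nn

logger = logging.getLogger(__name__)

DECISION_THRESHOLD = 0.5
FC_SIZES = (16, 8, 2)


@dataclass
class ModelConfig:
    """Hyperparameters of the multi-branch network.

    The FC head (16, 8, 2), kernel size 3 and the 0.5 decision threshold
    are architectural constants; channels, pooling, optimizer and the
    training schedule are tunable.
    """

    channels: int = 16
    kernel: int = 3
    pool: int = 2
    fusion: str = "concatenate"  # or "stacking"
    optimizer: str = "adam"  # or "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    early_stopping_patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion not in ("concatenate", "stacking"):
            raise StrategyError(f"unknown fusion strategy {self.fusion!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.kernel != 3:
            raise ConfigError("kernel size is fixed at 3")


@dataclass
class ScoredPrediction:
    """Per-pair true label, positive-class score, and thresholded class."""

    pair: InteractionPair
    score: float

    @property
    def predicted(self) -> int:
        return int(self.score > DECISION_THRESHOLD)


def fuse(branch_outputs: list[np.ndarray], strategy: str) -> np.ndarray:
    """Fuse per-branch outputs into the head's input.

    ``concatenate`` joins flattened branch outputs column-wise;
    ``stacking`` joins per-branch predicted probability pairs into the
    meta-feature matrix of the second-stage classifier (two columns per
    branch).
    """
    if len(branch_outputs) < 2:
        raise DimensionError("fusion requires at least two branch outputs")
    if strategy == "concatenate":
        return np.hstack(branch_outputs)
    if strategy == "stacking":
        for out in branch_outputs:
            if out.shape[1] != 2:
                raise DimensionError(
                    "stacking fuses per-branch probability pairs (width 2)"
                )
        return np.hstack(branch_outputs)
    raise StrategyError(f"unknown fusion strategy {strategy!r}")


def _branch_layers(
    dim: int, cfg: ModelConfig, rng: np.random.Generator
) -> tuple[list[nn.Layer], int]:
    """Build one conv branch; returns (layers, flattened output width)."""
    ch, k, p = cfg.channels, cfg.kernel, cfg.pool
    full_min = 3 * (k - 1) + 2 * p + 2  # survives 3 convs + 2 pools
    if dim >= full_min:
        layers: list[nn.Layer] = [
            nn.Conv1d(1, ch, k, rng),
            nn.Conv1d(ch, ch, k, rng),
            nn.ReLU(),
            nn.BatchNorm1d(ch),
            nn.MaxPool1d(p),
            nn.Conv1d(ch, ch, k, rng),
            nn.ReLU(),
            nn.BatchNorm1d(ch),
            nn.MaxPool1d(p),
            nn.Flatten(),
        ]
        L = (dim - 2 * (k - 1)) // p
        L = (L - (k - 1)) // p
    elif dim >= k + p - 1:
        logger.warning(
            "branch input dim %d too small for the full stack; "
            "falling back to a single conv + pool",
            dim,
        )
        layers = [
            nn.Conv1d(1, ch, k, rng),
            nn.ReLU(),
            nn.BatchNorm1d(ch),
            nn.MaxPool1d(p),
            nn.Flatten(),
        ]
        L = (dim - (k - 1)) // p
    else:
        raise ConfigError(f"branch input dim {dim} too small to convolve")
    return layers, L * ch


class RpiConvNet:
    """Multi-branch conv network with a concatenated FC 16-8-2 head."""

    def __init__(self, block_dims: dict[str, int], config: ModelConfig):
        if any(d <= 0 for d in block_dims.values()):
            raise ConfigError("all block dims must be positive")
        self.config = config
        self.block_names = list(block_dims)
        self.block_dims = dict(block_dims)
        rng = np.random.default_rng(config.seed)
        self.branches: dict[str, nn.Sequential] = {}
        widths = []
        for name, dim in block_dims.items():
            layers, width = _branch_layers(dim, config, rng)
            self.branches[name] = nn.Sequential(layers)
            widths.append(width)
        fused = sum(widths)
        head_layers: list[nn.Layer] = []
        d_in = fused
        for i, d_out in enumerate(FC_SIZES):
            head_layers.append(nn.Dense(d_in, d_out, rng))
            if i < len(FC_SIZES) - 1:
                head_layers.append(nn.ReLU())
            d_in = d_out
        self.head = nn.Sequential(head_layers)
        self._widths = widths
        self.loss_history: list[float] = []
        # per-block input standardization, fitted on the training set
        self.norm: dict[str, tuple[np.ndarray, np.ndarray]] = {
            name: (np.zeros(dim), np.ones(dim))
            for name, dim in block_dims.items()
        }

    def fit_normalization(self, blocks: dict[str, np.ndarray]) -> None:
        """Fit per-column mean/sd on the training blocks (sd floor 1e-8)."""
        for name in self.block_names:
            x = np.asarray(blocks[name], dtype=np.float64)
            self.norm[name] = (x.mean(axis=0), x.std(axis=0) + 1e-8)

    @property
    def params(self) -> list[nn.Param]:
        out = []
        for name in self.block_names:
            out.extend(self.branches[name].params)
        out.extend(self.head.params)
        return out

    def _forward(
        self, blocks: dict[str, np.ndarray], training: bool
    ) -> np.ndarray:
        outs = []
        for name in self.block_names:
            x = np.asarray(blocks[name], dtype=np.float64)
            if x.shape[1] != self.block_dims[name]:
                raise DimensionError(
                    f"block {name!r}: got dim {x.shape[1]}, "
                    f"model expects {self.block_dims[name]}"
                )
            mean, sd = self.norm[name]
            x = (x - mean) / sd
            outs.append(
                self.branches[name].forward(x[:, None, :], training)
            )
        fused = fuse(outs, "concatenate") if len(outs) > 1 else outs[0]
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        return self.head.forward(fused, training)

    def _backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        parts = np.split(grad, self._split, axis=1) if self._split.size else [grad]
        for name, g in zip(self.block_names, parts):
            self.branches[name].backward(g)

    def predict_proba(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        return nn.softmax(self._forward(blocks, training=False))

    def state_params(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params]
        for branch in list(self.branches.values()) + [self.head]:
            for layer in branch.layers:
                if isinstance(layer, nn.BatchNorm1d):
                    arrays.extend([layer.running_mean, layer.running_var])
        for name in self.block_names:
            arrays.extend(self.norm[name])
        return arrays

    def load_state_params(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params:
            p.value = next(it).copy()
        for branch in list(self.branches.values()) + [self.head]:
            for layer in branch.layers:
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean = next(it).copy()
                    layer.running_var = next(it).copy()
        for name in self.block_names:
            self.norm[name] = (next(it).copy(), next(it).copy())


def train(
    model: RpiConvNet,
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    config: ModelConfig | None = None,
) -> list[float]:
    """Train with cross-entropy; returns the per-epoch loss history.

    Uses an internal stratified validation split for early stopping
    (patience in epochs, best weights restored) when the training set is
    large enough; otherwise runs the full epoch budget. Deterministic
    given the config seed under single-threaded execution.
    """
    cfg = config or model.config
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise SingleClassError("training labels contain a single class")
    n = labels.size
    rng = np.random.default_rng(cfg.seed + 1)
    model.fit_normalization(blocks)

    val_blocks = None
    train_idx = np.arange(n)
    n_val = int(np.floor(cfg.val_fraction * n))
    if cfg.early_stopping_patience > 0 and n_val >= 8:
        # stratified validation split
        val_parts = []
        for cls in np.unique(labels):
            cls_idx = rng.permutation(np.flatnonzero(labels == cls))
            val_parts.append(cls_idx[: max(1, int(cfg.val_fraction * cls_idx.size))])
        val_idx = np.sort(np.concatenate(val_parts))
        train_idx = np.setdiff1d(train_idx, val_idx)
        val_blocks = {k: np.asarray(v)[val_idx] for k, v in blocks.items()}
        val_labels = labels[val_idx]

    X_train = {k: np.asarray(v)[train_idx] for k, v in blocks.items()}
    y_train = labels[train_idx]
    opt_cls = nn.Adam if cfg.optimizer == "adam" else nn.SGD
    optimizer = opt_cls(model.params, lr=cfg.learning_rate)

    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    patience_left = cfg.early_stopping_patience
    history: list[float] = []
    m = y_train.size
    for epoch in range(cfg.epochs):
        order = rng.permutation(m)
        epoch_losses = []
        for start in range(0, m, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if batch.size < 2:
                continue  # batchnorm needs >= 2 samples
            logits = model._forward(
                {k: v[batch] for k, v in X_train.items()}, training=True
            )
            loss, grad = nn.softmax_cross_entropy(logits, y_train[batch])
            model._backward(grad)
            optimizer.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
        if val_blocks is not None:
            val_logits = model._forward(val_blocks, training=False)
            val_loss, _ = nn.softmax_cross_entropy(val_logits, val_labels)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [a.copy() for a in model.state_params()]
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stop at epoch %d", epoch + 1)
                    break
    if best_state is not None:
        model.load_state_params(best_state)
    model.loss_history = history
    return history


def predict(
    model: "RpiConvNet | StackingClassifier",
    blocks: dict[str, np.ndarray],
    pairs: list[InteractionPair] | None = None,
) -> list[ScoredPrediction]:
    """Positive-class scores and 0.5-thresholded classes for each pair."""
    probs = model.predict_proba(blocks)
    n = probs.shape[0]
    if pairs is None:
        pairs = [InteractionPair(f"r{i}", f"p{i}", 0) for i in range(n)]
    return [
        ScoredPrediction(pair=pairs[i], score=float(probs[i, 1]))
        for i in range(n)
    ]


class StackingClassifier:
    """Stacking fusion: one conv net per branch + a logistic meta-model.

    Each feature block gets its own single-branch network; their predicted
    probabilities on the training set become the meta-features of a
    second-stage logistic regression.
    """

    def __init__(self, block_dims: dict[str, int], config: ModelConfig):
        self.config = config
        self.block_names = list(block_dims)
        self.branch_models = {
            name: RpiConvNet(
                {name: dim},
                ModelConfig(**{**asdict(config), "seed": config.seed + i}),
            )
            for i, (name, dim) in enumerate(block_dims.items())
        }
        self.meta: LogisticRegression | None = None
        self.loss_history: list[float] = []

    def fit(self, blocks: dict[str, np.ndarray], labels: np.ndarray) -> None:
        metas = []
        for name, model in self.branch_models.items():
            history = train(model, {name: blocks[name]}, labels)
            self.loss_history.append(history[-1])
            metas.append(model.predict_proba({name: blocks[name]}))
        meta_X = fuse(metas, "stacking")
        self.meta = LogisticRegression(max_iter=1000, random_state=self.config.seed)
        self.meta.fit(meta_X, labels)

    def predict_proba(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        if self.meta is None:
            raise ConfigError("stacking classifier is not fitted")
        metas = [
            model.predict_proba({name: blocks[name]})
            for name, model in self.branch_models.items()
        ]
        return self.meta.predict_proba(fuse(metas, "stacking"))


def build_model(
    config: ModelConfig, mask_dims: dict[str, int]
) -> "RpiConvNet | StackingClassifier":
    """Construct the classifier for the given per-block (kept) dims."""
    if config.fusion == "concatenate":
        return RpiConvNet(mask_dims, config)
    return StackingClassifier(mask_dims, config)


def save_model(model: RpiConvNet, path: str | Path, extra: dict | None = None) -> None:
    """Serialize weights + config (+ caller metadata) to an .npz next to a JSON."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_params())}
    np.savez(path, **arrays)
    meta = {
        "config": asdict(model.config),
        "block_dims": model.block_dims,
        "format_version": 1,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> RpiConvNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = RpiConvNet(
        {k: int(v) for k, v in meta["block_dims"].items()},
        ModelConfig(**meta["config"]),
    )
    with np.load(path) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.load_state_params(arrays)
    return model
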