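"""Binary diagnosis model: a three-branch multi-scale 1-D CNN.

One branch per kernel size (3, 5, 7 by default).  Each branch repeats
[conv(k) -> ReLU -> conv(k) -> ReLU -> pool] ``blocks_per_branch`` times,
is flattened, and the branch vectors are concatenated before a dense
hidden layer and a single sigmoid output unit.  Training minimizes binary
cross-entropy with Adam; the decision threshold is chosen on a held-out
validation slice by maximizing TPR - FPR (never on the test split).

Each sample enters as a length-n single-channel sequence whose CpG order
is the importance ranking, so "top-n" feature prefixes stay contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn
from .evaluation import ThresholdResult, roc_and_threshold

SCORE_EPS = 1e-9


@dataclass
class MsdcnnConfig:
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    blocks_per_branch: int = 2
    filters_per_block: tuple[int, ...] = (32, 64)
    pool_kind: str = "max"
    pool_size: int = 2
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd and positive")
        if len(self.filters_per_block) != self.blocks_per_branch:
            raise ValueError("filters_per_block must list one count per block")
        if any(f <= 0 for f in self.filters_per_block):
            raise ValueError("filter counts must be strictly positive")
        if self.pool_kind not in ("max", "average"):
            raise ValueError("pool_kind must be 'max' or 'average'")


class SizingError(ValueError):
    """Input too short for the configured pooling depth."""


@dataclass
class TrainedBinaryModel:
    net: _nn.Layer
    n_features: int
    config: MsdcnnConfig
    history: dict = field(default_factory=dict)
    threshold: ThresholdResult | None = None


def _min_length(cfg: MsdcnnConfig) -> int:
    return (cfg.pool_size ** cfg.blocks_per_branch) * min(cfg.kernel_sizes)


def build_msdcnn(n_features: int, cfg: MsdcnnConfig | None = None) -> TrainedBinaryModel:
    cfg = cfg or MsdcnnConfig()
    if n_features < _min_length(cfg):
        raise SizingError(
            f"n_features={n_features} is below the minimum input width "
            f"{_min_length(cfg)} for pool size {cfg.pool_size} over "
            f"{cfg.blocks_per_branch} block(s)"
        )
    rng = np.random.default_rng(cfg.seed)
    pool_cls = _nn.MaxPool1D if cfg.pool_kind == "max" else _nn.AvgPool1D
    branches = []
    concat_width = 0
    for k in cfg.kernel_sizes:
        layers: list[_nn.Layer] = []
        in_ch, length = 1, n_features
        for f in cfg.filters_per_block:
            layers += [
                _nn.Conv1D(in_ch, f, k, rng=rng),
                _nn.ReLU(),
                _nn.Conv1D(f, f, k, rng=rng),
                _nn.ReLU(),
                pool_cls(cfg.pool_size),
            ]
            in_ch = f
            length //= cfg.pool_size
        layers.append(_nn.Flatten())
        branches.append(_nn.Sequential(layers))
        concat_width += in_ch * length
    net = _nn.Sequential([
        _nn.BranchConcat(branches),
        _nn.Dense(concat_width, cfg.dense_units, rng=rng),
        _nn.ReLU(),
        _nn.Dense(cfg.dense_units, 1, rng=rng),
    ])
    return TrainedBinaryModel(net=net, n_features=n_features, config=cfg)


def _check_width(model: TrainedBinaryModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"input width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"model width {model.n_features}"
        )
    return X[:, None, :]


def train_binary(
    model: TrainedBinaryModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: MsdcnnConfig | None = None,
) -> TrainedBinaryModel:
    """Train in place; records the loss history and a validation-selected
    threshold on the model."""
    cfg = cfg or model.config
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("both classes must be present in the training labels")
    Xs = _check_width(model, X)
    if cfg.val_fraction > 0:
        idx_tr, idx_val = train_test_split(
            np.arange(len(y)),
            test_size=cfg.val_fraction,
            stratify=y,
            random_state=cfg.seed,
        )
    else:
        idx_tr = np.arange(len(y))
        idx_val = np.array([], dtype=int)
    history = _nn.train_network(
        model.net,
        Xs[idx_tr],
        y[idx_tr],
        loss="bce",
        lr=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
        X_val=Xs[idx_val] if len(idx_val) else None,
        Y_val=y[idx_val] if len(idx_val) else None,
        patience=cfg.patience if len(idx_val) else None,
    )
    model.history = history
    thr_idx = idx_val if len(idx_val) else idx_tr
    scores = predict_scores(model, X[thr_idx])
    model.threshold = roc_and_threshold(scores, y[thr_idx].astype(int))
    return model


def predict_scores(model: TrainedBinaryModel, X: np.ndarray) -> np.ndarray:
    """Per-sample sigmoid scores in the open interval (0, 1)."""
    Xs = _check_width(model, X)
    logits = model.net.forward(Xs, train=False)
    return np.clip(_nn.sigmoid(logits[:, 0]), SCORE_EPS, 1.0 - SCORE_EPS)


def diagnose(
    model: TrainedBinaryModel,
    X: np.ndarray,
    threshold: ThresholdResult | None = None,
) -> np.ndarray:
    """Binary call: 1 iff score strictly exceeds the threshold."""
    thr = threshold or model.threshold
    if thr is None:
        raise ValueError("no threshold available; train the model or pass one")
    return (predict_scores(model, X) > thr.threshold).astype(int)
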