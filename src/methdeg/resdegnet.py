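"""Four-class residual 1-D CNN with GAP embeddings.

Architecture: stem conv -> ReLU -> max pool, then three residual blocks
(block 1 has two conv layers, blocks 2 and 3 have three; stride-2 leading
convs shrink the sequence while channel counts grow), global average
pooling, and a 4-unit softmax head.  Skip paths get a 1x1 strided
projection whenever channels or stride change shape.  The GAP activations
double as per-sample embeddings for downstream community detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _nn
from .evaluation import MetricReport, multiclass_metrics
from .io import CLASS_ORDER


@dataclass
class ResdegnetConfig:
    stem_filters: int = 32
    stem_kernel: int = 7
    pool_size: int = 2
    block_channels: tuple[int, int, int] = (32, 64, 128)
    block_strides: tuple[tuple[int, ...], ...] = ((1, 1), (2, 1, 1), (2, 1, 1))
    block_kernel: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 60
    patience: int = 6
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_channels) != 3 or len(self.block_strides) != 3:
            raise ValueError("exactly three residual blocks are configured")
        if len(self.block_strides[0]) != 2:
            raise ValueError("block 1 must have 2 conv layers")
        if any(len(s) != 3 for s in self.block_strides[1:]):
            raise ValueError("blocks 2 and 3 must have 3 conv layers each")
        if list(self.block_channels) != sorted(self.block_channels):
            raise ValueError("block channels must be non-decreasing")


class SizingError(ValueError):
    pass


@dataclass
class TrainedMulticlassModel:
    body: _nn.Sequential          # everything up to and including GAP
    head: _nn.Dense               # GAP vector -> 4 logits
    n_features: int
    classes: tuple = CLASS_ORDER
    config: ResdegnetConfig = field(default_factory=ResdegnetConfig)
    history: dict = field(default_factory=dict)
    cv_report: dict = field(default_factory=dict)

    @property
    def net(self) -> _nn.Sequential:
        return _nn.Sequential([self.body, self.head])

    @property
    def embedding_dim(self) -> int:
        return self.config.block_channels[-1]


def build_resdegnet(
    n_features: int, cfg: ResdegnetConfig | None = None
) -> TrainedMulticlassModel:
    cfg = cfg or ResdegnetConfig()
    rng = np.random.default_rng(cfg.seed)
    layers: list[_nn.Layer] = [
        _nn.Conv1D(1, cfg.stem_filters, cfg.stem_kernel, rng=rng),
        _nn.ReLU(),
        _nn.MaxPool1D(cfg.pool_size),
    ]
    length = n_features // cfg.pool_size
    if length < 1:
        raise SizingError(f"n_features={n_features} too short for stem pooling")
    in_ch = cfg.stem_filters
    for ch, strides in zip(cfg.block_channels, cfg.block_strides):
        convs = []
        c = in_ch
        blk_len = length
        for s in strides:
            if s > 1 and blk_len < s:
                raise SizingError(
                    f"stride {s} cannot be applied to sequence length {blk_len} "
                    f"(block strides {strides})"
                )
            convs.append(_nn.Conv1D(c, ch, cfg.block_kernel, stride=s, rng=rng))
            blk_len = _nn.out_length(blk_len, s)
            c = ch
        total_stride = int(np.prod(strides))
        projection = None
        if in_ch != ch or total_stride != 1:
            projection = _nn.Conv1D(in_ch, ch, 1, stride=total_stride, rng=rng)
        layers.append(_nn.ResidualBlock(convs, projection))
        in_ch, length = ch, blk_len
    layers.append(_nn.GlobalAvgPool())
    body = _nn.Sequential(layers)
    head = _nn.Dense(in_ch, len(CLASS_ORDER), rng=rng)
    return TrainedMulticlassModel(body=body, head=head, n_features=n_features, config=cfg)


def _check_width(model: TrainedMulticlassModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"input width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"model width {model.n_features}"
        )
    return X[:, None, :]


def onehot(labels: np.ndarray, classes: tuple = CLASS_ORDER) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """8:2-style stratified train/test index split."""
    idx_tr, idx_te = train_test_split(
        np.arange(len(labels)),
        test_size=test_fraction,
        stratify=np.asarray(labels),
        random_state=seed,
    )
    return idx_tr, idx_te


def _fit_one(model: TrainedMulticlassModel, X, Y, cfg: ResdegnetConfig) -> dict:
    y_arg = Y.argmax(axis=1)
    if cfg.val_fraction > 0 and min(np.bincount(y_arg)) >= 2:
        idx_tr, idx_val = train_test_split(
            np.arange(len(Y)),
            test_size=cfg.val_fraction,
            stratify=y_arg,
            random_state=cfg.seed,
        )
    else:
        idx_tr, idx_val = np.arange(len(Y)), np.array([], dtype=int)
    return _nn.train_network(
        model.net,
        X[idx_tr],
        Y[idx_tr],
        loss="cce",
        lr=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
        X_val=X[idx_val] if len(idx_val) else None,
        Y_val=Y[idx_val] if len(idx_val) else None,
        patience=cfg.patience if len(idx_val) else None,
    )


def train_multiclass(
    model: TrainedMulticlassModel,
    X: np.ndarray,
    labels,
    cfg: ResdegnetConfig | None = None,
    k_folds: int = 5,
) -> TrainedMulticlassModel:
    """Stratified k-fold CV on the training split, then a final full fit.

    The CV report carries one MetricReport per fold plus their arithmetic
    mean; each fold trains a fresh, fold-seeded model.
    """
    cfg = cfg or model.config
    labels = np.asarray(labels)
    present = set(labels.tolist())
    if present != set(model.classes):
        raise ValueError(f"all classes must be present; missing {set(model.classes) - present}")
    Xs = _check_width(model, X)
    Y = onehot(labels, model.classes)

    fold_reports: list[MetricReport] = []
    if k_folds and k_folds >= 2:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=cfg.seed)
        for fold, (tr, te) in enumerate(skf.split(Xs, labels)):
            fold_cfg = replace(cfg, seed=cfg.seed + 1000 * (fold + 1))
            fm = build_resdegnet(model.n_features, fold_cfg)
            _fit_one(fm, Xs[tr], Y[tr], fold_cfg)
            pred = predict(fm, X[te])
            fold_reports.append(multiclass_metrics(labels[te], pred, model.classes))
        avg = MetricReport(
            accuracy=float(np.mean([r.accuracy for r in fold_reports])),
            precision=float(np.mean([r.precision for r in fold_reports])),
            recall=float(np.mean([r.recall for r in fold_reports])),
            f1=float(np.mean([r.f1 for r in fold_reports])),
        )
        model.cv_report = {"folds": fold_reports, "avg": avg}

    model.history = _fit_one(model, Xs, Y, cfg)
    return model


def predict_proba(model: TrainedMulticlassModel, X: np.ndarray) -> np.ndarray:
    """samples x 4 class probabilities (rows on the simplex)."""
    Xs = _check_width(model, X)
    return _nn.softmax(model.net.forward(Xs, train=False))


def predict(model: TrainedMulticlassModel, X: np.ndarray) -> np.ndarray:
    probs = predict_proba(model, X)
    return np.asarray([model.classes[i] for i in probs.argmax(axis=1)])


def extract_embeddings(model: TrainedMulticlassModel, X: np.ndarray) -> np.ndarray:
    """GAP-layer activations, one d-vector per sample (d = last block channels)."""
    Xs = _check_width(model, X)
    return model.body.forward(Xs, train=False)
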