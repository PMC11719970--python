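"""Shapley-value attribution of class probabilities to CpG inputs.

Permutation-sampling estimator: for each sampled feature ordering the
input is switched coordinate-by-coordinate from the baseline vector to the
actual sample, and the marginal change in each class probability is
credited to the switched feature.  Averaging over orderings converges to
the Shapley value, so additivity (attributions sum to f(x) - f(baseline))
holds up to Monte-Carlo error.  An exact coalition-enumeration mode exists
for <= ~12 features and serves as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CLASS_ORDER
from .resdegnet import TrainedMulticlassModel, predict_proba


@dataclass
class AttributionMatrix:
    """cpg x class mean Shapley values, rows in model input order."""

    values: np.ndarray           # (n_cpgs, n_classes)
    cpg_ids: list[str]
    classes: tuple
    baseline: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("attribution values must be finite")
        if self.values.shape != (len(self.cpg_ids), len(self.classes)):
            raise ValueError("attribution shape does not match ids/classes")


def _predict_fn(model):
    if isinstance(model, TrainedMulticlassModel):
        return lambda Z: predict_proba(model, Z)
    return model  # any callable mapping (m, d) -> (m, k)


def shapley_attributions(
    model,
    X: np.ndarray,
    baseline: np.ndarray,
    n_permutations: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample attributions, shape (n_samples, n_features, n_classes)."""
    f = _predict_fn(model)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    baseline = np.asarray(baseline, dtype=float).ravel()
    d = X.shape[1]
    if baseline.shape[0] != d:
        raise ValueError(f"baseline width {baseline.shape[0]} != input width {d}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n_classes = np.atleast_2d(f(baseline[None, :])).shape[1]
    out = np.zeros((X.shape[0], d, n_classes))
    for si, x in enumerate(X):
        acc = np.zeros((d, n_classes))
        for _ in range(n_permutations):
            order = rng.permutation(d)
            # walk baseline -> x along the ordering; batch all d+1 states
            Z = np.tile(baseline, (d + 1, 1))
            for t, feat in enumerate(order):
                Z[t + 1 :, feat] = x[feat]
            probs = f(Z)                      # (d+1, n_classes)
            acc[order] += np.diff(probs, axis=0)
        out[si] = acc / n_permutations
    return out


def exact_shapley_attributions(model, X: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Exact Shapley values by coalition enumeration (exponential; d <= ~12)."""
    f = _predict_fn(model)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    baseline = np.asarray(baseline, dtype=float).ravel()
    d = X.shape[1]
    if d > 16:
        raise ValueError("exact enumeration is limited to at most 16 features")
    n_classes = np.atleast_2d(f(baseline[None, :])).shape[1]
    feats = list(range(d))
    out = np.zeros((X.shape[0], d, n_classes))
    for si, x in enumerate(X):
        # evaluate every coalition once
        vals = {}
        for r in range(d + 1):
            for S in combinations(feats, r):
                z = baseline.copy()
                z[list(S)] = x[list(S)]
                vals[S] = f(z[None, :])[0]
        for i in feats:
            rest = [j for j in feats if j != i]
            for r in range(d):
                w = factorial(r) * factorial(d - r - 1) / factorial(d)
                for S in combinations(rest, r):
                    Si = tuple(sorted(S + (i,)))
                    out[si, i] += w * (vals[Si] - vals[S])
    return out


def mean_attribution(
    per_sample: np.ndarray,
    cpg_ids: list[str],
    classes: tuple = CLASS_ORDER,
    baseline: np.ndarray | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> AttributionMatrix:
    """Arithmetic mean over samples, per CpG per class."""
    per_sample = np.asarray(per_sample, dtype=float)
    if per_sample.ndim != 3 or per_sample.shape[0] < 1:
        raise ValueError("need a (n_samples, n_cpgs, n_classes) array with >= 1 sample")
    return AttributionMatrix(
        values=per_sample.mean(axis=0),
        cpg_ids=list(cpg_ids),
        classes=tuple(classes),
        baseline=np.zeros(per_sample.shape[1]) if baseline is None else np.asarray(baseline),
        n_permutations=n_permutations,
        seed=seed,
    )


def export_heatmap_table(m: AttributionMatrix, path: str | Path) -> Path:
    """TSV: one row per CpG, a value and a rank column per class (rank 1 = max)."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.cpg_ids, columns=list(m.classes))
    df.index.name = "cpg_id"
    for cls in m.classes:
        df[f"rank_{cls}"] = df[cls].rank(ascending=False, method="first").astype(int)
    df.to_csv(path, sep="\t", float_format="%.6f")
    return path


def read_heatmap_table(path: str | Path) -> AttributionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    classes = tuple(c for c in df.columns if not c.startswith("rank_"))
    return AttributionMatrix(
        values=df[list(classes)].to_numpy(dtype=float),
        cpg_ids=list(df.index.astype(str)),
        classes=classes,
        baseline=np.zeros(len(df)),
        n_permutations=0,
        seed=0,
    )
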