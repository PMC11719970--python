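"""Stage-1 screen: tree-ensemble importances over the binary task.

Fits a seeded random forest on healthy-vs-disease labels, scores every
probe by normalized total impurity decrease, drops exact-zero importances
(a never-split feature has importance exactly 0.0, so equality — not a
tolerance — is the right test) and ranks the rest in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .evaluation import MetricReport, binary_metrics, confusion
from .io import BetaMatrix


@dataclass
class ImportanceRanking:
    """CpGs ordered by non-increasing importance; ties break on cpg_id."""

    entries: list[tuple[str, float]]
    n_input: int

    def __post_init__(self) -> None:
        imps = [imp for _, imp in self.entries]
        if any(i < 0 for i in imps):
            raise ValueError("importances must be non-negative")

    @property
    def is_sorted(self) -> bool:
        imps = [imp for _, imp in self.entries]
        return all(a >= b for a, b in zip(imps, imps[1:]))

    @property
    def cpg_ids(self) -> list[str]:
        return [c for c, _ in self.entries]

    def top(self, n: int) -> list[str]:
        return self.cpg_ids[:n]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EvalConfig:
    method: str = "holdout"       # "holdout" | "kfold"
    test_fraction: float = 0.2
    k_folds: int = 5
    n_trees: int = 500
    seed: int = 0


def _labels_array(beta: BetaMatrix, y) -> np.ndarray:
    if hasattr(y, "aligned_to"):
        arr = y.aligned_to(beta)
    else:
        arr = np.asarray(y)
    arr = arr.astype(int)
    if set(np.unique(arr)) != {0, 1}:
        raise ValueError("binary labels with both classes present are required")
    return arr


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def fit_importances(
    beta: BetaMatrix, y, n_trees: int = 500, seed: int = 0
) -> ImportanceRanking:
    """Unfiltered descending ranking; importances sum to 1 over all probes."""
    labels = _labels_array(beta, y)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    clf = _forest(n_trees, seed)
    clf.fit(beta.values, labels)
    imps = clf.feature_importances_
    order = sorted(range(len(imps)), key=lambda j: (-imps[j], beta.cpg_ids[j]))
    entries = [(beta.cpg_ids[j], float(imps[j])) for j in order]
    return ImportanceRanking(entries=entries, n_input=beta.n_cpgs)


def filter_nonzero(r: ImportanceRanking) -> ImportanceRanking:
    """Drop exact-zero importances, preserving order; idempotent."""
    kept = [(c, imp) for c, imp in r.entries if imp != 0.0]
    if not kept:
        raise ValueError("all importances are zero; nothing survives the filter")
    return ImportanceRanking(entries=kept, n_input=r.n_input)


def evaluate_subset(
    beta: BetaMatrix, y, cpgs: list[str], eval_config: EvalConfig | None = None
) -> MetricReport:
    """Refit the ensemble on a probe subset and report held-out metrics."""
    cfg = eval_config or EvalConfig()
    if not cpgs:
        raise ValueError("empty probe subset")
    labels = _labels_array(beta, y)
    X = beta.subset_probes(cpgs).values
    if cfg.method == "holdout":
        Xtr, Xte, ytr, yte = train_test_split(
            X, labels, test_size=cfg.test_fraction, stratify=labels,
            random_state=cfg.seed,
        )
        clf = _forest(cfg.n_trees, cfg.seed)
        clf.fit(Xtr, ytr)
        return binary_metrics(confusion(yte, clf.predict(Xte)))
    if cfg.method == "kfold":
        skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
        reports = []
        for fold, (tr, te) in enumerate(skf.split(X, labels)):
            clf = _forest(cfg.n_trees, cfg.seed + fold)
            clf.fit(X[tr], labels[tr])
            reports.append(binary_metrics(confusion(labels[te], clf.predict(X[te]))))
        return MetricReport(
            accuracy=float(np.mean([r.accuracy for r in reports])),
            precision=float(np.mean([r.precision for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            mcc=float(np.mean([r.mcc for r in reports])),
        )
    raise ValueError(f"unknown evaluation method {cfg.method!r}")
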