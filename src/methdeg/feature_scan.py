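"""Stage-2 selection: CV scan of the binary CNN over a feature-count grid.

For each count n on the grid the top-n ranked CpGs feed a fresh, seeded
multi-scale CNN under stratified k-fold cross-validation.  Fold assignment
is fixed across all counts so they are compared on identical splits.  The
selected count is the smallest one whose fold-averaged primary metric is
within ``tol`` of the grid-wide maximum ("minimum features for optimal
results").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import msdcnn
from .evaluation import MetricReport, binary_metrics, confusion
from .io import BetaMatrix
from .rf_screen import ImportanceRanking


def make_grid(start: int, step: int, total: int) -> list[int]:
    """Counts start, start+step, ... <= total, with total appended if absent."""
    if start <= 0 or step <= 0:
        raise ValueError("start and step must be positive")
    if start > total:
        raise ValueError(f"start {start} exceeds total {total}")
    grid = list(range(start, total + 1, step))
    if grid[-1] != total:
        grid.append(total)
    return grid


@dataclass
class ScanResult:
    grid: list[int]
    per_count: dict  # count -> {"folds": [MetricReport], "mean": MetricReport}
    k_folds: int
    selected_count: int | None = None
    selection_tolerance: float | None = None

    def mean_metric(self, count: int, metric: str) -> float:
        return getattr(self.per_count[count]["mean"], metric)

    def as_dict(self) -> dict:
        return {
            "grid": self.grid,
            "k_folds": self.k_folds,
            "selected_count": self.selected_count,
            "selection_tolerance": self.selection_tolerance,
            "per_count": {
                str(n): {
                    "folds": [r.as_dict() for r in rec["folds"]],
                    "mean": rec["mean"].as_dict(),
                }
                for n, rec in self.per_count.items()
            },
        }


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
    )


def scan(
    beta: BetaMatrix,
    y,
    ranking: ImportanceRanking,
    grid: list[int],
    k_folds: int = 5,
    cfg: msdcnn.MsdcnnConfig | None = None,
    seed: int = 0,
) -> ScanResult:
    cfg = cfg or msdcnn.MsdcnnConfig()
    if max(grid) > len(ranking):
        raise ValueError("grid maximum exceeds ranking length")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    labels = y.aligned_to(beta).astype(int) if hasattr(y, "aligned_to") else np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(beta.values, labels))
    per_count: dict = {}
    for n in grid:
        cols = ranking.top(n)
        X = beta.subset_probes(cols).values
        fold_reports = []
        for fold, (tr, te) in enumerate(folds):
            fold_cfg = replace(cfg, seed=seed + 7919 * n + fold)
            model = msdcnn.build_msdcnn(n, fold_cfg)
            msdcnn.train_binary(model, X[tr], labels[tr])
            pred = msdcnn.diagnose(model, X[te])
            fold_reports.append(binary_metrics(confusion(labels[te], pred)))
        per_count[n] = {"folds": fold_reports, "mean": _mean_report(fold_reports)}
    return ScanResult(grid=list(grid), per_count=per_count, k_folds=k_folds)


def select_count(
    s: ScanResult, primary_metric: str = "mcc", tol: float = 0.005
) -> int:
    """Smallest count whose averaged primary metric is within tol of the max."""
    best = max(s.mean_metric(n, primary_metric) for n in s.grid)
    for n in s.grid:
        if s.mean_metric(n, primary_metric) >= best - tol:
            s.selected_count = n
            s.selection_tolerance = tol
            return n
    raise AssertionError("unreachable: the argmax count always qualifies")
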