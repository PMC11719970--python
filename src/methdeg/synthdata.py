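"""Synthetic methylation cohorts with planted class-specific markers.

Beta values are drawn from a Beta distribution in mean/precision form,
Beta(m*s, (1-m)*s), the natural noise model for fractions in [0, 1].
Each probe has a class-independent background mean; planted marker probes
shift that mean by +/- ``effect_delta`` in their target class (sign fixed
per probe by the seeded generator, since disease loci can be hyper- or
hypo-methylated).  Multi-class cohorts additionally support within-class
subtypes (secondary shifts of delta/2 at subtype-specific probes), a
bimodal age mixture for healthy samples, and a subset of probes whose mean
drifts linearly with age so the healthy population is age-separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CLASS_ORDER, BetaMatrix, LabelSet, write_ages, write_beta_matrix, write_labels

MEAN_LO, MEAN_HI = 0.01, 0.99


@dataclass
class CohortConfig:
    n_samples_per_class: dict | int = 100
    n_cpgs: int = 500
    n_informative_per_class: int = 20
    effect_delta: float = 0.3
    precision: float = 50.0
    background_mean_range: tuple[float, float] = (0.2, 0.8)
    n_subtypes_per_class: dict = field(default_factory=dict)
    healthy_age_means: tuple[float, float] = (33.74, 62.38)
    healthy_age_sd: float = 6.0
    age_drift_fraction: float = 0.1
    age_drift_scale: float = 0.15
    seed: int = 0

    def counts_for(self, classes: tuple) -> dict:
        if isinstance(self.n_samples_per_class, dict):
            missing = [c for c in classes if c not in self.n_samples_per_class]
            if missing:
                raise ValueError(f"missing sample counts for classes {missing}")
            return {c: int(self.n_samples_per_class[c]) for c in classes}
        return {c: int(self.n_samples_per_class) for c in classes}

    def validate(self, classes: tuple) -> None:
        counts = self.counts_for(classes)
        if any(c <= 0 for c in counts.values()):
            raise ValueError("sample counts must be positive")
        if self.n_cpgs <= 0 or self.n_informative_per_class < 0:
            raise ValueError("probe counts must be positive")
        n_disease_classes = sum(1 for c in classes if c != 0 and c != "healthy")
        if self.n_informative_per_class * n_disease_classes > self.n_cpgs:
            raise ValueError("planted markers exceed total probe count")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ValueError("effect_delta must be in [0, 1]")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        lo, hi = self.background_mean_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("background_mean_range must be an interval inside (0, 1)")
        for cls, k in self.n_subtypes_per_class.items():
            if k < 1:
                raise ValueError(f"subtype count for {cls!r} must be >= 1")


@dataclass
class SyntheticCohort:
    beta: BetaMatrix
    labels: LabelSet
    ages: dict[str, float]
    truth: dict
    subtype_of: dict[str, int]

    def write(self, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        """Write beta/labels/ages/truth as delimited text; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": write_beta_matrix(self.beta, outdir / f"{prefix}_beta.tsv"),
            "labels": write_labels(self.labels, outdir / f"{prefix}_labels.tsv"),
        }
        if self.ages:
            paths["ages"] = write_ages(self.ages, outdir / f"{prefix}_ages.tsv")
        truth_path = outdir / f"{prefix}_truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("cpg_id\tclass\n")
            for cls, cpgs in self.truth.items():
                for c in cpgs:
                    fh.write(f"{c}\t{cls}\n")
        paths["truth"] = truth_path
        return paths


def _clamp(m: np.ndarray) -> np.ndarray:
    return np.clip(m, MEAN_LO, MEAN_HI)


def _sample_beta(rng: np.random.Generator, means: np.ndarray, s: float) -> np.ndarray:
    means = _clamp(means)
    return rng.beta(means * s, (1.0 - means) * s)


def generate_binary_cohort(config: CohortConfig) -> SyntheticCohort:
    """Two classes (0 = healthy, 1 = disease) with markers planted for class 1."""
    classes = (0, 1)
    config.validate(classes)
    counts = config.counts_for(classes)
    rng = np.random.default_rng(config.seed)
    p = config.n_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(p)]

    background = rng.uniform(*config.background_mean_range, size=p)
    planted = rng.choice(p, size=config.n_informative_per_class, replace=False)
    signs = rng.choice((-1.0, 1.0), size=planted.size)

    rows, sample_ids, labels = [], [], []
    i = 0
    for cls in classes:
        means = np.tile(background, (counts[cls], 1))
        if cls == 1:
            means[:, planted] += signs * config.effect_delta
        rows.append(_sample_beta(rng, means, config.precision))
        for _ in range(counts[cls]):
            sample_ids.append(f"S{i:05d}")
            labels.append(cls)
            i += 1
    values = np.vstack(rows)
    beta = BetaMatrix(values, sample_ids, cpg_ids)
    truth = {1: [cpg_ids[j] for j in sorted(planted)]}
    subtype_of = {s: 0 for s in sample_ids}
    return SyntheticCohort(beta, LabelSet(sample_ids, labels), {}, truth, subtype_of)


def generate_multiclass_cohort(config: CohortConfig) -> SyntheticCohort:
    """Four-class cohort with per-class markers, subtypes, and bimodal healthy ages."""
    classes = CLASS_ORDER
    config.validate(classes)
    counts = config.counts_for(classes)
    rng = np.random.default_rng(config.seed)
    p = config.n_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(p)]

    background = rng.uniform(*config.background_mean_range, size=p)
    disease_classes = [c for c in classes if c != "healthy"]
    n_marked = config.n_informative_per_class * len(disease_classes)
    marked = rng.choice(p, size=n_marked, replace=False)
    planted = {
        cls: marked[k * config.n_informative_per_class : (k + 1) * config.n_informative_per_class]
        for k, cls in enumerate(disease_classes)
    }
    signs = {cls: rng.choice((-1.0, 1.0), size=len(planted[cls])) for cls in disease_classes}

    n_drift = int(round(config.age_drift_fraction * p))
    drift_probes = rng.choice(p, size=n_drift, replace=False) if n_drift else np.array([], dtype=int)
    drift_slopes = rng.normal(0.0, 1.0, size=n_drift)

    rows, sample_ids, labels = [], [], []
    ages: dict[str, float] = {}
    subtype_of: dict[str, int] = {}
    i = 0
    for cls in classes:
        n = counts[cls]
        means = np.tile(background, (n, 1))
        if cls in planted:
            means[:, planted[cls]] += signs[cls] * config.effect_delta

        n_sub = int(config.n_subtypes_per_class.get(cls, 1))
        sub_idx = np.arange(n) % n_sub
        if n_sub > 1:
            # each subtype shifts delta/2 at its own background-probe subset
            avail = np.setdiff1d(np.arange(p), marked)
            per = max(1, min(len(avail) // n_sub, config.n_informative_per_class))
            chosen = rng.choice(avail, size=per * n_sub, replace=False)
            for k in range(n_sub):
                sub_probes = chosen[k * per : (k + 1) * per]
                sub_signs = rng.choice((-1.0, 1.0), size=per)
                means[np.ix_(sub_idx == k, sub_probes)] += sub_signs * config.effect_delta / 2.0

        ids = [f"S{j:05d}" for j in range(i, i + n)]
        i += n
        if cls == "healthy":
            comp = rng.integers(0, 2, size=n)
            mu = np.asarray(config.healthy_age_means)[comp]
            cls_ages = rng.normal(mu, config.healthy_age_sd)
            cls_ages = np.clip(cls_ages, 1.0, 110.0)
            for sid, a in zip(ids, cls_ages):
                ages[sid] = float(a)
            if n_drift:
                ref = float(np.mean(config.healthy_age_means))
                span = max(
                    abs(config.healthy_age_means[0] - ref),
                    abs(config.healthy_age_means[1] - ref),
                    1.0,
                )
                z = (cls_ages - ref) / span
                means[:, drift_probes] += np.outer(z, drift_slopes) * config.age_drift_scale

        rows.append(_sample_beta(rng, means, config.precision))
        sample_ids.extend(ids)
        labels.extend([cls] * n)
        subtype_of.update({sid: int(k) for sid, k in zip(ids, sub_idx)})

    beta = BetaMatrix(np.vstack(rows), sample_ids, cpg_ids)
    truth = {cls: [cpg_ids[j] for j in sorted(planted[cls])] for cls in disease_classes}
    return SyntheticCohort(beta, LabelSet(sample_ids, labels), ages, truth, subtype_of)
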