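"""Reading and writing of beta matrices, labels, ages and CpG-gene manifests.

The canonical in-memory orientation is samples x probes.  GEO-style
series-matrix exports are probe-major, so orientation is always an explicit
argument, never guessed.  Delimiters are inferred from the file extension
(".tsv" -> tab, ".csv" -> comma) and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Orientation = Literal["samples_as_rows", "probes_as_rows"]

#: Fixed class order for the four-way task; index i corresponds to the
#: one-hot code with a "1" in position i ("1000" = first class, etc.).
CLASS_ORDER = ("neurodegenerative", "bone_degenerative", "breast_cancer", "healthy")

ONEHOT_TO_CLASS = {
    "1000": "neurodegenerative",
    "0100": "bone_degenerative",
    "0010": "breast_cancer",
    "0001": "healthy",
}
CLASS_TO_ONEHOT = {v: k for k, v in ONEHOT_TO_CLASS.items()}


class BetaMatrixError(ValueError):
    """Raised on malformed or out-of-range beta-matrix input."""


@dataclass
class BetaMatrix:
    """samples x probes matrix of methylation fractions in [0, 1]."""

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        if self.values.ndim != 2:
            raise BetaMatrixError("beta values must be a 2-D array")
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise BetaMatrixError("beta matrix must have at least one sample and one probe")
        if len(self.sample_ids) != n or len(self.cpg_ids) != p:
            raise BetaMatrixError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise BetaMatrixError("duplicate sample identifiers")
        if len(set(self.cpg_ids)) != p:
            raise BetaMatrixError("duplicate probe identifiers")
        if np.isnan(self.values).any():
            raise BetaMatrixError("beta matrix contains missing values")
        if (self.values < 0).any() or (self.values > 1).any():
            bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
            raise BetaMatrixError(
                f"beta value out of [0,1] at sample {self.sample_ids[bad[0]]!r}, "
                f"probe {self.cpg_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, cpgs: Sequence[str]) -> "BetaMatrix":
        """Return a copy restricted to ``cpgs`` in the given order."""
        index = {c: j for j, c in enumerate(self.cpg_ids)}
        try:
            cols = [index[c] for c in cpgs]
        except KeyError as exc:
            raise BetaMatrixError(f"unknown probe {exc.args[0]!r}") from None
        return BetaMatrix(self.values[:, cols].copy(), list(self.sample_ids), list(cpgs))

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return BetaMatrix(self.values[rows].copy(), list(sample_ids), list(self.cpg_ids))


@dataclass
class LabelSet:
    """Per-sample class labels, binary {0,1} or one of the four class strings."""

    sample_ids: list[str]
    labels: list

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in label set")
        decoded = []
        for lab in self.labels:
            decoded.append(_decode_label(lab))
        self.labels = decoded
        kinds = {type(l) for l in self.labels}
        if kinds == {int}:
            bad = set(self.labels) - {0, 1}
            if bad:
                raise ValueError(f"binary labels must be 0/1, got {sorted(bad)}")
        elif kinds == {str}:
            bad = set(self.labels) - set(CLASS_ORDER)
            if bad:
                raise ValueError(f"unknown class labels: {sorted(bad)}")
        else:
            raise ValueError("labels must be all-binary or all-class strings")

    @property
    def is_binary(self) -> bool:
        return all(isinstance(l, int) for l in self.labels)

    def aligned_to(self, beta: BetaMatrix) -> np.ndarray:
        """Labels reordered to ``beta.sample_ids``; errors on mismatch."""
        lookup = dict(zip(self.sample_ids, self.labels))
        if set(lookup) != set(beta.sample_ids):
            raise ValueError("label sample ids do not match beta matrix sample ids")
        return np.asarray([lookup[s] for s in beta.sample_ids])


def _decode_label(lab):
    s = str(lab).strip()
    if s in {"0", "1"}:
        return int(s)
    if s in ONEHOT_TO_CLASS:
        return ONEHOT_TO_CLASS[s]
    if s in CLASS_ORDER:
        return s
    raise ValueError(f"cannot decode label {lab!r}")


@dataclass
class CpgGeneManifest:
    """Many-to-many (cpg_id, gene_symbol) association table."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("manifest is empty")
        for cpg, gene in self.rows:
            if not str(cpg) or not str(gene):
                raise ValueError("manifest contains an empty identifier")
        self.rows = [(str(c), str(g)) for c, g in self.rows]

    def genes_of(self, cpg: str) -> set[str]:
        return {g for c, g in self.rows if c == cpg}


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(
    path: str | Path,
    orientation: Orientation = "samples_as_rows",
    *,
    delimiter: str | None = None,
    missing: Literal["strict", "impute"] = "strict",
) -> BetaMatrix:
    """Read a delimited beta-value table with one header row and one id column.

    ``probes_as_rows`` input (GEO series-matrix style) is transposed to the
    canonical samples x probes form.  In strict mode missing cells are an
    error; in ``impute`` mode they are replaced by the per-probe mean
    (logged).
    """
    path = Path(path)
    sep = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise BetaMatrixError(f"{path}: empty table")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad_rows[0] if len(bad_rows) else df.index[0]
            raise BetaMatrixError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if orientation == "probes_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if missing == "strict":
            i, j = np.argwhere(np.isnan(values))[0]
            raise BetaMatrixError(
                f"{path}: missing value at sample {df.index[i]!r}, probe {df.columns[j]!r}"
            )
        col_means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = np.take(col_means, idx[1])
        log.warning("%s: imputed %d missing values with per-probe means", path, len(idx[0]))
    return BetaMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_beta_matrix(
    matrix: BetaMatrix,
    path: str | Path,
    orientation: Orientation = "samples_as_rows",
    *,
    delimiter: str | None = None,
    decimals: int = 6,
) -> Path:
    """Write a beta matrix; round-trips through :func:`read_beta_matrix`."""
    path = Path(path)
    sep = _delimiter(path, delimiter)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.cpg_ids)
    if orientation == "probes_as_rows":
        df = df.T
        df.index.name = "cpg_id"
    elif orientation == "samples_as_rows":
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep, float_format=f"%.{decimals}f")
    return path


def read_labels(path: str | Path, *, delimiter: str | None = None) -> LabelSet:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, delimiter), dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: label file must have exactly two columns")
    return LabelSet(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: LabelSet, path: str | Path, *, delimiter: str | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels})
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False)
    return path


def read_ages(path: str | Path, *, delimiter: str | None = None) -> dict[str, float]:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, delimiter))
    if df.shape[1] != 2:
        raise ValueError(f"{path}: age file must have exactly two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_ages(ages: dict[str, float], path: str | Path, *, delimiter: str | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({"sample_id": list(ages), "age_years": [ages[s] for s in ages]})
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False, float_format="%.4f")
    return path


def read_manifest(path: str | Path, *, delimiter: str | None = None) -> CpgGeneManifest:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, delimiter), dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: manifest must have exactly two columns")
    return CpgGeneManifest([tuple(r) for r in df.itertuples(index=False)])


def intersect_probes(matrices: Sequence[BetaMatrix]) -> list[str]:
    """Sorted intersection of probe id sets across >= 2 matrices.

    Emulates restricting multi-platform cohorts to probes shared by all
    array designs.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].cpg_ids)
    for m in matrices[1:]:
        common &= set(m.cpg_ids)
    if not common:
        raise ValueError("probe intersection is empty; nothing to analyze")
    return sorted(common)


def align_to_common_probes(matrices: Sequence[BetaMatrix]) -> list[BetaMatrix]:
    """Subset and column-align every matrix to the shared sorted probe set."""
    common = intersect_probes(matrices)
    return [m.subset_probes(common) for m in matrices]


def filter_cpgs_by_genes(
    cpgs: Sequence[str],
    genes: Iterable[str],
    manifest: CpgGeneManifest,
) -> list[str]:
    """Keep, in input order, the CpGs whose mapped gene set meets ``genes``.

    Many-to-many semantics: a probe mapped to several genes is retained if
    any of them is listed.
    """
    wanted = set(genes)
    gene_map: dict[str, set[str]] = {}
    for cpg, gene in manifest.rows:
        gene_map.setdefault(cpg, set()).add(gene)
    return [c for c in cpgs if gene_map.get(c, set()) & wanted]
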