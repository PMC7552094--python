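"""Reading, validation and writing of subject connectomes and cohort tables.

A connectome is a symmetric, non-negative, zero-diagonal weighted adjacency
matrix over a fixed parcellation (by default the 84-region Desikan cortical +
subcortical scheme), with one row/column per region in label-file order.
Region order is never changed silently: a label mismatch is an error, because
silent reindexing is the classic connectome bug.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: maximum relative asymmetry tolerated in an input matrix; below this the
#: matrix is symmetrized as (W + W.T) / 2, above it the file is rejected as
#: corrupted (tractography-derived matrices are symmetric by construction).
ASYMMETRY_TOLERANCE = 1e-6

#: tolerance within which a validated connectome must be symmetric.
SYMMETRY_RTOL = 1e-9

GROUP_SYNONYMS = {
    "control": "control", "controls": "control", "ctrl": "control",
    "hc": "control", "healthy": "control",
    "patient": "patient", "patients": "patient", "poag": "patient",
    "glaucoma": "patient", "case": "patient",
}


class ConnectomeError(ValueError):
    """Base class for connectome / cohort validation failures."""


class NonSquareMatrixError(ConnectomeError):
    pass


class NegativeWeightError(ConnectomeError):
    pass


class AsymmetryError(ConnectomeError):
    pass


class LabelError(ConnectomeError):
    pass


class MatrixParseError(ConnectomeError):
    pass


class CohortError(ConnectomeError):
    pass


def _hemisphere_of(label: str) -> str:
    """Infer the hemisphere tag (L/R/midline) from a region label prefix."""
    low = label.lower()
    if re.match(r"^(l[-_. ]|lh[-_.]|left[-_ ])", low):
        return "L"
    if re.match(r"^(r[-_. ]|rh[-_.]|right[-_ ])", low):
        return "R"
    return "midline"


@dataclass
class Connectome:
    """One subject's weighted undirected brain network.

    Attributes
    ----------
    subject_id : str
        Subject identifier.
    weights : (N, N) ndarray
        Symmetric non-negative edge weights (streamline counts or arbitrary
        connectivity units); zero diagonal.
    region_labels : list of str
        Ordered region names; row i of ``weights`` is region ``labels[i]``.
    hemisphere : list of str
        Per-region tag in {"L", "R", "midline"}, inferred from the label
        unless given explicitly.
    """

    subject_id: str
    weights: np.ndarray
    region_labels: list[str]
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.region_labels = [str(x) for x in self.region_labels]
        if not self.hemisphere:
            self.hemisphere = [_hemisphere_of(x) for x in self.region_labels]
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareMatrixError(
                f"subject {self.subject_id!r}: weight matrix has shape {w.shape}, "
                "expected square")
        n = w.shape[0]
        if n < 3:
            raise ConnectomeError(
                f"subject {self.subject_id!r}: need at least 3 regions, got {n}")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise MatrixParseError(
                f"subject {self.subject_id!r}: non-finite weight at cell "
                f"({i}, {j})")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise NegativeWeightError(
                f"subject {self.subject_id!r}: negative weight {w[i, j]} at "
                f"cell ({i}, {j})")
        scale = np.abs(w).max() or 1.0
        asym = np.abs(w - w.T).max() / scale
        if asym > SYMMETRY_RTOL:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise AsymmetryError(
                f"subject {self.subject_id!r}: asymmetry {asym:.3g} at cell "
                f"({i}, {j}) exceeds tolerance {SYMMETRY_RTOL:g}")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError(
                f"subject {self.subject_id!r}: nonzero diagonal at region "
                f"{int(np.flatnonzero(np.diag(w))[0])}")
        if len(self.region_labels) != n:
            raise LabelError(
                f"subject {self.subject_id!r}: {len(self.region_labels)} labels "
                f"for {n} regions")
        if len(set(self.region_labels)) != n:
            dupes = {x for x in self.region_labels
                     if self.region_labels.count(x) > 1}
            raise LabelError(
                f"subject {self.subject_id!r}: duplicate region labels "
                f"{sorted(dupes)}")

    def copy_with(self, weights: np.ndarray) -> "Connectome":
        return Connectome(self.subject_id, np.array(weights, dtype=float),
                          list(self.region_labels), list(self.hemisphere))


@dataclass
class CohortTable:
    """Cohort metadata: one row per subject.

    ``table`` has columns ``subject_id``, ``group`` ("control"/"patient"),
    ``age``, ``sex`` ("M"/"F") plus any numeric clinical columns (VFI, RNFL,
    GCL, IOP, ...).  Missing clinical values are NaN, never zero.
    """

    table: pd.DataFrame
    clinical_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        required = ["subject_id", "group", "age", "sex"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise CohortError(f"cohort table missing required columns {missing}")
        if t["subject_id"].duplicated().any():
            dupes = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise CohortError(f"duplicate subject_id values {dupes}")
        bad = set(t["group"]) - {"control", "patient"}
        if bad:
            raise CohortError(f"unknown group labels {sorted(bad)}")

    @property
    def controls(self) -> list[str]:
        t = self.table
        return t.loc[t["group"] == "control", "subject_id"].tolist()

    @property
    def patients(self) -> list[str]:
        t = self.table
        return t.loc[t["group"] == "patient", "subject_id"].tolist()

    def group_counts(self) -> tuple[int, int]:
        """(n_patients, n_controls)."""
        return len(self.patients), len(self.controls)


# ---------------------------------------------------------------------------
# readers


def _read_dense_matrix(path: Path) -> np.ndarray:
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="%",
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise MatrixParseError(f"{path}: cannot parse matrix: {exc}") from exc
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                try:
                    float(arr[i, j])
                except (TypeError, ValueError):
                    raise MatrixParseError(
                        f"{path}: unparseable numeric value {arr[i, j]!r} at "
                        f"cell ({i}, {j})") from None
        arr = arr.astype(float)
    return arr.astype(float)


def read_labels(path: str | Path) -> list[str]:
    """Read region labels: one name per line, or two-column (index, name) TSV."""
    path = Path(path)
    labels = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        labels.append(parts[1] if len(parts) == 2 else parts[0])
    if not labels:
        raise LabelError(f"{path}: no region labels found")
    return labels


def read_connectome(path: str | Path, labels_path: str | Path,
                    subject_id: str | None = None) -> Connectome:
    """Read one subject's adjacency matrix (dense TSV/CSV or coordinate MTX).

    Mild asymmetry (relative magnitude <= ``ASYMMETRY_TOLERANCE``) is repaired
    as (W + W.T)/2; a nonzero diagonal is zeroed with a logged warning; larger
    defects raise a validation error naming the file and offending cell.
    """
    path = Path(path)
    labels = read_labels(labels_path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread
        try:
            m = mmread(path)
            w = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
        except Exception as exc:  # noqa: BLE001
            raise MatrixParseError(f"{path}: cannot parse MatrixMarket: {exc}") from exc
    else:
        w = _read_dense_matrix(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise NonSquareMatrixError(f"{path}: matrix has shape {w.shape}, expected square")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise NegativeWeightError(f"{path}: negative weight {w[i, j]} at cell ({i}, {j})")
    if len(labels) != w.shape[0]:
        raise LabelError(
            f"{path}: matrix size {w.shape[0]} does not match "
            f"{len(labels)} labels in {labels_path}")
    scale = np.abs(w).max() or 1.0
    asym = np.abs(w - w.T).max() / scale
    if asym > ASYMMETRY_TOLERANCE:
        i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
        raise AsymmetryError(
            f"{path}: relative asymmetry {asym:.3g} at cell ({i}, {j}) exceeds "
            f"{ASYMMETRY_TOLERANCE:g}")
    if asym > 0:
        w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        logger.warning("%s: nonzero diagonal forced to zero", path)
        np.fill_diagonal(w, 0.0)
    sid = subject_id if subject_id is not None else path.stem
    return Connectome(sid, w, labels)


def read_cohort(path: str | Path) -> CohortTable:
    """Read the cohort CSV (subject_id, group, age, sex, clinical columns...).

    Group strings are mapped case-insensitively through common synonyms
    (POAG/glaucoma/case -> patient; HC/healthy/ctrl -> control).  Any extra
    numeric column is treated as a clinical score; blanks stay missing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["subject_id", "group", "age", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")
    groups = df["group"].astype(str).str.strip().str.lower()
    unknown = sorted(set(groups) - set(GROUP_SYNONYMS))
    if unknown:
        raise CohortError(f"{path}: unknown group values {unknown}")
    df = df.copy()
    df["group"] = groups.map(GROUP_SYNONYMS)
    df["subject_id"] = df["subject_id"].astype(str)
    df["sex"] = df["sex"].astype(str).str.strip().str.upper().str[0]
    clinical = []
    for col in df.columns:
        if col in required:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.notna().any():
            df[col] = numeric
            clinical.append(col)
    return CohortTable(df, clinical_columns=clinical)


# ---------------------------------------------------------------------------
# writers


def write_connectome(c: Connectome, path: str | Path, format: str = "tsv") -> None:
    """Write a connectome as a dense TSV (full precision) or coordinate MTX.

    MTX output stores the strict upper triangle with 1-based indices under a
    ``symmetric`` header, so each undirected edge appears exactly once.
    """
    path = Path(path)
    if format == "tsv":
        np.savetxt(path, c.weights, delimiter="\t", fmt="%.17g")
    elif format == "mtx":
        n = c.n_regions
        rows, cols = np.triu_indices(n, k=1)
        mask = c.weights[rows, cols] != 0
        rows, cols = rows[mask], cols[mask]
        vals = c.weights[rows, cols]
        with open(path, "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate real symmetric\n")
            fh.write(f"{n} {n} {len(vals)}\n")
            for i, j, v in zip(rows, cols, vals):
                fh.write(f"{i + 1} {j + 1} {v:.17g}\n")
    else:
        raise ValueError(f"unknown connectome format {format!r}")


def write_labels(labels: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{lab}\n" for lab in labels))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)
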