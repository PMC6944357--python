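"""Subject and group functional-connectivity matrices.

The pipeline here is: per-subject Pearson full correlation between ROI
time courses (autocorrelations and anti-correlations zeroed), Fisher
r-to-z transform, entrywise group averaging in z-space, back-transform to
r, then absolute thresholding (strictly greater than the cutoff) with
optional binarization.  Thresholds are always stated and applied on the r
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    FormatError,
    ParameterError,
)

# r entries at or above this are clipped before arctanh so the z-transform
# stays finite (perfect correlations occur for duplicated series).
_R_CLIP = 1.0 - 1e-12


def _check_square(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"matrix must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=1e-10):
        raise FormatError("matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise FormatError("matrix diagonal must be zero")


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Per-subject ROI x time matrix, rows in atlas order."""

    subject_id: str
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.ndim != 2:
            raise FormatError("time series must be a 2-D ROI x time matrix")
        if v.shape[0] != len(self.labels):
            raise FormatError(
                f"{v.shape[0]} rows but {len(self.labels)} labels for {self.subject_id!r}"
            )
        if v.shape[1] < 3:
            raise FormatError("need at least 3 timepoints")
        if not np.isfinite(v).all():
            raise FormatError(f"non-finite values in time series of {self.subject_id!r}")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix with zero diagonal.

    ``space`` is ``"r"`` (correlation scale, entries in [0, 1]) or ``"z"``
    (Fisher-transformed scale).
    """

    values: np.ndarray
    labels: tuple[str, ...]
    space: str = "r"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_square(v)
        if v.shape[0] != len(self.labels):
            raise FormatError("label count does not match matrix size")
        if self.space not in ("r", "z"):
            raise ParameterError(f"space must be 'r' or 'z', got {self.space!r}")
        if self.space == "r" and ((v < 0).any() or (v > 1).any()):
            raise FormatError("r-space entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, indices: list[int]) -> "ConnectivityMatrix":
        """Slice to a network scope, preserving label order."""
        idx = np.asarray(indices, dtype=int)
        return ConnectivityMatrix(
            self.values[np.ix_(idx, idx)],
            tuple(self.labels[i] for i in indices),
            self.space,
        )


@dataclass(frozen=True)
class BinaryGraph:
    """Thresholded, binarized undirected adjacency with zero diagonal."""

    adjacency: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise FormatError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_square(a.astype(float))
        if a.shape[0] != len(self.labels):
            raise FormatError("label count does not match adjacency size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def subgraph(self, indices: list[int]) -> "BinaryGraph":
        idx = np.asarray(indices, dtype=int)
        return BinaryGraph(
            self.adjacency[np.ix_(idx, idx)], tuple(self.labels[i] for i in indices)
        )


def pearson_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson full-correlation matrix of a subject's ROI time courses.

    The diagonal (autocorrelations) is set to 0 and negative coefficients
    (anti-correlations) are clipped to 0.  A constant ROI row has no
    defined correlation and raises :class:`DegenerateInputError`.
    """
    v = ts.values
    stds = v.std(axis=1)
    if (stds == 0).any():
        bad = [ts.labels[i] for i in np.flatnonzero(stds == 0)]
        raise DegenerateInputError(
            f"constant time series (zero variance) for ROIs {bad} in {ts.subject_id!r}"
        )
    r = np.corrcoef(v)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, 0.0, 1.0)
    r = (r + r.T) / 2.0  # exact symmetry against floating-point asymmetry
    return ConnectivityMatrix(r, ts.labels, "r")


def fisher_z(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise Fisher r-to-z transform (arctanh).

    Entries at or above 1 - 1e-12 are clipped to that value first, so
    perfect correlations map to a large finite z rather than infinity.
    """
    if C.space != "r":
        raise ParameterError("fisher_z expects an r-space matrix")
    z = np.arctanh(np.minimum(C.values, _R_CLIP))
    return ConnectivityMatrix(z, C.labels, "z")


def inverse_fisher(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise z-to-r back-transform (tanh)."""
    if C.space != "z":
        raise ParameterError("inverse_fisher expects a z-space matrix")
    if not np.isfinite(C.values).all():
        raise ParameterError("z-space entries must be finite")
    return ConnectivityMatrix(np.tanh(C.values), C.labels, "r")


def group_mean(subject_matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group connectivity matrix: entrywise mean in z-space, returned in r.

    Cells that are zero in every subject stay exactly zero.  All inputs
    must share the same label order.
    """
    if not subject_matrices:
        raise ParameterError("need at least one subject matrix")
    labels = subject_matrices[0].labels
    for m in subject_matrices[1:]:
        if m.labels != labels:
            raise AlignmentError("subject matrices have mismatching labels")
    zs = np.stack([fisher_z(m).values for m in subject_matrices])
    mean_r = np.tanh(zs.mean(axis=0))
    np.fill_diagonal(mean_r, 0.0)
    return ConnectivityMatrix(np.clip(mean_r, 0.0, 1.0), labels, "r")


def apply_threshold(
    C: ConnectivityMatrix, thr: float, mode: str = "binary"
) -> ConnectivityMatrix | BinaryGraph:
    """Absolute threshold on the r scale: keep entries strictly above thr.

    ``mode="weighted"`` keeps surviving correlation values (the adjacent
    weighted undirected matrix); ``mode="binary"`` sets them to 1 (the
    adjacent unweighted undirected matrix).
    """
    if C.space != "r":
        raise ParameterError("thresholds are defined on the r scale")
    if not 0.0 <= thr <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {thr}")
    mask = C.values > thr
    if mode == "weighted":
        return ConnectivityMatrix(np.where(mask, C.values, 0.0), C.labels, "r")
    if mode == "binary":
        return BinaryGraph(mask.astype(np.int8), C.labels)
    raise ParameterError(f"mode must be 'weighted' or 'binary', got {mode!r}")


def connection_count(G: BinaryGraph) -> int:
    """Number of nonzero off-diagonal cells (ordered pairs = 2 x edges)."""
    return int(np.count_nonzero(G.adjacency))


def density_sweep(
    C: ConnectivityMatrix,
    thresholds: list[float],
    indices: list[int] | None = None,
) -> pd.DataFrame:
    """Network density across a list of absolute thresholds.

    Density is undirected edge count over n(n-1)/2, computed on the whole
    matrix or on the ``indices`` slice.  Returns a DataFrame with columns
    threshold, n_edges, density.
    """
    sub = C if indices is None else C.submatrix(indices)
    n = sub.n
    pairs = n * (n - 1) / 2
    rows = []
    for thr in thresholds:
        g = apply_threshold(sub, float(thr), "binary")
        edges = connection_count(g) // 2
        rows.append(
            {"threshold": float(thr), "n_edges": edges, "density": edges / pairs if pairs else 0.0}
        )
    return pd.DataFrame(rows)


def read_time_series(
    path: str | Path, labels: tuple[str, ...], subject_id: str | None = None
) -> TimeSeriesMatrix:
    """Read a delimited ROI x time matrix (rows = ROIs in atlas order).

    Accepts comma-, tab- or whitespace-separated numeric text.  The
    subject id defaults to the file stem.
    """
    path = Path(path)
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse time-series file {path}: {exc}") from exc
    sid = subject_id if subject_id is not None else path.stem
    if values.shape[0] != len(labels):
        raise FormatError(
            f"{path} has {values.shape[0]} ROI rows, atlas defines {len(labels)}"
        )
    return TimeSeriesMatrix(sid, values, labels)


def read_matrix(path: str | Path, labels: tuple[str, ...]) -> ConnectivityMatrix:
    """Read a labelled ROI x ROI correlation CSV (label header row/column)."""
    df = pd.read_csv(path, index_col=0, comment="#")
    if list(df.columns) != list(labels) or list(df.index) != list(labels):
        raise AlignmentError(f"matrix labels in {path} do not match the atlas order")
    return ConnectivityMatrix(df.to_numpy(dtype=float), labels, "r")


def write_matrix(C: ConnectivityMatrix, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a connectivity matrix as labelled CSV, optional # comment header."""
    df = pd.DataFrame(C.values, index=list(C.labels), columns=list(C.labels))
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh)
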