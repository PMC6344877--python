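"""Reading, normalizing and spline-smoothing of expression time series.

The expression input is a genes x timepoints table of positive intensities
(optionally stored on a log scale).  Each gene's series can be summarized by
a least-squares piecewise-cubic spline with a small number of interior
anchor points, which is then used as the continuous signal for kinetic
modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, LSQUnivariateSpline

__all__ = [
    "ExpressionMatrix",
    "SmoothedProfile",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize_timepoints",
    "smooth_profile",
]


@dataclass
class ExpressionMatrix:
    """Expression values for a set of genes on a shared time grid.

    ``values`` has one row per gene (linear-scale intensities) and one
    column per timepoint (hours, strictly increasing).
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} timepoints"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.times)


@dataclass
class SmoothedProfile:
    """A continuous, C1 piecewise-cubic representation of one gene's series.

    Evaluable anywhere inside ``[t_min, t_max]``; evaluation outside the
    domain raises (curves are never extrapolated).  When a profile is used
    as a regulator concentration, evaluate with ``clip_negative=True``.
    """

    gene_id: str
    t_min: float
    t_max: float
    knots: np.ndarray
    coefficients: np.ndarray
    _spline: object = field(repr=False, default=None)

    def __call__(self, t, clip_negative: bool = False) -> np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        tol = 1e-9 * max(1.0, abs(self.t_max))
        if np.any(t_arr < self.t_min - tol) or np.any(t_arr > self.t_max + tol):
            raise ValueError(
                f"evaluation outside domain [{self.t_min}, {self.t_max}]"
            )
        out = np.asarray(self._spline(np.clip(t_arr, self.t_min, self.t_max)),
                         dtype=float)
        if clip_negative:
            out = np.maximum(out, 0.0)
        return out if np.ndim(t) else float(out)

    @classmethod
    def from_least_squares(cls, gene_id: str, times, values,
                           n_anchors: int = 4) -> "SmoothedProfile":
        return smooth_profile(times, values, n_anchors=n_anchors, gene_id=gene_id)

    @classmethod
    def from_samples(cls, gene_id: str, times, values) -> "SmoothedProfile":
        """Interpolating cubic spline through dense samples (no smoothing)."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        cs = CubicSpline(times, values)
        return cls(gene_id=gene_id, t_min=float(times[0]), t_max=float(times[-1]),
                   knots=times.copy(), coefficients=cs.c.copy(), _spline=cs)


def read_expression_matrix(path, log_base: float | None = None) -> ExpressionMatrix:
    """Read a TSV with a ``gene_id`` column and numeric hour columns.

    If ``log_base`` is given every stored value v is replaced by
    ``log_base ** v`` (de-logging back to linear intensities).
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric time column header: {exc}") from exc
    if np.any(np.diff(times) <= 0):
        raise ValueError("time columns must be sorted strictly increasing")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids: {dupes}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-numeric or missing cells in expression table")
    if log_base is not None:
        values = np.power(float(log_base), values)
    return ExpressionMatrix(gene_ids=list(df.index.astype(str)), times=times,
                            values=values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.columns = [format(t, "g") for t in matrix.times]
    df.to_csv(path, sep="\t")


def normalize_timepoints(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every timepoint column to share the grand mean.

    Column j is multiplied by grand_mean / column_mean(j), so after the
    transform every column mean equals the original grand mean.  Idempotent.
    """
    if np.any(matrix.values <= 0):
        raise ValueError("normalization requires strictly positive values")
    col_means = matrix.values.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValueError("column mean <= 0")
    grand_mean = matrix.values.mean()
    scaled = matrix.values * (grand_mean / col_means)
    return ExpressionMatrix(gene_ids=list(matrix.gene_ids), times=matrix.times.copy(),
                            values=scaled)


def smooth_profile(times, values, n_anchors: int = 4,
                   gene_id: str = "") -> SmoothedProfile:
    """Least-squares cubic spline with ``n_anchors`` equally spaced interior knots.

    Requires at least ``n_anchors + 2`` observations.  The fit is linear in
    the data, so it commutes with affine scaling of the values, and its
    residual sum of squares never exceeds that of the best constant fit
    (constants lie in the spline space).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be matching 1-d arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times.size < n_anchors + 2:
        raise ValueError(
            f"need at least {n_anchors + 2} observations, got {times.size}"
        )
    interior = np.linspace(times[0], times[-1], n_anchors + 2)[1:-1]
    spline = LSQUnivariateSpline(times, values, t=interior, k=3)
    return SmoothedProfile(
        gene_id=gene_id,
        t_min=float(times[0]),
        t_max=float(times[-1]),
        knots=np.asarray(spline.get_knots(), dtype=float),
        coefficients=np.asarray(spline.get_coeffs(), dtype=float),
        _spline=spline,
    )
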