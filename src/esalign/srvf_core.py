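"""Square-root velocity representation of composite curves.

A curve ``P`` is parameterized by normalized cumulative spatial arc length
``T ∈ [0, 1]`` (computed from the first three rows only) and mapped to its
square-root velocity function (SRVF)

    q(t) = (dP/dT) / sqrt(‖dP/dT‖),

which makes the representation translation-invariant exactly and, after
normalization to unit L² norm, scale-invariant.  Two curves are brought
onto a common parameter grid by merging the unique parameter values and
resampling the SRVFs by piecewise-linear interpolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curve_model import CompositeCurve
from .errors import ContractError, DegenerateCurveError

logger = logging.getLogger(__name__)

#: parameter values closer than this are merged into one grid point
MERGE_TOL = 1e-12


@dataclass
class ParamGrid:
    """Strictly increasing parameter values with endpoints 0 and 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ContractError("a parameter grid needs at least 2 values")
        if abs(v[0]) > MERGE_TOL or abs(v[-1] - 1.0) > MERGE_TOL:
            raise ContractError("grid must start at 0 and end at 1")
        v = v.copy()
        v[0], v[-1] = 0.0, 1.0
        if np.any(np.diff(v) <= 0):
            raise ContractError("grid values must be strictly increasing")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SrvfCurve:
    """A (3 + k) × m SRVF matrix **Q** tied to its parameter grid."""

    values: np.ndarray
    grid: ParamGrid
    k: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.grid):
            raise ContractError("SRVF column count must match grid length")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("SRVF contains non-finite entries")


def arc_length_parameterization(P: CompositeCurve) -> tuple[ParamGrid, CompositeCurve]:
    """Normalized cumulative spatial arc length of a composite curve.

    Only the first three (spatial) rows enter the segment lengths.  Columns
    producing zero-length segments (duplicate atoms) are dropped from the
    curve with a log message, so the possibly reduced curve is returned
    alongside its grid.
    """
    seg = np.linalg.norm(np.diff(P.spatial, axis=1), axis=0)
    if np.any(seg <= MERGE_TOL):
        keep = np.concatenate([[True], seg > MERGE_TOL])
        if int(keep.sum()) < 2:
            raise DegenerateCurveError("curve has zero total spatial length")
        logger.warning("dropping %d duplicate curve column(s)", int((~keep).sum()))
        P = CompositeCurve(
            values=P.values[:, keep], row_labels=P.row_labels,
            criterion=P.criterion, k=P.k,
        )
        seg = np.linalg.norm(np.diff(P.spatial, axis=1), axis=0)
    total = seg.sum()
    if total <= MERGE_TOL:
        raise DegenerateCurveError("curve has zero total spatial length")
    t = np.concatenate([[0.0], np.cumsum(seg)]) / total
    return ParamGrid(t), P


def canonicalize_scale(P: CompositeCurve) -> CompositeCurve:
    """Rescale the spatial rows so the mean inter-point spacing is 1.

    Dividing the coordinates by the curve's own mean segment length removes
    the global scale (the scaled copy of a structure maps to the identical
    curve) while keeping the spatial derivative commensurate with the
    standardized auxiliary rows, whose derivatives grow with the same point
    density.  Auxiliary rows are untouched — they carry no length unit.
    """
    seg = np.linalg.norm(np.diff(P.spatial, axis=1), axis=0)
    total = seg.sum()
    if total <= MERGE_TOL:
        raise DegenerateCurveError("curve has zero total spatial length")
    values = P.values.copy()
    values[:3] *= (P.n - 1) / total
    return CompositeCurve(values=values, row_labels=P.row_labels,
                          criterion=P.criterion, k=P.k)


def srvf_transform(P: CompositeCurve, T: ParamGrid) -> SrvfCurve:
    """SRVF of the piecewise-linear curve ``P`` on grid ``T``.

    The derivative is estimated per column by nonuniform finite differences
    (central in the interior, one-sided at the ends); each column is then
    divided by the square root of its own Euclidean norm.  Zero-derivative
    columns map to zero columns.
    """
    if P.n != len(T):
        raise ContractError(f"curve has {P.n} columns but grid has {len(T)} values")
    deriv = np.gradient(P.values, T.values, axis=1)
    norms = np.linalg.norm(deriv, axis=0)
    zero = norms <= MERGE_TOL
    if np.any(zero):
        logger.warning("%d zero-derivative SRVF column(s)", int(zero.sum()))
    scale = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, norms)))
    q = np.where(zero, 0.0, deriv / scale)
    return SrvfCurve(values=q, grid=T, k=P.k)


def merge_grids(T1: ParamGrid, T2: ParamGrid, tol: float = MERGE_TOL) -> ParamGrid:
    """Sorted union of two grids with near-duplicates (< tol) collapsed.

    The merged length ``n`` satisfies ``max(n₁, n₂) ≤ n ≤ n₁ + n₂ − 2``
    (the two endpoints are always shared).
    """
    merged = np.sort(np.concatenate([T1.values, T2.values]))
    keep = np.concatenate([[True], np.diff(merged) > tol])
    return ParamGrid(merged[keep])


def resample_srvf(Q: SrvfCurve, T_new: ParamGrid) -> SrvfCurve:
    """Carry SRVF values onto a new grid by per-row linear interpolation."""
    if T_new.values[0] < -MERGE_TOL or T_new.values[-1] > 1.0 + MERGE_TOL:
        raise ContractError("target grid must lie within [0, 1]")
    new_values = np.vstack([
        np.interp(T_new.values, Q.grid.values, row) for row in Q.values
    ])
    return SrvfCurve(values=new_values, grid=T_new, k=Q.k)


def grid_weights(T: ParamGrid) -> np.ndarray:
    """Trapezoidal cell width assigned to each grid point."""
    t = T.values
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w


def srvf_inner_product(Q1: SrvfCurve, Q2: SrvfCurve) -> float:
    """Discrete L² inner product  Σᵢ ⟨q₁(tᵢ), q₂(tᵢ)⟩ Δᵢ  on a common grid."""
    if len(Q1.grid) != len(Q2.grid) or not np.allclose(
        Q1.grid.values, Q2.grid.values, atol=MERGE_TOL, rtol=0.0
    ):
        raise ContractError("inner product requires identical grids")
    pointwise = np.einsum("ri,ri->i", Q1.values, Q2.values)
    return float(np.dot(grid_weights(Q1.grid), pointwise))


def normalize_srvf(Q: SrvfCurve) -> SrvfCurve:
    """Scale Q to unit L² norm so that inner products lie in [−1, 1]."""
    norm_sq = srvf_inner_product(Q, Q)
    if norm_sq <= MERGE_TOL:
        raise DegenerateCurveError("cannot normalize a zero-norm SRVF")
    return SrvfCurve(values=Q.values / np.sqrt(norm_sq), grid=Q.grid, k=Q.k)
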