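"""NURBS curve mathematics for contour refinement.

A NURBS curve of degree ``p`` with control points ``P_i``, weights ``w_i``
and knot vector ``U`` evaluates as

    c(t) = sum_i N_{i,p}(t) w_i P_i / sum_j N_{j,p}(t) w_j,   t in [0, 1]

with ``N_{i,p}`` the B-spline basis functions (Cox–de Boor recursion).
With all weights equal the curve reduces to an ordinary B-spline.  Curves
here are clamped (end knots repeated ``p+1`` times) so they interpolate
their first and last control points; closed contours are handled by seam
repetition (first control point equals the last), which is where automated
segmentation boundaries re-enter the pipeline after manual control-point
edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .contour_ops import Contour, resample_contour

__all__ = [
    "NurbsCurve",
    "ControlEdit",
    "clamped_uniform_knots",
    "find_span",
    "basis_function",
    "basis_functions",
    "evaluate_curve",
    "fit_curve_to_contour",
    "apply_edits",
    "curve_to_contour",
    "rational_circle",
    "curve_to_json",
    "curve_from_json",
]


@dataclass
class NurbsCurve:
    """A clamped planar NURBS curve.

    ``n+1`` control points require ``len(knots) == n + degree + 2``;
    weights are strictly positive and pair one-to-one with control points.
    """

    control_points: np.ndarray  # (n+1, 2)
    weights: np.ndarray         # (n+1,)
    degree: int
    knots: np.ndarray
    fit_residual: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        P = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        w = np.asarray(self.weights, dtype=float).ravel()
        U = np.asarray(self.knots, dtype=float).ravel()
        p = int(self.degree)
        if p < 1:
            raise ValueError("degree must be >= 1")
        if len(w) != len(P):
            raise ValueError("one weight per control point required")
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")
        if len(U) != len(P) + p + 1:
            raise ValueError(
                f"knot vector length {len(U)} != n_ctrl + degree + 1 = {len(P) + p + 1}")
        if np.any(np.diff(U) < 0):
            raise ValueError("knot vector must be non-decreasing")
        if not (np.allclose(U[:p + 1], U[0]) and np.allclose(U[-p - 1:], U[-1])):
            raise ValueError("curve must be clamped: end knots repeated degree+1 times")
        self.control_points = P
        self.weights = w
        self.knots = U
        self.degree = p

    @property
    def n_ctrl(self) -> int:
        return len(self.control_points)

    def copy(self) -> "NurbsCurve":
        return NurbsCurve(self.control_points.copy(), self.weights.copy(),
                          self.degree, self.knots.copy())


@dataclass
class ControlEdit:
    """One manual refinement action: move a control point, optionally reweight it."""

    index: int
    delta: tuple[float, float] = (0.0, 0.0)
    new_weight: float | None = None

    def __post_init__(self) -> None:
        if self.new_weight is not None and self.new_weight <= 0:
            raise ValueError("new_weight must be positive")


def clamped_uniform_knots(n_ctrl: int, p: int) -> np.ndarray:
    """Clamped knot vector on [0, 1] with uniformly spaced interior knots."""
    if n_ctrl <= p:
        raise ValueError(f"need n_ctrl > degree; got n_ctrl={n_ctrl}, p={p}")
    n_interior = n_ctrl - p - 1
    interior = np.arange(1, n_interior + 1) / (n_interior + 1)
    return np.concatenate([np.zeros(p + 1), interior, np.ones(p + 1)])


def find_span(t: float, p: int, U: np.ndarray) -> int:
    """Index mu with U[mu] <= t < U[mu+1] (last nontrivial span at t = U[-1])."""
    n = len(U) - p - 2  # highest control-point index
    if t >= U[n + 1]:
        return n
    if t <= U[p]:
        return p
    return int(np.searchsorted(U, t, side="right") - 1)


def basis_functions(span: int, t: float, p: int, U: np.ndarray) -> np.ndarray:
    """The p+1 basis functions N_{span-p..span, p}(t) that are nonzero at t.

    Triangular-scheme evaluation of the Cox–de Boor recursion; the 0/0
    convention never arises because only nonzero-support functions are
    visited.
    """
    N = np.ones(p + 1)
    left = np.empty(p + 1)
    right = np.empty(p + 1)
    for j in range(1, p + 1):
        left[j] = t - U[span + 1 - j]
        right[j] = U[span + j] - t
        saved = 0.0
        for r in range(j):
            temp = N[r] / (right[r + 1] + left[j - r])
            N[r] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        N[j] = saved
    return N


def basis_function(i: int, p: int, t: float, U: np.ndarray) -> float:
    """Single basis function N_{i,p}(t), zero outside its support."""
    span = find_span(t, p, U)
    if i < span - p or i > span:
        return 0.0
    return float(basis_functions(span, t, p, U)[i - (span - p)])


def all_basis_row(t: float, p: int, U: np.ndarray) -> np.ndarray:
    """Dense row of all n+1 basis values at t (collocation-matrix row)."""
    n_ctrl = len(U) - p - 1
    row = np.zeros(n_ctrl)
    span = find_span(t, p, U)
    row[span - p: span + 1] = basis_functions(span, t, p, U)
    return row


def evaluate_curve(curve: NurbsCurve, t) -> np.ndarray:
    """Point(s) on the curve at parameter(s) t in [0, 1].

    Scalar t returns shape (2,); an array of m parameters returns (m, 2).
    """
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    p, U = curve.degree, curve.knots
    Pw = curve.control_points * curve.weights[:, None]
    out = np.empty((len(ts), 2))
    for k, tk in enumerate(ts):
        span = find_span(tk, p, U)
        N = basis_functions(span, tk, p, U)
        idx = slice(span - p, span + 1)
        denom = N @ curve.weights[idx]
        out[k] = (N @ Pw[idx]) / denom
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def fit_curve_to_contour(contour: Contour, n_ctrl: int | None = None,
                         p: int = 3, params: np.ndarray | None = None) -> NurbsCurve:
    """Least-squares NURBS approximation of a closed contour.

    Data points are the contour vertices with the seam (first) point
    repeated at the end; parameters default to chord length on [0, 1].
    The first and last control points are pinned to the seam point so the
    fitted curve closes exactly; all weights are 1.  The maximum pointwise
    fitting residual (mm) is stored on the returned curve.
    """
    pts = contour.points
    if n_ctrl is None:
        n_ctrl = max(8, len(pts) // 10)
    if n_ctrl <= p:
        raise ValueError("n_ctrl must exceed the degree")
    if n_ctrl > len(pts):
        raise ValueError(f"n_ctrl={n_ctrl} exceeds contour point count {len(pts)}")

    Q = np.vstack([pts, pts[:1]])  # seam repetition closes the data
    if params is None:
        chord = np.linalg.norm(np.diff(Q, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(chord)])
        params = s / s[-1]
    else:
        params = np.asarray(params, dtype=float)
        if len(params) != len(Q):
            raise ValueError("params must cover the seam-repeated point list")

    U = clamped_uniform_knots(n_ctrl, p)
    A = np.array([all_basis_row(t, p, U) for t in params])
    seam = Q[0]
    # pin endpoints: move their (known) columns to the right-hand side
    rhs = Q - np.outer(A[:, 0], seam) - np.outer(A[:, -1], seam)
    A_free = A[:, 1:-1]
    if A_free.shape[0] < A_free.shape[1]:
        raise ValueError("underdetermined fit: more free control points than data")
    sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
    P = np.vstack([seam, sol, seam])
    curve = NurbsCurve(P, np.ones(n_ctrl), p, U)
    fitted = np.array([evaluate_curve(curve, t) for t in params])
    curve.fit_residual = float(np.linalg.norm(fitted - Q, axis=1).max())
    return curve


def apply_edits(curve: NurbsCurve, edits: list[ControlEdit]) -> NurbsCurve:
    """Apply control-point edits, returning a new curve (pure).

    By local support of B-splines, editing control point ``i`` changes the
    curve only on knot spans ``[U_i, U_{i+p+1})``; everything else is
    bitwise untouched, which is what lets a reviewer refine a boundary
    locally without disturbing the rest of the slice.
    """
    out = curve.copy()
    for e in edits:
        if not 0 <= e.index < out.n_ctrl:
            raise IndexError(f"control point index {e.index} out of range")
        out.control_points[e.index] += np.asarray(e.delta, dtype=float)
        if e.new_weight is not None:
            out.weights[e.index] = e.new_weight
    return out


def curve_to_contour(curve: NurbsCurve, n_samples: int = 256,
                     slice_index: int = 0, z: float = 0.0) -> Contour:
    """Sample the curve back into a contour (uniform t, then arc-length)."""
    if n_samples < 8:
        raise ValueError("need n_samples >= 8")
    ts = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    pts = evaluate_curve(curve, ts)
    raw = Contour(pts, slice_index=slice_index, z=z)
    return resample_contour(raw, n_samples)


def rational_circle(radius: float = 1.0, center=(0.0, 0.0)) -> NurbsCurve:
    """Exact full circle as a 9-control-point rational quadratic.

    The classic square-based construction: control points at the corners
    and edge midpoints of the bounding square, weights alternating
    1 and sqrt(2)/2, with double interior knots at 1/4, 1/2, 3/4.  Every
    point of the curve lies exactly on the circle.
    """
    cx, cy = center
    r = float(radius)
    P = np.array([
        [cx + r, cy], [cx + r, cy + r], [cx, cy + r], [cx - r, cy + r],
        [cx - r, cy], [cx - r, cy - r], [cx, cy - r], [cx + r, cy - r],
        [cx + r, cy],
    ])
    s = np.sqrt(2.0) / 2.0
    w = np.array([1, s, 1, s, 1, s, 1, s, 1], dtype=float)
    U = np.array([0, 0, 0, 0.25, 0.25, 0.5, 0.5, 0.75, 0.75, 1, 1, 1], dtype=float)
    return NurbsCurve(P, w, 2, U)


# ---------------------------------------------------------------------------
# serialization

def curve_to_json(curve: NurbsCurve, path) -> None:
    payload = dict(control_points=curve.control_points.tolist(),
                   weights=curve.weights.tolist(),
                   degree=curve.degree,
                   knots=curve.knots.tolist())
    with open(path, "w") as fh:
        json.dump(payload, fh)


def curve_from_json(path) -> NurbsCurve:
    with open(path) as fh:
        d = json.load(fh)
    return NurbsCurve(np.asarray(d["control_points"]), np.asarray(d["weights"]),
                      int(d["degree"]), np.asarray(d["knots"]))
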