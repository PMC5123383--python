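"""Possibilistic differential-expression calls.

Fold-change variability between comparable samples is strongly count
dependent: the scatter of log2 fold changes against mean expression is wide
at low counts and narrows as counts grow.  The significance boundary is
estimated from the data as a symmetric envelope ±t(m), with

``t(m) = a / (m + c) + b``,  ``a > 0, b >= 0, c >= 0``

fitted by least squares to per-bin upper quantiles of |log2 FC| (log-spaced
bins in mean expression m, quantile ``q`` per bin, default 0.99).  The
envelope is turned into three fuzzy DE concepts over log2 FC at each m —
*under-expression*, *same-expression*, *over-expression* — built so that
all three cross possibility 0.5 exactly at the envelope:

* same: Gaussian, ``exp(-fc^2 / (2 sigma^2))`` with ``sigma = t / sqrt(2 ln 2)``
  (peak 1 at fc = 0, value 0.5 at fc = ±t);
* over: logistic, ``1 / (1 + exp(-s (fc - t)))`` with ``s = ln(99) / t``
  (0.5 at fc = t, below 0.01 at fc = 0);
* under: the mirror image of over.

All three have infinite support, so every fold change receives a graded
possibility rather than a hard in/out verdict.

A gene's fuzzy counts in the two conditions form a joint fuzzy relation
``min(case(x), control(y))`` (a truncated pyramid over the count plane).
Its three DE possibilities are the sup-min intersection of that relation
with each concept surface: the max over (x, y) of the min between the
relation and the surface evaluated at ``m = (x + y) / 2``,
``fc = log2(x / y)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import expit

from .fuzzy_counts import TrapezoidalCount

__all__ = [
    "DEThresholdModel",
    "DEModelError",
    "MembershipSurfaces",
    "DEPossibility",
    "fit_hyperbolas",
    "membership_surfaces",
    "joint_relation",
    "de_possibilities",
]

#: smallest admissible envelope value (log2 units); keeps the sigmoid
#: steepness and Gaussian width finite when replicates are nearly identical
T_FLOOR = 1e-3

_SIGMA_SCALE = 1.0 / math.sqrt(2.0 * math.log(2.0))  # sigma = t * this
_STEEPNESS = math.log(99.0)  # s = ln(99)/t  ->  over(0) = 0.01


class DEModelError(ValueError):
    """Raised when the envelope cannot be fitted."""


def _hyperbola(m, a, b, c):
    return a / (m + c) + b


@dataclass(frozen=True)
class DEThresholdModel:
    """Fitted fold-change significance envelope ±t(m).

    ``method`` is "hyperbola" for the parametric fit and "isotonic" for the
    monotone-envelope fallback.  Outside the fitted mean-expression range
    ``[m_lo, m_hi]`` the threshold is clamped to the range endpoints.
    """

    a: float
    b: float
    c: float
    q: float
    m_lo: float
    m_hi: float
    bin_centers: np.ndarray
    bin_thresholds: np.ndarray
    method: str = "hyperbola"
    t_floor: float = T_FLOOR

    def threshold(self, m):
        """Envelope value t(m) > 0 (scalar or array)."""
        m = np.clip(np.asarray(m, dtype=float), self.m_lo, self.m_hi)
        if self.method == "hyperbola":
            t = _hyperbola(m, self.a, self.b, self.c)
        else:
            t = np.interp(
                np.log(m), np.log(self.bin_centers), self.bin_thresholds
            )
        t = np.maximum(t, self.t_floor)
        return t if t.ndim else float(t)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "quantile": self.q,
            "m_range": [self.m_lo, self.m_hi],
            "bin_centers": list(map(float, self.bin_centers)),
            "bin_thresholds": list(map(float, self.bin_thresholds)),
            "t_floor": self.t_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DEThresholdModel":
        return cls(
            a=d["a"],
            b=d["b"],
            c=d["c"],
            q=d["quantile"],
            m_lo=d["m_range"][0],
            m_hi=d["m_range"][1],
            bin_centers=np.asarray(d["bin_centers"], dtype=float),
            bin_thresholds=np.asarray(d["bin_thresholds"], dtype=float),
            method=d["method"],
            t_floor=d.get("t_floor", T_FLOOR),
        )


def fit_hyperbolas(
    points,
    q: float = 0.99,
    min_m: float = 1.0,
    n_bins: int = 12,
    min_points: int = 50,
    t_floor: float = T_FLOOR,
) -> DEThresholdModel:
    """Fit the symmetric fold-change envelope ±t(m) to (m, log2fc) points.

    Points with non-finite fold change or mean expression <= ``min_m`` are
    excluded.  The remaining points are binned on a log-spaced mean grid,
    each bin contributes the ``q``-quantile of |fc| at its geometric centre,
    and ``t(m) = a/(m+c) + b`` is least-squares fitted to the bin boundary
    with ``a > 0`` (hence strictly decreasing), ``b, c >= 0``.  If the
    parametric fit fails, a monotone (non-increasing) interpolated envelope
    of the bin quantiles is used instead, with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DEModelError("points must be an (n, 2) array of (mean, log2fc)")
    m, fc = pts[:, 0], pts[:, 1]
    keep = np.isfinite(m) & np.isfinite(fc) & (m > min_m)
    if keep.sum() < min_points:
        raise DEModelError(
            f"need at least {min_points} finite points with mean > {min_m}, "
            f"got {int(keep.sum())}"
        )
    m, afc = m[keep], np.abs(fc[keep])
    edges = np.geomspace(m.min(), m.max() * (1.0 + 1e-12), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, m, side="right") - 1, 0, n_bins - 1)
    occupancy = 3 if m.size >= 30 else 1
    centers, quants = [], []
    for i in range(n_bins):
        sel = idx == i
        if sel.sum() >= occupancy:
            centers.append(math.sqrt(edges[i] * edges[i + 1]))
            quants.append(float(np.quantile(afc[sel], q)))
    centers = np.asarray(centers)
    quants = np.maximum(np.asarray(quants), t_floor)
    m_lo, m_hi = float(m.min()), float(m.max())
    if len(centers) < 3:
        # degenerate designs (a handful of genes): fall back to a flat /
        # interpolated envelope instead of a parametric fit
        warnings.warn(
            "fewer than 3 populated mean-expression bins; using a "
            "piecewise-constant envelope",
            stacklevel=2,
        )
        if len(centers) == 0:
            centers = np.array([math.sqrt(m_lo * m_hi)])
            quants = np.array([max(float(np.quantile(afc, q)), t_floor)])
        return DEThresholdModel(
            a=math.nan, b=math.nan, c=math.nan, q=q, m_lo=m_lo, m_hi=m_hi,
            bin_centers=centers,
            bin_thresholds=np.maximum.accumulate(quants[::-1])[::-1],
            method="isotonic", t_floor=t_floor,
        )
    try:
        p0 = [max(quants[0], 2 * t_floor) * centers[0], quants[-1], 1.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _hyperbola,
                centers,
                quants,
                p0=p0,
                bounds=([1e-12, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        return DEThresholdModel(
            a=float(popt[0]),
            b=float(popt[1]),
            c=float(popt[2]),
            q=q,
            m_lo=m_lo,
            m_hi=m_hi,
            bin_centers=centers,
            bin_thresholds=quants,
            method="hyperbola",
            t_floor=t_floor,
        )
    except RuntimeError:
        warnings.warn(
            "hyperbola fit did not converge; falling back to a monotone "
            "interpolated envelope",
            stacklevel=2,
        )
        from scipy.optimize import isotonic_regression

        iso = isotonic_regression(quants, increasing=False).x
        return DEThresholdModel(
            a=math.nan,
            b=math.nan,
            c=math.nan,
            q=q,
            m_lo=m_lo,
            m_hi=m_hi,
            bin_centers=centers,
            bin_thresholds=np.maximum(iso, t_floor),
            method="isotonic",
            t_floor=t_floor,
        )


@dataclass(frozen=True)
class MembershipSurfaces:
    """The three DE membership functions over log2 FC at one mean expression."""

    m: float
    t: float

    @property
    def sigma(self) -> float:
        return self.t * _SIGMA_SCALE

    @property
    def steepness(self) -> float:
        return _STEEPNESS / self.t

    def same(self, fc):
        fc = np.asarray(fc, dtype=float)
        with np.errstate(invalid="ignore"):
            out = np.exp(-(fc ** 2) / (2.0 * self.sigma ** 2))
        out = np.where(np.isinf(fc), 0.0, out)
        return out if out.ndim else float(out)

    def over(self, fc):
        fc = np.asarray(fc, dtype=float)
        out = expit(self.steepness * (fc - self.t))
        return out if out.ndim else float(out)

    def under(self, fc):
        fc = np.asarray(fc, dtype=float)
        out = expit(self.steepness * (-fc - self.t))
        return out if out.ndim else float(out)


def membership_surfaces(model: DEThresholdModel, m: float) -> MembershipSurfaces:
    """Instantiate the under/same/over membership functions at mean
    expression ``m`` (> 0); outside the fitted range the envelope is clamped."""
    if not (np.isfinite(m) and m > 0):
        raise DEModelError(f"mean expression must be positive, got {m!r}")
    return MembershipSurfaces(m=float(m), t=float(model.threshold(m)))


def joint_relation(
    case: TrapezoidalCount, control: TrapezoidalCount
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Joint possibility that the case has x reads and the control y reads.

    The two counts are non-interacting, so the relation is the min t-norm of
    the two trapezoid memberships — a truncated pyramid over the count plane.
    """

    def relation(x, y):
        return np.minimum(case.membership(x), control.membership(y))

    return relation


@dataclass(frozen=True)
class DEPossibility:
    """Possibility degrees of under-, same- and over-expression."""

    under: float
    same: float
    over: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("under", "same", "over"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name} possibility out of [0, 1]: {v}")

    @property
    def max_possibility(self) -> float:
        return max(self.under, self.same, self.over)

    def swapped(self) -> "DEPossibility":
        """The verdict of the comparison with case and control exchanged."""
        return DEPossibility(self.over, self.same, self.under, self.degenerate)


def _axis_grid(t: TrapezoidalCount, grid_n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample points and memberships along one count axis.

    A point trapezoid (no multireads) is a crisp count: its axis carries the
    single fully-possible value.  Otherwise the axis spans the support
    [max(A-1, 0), D+1] on ``grid_n`` points with the trapezoid knots always
    included exactly.
    """
    if t.is_point:
        return np.array([t.a]), np.array([1.0])
    lo, hi = t.support
    knots = np.array([lo, t.a, t.b, t.c, t.d, hi])
    xs = np.unique(np.concatenate([np.linspace(lo, hi, grid_n), knots]))
    return xs, np.asarray(t.membership(xs))


def de_possibilities(
    case: TrapezoidalCount,
    control: TrapezoidalCount,
    model: DEThresholdModel,
    grid_n: int = 64,
) -> DEPossibility:
    """Sup-min intersection of the joint count relation with the three DE
    surfaces.

    The joint support is sampled on a ``grid_n`` x ``grid_n`` grid (plus the
    exact trapezoid knots); at each cell the relation value is min-combined
    with each surface evaluated at ``m = (x+y)/2`` and ``fc = log2(x/y)``,
    and the possibility is the max over cells.  Cells with a zero count use
    the fold-change limits (over -> 1 or 0, same -> 0); a cell at the origin
    carries no evidence of change (fc = 0).  Two all-zero trapezoids return
    the conventional (0, 1, 0) with ``degenerate=True``.
    """
    if case.d == 0 and control.d == 0:
        return DEPossibility(0.0, 1.0, 0.0, degenerate=True)

    def evaluate(xs, wx, ys, wy):
        """min(relation, surface) matrices for the three surfaces."""
        X = xs[:, None]
        Y = ys[None, :]
        R = np.minimum(wx[:, None], wy[None, :])
        FC = np.where((X > 0) & (Y > 0), np.log2(np.where(X > 0, X, 1.0))
                      - np.log2(np.where(Y > 0, Y, 1.0)), 0.0)
        FC = np.where((X == 0) & (Y > 0), -np.inf, FC)
        FC = np.where((X > 0) & (Y == 0), np.inf, FC)
        M = (X + Y) / 2.0  # origin cells have M=0; threshold() clamps to m_lo
        T = np.asarray(model.threshold(np.maximum(M, model.t_floor)))
        sigma = T * _SIGMA_SCALE
        s = _STEEPNESS / T
        with np.errstate(invalid="ignore", over="ignore"):
            same_s = np.exp(-(FC ** 2) / (2.0 * sigma ** 2))
        same_s = np.where(np.isinf(FC), 0.0, same_s)
        over_s = expit(s * (FC - T))    # expit(+/-inf) gives the 1/0 limits
        under_s = expit(s * (-FC - T))
        return (
            np.minimum(R, under_s),
            np.minimum(R, same_s),
            np.minimum(R, over_s),
        )

    def subgrid(t, values, i, n):
        """Fine grid spanning the coarse cells around index ``i``."""
        if values.size == 1:
            return values, np.array([1.0])
        lo = values[max(i - 1, 0)]
        hi = values[min(i + 1, values.size - 1)]
        xs = np.linspace(lo, hi, n)
        return xs, np.asarray(t.membership(xs))

    xs, wx = _axis_grid(case, grid_n)
    ys, wy = _axis_grid(control, grid_n)
    coarse = evaluate(xs, wx, ys, wy)
    n_starts = 6  # refine around several coarse candidates (basins can compete)
    best = []
    for k, mat in enumerate(coarse):
        value = float(mat.max())
        order = np.argsort(mat, axis=None)[::-1][:n_starts]
        for flat in order:
            i, j = np.unravel_index(int(flat), mat.shape)
            gx, gwx = subgrid(case, xs, i, grid_n)
            gy, gwy = subgrid(control, ys, j, grid_n)
            for _ in range(2):
                fine = evaluate(gx, gwx, gy, gwy)[k]
                value = max(value, float(fine.max()))
                fi, fj = np.unravel_index(int(np.argmax(fine)), fine.shape)
                gx, gwx = subgrid(case, gx, fi, grid_n)
                gy, gwy = subgrid(control, gy, fj, grid_n)
        best.append(value)
    return DEPossibility(under=best[0], same=best[1], over=best[2])
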