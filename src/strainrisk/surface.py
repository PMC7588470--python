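"""Strain surface interpolation, critical curves and the normalized area.

Per aneurysm, the 16 sweep strains define a surface over the design
rectangle [0.25, 1.0]^2 of (thickness fraction tau, modulus fraction eta).
A 4x4 node grid determines a unique tensor-product bicubic polynomial

    eps(tau, eta) = sum_{i,j=0..3} c_ij tau^i eta^j

and the *critical curve* is the level set eps = failure strain (0.3 by
default): the combinations of wall thinning and softening at which the wall
is predicted to rupture.  The *normalized area* (NA) is the fraction of the
design rectangle on the rupture side of the curve — the risk score in
[0, 1].  NA is computed as the exceedance measure

    NA = |{(tau, eta) : eps(tau, eta) >= level}| / 0.75^2

which coincides with the area under the critical curve for physically
monotone surfaces and stays well defined for oscillatory interpolants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .grids import FRACTIONS, ConditionGrid, StrainGrid

__all__ = [
    "BicubicSurface",
    "CriticalCurve",
    "DOMAIN",
    "MembraneSurface",
    "extract_critical_curve",
    "fit_surface",
    "hyperbola_constant_from_na",
    "hyperbola_na_closed_form",
    "na_of_grid",
    "normalized_area",
    "reference_curve_from_na",
]

#: The design rectangle in fraction coordinates: tau, eta in [0.25, 1.0].
DOMAIN = (0.25, 1.0)

_LO, _HI = DOMAIN
_SPAN = _HI - _LO
_ENTIRE_AREA = _SPAN * _SPAN  # 0.5625 in fraction units


def _powers(x: np.ndarray) -> np.ndarray:
    """Column matrix [1, x, x^2, x^3] for a 1-D coordinate array."""
    x = np.asarray(x, dtype=float)
    return x[:, None] ** np.arange(4)


@dataclass(frozen=True)
class BicubicSurface:
    """Tensor-product bicubic interpolant of a 4x4 strain grid.

    ``coefficients[i, j]`` multiplies tau^i * eta^j.
    """

    coefficients: np.ndarray
    domain: tuple[float, float] = DOMAIN

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)
        if c.shape != (4, 4) or not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be a finite 4x4 array")

    def __call__(self, tau, eta):
        """Evaluate at (broadcastable) tau, eta."""
        return np.polynomial.polynomial.polyval2d(
            np.asarray(tau, dtype=float), np.asarray(eta, dtype=float),
            self.coefficients)

    def evaluate_mesh(self, taus: np.ndarray, etas: np.ndarray) -> np.ndarray:
        """Evaluate on the tensor mesh; result[i, j] = eps(taus[i], etas[j])."""
        return _powers(taus) @ self.coefficients @ _powers(etas).T

    def range_on_mesh(self, resolution: int = 256) -> tuple[float, float]:
        """(min, max) of the surface on a uniform evaluation mesh."""
        x = np.linspace(_LO, _HI, resolution)
        z = self.evaluate_mesh(x, x)
        return float(z.min()), float(z.max())


@dataclass(frozen=True)
class MembraneSurface:
    """Exact membrane-surrogate surface eps(tau, eta) = eps0 / (tau * eta).

    ``eps0`` is the nominal-condition strain.  Its level sets are the
    hyperbolas tau * eta = eps0 / level, so the normalized area has the
    closed form :func:`hyperbola_na_closed_form` — the analytic oracle for
    the numerical quadrature.  Shares the evaluation interface of
    :class:`BicubicSurface`, so the curve and area operations accept either.
    """

    eps0: float
    domain: tuple[float, float] = DOMAIN

    def __post_init__(self) -> None:
        if self.eps0 <= 0.0:
            raise ValueError("nominal strain eps0 must be > 0")

    def __call__(self, tau, eta):
        return self.eps0 / (np.asarray(tau, dtype=float)
                            * np.asarray(eta, dtype=float))

    def evaluate_mesh(self, taus: np.ndarray, etas: np.ndarray) -> np.ndarray:
        return self.eps0 / np.outer(taus, etas)


def fit_surface(grid: StrainGrid) -> BicubicSurface:
    """The unique bicubic polynomial through all 16 grid nodes.

    Solves the separable tensor Vandermonde system; node values are
    reproduced to ~1e-9 relative (machine precision for these node levels).
    """
    if not isinstance(grid, StrainGrid):
        grid = StrainGrid(np.asarray(grid, dtype=float))
    vt = _powers(np.array(grid.conditions.thickness_fractions))
    ve = _powers(np.array(grid.conditions.modulus_fractions))
    # G = Vt @ C @ Ve.T  =>  C = Vt^{-1} G Ve^{-T}
    c = np.linalg.solve(ve, np.linalg.solve(vt, grid.values).T).T
    return BicubicSurface(c)


@dataclass(frozen=True)
class CriticalCurve:
    """Level set of a strain surface at the failure strain.

    ``segments`` is a tuple of (N, 2) polyline vertex arrays in (tau, eta)
    fraction coordinates.  When the surface never crosses the level the
    tuple is empty and ``empty_reason`` records which side the whole domain
    lies on: ``all_below`` (no rupture predicted anywhere in the sweep) or
    ``all_above`` (rupture predicted everywhere).
    """

    level: float
    segments: tuple[np.ndarray, ...] = ()
    empty_reason: str = "none"

    def __post_init__(self) -> None:
        if self.empty_reason not in ("none", "all_below", "all_above"):
            raise ValueError(f"bad empty_reason {self.empty_reason!r}")
        segs = tuple(np.asarray(s, dtype=float) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        for s in segs:
            if s.ndim != 2 or s.shape[1] != 2:
                raise ValueError("each segment must be an (N, 2) vertex array")
            if np.any(s < _LO - 1e-9) or np.any(s > _HI + 1e-9):
                raise ValueError("curve vertices must lie inside the domain")

    @property
    def is_empty(self) -> bool:
        return len(self.segments) == 0

    def vertices(self) -> np.ndarray:
        """All vertices stacked, (N, 2); empty array for an empty curve."""
        if self.is_empty:
            return np.empty((0, 2))
        return np.vstack(self.segments)


def extract_critical_curve(surface, level: float = 0.3,
                           resolution: int = 256) -> CriticalCurve:
    """Extract the failure-strain level set by marching squares.

    The surface is sampled on a uniform ``resolution`` x ``resolution``
    mesh over the domain and contoured with linear in-cell interpolation.
    Vertices come back in (tau, eta) fraction coordinates.
    """
    if level <= 0.0:
        raise ValueError("failure-strain level must be > 0")
    if resolution < 32:
        raise ValueError("contour resolution must be >= 32")
    x = np.linspace(_LO, _HI, resolution)
    z = surface.evaluate_mesh(x, x)
    if z.max() < level:
        return CriticalCurve(level=level, empty_reason="all_below")
    if z.min() >= level:
        return CriticalCurve(level=level, empty_reason="all_above")
    step = _SPAN / (resolution - 1)
    segments = []
    for contour in measure.find_contours(z, level):
        # find_contours returns (row, col) = (tau index, eta index)
        verts = _LO + contour * step
        segments.append(np.clip(verts, _LO, _HI))
    if not segments:  # level only grazes the surface at isolated points
        reason = "all_above" if np.mean(z >= level) > 0.5 else "all_below"
        return CriticalCurve(level=level, empty_reason=reason)
    return CriticalCurve(level=level, segments=tuple(segments))


def normalized_area(surface, level: float = 0.3,
                    resolution: int = 512) -> float:
    """Normalized area: fraction of the design rectangle at or above level.

    Midpoint quadrature on a uniform ``resolution`` x ``resolution`` cell
    grid.  Strain exactly equal to the failure level counts as exceedance
    (the wall fails when the strain *reaches* the failure strain).
    """
    if level <= 0.0:
        raise ValueError("failure-strain level must be > 0")
    if resolution < 32:
        raise ValueError("quadrature resolution must be >= 32")
    mid = _LO + (np.arange(resolution) + 0.5) * (_SPAN / resolution)
    z = surface.evaluate_mesh(mid, mid)
    return float(np.mean(z >= level))


def na_of_grid(grid: StrainGrid, level: float = 0.3,
               resolution: int = 512) -> float:
    """Convenience: fit the bicubic surface and return its normalized area."""
    return normalized_area(fit_surface(grid), level=level, resolution=resolution)


def hyperbola_na_closed_form(c: float) -> float:
    """Exact NA of the membrane-family curve tau * eta = c.

    For the membrane surrogate eps = eps0/(tau*eta) at level L the
    exceedance region is {tau*eta <= c} with c = eps0/L; its area fraction
    inside [0.25, 1]^2 has the closed piecewise form implemented here.
    Serves as the analytic oracle for the numerical NA quadrature.
    """
    if c <= 0.0:
        raise ValueError("hyperbola constant c must be > 0")
    if c <= 1.0 / 16.0:
        return 0.0
    if c <= 0.25:
        area = c * math.log(16.0 * c) - (c - 1.0 / 16.0)
    elif c <= 1.0:
        area = c - c * math.log(c) - 7.0 / 16.0
    else:
        return 1.0
    return area / _ENTIRE_AREA


def hyperbola_constant_from_na(target_na: float, tol: float = 1e-9) -> float:
    """Invert the closed-form NA: the c with NA(tau*eta = c) = target_na.

    Monotone bisection on c in (1/16, 1); converges to ``tol`` in NA.
    """
    if not (0.0 < target_na < 1.0):
        raise ValueError("target NA must lie strictly between 0 and 1")
    lo, hi = 1.0 / 16.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        na_mid = hyperbola_na_closed_form(mid)
        if abs(na_mid - target_na) <= tol:
            return mid
        if na_mid < target_na:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def reference_curve_from_na(target_na: float, level: float = 0.3,
                            n_vertices: int = 257) -> CriticalCurve:
    """Reference line: the membrane-family curve with the given NA.

    Inverts the closed-form NA to the hyperbola constant c and returns
    tau * eta = c, clipped to the design rectangle, as a polyline.  This is
    the critical curve of the membrane surface eps = (level*c)/(tau*eta) at
    the failure strain ``level``: aneurysms whose critical curves lie above
    it score NA beyond the target and are flagged as rupture-prone.
    """
    c = hyperbola_constant_from_na(target_na)
    tau = np.linspace(max(_LO, c), min(_HI, 4.0 * c), n_vertices)
    eta = np.clip(c / tau, _LO, _HI)
    return CriticalCurve(level=level,
                         segments=(np.column_stack([tau, eta]),))
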