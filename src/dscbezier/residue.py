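"""Constrained cubic Bezier representation of the tissue residue function.

The residue function R(t) is the fraction of tracer still inside a tissue
element a time t after instantaneous arterial arrival.  Physiology requires
R(0) = 1 and R non-increasing; common SVD deconvolution violates both.  Here
R is a cubic Bezier curve with control points

    P0 = (0, 1),  P1 = (p1x, p1y),  P2 = (p2x, p2y),  P3 = (t_end, 0),

leaving five free coordinates.  The orderings 0 <= p1x <= p2x <= t_end and
1 >= p1y >= p2y >= 0 make the parametric coordinates x(s) non-decreasing and
y(s) non-increasing, so R is a monotone function of time that falls from 1
to 0 on [0, t_end].  Consequences used throughout the package:

* the transit-time distribution h(t) = -dR/dt is a proper probability
  density (non-negative, unit mass),
* the mean transit time MTT = integral of R(t) dt and the transit-time
  heterogeneity CTH = central second moment of h are polynomial integrals in
  the Bezier parameter s and are computed exactly by fixed-order
  Gauss-Legendre quadrature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BezierResidue",
    "GriddedResidue",
    "TransitTimeDistribution",
    "transit_time_density",
    "mtt",
    "cth",
]

# Gauss-Legendre nodes/weights on [0, 1]; order 5 is exact for polynomials
# up to degree 9, covering both the MTT (degree 5) and CTH (degree 8)
# integrands.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)
_GL_S = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


@dataclass(frozen=True)
class BezierResidue:
    """Residue function R(t) as a constrained cubic Bezier curve.

    Parameters
    ----------
    p1x, p2x : float
        Abscissae (seconds) of the two interior control points.
    p1y, p2y : float
        Ordinates (dimensionless) of the two interior control points.
    t_end : float
        Time (seconds) at which the residue reaches zero; abscissa of P3.
    """

    p1x: float
    p1y: float
    p2x: float
    p2y: float
    t_end: float

    _TOL = 1e-12

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")
        if not (-self._TOL <= self.p1x <= self.p2x + self._TOL <= self.t_end + 2 * self._TOL):
            raise ValueError("need 0 <= p1x <= p2x <= t_end")
        if not (1 + self._TOL >= self.p1y >= self.p2y - self._TOL >= -2 * self._TOL):
            raise ValueError("need 1 >= p1y >= p2y >= 0")

    # -- parametric curve ---------------------------------------------------

    def _xy(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = 1.0 - s
        x = 3 * s * u * u * self.p1x + 3 * s * s * u * self.p2x + s**3 * self.t_end
        y = u**3 + 3 * s * u * u * self.p1y + 3 * s * s * u * self.p2y
        return x, y

    def _dxy(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = 1.0 - s
        dx = 3 * (u * u * self.p1x + 2 * s * u * (self.p2x - self.p1x) + s * s * (self.t_end - self.p2x))
        dy = 3 * (u * u * (self.p1y - 1.0) + 2 * s * u * (self.p2y - self.p1y) - s * s * self.p2y)
        return dx, dy

    def _invert_x(self, t: np.ndarray) -> np.ndarray:
        """Solve x(s) = t for s in [0, 1], vectorised safeguarded Newton.

        x(s) is non-decreasing, so each query is bracketed by [0, 1];
        Newton steps are taken when they stay inside the shrinking bracket
        and bisection is used otherwise.  Converges to ~1e-14 in s.
        """
        t = np.asarray(t, dtype=float)
        lo = np.zeros_like(t)
        hi = np.ones_like(t)
        s = np.clip(t / self.t_end, 0.0, 1.0)
        ftol = 1e-13 * max(self.t_end, 1.0)
        for _ in range(200):
            x, _ = self._xy(s)
            f = x - t
            hi = np.where(f > 0, np.minimum(hi, s), hi)
            lo = np.where(f < 0, np.maximum(lo, s), lo)
            if np.max(np.abs(f)) < ftol or np.max(hi - lo) < 1e-15:
                break
            dx, _ = self._dxy(s)
            with np.errstate(divide="ignore", invalid="ignore"):
                newton = s - f / dx
            mid = 0.5 * (lo + hi)
            ok = (dx > 0) & (newton > lo) & (newton < hi)
            s = np.where(ok, newton, mid)
        return s

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, t) -> np.ndarray:
        """R(t): 1 at t = 0, 0 for t >= t_end, monotone in between."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        out = np.zeros_like(t)
        inside = t < self.t_end
        if np.any(inside):
            s = self._invert_x(t[inside])
            _, y = self._xy(s)
            out[inside] = np.clip(y, 0.0, 1.0)
        return out

    __call__ = evaluate

    def density(self, t) -> np.ndarray:
        """Transit-time density h(t) = -dR/dt = -y'(s)/x'(s) at x(s) = t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        inside = (t >= 0) & (t < self.t_end)
        if np.any(inside):
            s = self._invert_x(t[inside])
            dx, dy = self._dxy(s)
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(dx > 0, -dy / np.where(dx > 0, dx, 1.0), np.inf)
            out[inside] = np.maximum(h, 0.0)
        return out

    # -- moments ------------------------------------------------------------

    def mtt(self) -> float:
        """Mean transit time (s): the time integral of R(t).

        Computed in Bezier parameter space as int_0^1 y(s) x'(s) ds, a
        degree-5 polynomial integrand that the fixed Gauss rule integrates
        exactly.
        """
        x, y = self._xy(_GL_S)
        dx, _ = self._dxy(_GL_S)
        return float(np.sum(_GL_W * y * dx))

    def cth(self, as_std: bool = False) -> float:
        """Capillary transit-time heterogeneity.

        By default the central second moment of h(t) in s^2,
        int (t - MTT)^2 h(t) dt = int_0^1 (x(s) - MTT)^2 (-y'(s)) ds,
        a degree-8 polynomial integrated exactly.  With ``as_std=True`` the
        square root is returned (standard-deviation convention).
        """
        m = self.mtt()
        x, _ = self._xy(_GL_S)
        _, dy = self._dxy(_GL_S)
        var = float(np.sum(_GL_W * (x - m) ** 2 * (-dy)))
        var = max(var, 0.0)
        return float(np.sqrt(var)) if as_std else var

    # -- constructors -------------------------------------------------------

    @classmethod
    def linear(cls, t_end: float) -> "BezierResidue":
        """Straight-line residue R(t) = 1 - t/t_end (collinear control points)."""
        return cls(t_end / 3.0, 2.0 / 3.0, 2.0 * t_end / 3.0, 1.0 / 3.0, t_end)

    @classmethod
    def from_unit_box(cls, a: float, b: float, c: float, d: float, t_end: float) -> "BezierResidue":
        """Build a residue from the optimizer parameterisation.

        a, b, c, d in [0, 1] encode the interior control points so that the
        ordering constraints become simple box bounds:
        p1x = a*t_end, p2x = p1x + b*(t_end - p1x), p1y = 1 - c,
        p2y = p1y*(1 - d).
        """
        for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        p1x = a * t_end
        p2x = p1x + b * (t_end - p1x)
        p1y = 1.0 - c
        p2y = p1y * (1.0 - d)
        return cls(p1x, p1y, p2x, p2y, t_end)

    def to_unit_box(self) -> tuple[float, float, float, float, float]:
        """Inverse of :meth:`from_unit_box` (degenerate axes map to 0)."""
        a = self.p1x / self.t_end
        rem = self.t_end - self.p1x
        b = (self.p2x - self.p1x) / rem if rem > 0 else 0.0
        c = 1.0 - self.p1y
        d = 1.0 - self.p2y / self.p1y if self.p1y > 0 else 0.0
        clip = lambda v: float(min(max(v, 0.0), 1.0))
        return clip(a), clip(b), clip(c), clip(d), float(self.t_end)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "p1x": self.p1x,
            "p1y": self.p1y,
            "p2x": self.p2x,
            "p2y": self.p2y,
            "t_end": self.t_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BezierResidue":
        return cls(d["p1x"], d["p1y"], d["p2x"], d["p2y"], d["t_end"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BezierResidue":
        return cls.from_dict(json.loads(s))

    def plot(self, ax=None, n: int = 200, **kwargs):
        """Plot R(t) on [0, 1.1*t_end]."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0.0, 1.1 * self.t_end, n)
        ax.plot(t, self.evaluate(t), **kwargs)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("R(t)")
        ax.set_ylim(-0.05, 1.05)
        return ax


@dataclass(frozen=True)
class GriddedResidue:
    """Residue function tabulated on a fine grid (linear interpolation).

    Used by the phantom generator for residue families that are not exactly
    representable as cubic Beziers (boxcar plug flow, gamma transit-time
    distributions).  ``values`` must start at 1 and be non-increasing.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times/values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(v[0] - 1.0) > 1e-9 or np.any(np.diff(v) > 1e-12):
            raise ValueError("residue values must start at 1 and be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.interp(t, self.times, self.values, left=1.0, right=float(self.values[-1]))

    __call__ = evaluate

    def mtt(self) -> float:
        return float(np.trapezoid(self.values, self.times))


@dataclass(frozen=True)
class TransitTimeDistribution:
    """Transit-time density h(tau) tabulated on a grid of transit times."""

    tau: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.tau))

    def moment(self, order: int = 1, center: float = 0.0) -> float:
        return float(np.trapezoid((self.tau - center) ** order * self.density, self.tau))


def transit_time_density(residue: BezierResidue, n: int = 2001) -> TransitTimeDistribution:
    """Tabulate h(t) = -dR/dt of a Bezier residue.

    Evaluated along the curve parameter on a closed grid over [0, 1] so no
    endpoint mass is truncated.  x'(s) can vanish only at isolated
    parameter values (a vertical curve segment is impossible under the
    coordinate orderings); grid points that hit such a zero are nudged by a
    quarter cell, which realises the limit value of the density there.
    """
    s = np.linspace(0.0, 1.0, n)
    dx, dy = residue._dxy(s)
    bad = dx <= 1e-300
    if np.any(bad):
        s = np.where(bad & (s >= 1.0), s - 0.25 / n, np.where(bad, s + 0.25 / n, s))
        dx, dy = residue._dxy(s)
        if np.any(dx <= 0):
            raise ValueError("x'(s) vanished on the evaluation grid; vertical segment")
    x, _ = residue._xy(s)
    return TransitTimeDistribution(x, -dy / dx)


def mtt(residue) -> float:
    """Mean transit time of any residue object exposing ``mtt``."""
    return residue.mtt()


def cth(residue: BezierResidue, as_std: bool = False) -> float:
    """Transit-time heterogeneity of a Bezier residue (see method docs)."""
    return residue.cth(as_std=as_std)
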