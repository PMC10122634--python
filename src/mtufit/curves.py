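"""Passive force-length curves for muscle fibre and tendon.

Both tissues are described by normalised, monotonically increasing,
continuously differentiable (C1) force-length curves:

* the **fibre** curve maps normalised fibre length ``l/l_o_f`` to passive
  force in units of the maximal isometric force ``F_max``.  It is zero up to
  the engagement length ``1 + eps_zero_f``, reaches exactly 1 at
  ``1 + eps_one_f`` with slope ``K_one_f = 2/(eps_one_f - eps_zero_f)``, and
  continues linearly with that slope beyond.
* the **tendon** curve maps normalised tendon length ``l/l_s_t`` to force in
  units of ``F_max``.  It is zero at or below slack length (normalised 1),
  passes through the toe-end point ``(1 + eps_toe, f_toe_t)``, then is exactly
  linear with slope ``K_one_t = 1.375/eps_one_t`` through ``(1 + eps_one_t, 1)``
  and beyond.

The curved portions are built from quintic Bezier "corner" segments: a corner
is the smooth blend between two straight lines (the entry line with the entry
slope and the exit line with the exit slope), with a curviness parameter in
[0, 1] moving the inner control points from near-straight (0) towards the
sharp intersection corner (1).  End values and end slopes are met exactly by
construction, which is what the rest of the model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "FibreCurveParams",
    "TendonCurveParams",
    "CurveParameterError",
    "SmoothSegmentedCurve",
    "make_fibre_curve",
    "make_tendon_curve",
    "fibre_passive_force",
    "tendon_force",
    "derived_stiffnesses",
]


class CurveParameterError(ValueError):
    """Raised when curve parameters violate their admissibility conditions."""


@dataclass(frozen=True)
class FibreCurveParams:
    """Parameters of the passive fibre force-length curve.

    eps_zero_f : fibre strain at which passive force starts to engage
    eps_one_f  : fibre strain at which the fibre develops F_max
    k_low_scale: scaling factor x of the low-force stiffness,
                 K_low_f = x / (eps_one_f - eps_zero_f)
    curviness_f: shape factor in [0, 1]
    """

    eps_zero_f: float = 0.0
    eps_one_f: float = 0.70
    k_low_scale: float = 0.14
    curviness_f: float = 0.75

    def __post_init__(self) -> None:
        if not self.eps_one_f > self.eps_zero_f:
            raise CurveParameterError(
                f"eps_one_f ({self.eps_one_f}) must exceed eps_zero_f "
                f"({self.eps_zero_f})"
            )
        if not 0.0 < self.k_low_scale < 1.0:
            raise CurveParameterError(
                f"k_low_scale must lie in (0, 1), got {self.k_low_scale}"
            )
        if not 0.0 <= self.curviness_f <= 1.0:
            raise CurveParameterError(
                f"curviness_f must lie in [0, 1], got {self.curviness_f}"
            )

    @property
    def k_one_f(self) -> float:
        """Normalised stiffness where the fibre develops F_max."""
        return 2.0 / (self.eps_one_f - self.eps_zero_f)

    @property
    def k_low_f(self) -> float:
        """Normalised stiffness where passive force just engages."""
        return self.k_low_scale / (self.eps_one_f - self.eps_zero_f)

    def curve(self) -> "SmoothSegmentedCurve":
        return make_fibre_curve(self)


@dataclass(frozen=True)
class TendonCurveParams:
    """Parameters of the tendon force-length curve.

    eps_one_t  : tendon strain at which the tendon develops F_max
    f_toe_t    : normalised force at the end of the toe region
    curviness_t: shape factor in [0, 1]
    """

    eps_one_t: float = 0.049
    f_toe_t: float = 0.67
    curviness_t: float = 0.5

    def __post_init__(self) -> None:
        if not self.eps_one_t > 0.0:
            raise CurveParameterError(
                f"eps_one_t must be positive, got {self.eps_one_t}"
            )
        if not 0.0 < self.f_toe_t < 1.0:
            raise CurveParameterError(
                f"f_toe_t must lie in (0, 1), got {self.f_toe_t}"
            )
        if not 0.0 <= self.curviness_t <= 1.0:
            raise CurveParameterError(
                f"curviness_t must lie in [0, 1], got {self.curviness_t}"
            )

    @property
    def k_one_t(self) -> float:
        """Normalised tendon stiffness at one norm force."""
        return 1.375 / self.eps_one_t

    @property
    def eps_toe_t(self) -> float:
        """Strain at the toe-region end (where the curve becomes linear)."""
        return self.eps_one_t - (1.0 - self.f_toe_t) / self.k_one_t

    def curve(self) -> "SmoothSegmentedCurve":
        return make_tendon_curve(self)


def derived_stiffnesses(
    fp: FibreCurveParams, tp: TendonCurveParams
) -> tuple[float, float, float]:
    """Return the dependent stiffnesses ``(K_low_f, K_one_f, K_one_t)``."""
    return fp.k_low_f, fp.k_one_f, tp.k_one_t


# --- quintic Bezier machinery ------------------------------------------------

# power-basis conversion: B(u) = sum_i p_i C(5,i) u^i (1-u)^(5-i) = sum_k a_k u^k
def _bezier_matrix() -> np.ndarray:
    from math import comb

    m = np.zeros((6, 6))
    for i in range(6):
        for k in range(i, 6):
            m[k, i] = comb(5, i) * comb(5 - i, k - i) * (-1.0) ** (k - i)
    return m


_BEZ_M = _bezier_matrix()


class _BezierSegment:
    """One quintic Bezier span y(x), with x(u), y(u) monotone in u."""

    def __init__(self, x_ctrl: np.ndarray, y_ctrl: np.ndarray):
        self.x0 = float(x_ctrl[0])
        self.x1 = float(x_ctrl[-1])
        self.y0 = float(y_ctrl[0])
        self.y1 = float(y_ctrl[-1])
        self.ax = _BEZ_M @ np.asarray(x_ctrl, float)  # ascending power coeffs
        self.ay = _BEZ_M @ np.asarray(y_ctrl, float)
        self.dax = self.ax[1:] * np.arange(1, 6)
        self.day = self.ay[1:] * np.arange(1, 6)
        # integrand for  int y dx = int y(u) x'(u) du : degree-9 polynomial
        q = np.polynomial.polynomial.polymul(self.ay, self.dax)
        self.iq = np.polynomial.polynomial.polyint(q)
        # lookup table for inverting x(u)
        u = np.linspace(0.0, 1.0, 65)
        self._u_tab = u
        self._x_tab = self._pv(self.ax, u)

    @staticmethod
    def _pv(c: np.ndarray, u: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(u, c)

    def _u_of_x(self, x: np.ndarray) -> np.ndarray:
        u = np.interp(x, self._x_tab, self._u_tab)
        for _ in range(4):  # Newton polish; x(u) is monotone on [0, 1]
            du = (self._pv(self.ax, u) - x) / np.maximum(
                self._pv(self.dax, u), 1e-14
            )
            u = np.clip(u - du, 0.0, 1.0)
        return u

    def value(self, x: np.ndarray) -> np.ndarray:
        return self._pv(self.ay, self._u_of_x(x))

    def derivative(self, x: np.ndarray) -> np.ndarray:
        u = self._u_of_x(x)
        return self._pv(self.day, u) / np.maximum(self._pv(self.dax, u), 1e-14)

    def integral(self, x: np.ndarray) -> np.ndarray:
        """Integral of y dx from the segment start to x (x inside span)."""
        u = self._u_of_x(x)
        return self._pv(self.iq, u) - self._pv(self.iq, 0.0)

    @property
    def full_integral(self) -> float:
        return float(self._pv(self.iq, 1.0) - self._pv(self.iq, 0.0))


class _LinearSegment:
    """Exactly linear span (used for the tendon beyond the toe region)."""

    def __init__(self, x0: float, x1: float, y0: float, slope: float):
        self.x0, self.x1, self.y0, self.slope = x0, x1, y0, slope
        self.y1 = y0 + slope * (x1 - x0)

    def value(self, x):
        return self.y0 + self.slope * (np.asarray(x, float) - self.x0)

    def derivative(self, x):
        return np.full_like(np.asarray(x, float), self.slope)

    def integral(self, x):
        d = np.asarray(x, float) - self.x0
        return self.y0 * d + 0.5 * self.slope * d * d

    @property
    def full_integral(self) -> float:
        d = self.x1 - self.x0
        return self.y0 * d + 0.5 * self.slope * d * d


def _corner_controls(
    x0: float, y0: float, d0: float,
    x1: float, y1: float, d1: float,
    curviness: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Quintic Bezier control points blending two lines into a smooth corner."""
    c = 0.1 + 0.8 * curviness  # keep away from degenerate extremes
    xc = (y1 - y0 + d0 * x0 - d1 * x1) / (d0 - d1)
    yc = y0 + d0 * (xc - x0)
    x_ctrl = np.array(
        [x0, x0 + c * (xc - x0), x0 + c * (xc - x0),
         x1 + c * (xc - x1), x1 + c * (xc - x1), x1]
    )
    y_ctrl = np.array(
        [y0, y0 + c * (yc - y0), y0 + c * (yc - y0),
         y1 + c * (yc - y1), y1 + c * (yc - y1), y1]
    )
    return x_ctrl, y_ctrl


class SmoothSegmentedCurve:
    """Piecewise curve: zero left tail, smooth segments, linear right tail."""

    def __init__(self, segments: list):
        self.segments = segments
        self.x_start = segments[0].x0
        self.x_end = segments[-1].x1
        self.y_end = segments[-1].y1
        last = segments[-1]
        self.end_slope = float(np.atleast_1d(last.derivative(np.array([self.x_end])))[0])
        self._breaks = np.array([s.x0 for s in segments] + [self.x_end])
        cum = np.concatenate([[0.0], np.cumsum([s.full_integral for s in segments])])
        self._cum_integral = cum  # integral from x_start to each break
        self._fast_tab: tuple[np.ndarray, np.ndarray] | None = None

    def _masked(self, x, fn_name: str, right_fn, left_value=0.0):
        x = np.asarray(x, float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.full(x.shape, left_value, float)
        idx = np.searchsorted(self._breaks, x, side="right") - 1
        for i, seg in enumerate(self.segments):
            m = (idx == i) & (x >= self.x_start)
            if m.any():
                out[m] = getattr(seg, fn_name)(x[m])
                if fn_name == "integral":
                    out[m] += self._cum_integral[i]
        m = x >= self.x_end
        if m.any():
            out[m] = right_fn(x[m])
        return out[0] if scalar else out

    def value(self, x):
        return self._masked(
            x, "value", lambda t: self.y_end + self.end_slope * (t - self.x_end)
        )

    __call__ = value

    def derivative(self, x):
        return self._masked(
            x, "derivative", lambda t: np.full_like(t, self.end_slope)
        )

    def fast_value(self, x: np.ndarray) -> np.ndarray:
        """Dense-table linear-interpolation evaluation for inner solver loops.

        Accurate to a few 1e-9 over the curved span; the linear tail and the
        zero region are exact.  ``value`` remains the exact reference.
        """
        if self._fast_tab is None:
            xs = np.linspace(self.x_start, self.x_end, 32769)
            self._fast_tab = (xs, self.value(xs))
        xs, ys = self._fast_tab
        y = np.interp(x, xs, ys)  # clamps to 0 below and y_end above
        beyond = x > self.x_end
        if beyond.any():
            y = np.where(beyond, self.y_end + self.end_slope * (x - self.x_end), y)
        return y

    def integral(self, x):
        """Integral of the curve from the engagement point to x (in x-units)."""
        total = self._cum_integral[-1]

        def right(t):
            d = t - self.x_end
            return total + self.y_end * d + 0.5 * self.end_slope * d * d

        return self._masked(x, "integral", right)


@lru_cache(maxsize=512)
def make_fibre_curve(p: FibreCurveParams) -> SmoothSegmentedCurve:
    """Build the passive fibre force-length curve over normalised length."""
    k_one, k_low = p.k_one_f, p.k_low_f
    x_zero = 1.0 + p.eps_zero_f
    x_iso = 1.0 + p.eps_one_f
    # short run-in span where the slope rises from 0 to K_low
    delta = min(0.1 / k_one, 0.1 * (x_iso - x_zero))
    x_low = x_zero + delta
    x_foot = x_zero + 0.5 * delta
    y_low = k_low * (x_low - x_foot)
    seg1 = _BezierSegment(
        *_corner_controls(x_zero, 0.0, 0.0, x_low, y_low, k_low, p.curviness_f)
    )
    seg2 = _BezierSegment(
        *_corner_controls(x_low, y_low, k_low, x_iso, 1.0, k_one, p.curviness_f)
    )
    return SmoothSegmentedCurve([seg1, seg2])


@lru_cache(maxsize=512)
def make_tendon_curve(p: TendonCurveParams) -> SmoothSegmentedCurve:
    """Build the tendon force-length curve over normalised length."""
    k_one = p.k_one_t
    x_iso = 1.0 + p.eps_one_t
    x_toe = 1.0 + p.eps_toe_t
    toe = _BezierSegment(
        *_corner_controls(1.0, 0.0, 0.0, x_toe, p.f_toe_t, k_one, p.curviness_t)
    )
    lin = _LinearSegment(x_toe, x_iso, p.f_toe_t, k_one)
    return SmoothSegmentedCurve([toe, lin])


def fibre_passive_force(l_norm, p: FibreCurveParams):
    """Normalised passive fibre force at normalised fibre length ``l_norm``."""
    return make_fibre_curve(p).value(l_norm)


def tendon_force(l_norm, p: TendonCurveParams):
    """Normalised tendon force at normalised tendon length ``l_norm``."""
    return make_tendon_curve(p).value(l_norm)
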