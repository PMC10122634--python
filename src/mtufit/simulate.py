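"""Quasi-static passive stretch simulation.

At each ankle angle, with zero activation, the fibre and elastic tendon of
each MTU must transmit the same force along the tendon line of action:

    F_max * f_t(l_t / l_s_t)  =  F_max * f_f(l_f / l_o_f) * cos(alpha)

with the fixed-height pennation relation ``l_f * sin(alpha) = l_o_f *
sin(alpha_opt)`` and the length constraint ``l_t + l_f * cos(alpha) =
l_mt(theta)``.  Both passive curves are monotone, so the force imbalance is
monotone in fibre length and the equilibrium root is unique; it is found by
bracketed bisection, vectorised over the angle grid.

When the musculotendon length is short enough for both tissues to be slack
(zero-force band) the split is indeterminate; the convention used is tendon
at slack length and the fibre taking the remainder.

Net plantarflexor torque is the sum over MTUs of tendon force times the
muscle's plantarflexion moment arm; the simulated GASM fascicle length is the
model fibre length of GASM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import make_fibre_curve, make_tendon_curve
from .model import MTU

__all__ = [
    "EquilibriumState",
    "SimulatedCurves",
    "EquilibriumError",
    "solve_equilibrium",
    "simulate_stretch",
    "stored_energy",
]

_BISECT_ITERS = 42  # bracket < 1 m shrinks to ~2e-13 m: below the force tol
FORCE_TOL = 1e-8  # absolute force tolerance, in units of F_max


class EquilibriumError(RuntimeError):
    pass


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium of one MTU at one (or a grid of) musculotendon length(s)."""

    fibre_length: np.ndarray  # m
    tendon_length: np.ndarray  # m
    tendon_force: np.ndarray  # N
    pennation: np.ndarray  # rad
    residual: np.ndarray  # N, |force imbalance| along the tendon


def _solve_core(fib, ten, lof, lst, h, eps_zero_f, l_mt) -> np.ndarray:
    """Vectorised equilibrium fibre length; lof/lst/h broadcast over l_mt."""
    l_mt = np.asarray(l_mt, float)
    if np.any(l_mt <= 0):
        raise EquilibriumError("musculotendon length must be positive")
    lof, lst, h = (np.broadcast_to(np.asarray(a, float), l_mt.shape) for a in (lof, lst, h))
    lf = np.empty_like(l_mt)

    # zero-force band: tendon at slack, fibre takes the remainder
    engage_along = np.sqrt(np.maximum((lof * (1.0 + eps_zero_f)) ** 2 - h * h, 0.0))
    slack = l_mt <= lst + engage_along
    if slack.any():
        along = np.maximum(l_mt[slack] - lst[slack], 1e-9)
        lf[slack] = np.sqrt(along**2 + h[slack] ** 2)

    active = ~slack
    if active.any():
        lm = l_mt[active]
        lofa, lsta, ha = lof[active], lst[active], h[active]
        lo = np.maximum(ha * (1.0 + 1e-12), 0.01 * lofa)
        hi = np.sqrt(lm * lm + ha * ha) * (1.0 + 1e-12)

        def imbalance(l_fibre):
            along = np.sqrt(np.maximum(l_fibre**2 - ha * ha, 0.0))
            cos_a = np.where(l_fibre > 0, along / l_fibre, 0.0)
            f_t = ten.fast_value(np.maximum(lm - along, 0.0) / lsta)
            f_f = fib.fast_value(l_fibre / lofa)
            return f_t - f_f * cos_a  # monotone decreasing in fibre length

        if np.any(imbalance(lo) < -FORCE_TOL) or np.any(imbalance(hi) > FORCE_TOL):
            raise EquilibriumError(
                f"no bracketing root: l_mt in [{lm.min():.4f}, {lm.max():.4f}] m, "
                f"l_o_f={lofa.min():.4f}, l_s_t={lsta.min():.4f}"
            )
        for _ in range(_BISECT_ITERS):
            mid = 0.5 * (lo + hi)
            pos = imbalance(mid) > 0.0  # tendon still stronger: fibre longer
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        lf[active] = 0.5 * (lo + hi)
    return lf


def _solve_fibre_length(mtu: MTU, l_mt: np.ndarray) -> np.ndarray:
    """Equilibrium fibre length for one MTU over an array of MTU lengths."""
    try:
        return _solve_core(
            make_fibre_curve(mtu.fibre),
            make_tendon_curve(mtu.tendon),
            mtu.l_o_f,
            mtu.l_s_t,
            mtu.fibre_height,
            mtu.fibre.eps_zero_f,
            l_mt,
        )
    except EquilibriumError as err:
        raise EquilibriumError(f"{mtu.name}: {err}") from err


def solve_equilibrium(mtu: MTU, l_mt) -> EquilibriumState:
    """Solve fibre-tendon force equilibrium at musculotendon length ``l_mt``."""
    scalar = np.ndim(l_mt) == 0
    l_mt = np.atleast_1d(np.asarray(l_mt, float))
    lf = _solve_fibre_length(mtu, l_mt)
    h = mtu.fibre_height
    along = np.sqrt(np.maximum(lf * lf - h * h, 0.0))
    lt = l_mt - along
    alpha = np.arcsin(np.clip(h / lf, 0.0, 1.0))
    ten = make_tendon_curve(mtu.tendon)
    fib = make_fibre_curve(mtu.fibre)
    f_t = mtu.f_max * ten.value(lt / mtu.l_s_t)
    f_f = mtu.f_max * fib.value(lf / mtu.l_o_f) * np.cos(alpha)
    res = np.abs(f_t - f_f)
    if scalar:
        sq = lambda a: float(a[0])  # noqa: E731
        return EquilibriumState(sq(lf), sq(lt), sq(f_t), sq(alpha), sq(res))
    return EquilibriumState(lf, lt, f_t, alpha, res)


@dataclass(frozen=True)
class SimulatedCurves:
    """Simulated net plantarflexor torque and GASM fascicle length over angle."""

    angle: np.ndarray  # rad, dorsiflexion positive
    torque: np.ndarray  # Nm, internal plantarflexion moment
    gasm_fascicle_length: np.ndarray  # m

    @property
    def angle_deg(self) -> np.ndarray:
        return np.degrees(self.angle)

    @property
    def gasm_fascicle_mm(self) -> np.ndarray:
        return 1e3 * self.gasm_fascicle_length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angle_deg,
                "torque_Nm": self.torque,
                "gasm_fascicle_mm": self.gasm_fascicle_mm,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SimulatedCurves":
        df = pd.read_csv(path)
        return cls(
            angle=np.radians(df["angle_deg"].to_numpy()),
            torque=df["torque_Nm"].to_numpy(),
            gasm_fascicle_length=1e-3 * df["gasm_fascicle_mm"].to_numpy(),
        )


def simulate_stretch(
    mtus: Mapping[str, MTU],
    theta=None,
    *,
    theta_min: float | None = None,
    theta_max: float | None = None,
    step_deg: float = 0.5,
) -> SimulatedCurves:
    """Simulate the passive stretch over an angle grid (rad).

    Either pass an explicit ``theta`` sequence, or a range; the range form
    uses a uniform grid with ``step_deg`` spacing.
    """
    if theta is None:
        if theta_min is None or theta_max is None:
            raise ValueError("provide theta or (theta_min, theta_max)")
        n = int(round((theta_max - theta_min) / math.radians(step_deg))) + 1
        theta = np.linspace(theta_min, theta_max, max(n, 2))
    theta = np.atleast_1d(np.asarray(theta, float))

    # group MTUs sharing curve parameters so one bisection covers them all
    groups: dict[tuple, list[str]] = {}
    for name, mtu in mtus.items():
        groups.setdefault((mtu.fibre, mtu.tendon), []).append(name)

    n = theta.size
    torque = np.zeros_like(theta)
    gasm_lf = None
    for (fibre, tendon), names in groups.items():
        ms = [mtus[name] for name in names]
        l_mt = np.concatenate([m.path.length(theta) for m in ms])
        lof = np.repeat([m.l_o_f for m in ms], n)
        lst = np.repeat([m.l_s_t for m in ms], n)
        h = np.repeat([m.fibre_height for m in ms], n)
        lf = _solve_core(
            make_fibre_curve(fibre), make_tendon_curve(tendon),
            lof, lst, h, fibre.eps_zero_f, l_mt,
        )
        along = np.sqrt(np.maximum(lf * lf - h * h, 0.0))
        f_t = make_tendon_curve(tendon).value((l_mt - along) / lst)
        for i, (name, mtu) in enumerate(zip(names, ms)):
            sl = slice(i * n, (i + 1) * n)
            torque = torque + mtu.f_max * f_t[sl] * mtu.path.moment_arm(theta)
            if name == "GASM":
                gasm_lf = lf[sl]
    if gasm_lf is None:
        gasm_lf = np.full_like(theta, np.nan)
    return SimulatedCurves(theta, torque, np.atleast_1d(gasm_lf))


def stored_energy(mtus: Mapping[str, MTU], theta) -> np.ndarray:
    """Total elastic energy (J) stored in fibres and tendons at angle(s)."""
    theta = np.atleast_1d(np.asarray(theta, float))
    energy = np.zeros_like(theta)
    for mtu in mtus.values():
        fib = make_fibre_curve(mtu.fibre)
        ten = make_tendon_curve(mtu.tendon)
        state = solve_equilibrium(mtu, mtu.path.length(theta))
        lf = np.atleast_1d(state.fibre_length)
        lt = np.atleast_1d(state.tendon_length)
        energy += mtu.f_max * (
            mtu.l_o_f * fib.integral(lf / mtu.l_o_f)
            + mtu.l_s_t * ten.integral(lt / mtu.l_s_t)
        )
    return energy
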