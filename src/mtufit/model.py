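"""Subject-scaled musculotendon units of the plantarflexors.

Three musculotendon units (MTUs) span the modelled ankle: medial
gastrocnemius (GASM), lateral gastrocnemius (GASL) and soleus (SOL).  Each
carries a maximal isometric force, an optimal fibre length ``l_o_f``, a
tendon slack length ``l_s_t``, a pennation angle at optimum, the shared
passive curve parameters, and a muscle-path model giving musculotendon length
``l_mt(theta)`` over ankle angle.

Geometry convention: ankle angle ``theta`` is in radians, dorsiflexion
positive, 0 at the neutral ankle; the knee is fixed at 20 degrees of flexion.
The path is a polynomial in ``theta``; the plantarflexion moment arm is its
analytic derivative ``r = d l_mt / d theta`` (virtual work), positive for a
plantarflexor being stretched into dorsiflexion.  File I/O uses degrees.

Scaling: lengths (including the path polynomial) scale linearly with a chosen
segment-length ratio (tibia by default), preserving the ``l_o_f : l_s_t``
ratio; maximal isometric force scales with body mass to the power 2/3.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .curves import FibreCurveParams, TendonCurveParams
from .parameters import DEFAULT_BOUNDS, fibre_params_from, tendon_params_from

__all__ = [
    "SubjectRecord",
    "PathModel",
    "MTU",
    "MUSCLES",
    "DEFAULT_MODEL_CONFIG",
    "scale_fmax",
    "scale_lengths",
    "apply_parameter_scalings",
    "mt_length_and_moment_arm",
    "build_generic_model",
    "build_subject_model",
    "load_model_config",
]

MUSCLES = ("GASM", "GASL", "SOL")


class PathRangeError(ValueError):
    """Requested ankle angle outside the path model's validity range."""


@dataclass(frozen=True)
class SubjectRecord:
    """Anthropometry and group label of one subject."""

    id: str
    group: str  # "CP" or "TD"
    mass: float  # kg
    height_cm: float
    tibia_m: float
    foot_m: float
    leg_m: float
    knee_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"subject {self.id}: mass must be positive")
        if self.tibia_m <= 0:
            raise ValueError(f"subject {self.id}: tibia length must be positive")


@dataclass(frozen=True)
class PathModel:
    """Polynomial musculotendon length over ankle angle at fixed knee angle.

    ``coeffs`` are ascending polynomial coefficients (metres, per rad^k).
    """

    coeffs: tuple[float, ...]
    theta_min: float = math.radians(-45.0)
    theta_max: float = math.radians(40.0)
    knee_deg: float = 20.0

    def _check(self, theta) -> np.ndarray:
        th = np.asarray(theta, float)
        if np.any(th < self.theta_min - 1e-12) or np.any(th > self.theta_max + 1e-12):
            raise PathRangeError(
                f"ankle angle outside path validity "
                f"[{self.theta_min:.3f}, {self.theta_max:.3f}] rad"
            )
        return th

    def length(self, theta):
        th = self._check(theta)
        return np.polynomial.polynomial.polyval(th, np.asarray(self.coeffs))

    def moment_arm(self, theta):
        th = self._check(theta)
        c = np.asarray(self.coeffs)
        dc = c[1:] * np.arange(1, len(c))
        return np.polynomial.polynomial.polyval(th, dc)

    def scaled(self, s: float) -> "PathModel":
        return replace(self, coeffs=tuple(s * c for c in self.coeffs))


def mt_length_and_moment_arm(path: PathModel, theta):
    """Musculotendon length and moment arm (= d l_mt/d theta) at ``theta``."""
    return path.length(theta), path.moment_arm(theta)


@dataclass(frozen=True)
class MTU:
    """One scaled musculotendon unit."""

    name: str
    f_max: float  # N
    l_o_f: float  # m, optimal fibre length
    l_s_t: float  # m, tendon slack length
    alpha_opt: float  # rad, pennation at optimal fibre length
    fibre: FibreCurveParams = field(default_factory=FibreCurveParams)
    tendon: TendonCurveParams = field(default_factory=TendonCurveParams)
    path: PathModel = field(default_factory=lambda: PathModel((0.45, 0.05)))

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_o_f <= 0 or self.l_s_t <= 0:
            raise ValueError(f"{self.name}: F_max, l_o_f, l_s_t must be positive")
        if not 0.0 <= self.alpha_opt < math.pi / 2:
            raise ValueError(f"{self.name}: pennation must lie in [0, pi/2)")

    @property
    def fibre_height(self) -> float:
        """Constant fibre height of the fixed-height pennation model."""
        return self.l_o_f * math.sin(self.alpha_opt)


def scale_fmax(f_generic: float, m_subject: float, m_generic: float) -> float:
    """Scale maximal isometric force by the body-mass ratio to the 2/3 power."""
    if m_subject <= 0 or m_generic <= 0:
        raise ValueError("masses must be positive")
    if f_generic <= 0:
        raise ValueError("generic F_max must be positive")
    return f_generic * (m_subject / m_generic) ** (2.0 / 3.0)


# Generic (adult) model configuration.  Lengths are chosen so that the
# normalised defaults l_s_t/tibia = {GASM 1.00, GASL 0.95, SOL 0.70} and
# l_o_f/tibia = {0.13, 0.15, 0.11} hold, with anatomically plausible
# plantarflexor moment arms (~4-5 cm at the generic size).  The path is a
# quadratic l_mt(theta) = c0 + c1*theta + c2*theta^2 whose constant term puts
# the passive engagement of each default MTU in slight plantarflexion.
DEFAULT_MODEL_CONFIG: dict = {
    "generic_mass_kg": 75.3,
    "generic_tibia_m": 0.40,
    "generic_foot_m": 0.25,
    "generic_leg_m": 0.84,
    "length_scale_segment": "tibia",  # which segment ratio scales lengths
    "muscles": {
        "GASM": {
            "f_max_n": 1558.0,
            "l_o_f_m": 0.052,   # 0.13 * tibia
            "l_s_t_m": 0.400,   # 1.00 * tibia
            "alpha_opt_deg": 9.9,
            "path_engagement_rad": -0.20,
            "moment_arm_m": 0.050,
            "moment_arm_slope_m_per_rad": -0.008,
        },
        "GASL": {
            "f_max_n": 683.0,
            "l_o_f_m": 0.060,   # 0.15 * tibia
            "l_s_t_m": 0.380,   # 0.95 * tibia
            "alpha_opt_deg": 12.0,
            "path_engagement_rad": -0.18,
            "moment_arm_m": 0.048,
            "moment_arm_slope_m_per_rad": -0.008,
        },
        "SOL": {
            "f_max_n": 3549.0,
            "l_o_f_m": 0.044,   # 0.11 * tibia
            "l_s_t_m": 0.280,   # 0.70 * tibia
            "alpha_opt_deg": 28.3,
            "path_engagement_rad": -0.22,
            "moment_arm_m": 0.046,
            "moment_arm_slope_m_per_rad": -0.008,
        },
    },
    "path_theta_min_deg": -45.0,
    "path_theta_max_deg": 40.0,
}


def load_model_config(path: str | Path) -> dict:
    """Load a model config file, merged over the built-in generic defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = copy.deepcopy(DEFAULT_MODEL_CONFIG)
    for key, val in user.items():
        if key == "muscles":
            for m, mv in val.items():
                cfg["muscles"].setdefault(m, {}).update(mv)
        else:
            cfg[key] = val
    return cfg


def _default_path(mcfg: Mapping, cfg: Mapping, alpha_opt: float) -> PathModel:
    """Construct the generic path polynomial for one muscle.

    The constant term is set so that, with default curve parameters, the MTU
    reaches its slack threshold (tendon at slack length, fibre at engagement
    length) at the configured engagement angle.
    """
    lof, lst = mcfg["l_o_f_m"], mcfg["l_s_t_m"]
    h = lof * math.sin(alpha_opt)
    l_star = lst + math.sqrt((lof * 1.0) ** 2 - h * h)  # default eps_zero_f = 0
    th_e = mcfg["path_engagement_rad"]
    c1 = mcfg["moment_arm_m"]
    c2 = 0.5 * mcfg["moment_arm_slope_m_per_rad"]
    c0 = l_star - c1 * th_e - c2 * th_e * th_e
    return PathModel(
        coeffs=(c0, c1, c2),
        theta_min=math.radians(cfg["path_theta_min_deg"]),
        theta_max=math.radians(cfg["path_theta_max_deg"]),
    )


def build_generic_model(config: Mapping | None = None) -> dict[str, MTU]:
    """Build the generic (unscaled, default-parameter) three-MTU model."""
    cfg = config or DEFAULT_MODEL_CONFIG
    model = {}
    for name in MUSCLES:
        mcfg = cfg["muscles"][name]
        alpha = math.radians(mcfg["alpha_opt_deg"])
        model[name] = MTU(
            name=name,
            f_max=mcfg["f_max_n"],
            l_o_f=mcfg["l_o_f_m"],
            l_s_t=mcfg["l_s_t_m"],
            alpha_opt=alpha,
            path=_default_path(mcfg, cfg, alpha),
        )
    return model


def scale_lengths(
    generic_mtu: MTU, subject: SubjectRecord, config: Mapping | None = None
) -> MTU:
    """Linearly scale the MTU's lengths (and path) to the subject's segment size."""
    cfg = config or DEFAULT_MODEL_CONFIG
    segment = cfg.get("length_scale_segment", "tibia")
    generic = {
        "tibia": cfg["generic_tibia_m"],
        "foot": cfg["generic_foot_m"],
        "leg": cfg["generic_leg_m"],
    }
    subj = {"tibia": subject.tibia_m, "foot": subject.foot_m, "leg": subject.leg_m}
    if segment not in generic:
        raise KeyError(f"unknown length_scale_segment {segment!r}")
    if subj[segment] is None or subj[segment] <= 0:
        raise ValueError(f"subject {subject.id}: missing {segment} length")
    s = subj[segment] / generic[segment]
    return replace(
        generic_mtu,
        l_o_f=s * generic_mtu.l_o_f,
        l_s_t=s * generic_mtu.l_s_t,
        path=generic_mtu.path.scaled(s),
    )


def apply_parameter_scalings(
    mtus: Mapping[str, MTU], lof_scale: float, lst_scale: float
) -> dict[str, MTU]:
    """Apply the optimisable length scaling factors to all MTUs alike."""
    DEFAULT_BOUNDS.check("lof_scale", lof_scale)
    DEFAULT_BOUNDS.check("lst_scale", lst_scale)
    return {
        name: replace(m, l_o_f=lof_scale * m.l_o_f, l_s_t=lst_scale * m.l_s_t)
        for name, m in mtus.items()
    }


def build_subject_model(
    subject: SubjectRecord,
    params: Mapping[str, float] | None = None,
    config: Mapping | None = None,
) -> dict[str, MTU]:
    """Full model build: generic -> subject-scaled -> parameterised.

    ``params`` may contain any of the nine independent parameters; unlisted
    ones keep their defaults.
    """
    from .parameters import validate_params

    cfg = config or DEFAULT_MODEL_CONFIG
    p = validate_params(params)
    fibre = fibre_params_from(p)
    tendon = tendon_params_from(p)
    model = {}
    for name, generic in build_generic_model(cfg).items():
        scaled = scale_lengths(generic, subject, cfg)
        scaled = replace(
            scaled,
            f_max=scale_fmax(generic.f_max, subject.mass, cfg["generic_mass_kg"]),
            fibre=fibre,
            tendon=tendon,
        )
        model[name] = scaled
    return apply_parameter_scalings(model, p["lof_scale"], p["lst_scale"])
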