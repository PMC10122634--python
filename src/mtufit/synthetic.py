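"""Synthetic cohorts and raw stretch recordings with known ground truth.

The generator emulates the instrumented slow-stretch experiment: subjects lie
prone with the knee at 20 degrees flexion while the ankle is rotated from
plantarflexion to maximal dorsiflexion at about 15 +/- 5 deg/s, three
stretches per subject.  Channels are emitted at their native rates — ankle
angle 120 Hz, torque 200 Hz, GASM fascicle length 60 Hz, sEMG envelopes
1600 Hz — with additive i.i.d. Gaussian noise at the standard error of
measurement of the instruments (0.72 Nm torque, 2.0 mm fascicle length).

Anthropometry is drawn from truncated normals with the published group means
and SDs; true musculotendon parameters are drawn per group around the
published group medians with IQR-scaled dispersion (normal SD = IQR/1.349),
clipped to the optimisation bounds.  The ground truth (true parameters and
noise-free simulated curves) is kept separate from the generated
"measurements" so every pipeline stage can be checked against it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model import SubjectRecord, build_subject_model
from .parameters import DEFAULT_BOUNDS, DEFAULT_PARAMS, validate_params
from .preprocess import StretchTrial
from .simulate import SimulatedCurves, simulate_stretch

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "GROUP_ANTHROPOMETRY",
    "GROUP_PARAMETER_MEDIANS",
    "GROUP_PARAMETER_IQRS",
    "GROUP_NORMALISED_LENGTHS",
    "cohort_spec",
    "sample_cohort",
    "generate_trials",
    "write_trial",
    "write_cohort",
]

# Published participant characteristics: mean, SD per group.
GROUP_ANTHROPOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "CP": {"mass_kg": (37.5, 19.0), "height_cm": (143.7, 21.4), "tibia_cm": (34.2, 0.6)},
    "TD": {"mass_kg": (39.2, 14.4), "height_cm": (143.7, 17.6), "tibia_cm": (33.0, 0.5)},
}

# Published group-median personalised parameters (the four selected ones; the
# remaining independent parameters stayed at their defaults).
GROUP_PARAMETER_MEDIANS: dict[str, dict[str, float]] = {
    "CP": {"lst_scale": 1.03, "lof_scale": 0.81, "eps_one_t": 0.23, "eps_zero_f": 0.089},
    "TD": {"lst_scale": 1.00, "lof_scale": 1.15, "eps_one_t": 0.16, "eps_zero_f": -0.055},
}

GROUP_PARAMETER_IQRS: dict[str, dict[str, float]] = {
    "CP": {"lst_scale": 0.03, "lof_scale": 0.27, "eps_one_t": 0.14, "eps_zero_f": 0.30},
    "TD": {"lst_scale": 0.03, "lof_scale": 0.23, "eps_one_t": 0.14, "eps_zero_f": 0.25},
}

# Published per-muscle tibia-normalised length medians (GASM, GASL, SOL).
GROUP_NORMALISED_LENGTHS: dict[str, dict[str, tuple[float, float, float]]] = {
    "CP": {"l_s_t": (1.04, 0.98, 0.72), "l_o_f": (0.10, 0.12, 0.09)},
    "TD": {"l_s_t": (1.00, 0.95, 0.70), "l_o_f": (0.15, 0.17, 0.13)},
    "default": {"l_s_t": (1.00, 0.95, 0.70), "l_o_f": (0.13, 0.15, 0.11)},
}

_IQR_TO_SD = 1.0 / 1.349  # normal-distribution IQR -> SD


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic group."""

    group: str
    n: int = 13
    anthropometry: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    param_medians: Mapping[str, float] = field(default_factory=dict)
    param_iqrs: Mapping[str, float] = field(default_factory=dict)
    torque_noise_nm: float = 0.72
    fascicle_noise_mm: float = 2.0
    angle_noise_deg: float = 0.1
    emg_baseline_mvc: float = 0.02
    velocity_mean_deg_s: float = 15.0
    velocity_sd_deg_s: float = 5.0
    n_stretches: int = 3
    start_angle_deg: float = -30.0
    # the examiner stretches until the resisting torque tops out: per-subject
    # end-range torque is drawn from this interval, and the resulting maximal
    # dorsiflexion is clipped to the limits below
    end_torque_range_nm: tuple[float, float] = (10.0, 25.0)
    max_dorsiflexion_limits_deg: tuple[float, float] = (5.0, 30.0)
    # a measurable subject develops at least this much resistance within the
    # reachable range; parameter draws that never load are redrawn (the study
    # population is implicitly conditioned on being measurable)
    min_end_torque_nm: float = 2.0
    contaminate_one_trial: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.velocity_mean_deg_s <= 0:
            raise ValueError("stretch velocity must be positive")
        for label, (mu, sd) in self.anthropometry.items():
            if sd < 0:
                raise ValueError(f"negative SD for {label}")


def cohort_spec(group: str, n: int = 13, **overrides) -> CohortSpec:
    """CohortSpec with the published defaults for group ``CP`` or ``TD``."""
    if group not in GROUP_ANTHROPOMETRY:
        raise ValueError(f"unknown group {group!r}; expected CP or TD")
    base = dict(
        group=group,
        n=n,
        anthropometry=dict(GROUP_ANTHROPOMETRY[group]),
        param_medians=dict(GROUP_PARAMETER_MEDIANS[group]),
        param_iqrs=dict(GROUP_PARAMETER_IQRS[group]),
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass(frozen=True)
class SyntheticSubject:
    """A sampled subject together with its ground truth."""

    record: SubjectRecord
    true_params: dict[str, float]
    truth: SimulatedCurves  # noise-free curves of the true model
    max_dorsiflexion_deg: float


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lo: float) -> float:
    """Normal draw with a positivity-style lower truncation (redraw)."""
    if sd == 0.0:
        return mu
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if x > lo:
            return float(x)
    raise RuntimeError("infeasible anthropometry specification")


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> dict[str, float]:
    params = dict(DEFAULT_PARAMS)
    for name, med in spec.param_medians.items():
        sd = spec.param_iqrs.get(name, 0.0) * _IQR_TO_SD
        lo, hi = DEFAULT_BOUNDS.lower(name), DEFAULT_BOUNDS.upper(name)
        if lo >= hi:
            raise ValueError(f"bounds collapse for {name}")
        params[name] = float(np.clip(rng.normal(med, sd) if sd else med, lo, hi))
    # keep the fibre curve admissible: engagement strictly below one-norm strain
    if params["eps_zero_f"] >= params["eps_one_f"]:
        params["eps_zero_f"] = params["eps_one_f"] - 0.05
    return validate_params(params)


def sample_cohort(
    spec: CohortSpec, seed: int | np.random.Generator, config: Mapping | None = None
) -> list[SyntheticSubject]:
    """Draw a reproducible cohort with ground-truth models and curves."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(spec.n):
        mass = _truncated_normal(rng, *spec.anthropometry["mass_kg"], lo=10.0)
        height = _truncated_normal(rng, *spec.anthropometry["height_cm"], lo=80.0)
        tibia_m = _truncated_normal(rng, *spec.anthropometry["tibia_cm"], lo=15.0) / 100.0
        record = SubjectRecord(
            id=f"{spec.group}{i + 1:02d}",
            group=spec.group,
            mass=mass,
            height_cm=height,
            tibia_m=tibia_m,
            foot_m=0.625 * tibia_m,
            leg_m=2.1 * tibia_m,
        )
        lo_df, hi_df = spec.max_dorsiflexion_limits_deg
        for _ in range(100):
            params = _draw_params(spec, rng)
            model = build_subject_model(record, params, config)
            probe = simulate_stretch(
                model,
                theta_min=math.radians(spec.start_angle_deg),
                theta_max=math.radians(hi_df),
                step_deg=0.25,
            )
            if probe.torque[-1] >= spec.min_end_torque_nm:
                break
        else:
            raise RuntimeError(
                f"{record.id}: no measurable parameter draw in 100 attempts"
            )
        # end of range of motion: where the manually applied torque tops out
        end_torque = float(rng.uniform(*spec.end_torque_range_nm))
        reached = np.nonzero(probe.torque >= end_torque)[0]
        max_df = float(
            np.clip(probe.angle_deg[reached[0]] if reached.size else hi_df, lo_df, hi_df)
        )
        truth = simulate_stretch(
            model,
            theta_min=math.radians(spec.start_angle_deg),
            theta_max=math.radians(max_df),
        )
        out.append(SyntheticSubject(record, params, truth, max_df))
    return out


def _angle_trajectory(
    start_deg: float, end_deg: float, peak_vel_deg_s: float, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth cosine ramp with short holds; peak velocity as specified."""
    sweep = end_deg - start_deg
    ramp_t = sweep * math.pi / (2.0 * peak_vel_deg_s)
    hold = 0.3
    t = np.arange(0.0, ramp_t + 2 * hold, 1.0 / rate)
    tau = np.clip((t - hold) / ramp_t, 0.0, 1.0)
    angle = start_deg + sweep * 0.5 * (1.0 - np.cos(math.pi * tau))
    return t, angle


def generate_trials(
    subject: SyntheticSubject,
    spec: CohortSpec,
    rng: np.random.Generator,
    noise_free: bool = False,
) -> list[StretchTrial]:
    """Emit multi-rate stretch recordings for one subject.

    With ``spec.contaminate_one_trial`` the first stretch carries an EMG
    envelope above 10% MVC, exercising the passive-trial gate downstream.
    """
    truth = subject.truth
    if np.degrees(truth.angle[-1]) < subject.max_dorsiflexion_deg - 1e-6:
        raise ValueError("truth curves do not cover the requested dorsiflexion range")
    torque_of = lambda a: np.interp(a, truth.angle_deg, truth.torque)  # noqa: E731
    fascicle_of = lambda a: np.interp(a, truth.angle_deg, truth.gasm_fascicle_mm)  # noqa: E731

    mvc = {"GASL": 1.0, "SOL": 1.0, "TA": 1.0}
    trials = []
    for k in range(spec.n_stretches):
        vel = max(float(rng.normal(spec.velocity_mean_deg_s, spec.velocity_sd_deg_s)), 5.0)
        t_a, ang = _angle_trajectory(
            spec.start_angle_deg, subject.max_dorsiflexion_deg, vel, 120.0
        )
        duration = t_a[-1]
        t_t = np.arange(0.0, duration, 1.0 / 200.0)
        t_f = np.arange(0.0, duration, 1.0 / 60.0)
        t_e = np.arange(0.0, duration, 1.0 / 1600.0)
        ang_t = np.interp(t_t, t_a, ang)
        ang_f = np.interp(t_f, t_a, ang)
        s_ang = 0.0 if noise_free else spec.angle_noise_deg
        s_trq = 0.0 if noise_free else spec.torque_noise_nm
        s_fas = 0.0 if noise_free else spec.fascicle_noise_mm
        contaminated = spec.contaminate_one_trial and k == 0
        emg = {}
        for muscle in mvc:
            level = 0.20 if (contaminated and muscle == "GASL") else spec.emg_baseline_mvc
            emg[muscle] = (t_e, np.abs(rng.normal(level, 0.2 * level, t_e.shape)))
        trials.append(
            StretchTrial(
                angle_time=t_a,
                angle_deg=ang + rng.normal(0.0, s_ang, ang.shape) if s_ang else ang,
                torque_time=t_t,
                torque_Nm=torque_of(ang_t) + rng.normal(0.0, s_trq, t_t.shape)
                if s_trq
                else torque_of(ang_t),
                fascicle_time=t_f,
                fascicle_mm=fascicle_of(ang_f) + rng.normal(0.0, s_fas, t_f.shape)
                if s_fas
                else fascicle_of(ang_f),
                emg=emg,
                mvc=dict(mvc),
                name=f"{subject.record.id}_stretch{k + 1}",
            )
        )
    return trials


def processed_from_truth(subject: SyntheticSubject) -> "ProcessedCurves":
    """Noise-free ProcessedCurves from a subject's ground-truth simulation.

    Applies the same cropping rule as the measurement pipeline (from where the
    plantarflexion moment becomes and stays positive, to maximal dorsiflexion)
    but bypasses resampling and filtering, for clean recovery studies.
    """
    from .preprocess import ProcessedCurves

    sim = subject.truth
    nonpos = np.nonzero(sim.torque <= 0.0)[0]
    start = int(nonpos[-1]) + 1 if nonpos.size else 0
    if start >= sim.torque.size - 1:
        raise ValueError(f"{subject.record.id}: no loaded range in truth curves")
    return ProcessedCurves(
        angle_deg=sim.angle_deg[start:],
        torque=sim.torque[start:],
        fascicle_mm=sim.gasm_fascicle_mm[start:],
        n_stretches=0,
        crop_deg=(float(sim.angle_deg[start]), float(sim.angle_deg[-1])),
    )


# --- file emission --------------------------------------------------------------


def write_trial(trial: StretchTrial, path: str | Path) -> None:
    """Write a trial as a wide CSV on the union timeline (NaN where unsampled)."""
    frames = [
        pd.DataFrame({"time_s": trial.angle_time, "angle_deg": trial.angle_deg}),
        pd.DataFrame({"time_s": trial.torque_time, "torque_Nm": trial.torque_Nm}),
        pd.DataFrame({"time_s": trial.fascicle_time, "fascicle_mm": trial.fascicle_mm}),
    ]
    for muscle, (t, env) in trial.emg.items():
        frames.append(pd.DataFrame({"time_s": t, f"emg_{muscle}": env}))
    wide = frames[0]
    for f in frames[1:]:
        wide = wide.merge(f, on="time_s", how="outer")
    wide.sort_values("time_s").to_csv(path, index=False, float_format="%.8g")


def write_cohort(
    spec: CohortSpec,
    seed: int,
    out_dir: str | Path,
    noise_free: bool = False,
    config: Mapping | None = None,
) -> list[Path]:
    """Sample a cohort, emit trial files + per-subject manifests + ground truth.

    Returns the list of manifest paths (one per subject).  Ground truth goes to
    ``<out_dir>/truth/`` so it cannot be confused with the measurements.
    """
    out_dir = Path(out_dir)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort = sample_cohort(spec, rng, config)
    manifests = []
    for subj in cohort:
        rec = subj.record
        trials = generate_trials(subj, spec, rng, noise_free=noise_free)
        rels = []
        for trial in trials:
            rel = f"{trial.name}.csv"
            write_trial(trial, out_dir / rel)
            rels.append(rel)
        manifest = {
            "subject": dataclasses.asdict(rec),
            "mvc": {k: float(v) for k, v in trials[0].mvc.items()},
            "trials": rels,
        }
        mpath = out_dir / f"{rec.id}_manifest.yaml"
        with open(mpath, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        truth = {
            "true_params": subj.true_params,
            "max_dorsiflexion_deg": subj.max_dorsiflexion_deg,
        }
        with open(out_dir / "truth" / f"{rec.id}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
        subj.truth.write(out_dir / "truth" / f"{rec.id}_curves.csv")
        manifests.append(mpath)
    return manifests
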