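"""Bounded least-squares personalisation of musculotendon parameters.

The fit minimises the sum of squared residuals of the concatenated vector
[torque residuals in Nm; fascicle residuals in mm] over the measured angle
grid — expressing fascicle length in millimetres puts both channels on the
same order of magnitude and thus weights them roughly equally.  Free
parameters are any subset of the nine independent ones; they start at their
defaults and are constrained to the Table-of-bounds intervals.

Reported RMSEs are normalised for between-subject comparison: torque by body
mass (Nm/kg) and fascicle length by tibia length (dimensionless).

The stepwise selection is a greedy forward search: at each round every
not-yet-selected candidate is fitted jointly with the already selected set
for every subject, candidates are scored by the sum of the two
default-normalised median RMSEs, and the best is kept.  Selection stops once
both median RMSEs fall below 10% of their default-parameter medians (or when
no candidate improves the score).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import kstest, mannwhitneyu, wilcoxon

from .model import SubjectRecord, build_subject_model
from .parameters import DEFAULT_BOUNDS, DEFAULT_PARAMS, PARAMETER_NAMES, ParameterBounds
from .preprocess import ProcessedCurves
from .simulate import simulate_stretch

__all__ = [
    "FitSpec",
    "FitResult",
    "GroupModel",
    "StepwiseResult",
    "rmse",
    "simulate_subject_curves",
    "fit_parameters",
    "default_fit",
    "stepwise_selection",
    "group_median_model",
    "evaluate_group_model",
    "group_statistics",
    "compare_rmse_groups",
]


def rmse(sim, meas, normaliser: float = 1.0) -> float:
    """Root-mean-square difference of two curves on a common grid."""
    sim = np.asarray(sim, float)
    meas = np.asarray(meas, float)
    if sim.shape != meas.shape:
        raise ValueError(f"curve grids differ: {sim.shape} vs {meas.shape}")
    return float(np.sqrt(np.mean((sim - meas) ** 2)) / normaliser)


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are free, their bounds, and solver settings."""

    free: tuple[str, ...]
    bounds: ParameterBounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        bad = [p for p in self.free if p not in PARAMETER_NAMES]
        if bad:
            raise ValueError(
                f"not optimisable: {bad}; eligible parameters are {PARAMETER_NAMES}"
            )
        if len(set(self.free)) != len(self.free):
            raise ValueError("duplicate parameter in free set")


@dataclass(frozen=True)
class FitResult:
    subject_id: str
    group: str
    params: dict[str, float]  # full nine-parameter map
    free: tuple[str, ...]
    rmse_torque_norm: float  # Nm/kg
    rmse_fascicle_norm: float  # fraction of tibia length
    rmse_torque_nm: float
    rmse_fascicle_mm: float
    cost: float
    nfev: int
    converged: bool
    message: str = ""


def simulate_subject_curves(
    subject: SubjectRecord,
    params: Mapping[str, float] | None,
    angle_deg: np.ndarray,
    config: Mapping | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (torque Nm, GASM fascicle mm) on a measured angle grid."""
    model = build_subject_model(subject, params, config)
    sim = simulate_stretch(model, np.radians(np.asarray(angle_deg, float)))
    return sim.torque, sim.gasm_fascicle_mm


def _result_from(
    subject: SubjectRecord,
    curves: ProcessedCurves,
    params: Mapping[str, float],
    free: tuple[str, ...],
    config,
    cost: float,
    nfev: int,
    converged: bool,
    message: str = "",
) -> FitResult:
    torque, fasc = simulate_subject_curves(subject, params, curves.angle_deg, config)
    r_t = rmse(torque, curves.torque)
    r_f = rmse(fasc, curves.fascicle_mm)
    return FitResult(
        subject_id=subject.id,
        group=subject.group,
        params=dict(params),
        free=tuple(free),
        rmse_torque_norm=r_t / subject.mass,
        rmse_fascicle_norm=r_f / (subject.tibia_m * 1e3),
        rmse_torque_nm=r_t,
        rmse_fascicle_mm=r_f,
        cost=cost,
        nfev=nfev,
        converged=converged,
        message=message,
    )


def default_fit(
    subject: SubjectRecord, curves: ProcessedCurves, config: Mapping | None = None
) -> FitResult:
    """RMSEs of the default-parameter model (no optimisation)."""
    t, f = simulate_subject_curves(subject, None, curves.angle_deg, config)
    cost = 0.5 * float(
        np.sum((t - curves.torque) ** 2) + np.sum((f - curves.fascicle_mm) ** 2)
    )
    return _result_from(
        subject, curves, dict(DEFAULT_PARAMS), (), config, cost, 0, True, "defaults"
    )


def fit_parameters(
    curves: ProcessedCurves,
    subject: SubjectRecord,
    spec: FitSpec,
    config: Mapping | None = None,
) -> FitResult:
    """Bounded least-squares fit of the free parameters to one subject."""
    if not spec.free:
        return default_fit(subject, curves, config)
    x0, lo, hi = spec.bounds.arrays(spec.free)
    meas_t = np.asarray(curves.torque, float)
    meas_f = np.asarray(curves.fascicle_mm, float)
    angle = np.asarray(curves.angle_deg, float)

    def residuals(x):
        params = dict(DEFAULT_PARAMS)
        params.update(zip(spec.free, x))
        sim_t, sim_f = simulate_subject_curves(subject, params, angle, config)
        return np.concatenate([sim_t - meas_t, sim_f - meas_f])

    res = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=spec.ftol,
        xtol=spec.xtol,
        gtol=spec.gtol,
        max_nfev=spec.max_nfev,
    )
    if not res.success:
        warnings.warn(
            f"fit for subject {subject.id} did not converge: {res.message}",
            stacklevel=2,
        )
    params = dict(DEFAULT_PARAMS)
    params.update(zip(spec.free, np.clip(res.x, lo, hi)))
    return _result_from(
        subject, curves, params, spec.free, config,
        float(res.cost), int(res.nfev), bool(res.success), str(res.message),
    )


# --- stepwise selection --------------------------------------------------------


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    fits: tuple[FitResult, ...]  # final per-subject fits with the selected set
    default_medians: tuple[float, float]  # (torque Nm/kg, fascicle /tibia)
    median_trajectory: tuple[tuple[float, float], ...]  # after each round
    candidate_scores: tuple[dict[str, float], ...]  # per round
    stopped_by_rule: bool


def _medians(fits: Sequence[FitResult]) -> tuple[float, float]:
    return (
        float(np.median([f.rmse_torque_norm for f in fits])),
        float(np.median([f.rmse_fascicle_norm for f in fits])),
    )


def stepwise_selection(
    cohort: Sequence[tuple[SubjectRecord, ProcessedCurves]],
    candidates: Sequence[str] = PARAMETER_NAMES,
    stop_fraction: float = 0.10,
    config: Mapping | None = None,
    abs_floor: tuple[float, float] = (1e-6, 1e-7),
    max_rounds: int | None = None,
) -> StepwiseResult:
    """Greedy forward selection of the parameters that reduce median RMSEs most.

    ``abs_floor`` (Nm/kg, /tibia) handles the degenerate case of a cohort whose
    default-parameter fit is already essentially exact, where a relative
    stopping rule could never trigger.
    """
    if len(cohort) < 2:
        raise ValueError("stepwise selection needs at least two subjects")
    default_fits = [default_fit(s, c, config) for s, c in cohort]
    med0 = _medians(default_fits)
    targets = (
        max(stop_fraction * med0[0], abs_floor[0]),
        max(stop_fraction * med0[1], abs_floor[1]),
    )
    selected: list[str] = []
    current_fits = default_fits
    trajectory: list[tuple[float, float]] = []
    all_scores: list[dict[str, float]] = []
    stopped = med0[0] <= targets[0] and med0[1] <= targets[1]
    current_score = 2.0  # med/med0 sums to 2 with no parameter fitted

    remaining = [p for p in PARAMETER_NAMES if p in set(candidates)]
    n_rounds = max_rounds if max_rounds is not None else len(remaining)
    while remaining and not stopped and len(selected) < n_rounds:
        scores: dict[str, float] = {}
        fits_by_cand: dict[str, list[FitResult]] = {}
        for cand in remaining:  # table order; ties resolved by strict '<'
            spec = FitSpec(free=tuple(selected + [cand]))
            fits = [fit_parameters(c, s, spec, config) for s, c in cohort]
            med = _medians(fits)
            scores[cand] = (med[0] / med0[0] if med0[0] > 0 else 0.0) + (
                med[1] / med0[1] if med0[1] > 0 else 0.0
            )
            fits_by_cand[cand] = fits
        all_scores.append(scores)
        best = min(scores, key=lambda k: (scores[k], PARAMETER_NAMES.index(k)))
        if scores[best] >= current_score - 1e-12:
            warnings.warn("stepwise selection: no candidate improves the score")
            break
        selected.append(best)
        remaining.remove(best)
        current_fits = fits_by_cand[best]
        current_score = scores[best]
        med = _medians(current_fits)
        trajectory.append(med)
        stopped = med[0] <= targets[0] and med[1] <= targets[1]

    return StepwiseResult(
        selected=tuple(selected),
        fits=tuple(current_fits),
        default_medians=med0,
        median_trajectory=tuple(trajectory),
        candidate_scores=tuple(all_scores),
        stopped_by_rule=stopped,
    )


# --- group models and statistics ----------------------------------------------


@dataclass(frozen=True)
class GroupModel:
    """Per-parameter median and IQR over a group's personalised fits."""

    group: str
    median: dict[str, float]
    iqr: dict[str, float]
    n: int


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    # linear interpolation between order statistics (numpy default)
    q25, q50, q75 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return float(q50), float(q75 - q25)


def group_median_model(fits: Sequence[FitResult]) -> GroupModel:
    if not fits:
        raise ValueError("empty group")
    groups = {f.group for f in fits}
    label = groups.pop() if len(groups) == 1 else "mixed"
    median, iqr = {}, {}
    for name in PARAMETER_NAMES:
        vals = np.array([f.params[name] for f in fits])
        median[name], iqr[name] = _median_iqr(vals)
    return GroupModel(group=label, median=median, iqr=iqr, n=len(fits))


def evaluate_group_model(
    gm: GroupModel,
    cohort: Sequence[tuple[SubjectRecord, ProcessedCurves]],
    config: Mapping | None = None,
) -> list[FitResult]:
    """Re-simulate every subject with the group-median parameters."""
    out = []
    for subject, curves in cohort:
        out.append(
            _result_from(
                subject, curves, dict(gm.median), (), config, math.nan, 0, True,
                f"group medians ({gm.group})",
            )
        )
    return out


def _safe_wilcoxon(diff: np.ndarray) -> tuple[float, float, bool]:
    """One-sample Wilcoxon signed-rank; degenerate all-zero flagged."""
    if np.allclose(diff, 0.0):
        return math.nan, 1.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = wilcoxon(diff, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p), False


def group_statistics(
    cp_fits: Sequence[FitResult],
    td_fits: Sequence[FitResult],
    defaults: Mapping[str, float] | None = None,
    parameters: Sequence[str] = PARAMETER_NAMES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter tests: Wilcoxon vs default, Mann-Whitney CP vs TD,
    Kolmogorov-Smirnov normality; two-sided, alpha = 0.05."""
    defaults = dict(defaults or DEFAULT_PARAMS)
    rows = []
    for name in parameters:
        cp = np.array([f.params[name] for f in cp_fits])
        td = np.array([f.params[name] for f in td_fits])
        row: dict = {"parameter": name, "default": defaults[name]}
        for label, vals in (("cp", cp), ("td", td)):
            med, iqr = _median_iqr(vals)
            row[f"{label}_median"], row[f"{label}_iqr"] = med, iqr
            if len(vals) < 2:
                row[f"wilcoxon_p_{label}"] = math.nan
                row[f"{label}_note"] = "n<2: test skipped"
                continue
            stat, p, degenerate = _safe_wilcoxon(vals - defaults[name])
            row[f"wilcoxon_p_{label}"] = p
            row[f"wilcoxon_degenerate_{label}"] = degenerate
            sd = vals.std(ddof=1)
            if sd > 0:
                row[f"ks_normality_p_{label}"] = float(
                    kstest((vals - vals.mean()) / sd, "norm").pvalue
                )
            else:
                row[f"ks_normality_p_{label}"] = math.nan
        if len(cp) >= 2 and len(td) >= 2:
            row["mannwhitney_p"] = float(
                mannwhitneyu(cp, td, alternative="two-sided").pvalue
            )
            row["significant_cp_vs_td"] = row["mannwhitney_p"] < alpha
        else:
            row["mannwhitney_p"] = math.nan
        row["significant_cp_vs_default"] = (
            row.get("wilcoxon_p_cp", math.nan) < alpha
            if not row.get("wilcoxon_degenerate_cp", False)
            else False
        )
        row["significant_td_vs_default"] = (
            row.get("wilcoxon_p_td", math.nan) < alpha
            if not row.get("wilcoxon_degenerate_td", False)
            else False
        )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_rmse_groups(rmses_a: Sequence[float], rmses_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value between two RMSE samples."""
    if len(rmses_a) < 2 or len(rmses_b) < 2:
        warnings.warn("n < 2: RMSE comparison skipped")
        return math.nan
    return float(
        mannwhitneyu(np.asarray(rmses_a), np.asarray(rmses_b), alternative="two-sided").pvalue
    )
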