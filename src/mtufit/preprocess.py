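"""From raw multi-rate stretch recordings to averaged torque/fascicle curves.

A stretch trial carries channels sampled at their native rates: ankle angle
from motion capture (120 Hz), net ankle torque from a load-cell (200 Hz,
either precomputed or as raw force/moment components), GASM fascicle length
from ultrasound (60 Hz) and optional sEMG envelopes (1600 Hz) normalised to
maximal voluntary contraction (MVC).

Processing steps:

1. net ankle moment from the load-cell channels (quasi-static moment balance,
   inertia neglected):  M_joint = Fx*dy + Fy*dx + M_handle + M_orthosis
2. EMG gate: a trial is discarded when the RMS of any EMG envelope exceeds
   10% of MVC (the stretch was not passive);
3. all channels linearly interpolated to the 120 Hz angle timeline; angle and
   torque filtered with a zero-phase 2nd-order 6 Hz Butterworth;
4. each stretch time-normalised to 101 samples, channel-wise mean over the
   (>= 1) accepted stretches;
5. curves expressed against ankle angle on a uniform 0.5 degree grid and
   cropped from the point where the internal plantarflexion moment becomes
   (and stays) positive up to maximal dorsiflexion.

Sign convention: dorsiflexion angle positive, internal plantarflexion
(resisting) moment positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt

__all__ = [
    "LoadCellRecord",
    "StretchTrial",
    "ProcessedCurves",
    "GateResult",
    "SubjectExcludedError",
    "net_ankle_moment",
    "lowpass",
    "emg_gate",
    "average_and_crop",
    "process_subject",
    "read_trial",
    "read_manifest",
]

LOAD_CELL_COLUMNS = ("fx_N", "fy_N", "mz_handle_Nm", "mz_orthosis_Nm", "dx_m", "dy_m")


class SubjectExcludedError(RuntimeError):
    """No stretch of a subject passed the EMG gate."""


@dataclass(frozen=True)
class LoadCellRecord:
    """Time-aligned load-cell channels around the malleolus-aligned axis."""

    f_x: np.ndarray  # N
    f_y: np.ndarray  # N
    m_z_handle: np.ndarray  # Nm
    m_z_orthosis: np.ndarray  # Nm
    d_x: np.ndarray  # m
    d_y: np.ndarray  # m


def net_ankle_moment(rec: LoadCellRecord) -> np.ndarray:
    """Net (internal plantarflexion) ankle joint moment, inertia neglected.

    With the total moment zero in quasi-static stretching, the joint moment
    equals the sum of the applied moments.
    """
    for name in ("f_x", "f_y", "m_z_handle", "m_z_orthosis", "d_x", "d_y"):
        if getattr(rec, name) is None:
            raise ValueError(f"load-cell channel {name!r} is missing")
    return (
        np.asarray(rec.f_x) * np.asarray(rec.d_y)
        + np.asarray(rec.f_y) * np.asarray(rec.d_x)
        + np.asarray(rec.m_z_handle)
        + np.asarray(rec.m_z_orthosis)
    )


@dataclass
class StretchTrial:
    """One raw stretch recording with per-channel timelines."""

    angle_time: np.ndarray  # s, 120 Hz
    angle_deg: np.ndarray
    torque_time: np.ndarray  # s, 200 Hz
    torque_Nm: np.ndarray
    fascicle_time: np.ndarray  # s, 60 Hz
    fascicle_mm: np.ndarray
    emg: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    mvc: dict[str, float] = field(default_factory=dict)
    name: str = ""

    @property
    def angle_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.angle_time)))

    @property
    def torque_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.torque_time)))


@dataclass(frozen=True)
class GateResult:
    keep: bool
    rms: dict[str, float]
    checked: bool  # False when no EMG channels were present


@dataclass(frozen=True)
class ProcessedCurves:
    """Averaged, cropped torque-angle and fascicle-length-angle curves."""

    angle_deg: np.ndarray  # strictly increasing uniform grid
    torque: np.ndarray  # Nm
    fascicle_mm: np.ndarray
    n_stretches: int
    crop_deg: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angle_deg,
                "torque_Nm": self.torque,
                "fascicle_mm": self.fascicle_mm,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path, n_stretches: int = 0) -> "ProcessedCurves":
        df = pd.read_csv(path)
        ang = df["angle_deg"].to_numpy()
        return cls(
            angle_deg=ang,
            torque=df["torque_Nm"].to_numpy(),
            fascicle_mm=df["fascicle_mm"].to_numpy(),
            n_stretches=n_stretches,
            crop_deg=(float(ang[0]), float(ang[-1])),
        )


def lowpass(series, rate: float, cutoff: float = 6.0, order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if rate <= 2.0 * cutoff:
        raise ValueError(
            f"sampling rate {rate} Hz must exceed twice the cutoff ({cutoff} Hz)"
        )
    b, a = butter(order, cutoff, btype="low", fs=rate)
    return filtfilt(b, a, np.asarray(series, float))


def emg_gate(trial: StretchTrial, threshold: float = 0.10) -> GateResult:
    """Keep a trial only if all EMG envelope RMS values stay below
    ``threshold`` of the muscle's MVC."""
    if not trial.emg:
        warnings.warn(
            f"trial {trial.name or '?'}: no EMG channels, gate passed through",
            stacklevel=2,
        )
        return GateResult(keep=True, rms={}, checked=False)
    rms: dict[str, float] = {}
    keep = True
    for muscle, (_, env) in trial.emg.items():
        mvc = trial.mvc.get(muscle)
        if mvc is None or mvc <= 0:
            raise ValueError(f"trial {trial.name or '?'}: missing MVC for {muscle!r}")
        r = float(np.sqrt(np.mean(np.square(np.asarray(env, float))))) / mvc
        rms[muscle] = r
        if r > threshold:
            keep = False
    return GateResult(keep=keep, rms=rms, checked=True)


def _align_and_filter(trial: StretchTrial, cutoff: float = 6.0) -> pd.DataFrame:
    """Interpolate all channels to the angle (120 Hz) timeline and filter."""
    t = np.asarray(trial.angle_time, float)
    angle = lowpass(trial.angle_deg, trial.angle_rate, cutoff)
    torque = np.interp(t, trial.torque_time, trial.torque_Nm)
    torque = lowpass(torque, trial.angle_rate, cutoff)
    fascicle = np.interp(t, trial.fascicle_time, trial.fascicle_mm)
    return pd.DataFrame(
        {"time_s": t, "angle_deg": angle, "torque_Nm": torque, "fascicle_mm": fascicle}
    )


def _time_normalise(df: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    t = df["time_s"].to_numpy()
    u = (t - t[0]) / (t[-1] - t[0])
    ug = np.linspace(0.0, 1.0, n_samples)
    return pd.DataFrame(
        {c: np.interp(ug, u, df[c].to_numpy()) for c in df.columns if c != "time_s"}
    )


def average_and_crop(
    trials: Sequence[StretchTrial],
    n_samples: int = 101,
    grid_step_deg: float = 0.5,
    cutoff: float = 6.0,
) -> ProcessedCurves:
    """Average (>= 1) accepted stretches and crop to the loaded range."""
    if len(trials) == 0:
        raise SubjectExcludedError("no accepted stretches to average")
    resampled = [_time_normalise(_align_and_filter(tr, cutoff), n_samples) for tr in trials]
    angle = np.mean([r["angle_deg"].to_numpy() for r in resampled], axis=0)
    torque = np.mean([r["torque_Nm"].to_numpy() for r in resampled], axis=0)
    fascicle = np.mean([r["fascicle_mm"].to_numpy() for r in resampled], axis=0)

    # express against angle on a uniform grid (angle ramps are monotone up to
    # noise; sort to get a valid interpolation table)
    order = np.argsort(angle, kind="stable")
    a_sorted = angle[order]
    grid = np.arange(
        np.ceil(a_sorted[0] / grid_step_deg),
        np.floor(a_sorted[-1] / grid_step_deg) + 1,
    ) * grid_step_deg
    torque_g = np.interp(grid, a_sorted, torque[order])
    fascicle_g = np.interp(grid, a_sorted, fascicle[order])

    # crop: from where the internal plantarflexion moment becomes and stays
    # positive, up to maximal dorsiflexion (the end of the grid)
    nonpos = np.nonzero(torque_g <= 0.0)[0]
    start = int(nonpos[-1]) + 1 if nonpos.size else 0
    if start >= grid.size - 1:
        raise SubjectExcludedError("no loaded range: torque never stays positive")
    return ProcessedCurves(
        angle_deg=grid[start:],
        torque=torque_g[start:],
        fascicle_mm=fascicle_g[start:],
        n_stretches=len(trials),
        crop_deg=(float(grid[start]), float(grid[-1])),
    )


def process_subject(
    trials: Sequence[StretchTrial],
    threshold: float = 0.10,
    n_samples: int = 101,
    grid_step_deg: float = 0.5,
) -> ProcessedCurves:
    """EMG-gate the trials, then average and crop the accepted ones."""
    kept = [tr for tr in trials if emg_gate(tr, threshold).keep]
    if not kept:
        raise SubjectExcludedError(
            f"all {len(trials)} stretches exceeded {threshold:.0%} MVC"
        )
    return average_and_crop(kept, n_samples=n_samples, grid_step_deg=grid_step_deg)


# --- file I/O -----------------------------------------------------------------


def read_trial(path: str | Path, mvc: Mapping[str, float] | None = None) -> StretchTrial:
    """Read one stretch trial from a wide CSV with per-rate NaN padding.

    Columns: ``time_s``, ``angle_deg``, ``torque_Nm`` (or the six load-cell
    columns), ``fascicle_mm``, optional ``emg_<muscle>`` envelopes.
    """
    df = pd.read_csv(path)

    def channel(col: str) -> tuple[np.ndarray, np.ndarray]:
        sub = df[["time_s", col]].dropna()
        return sub["time_s"].to_numpy(), sub[col].to_numpy()

    ta, angle = channel("angle_deg")
    if "torque_Nm" in df.columns:
        tt, torque = channel("torque_Nm")
    else:
        missing = [c for c in LOAD_CELL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing torque and load-cell columns {missing}")
        sub = df[["time_s", *LOAD_CELL_COLUMNS]].dropna()
        tt = sub["time_s"].to_numpy()
        torque = net_ankle_moment(
            LoadCellRecord(
                f_x=sub["fx_N"].to_numpy(),
                f_y=sub["fy_N"].to_numpy(),
                m_z_handle=sub["mz_handle_Nm"].to_numpy(),
                m_z_orthosis=sub["mz_orthosis_Nm"].to_numpy(),
                d_x=sub["dx_m"].to_numpy(),
                d_y=sub["dy_m"].to_numpy(),
            )
        )
    tf, fascicle = channel("fascicle_mm")
    emg = {}
    for col in df.columns:
        if col.startswith("emg_"):
            emg[col[4:]] = channel(col)
    return StretchTrial(
        angle_time=ta,
        angle_deg=angle,
        torque_time=tt,
        torque_Nm=torque,
        fascicle_time=tf,
        fascicle_mm=fascicle,
        emg=emg,
        mvc=dict(mvc or {}),
        name=Path(path).stem,
    )


def read_manifest(path: str | Path) -> tuple[dict, list[StretchTrial]]:
    """Read a subject manifest (YAML) and its trial files.

    The manifest holds the subject record fields, the MVC reference values and
    the relative paths of the stretch trial files.
    """
    path = Path(path)
    with open(path) as fh:
        man = yaml.safe_load(fh)
    mvc = {k: float(v) for k, v in man.get("mvc", {}).items()}
    trials = [read_trial(path.parent / rel, mvc) for rel in man["trials"]]
    return man, trials
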