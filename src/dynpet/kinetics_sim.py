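"""Synthetic dynamic whole-body FDG PET data.

This module is the stand-in for a real acquisition: it builds the frame
schedule of a whole-body dynamic (WBD) protocol (an early single-bed cardiac
segment followed by sparse, evenly spaced whole-body passes over one tracked
bed position), generates plasma input functions and irreversible two-tissue
compartment (2TC) tissue curves, samples them into frames, adds
duration-scaled Gaussian noise, assembles 4D digital phantoms with ground
truth attached, and draws lesion cohorts whose true Ki/Vd distributions are
log-normal around configurable group medians.

Conventions: time in minutes post-injection, activity concentration in
kBq/mL, Ki in mL/min/mL, Vd in mL/mL.  All curves are decay-corrected to
injection time, so no physical-decay term appears anywhere.  Random seeds
are explicit arguments, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "InputFunctionParams",
    "PartitionModel",
    "PlasmaInputFunction",
    "TissueKinetics",
    "DynamicPhantom",
    "CohortSpec",
    "CohortSample",
    "make_study_schedule",
    "bmi_adapted_dose",
    "plasma_curve",
    "solve_2tc_irreversible",
    "macro_patlak_curve",
    "sample_frames",
    "add_noise",
    "as_curve",
    "phantom_geometry",
    "default_phantom_labels",
    "build_phantom",
    "generate_cohort",
    "lognormal_sigma",
    "DEFAULT_LIVER_KINETICS",
]

# quartile of the standard normal; converts an IQR into a log-normal sigma
_Z75 = 0.6744897501960817

#: fixed early cardiac frame ladder, in seconds (12x5 s, 4x10 s, 8x25 s)
EARLY_LADDER_SEC: tuple[int, ...] = (5,) * 12 + (10,) * 4 + (25,) * 8


# ---------------------------------------------------------------------------
# frame schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping dynamic frames.

    Parameters
    ----------
    frame_start : array of minutes post-injection.
    frame_duration : array of minutes, all positive.
    bed_label : optional per-frame tag ("cardiac" for the early single-bed
        segment, "wb" for whole-body passes).
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    bed_label: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule needs at least one frame")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) < 0):
            raise ValueError("frames must be time-ordered")
        if np.any(start[1:] < start[:-1] + dur[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if self.bed_label is not None and len(self.bed_label) != start.size:
            raise ValueError("bed_label length must match the number of frames")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_times(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def span(self) -> tuple[float, float]:
        return float(self.frame_start[0]), float(self.end_times[-1])


def make_study_schedule(
    n_early_60s: int = 5,
    n_passes: int = 11,
    n_beds: int = 5,
    sec_per_bed: float = 35.0,
) -> FrameSchedule:
    """Frame schedule of the WBD protocol, for one tracked bed position.

    The early cardiac segment is the fixed ladder 12x5 s, 4x10 s, 8x25 s plus
    ``n_early_60s`` frames of 60 s, contiguous from t=0.  It is followed by
    ``n_passes`` whole-body frames of ``sec_per_bed`` seconds whose starts are
    spaced ``n_beds * sec_per_bed`` seconds apart (the unidirectional table
    motion makes the revisit interval of any bed position even), the first
    starting immediately after the early segment.
    """
    if n_early_60s < 0 or n_passes < 0 or n_beds < 0:
        raise ValueError("counts must be non-negative")
    if sec_per_bed <= 0:
        raise ValueError("sec_per_bed must be positive")
    durs_s = list(EARLY_LADDER_SEC) + [60.0] * int(n_early_60s)
    starts_s = np.concatenate([[0.0], np.cumsum(durs_s)[:-1]]) if durs_s else np.array([])
    labels = ["cardiac"] * len(durs_s)
    early_end_s = float(np.sum(durs_s))
    if n_passes > 0:
        gap_s = n_beds * sec_per_bed
        wb_starts = early_end_s + gap_s * np.arange(n_passes)
        starts_s = np.concatenate([starts_s, wb_starts])
        durs_s = durs_s + [sec_per_bed] * int(n_passes)
        labels += ["wb"] * int(n_passes)
    return FrameSchedule(
        frame_start=np.asarray(starts_s) / 60.0,
        frame_duration=np.asarray(durs_s) / 60.0,
        bed_label=tuple(labels),
    )


def bmi_adapted_dose(weight_kg: float, height_m: float) -> float:
    """BMI-adapted injected FDG activity in MBq.

    1.5 MBq/kg below BMI 20, 2 MBq/kg for BMI 20-24.5, 3.1 MBq/kg above,
    capped at 320 MBq.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    if bmi < 20.0:
        dose = 1.5 * weight_kg
    elif bmi <= 24.5:
        dose = 2.0 * weight_kg
    else:
        dose = 3.1 * weight_kg
    return min(dose, 320.0)


# ---------------------------------------------------------------------------
# input function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputFunctionParams:
    """Shape of the simulated plasma curve: triangular bolus + double-exponential tail.

    The defaults were calibrated once, analytically, so that typical liver
    (Ki 1.0e-2 mL/min/mL, Vd 1.1) and tumour (Ki 3.0e-2, Vd 0.9) kinetics map
    onto clinically familiar SUVs at a 210 MBq / 82 kg reference patient; see
    docs/methods.md.
    """

    A1: float = 71.2  # kBq/mL
    A2: float = 17.3  # kBq/mL
    lambda1: float = 0.35  # 1/min, fast clearance
    lambda2: float = 0.04  # 1/min, slow clearance
    peak_time: float = 0.5  # min
    peak_amplitude: float = 88.5  # kBq/mL

    def __post_init__(self) -> None:
        if not (self.lambda1 >= self.lambda2 > 0):
            raise ValueError("decay rates must satisfy lambda1 >= lambda2 > 0")
        if min(self.A1, self.A2, self.peak_amplitude) <= 0 or self.peak_time <= 0:
            raise ValueError("amplitudes and peak_time must be positive")


@dataclass(frozen=True)
class PartitionModel:
    """Time-varying plasma-to-whole-blood ratio p(t) = p_inf - (p_inf - p0) e^(-t/tau)."""

    p0: float = 1.0
    p_inf: float = 1.16
    tau: float = 5.0  # minutes

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.p_inf <= 0 or self.tau <= 0:
            raise ValueError("partition parameters must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.p_inf - (self.p_inf - self.p0) * np.exp(-t / self.tau)


def plasma_curve(params: InputFunctionParams, t: np.ndarray | float) -> np.ndarray:
    """Plasma activity Cp(t): linear rise to the bolus peak, then a scaled
    double exponential continuous at the peak."""
    t = np.asarray(t, dtype=float)
    p = params
    scale = p.peak_amplitude / (p.A1 + p.A2)
    dt = t - p.peak_time
    tail = scale * (p.A1 * np.exp(-p.lambda1 * np.clip(dt, 0, None))
                    + p.A2 * np.exp(-p.lambda2 * np.clip(dt, 0, None)))
    rise = p.peak_amplitude * np.clip(t, 0, None) / p.peak_time
    return np.where(t < p.peak_time, rise, tail)


@dataclass
class PlasmaInputFunction:
    """Discretized plasma curve on a fine uniform grid, with cached running integral."""

    grid: np.ndarray
    values: np.ndarray
    tail_params: tuple[float, float, float, float] | None = None
    cumulative_integral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.cumulative_integral is None:
            self.cumulative_integral = cumulative_trapezoid(
                self.values, self.grid, initial=0.0
            )

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.grid, self.values)

    def cumint(self, t: np.ndarray | float) -> np.ndarray:
        """Running integral of Cp from 0 (well, grid start) to t."""
        return np.interp(t, self.grid, self.cumulative_integral)

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @classmethod
    def from_params(
        cls,
        params: InputFunctionParams,
        t_end: float = 70.0,
        grid_step: float = 0.01,
    ) -> "PlasmaInputFunction":
        grid = np.arange(0.0, t_end + grid_step / 2, grid_step)
        return cls(grid=grid, values=plasma_curve(params, grid))


# ---------------------------------------------------------------------------
# tissue kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueKinetics:
    """Tissue curve parameters, either micro (K1, k2, k3, vb) or macro (Ki, Vd).

    In the irreversible 2TC model the implied Patlak slope is
    K1*k3/(k2+k3) and the implied asymptotic intercept is vb + K1*k2/(k2+k3)^2.
    """

    mode: str
    K1: float = 0.0  # mL/min/mL
    k2: float = 0.0  # 1/min
    k3: float = 0.0  # 1/min
    vb: float = 0.0  # unitless blood volume fraction
    Ki: float = 0.0  # mL/min/mL
    Vd: float = 0.0  # mL/mL

    def __post_init__(self) -> None:
        if self.mode not in ("micro", "macro"):
            raise ValueError("mode must be 'micro' or 'macro'")
        if self.mode == "micro":
            if min(self.K1, self.k2, self.k3) < 0 or not (0 <= self.vb <= 1):
                raise ValueError("micro rates must be >= 0 and 0 <= vb <= 1")
        else:
            if self.Ki < 0 or self.Vd < 0:
                raise ValueError("macro parameters must be >= 0")

    @classmethod
    def micro(cls, K1: float, k2: float, k3: float, vb: float = 0.0) -> "TissueKinetics":
        return cls(mode="micro", K1=K1, k2=k2, k3=k3, vb=vb)

    @classmethod
    def macro(cls, Ki: float, Vd: float) -> "TissueKinetics":
        return cls(mode="macro", Ki=Ki, Vd=Vd)

    @property
    def ki_macro(self) -> float:
        """Implied Patlak slope."""
        if self.mode == "macro":
            return self.Ki
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else self.K1

    @property
    def vd_macro(self) -> float:
        """Implied asymptotic Patlak intercept."""
        if self.mode == "macro":
            return self.Vd
        denom = self.k2 + self.k3
        return self.vb + (self.K1 * self.k2 / denom**2 if denom > 0 else 0.0)


#: liver micro-parameters implying Ki ~ 1.0e-2 mL/min/mL and Vd ~ 1.06 mL/mL
DEFAULT_LIVER_KINETICS = TissueKinetics.micro(K1=0.5, k2=0.476, k3=0.0097, vb=0.05)


def solve_2tc_irreversible(
    kin: TissueKinetics,
    cp: PlasmaInputFunction,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Tissue curve of the irreversible 2TC model driven by plasma Cp.

    dC1/dt = K1*Cp - (k2+k3)*C1,  dC2/dt = k3*C1,  C_T = C1 + C2 + vb*Cp.

    Solved on the input function's fine grid with an exact exponential-
    integrator step for piecewise-linear Cp (the first compartment update is
    exact per step; the trapped compartment is accumulated by trapezoid).
    Returns C_T at ``t`` (default: the fine grid itself).
    """
    if kin.mode != "micro":
        raise ValueError("solve_2tc_irreversible needs micro-mode kinetics")
    grid = cp.grid
    h = np.diff(grid)
    if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12):
        raise ValueError("input-function grid must be uniform")
    h = float(h[0])
    cpv = cp.values
    beta = kin.k2 + kin.k3
    a, b = cpv[:-1], cpv[1:]
    if beta * h > 1e-10:
        one_m_e = -math.expm1(-beta * h)  # 1 - exp(-beta h), accurately
        decay = 1.0 - one_m_e
        # integral over one step of a linear Cp against the decay kernel
        step = a * one_m_e / beta + (b - a) * (beta * h - one_m_e) / (beta**2 * h)
        drive = kin.K1 * step
        # C1[n+1] = decay * C1[n] + drive[n]
        c1 = np.concatenate([[0.0], lfilter([1.0], [1.0, -decay], drive)])
    else:
        c1 = kin.K1 * cumulative_trapezoid(cpv, grid, initial=0.0)
    c2 = kin.k3 * cumulative_trapezoid(c1, grid, initial=0.0)
    ct = c1 + c2 + kin.vb * cpv
    if t is None:
        return ct
    return np.interp(np.asarray(t, dtype=float), grid, ct)


def macro_patlak_curve(
    kin: TissueKinetics,
    cp: PlasmaInputFunction,
    t: np.ndarray | float,
) -> np.ndarray:
    """Exact Patlak-linear tissue curve C_T(t) = Ki * int_0^t Cp + Vd * Cp(t)."""
    if kin.mode != "macro":
        raise ValueError("macro_patlak_curve needs macro-mode kinetics")
    t = np.asarray(t, dtype=float)
    return kin.Ki * cp.cumint(t) + kin.Vd * cp(t)


def tissue_curve(kin: TissueKinetics, cp: PlasmaInputFunction) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous tissue curve for either kinetics mode, as a callable of time."""
    if kin.mode == "macro":
        return lambda t: macro_patlak_curve(kin, cp, t)
    ct = solve_2tc_irreversible(kin, cp)
    grid = cp.grid
    return lambda t: np.interp(np.asarray(t, dtype=float), grid, ct)


# ---------------------------------------------------------------------------
# frame sampling and noise
# ---------------------------------------------------------------------------


def as_curve(t: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap sampled values into a linear-interpolation callable."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    return lambda tt: np.interp(np.asarray(tt, dtype=float), t, y)


def sample_frames(
    curve: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    n_sub: int = 64,
    support: tuple[float, float] | None = None,
) -> np.ndarray:
    """Frame activities as time-averages of a continuous curve.

    Each frame value is the trapezoidal mean of the curve over
    [start, start+duration] with ``n_sub`` sub-intervals (>= 32).
    If the curve carries a ``grid`` (e.g. a PlasmaInputFunction) its extent is
    used as the support; a schedule extending beyond the support is an error.
    """
    if n_sub < 32:
        raise ValueError("n_sub must be at least 32")
    if support is None and hasattr(curve, "grid"):
        g = curve.grid
        support = (float(g[0]), float(g[-1]))
    if support is not None:
        t0, t1 = support
        if schedule.frame_start[0] < t0 - 1e-9 or schedule.end_times[-1] > t1 + 1e-9:
            raise ValueError("schedule extends beyond curve support")
    frac = np.linspace(0.0, 1.0, n_sub + 1)
    tt = schedule.frame_start[:, None] + schedule.frame_duration[:, None] * frac[None, :]
    vals = np.asarray(curve(tt.ravel()), dtype=float).reshape(tt.shape)
    return np.trapezoid(vals, tt, axis=1) / schedule.frame_duration


def add_noise(
    frames: np.ndarray,
    schedule: FrameSchedule,
    noise_scale: float,
    seed: int,
    floor: float = 1e-3,
) -> np.ndarray:
    """Additive Gaussian noise with count-statistics-like variance.

    The standard deviation of frame k is
    ``noise_scale * sqrt(max(value, floor) / duration_k)`` — variance inversely
    proportional to frame duration, as for reconstructed-image means.  Output
    is clipped at zero and reproducible for a fixed seed.  The trailing axis
    of ``frames`` must index frames.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    frames = np.asarray(frames, dtype=float)
    if frames.shape[-1] != schedule.n_frames:
        raise ValueError("trailing axis of frames must match the schedule")
    if noise_scale == 0:
        return frames.copy()
    rng = np.random.default_rng(seed)
    sd = noise_scale * np.sqrt(np.maximum(frames, floor) / schedule.frame_duration)
    return np.clip(frames + rng.standard_normal(frames.shape) * sd, 0.0, None)


# ---------------------------------------------------------------------------
# 4D phantom
# ---------------------------------------------------------------------------

AORTA_LABEL = 1
LIVER_LABEL = 2
FIRST_LESION_LABEL = 3


@dataclass
class DynamicPhantom:
    """4D activity volume with ground-truth label map and per-label kinetics.

    Label semantics: 0 background (no activity), 1 aortic tube (whole blood),
    2 liver, >= 3 lesions.
    """

    activity: np.ndarray  # (x, y, z, frame), kBq/mL
    labels: np.ndarray  # (x, y, z) int
    truth: Mapping[int, TissueKinetics]
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float]  # mm
    cp_truth: PlasmaInputFunction | None = None
    partition: PartitionModel | None = None
    if_params: InputFunctionParams | None = None
    noise_scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.activity.ndim != 4:
            raise ValueError("activity must be 4-D (x, y, z, frame)")
        if self.activity.shape[:3] != self.labels.shape:
            raise ValueError("labels shape must match the spatial shape of activity")
        if self.activity.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis must match the schedule")
        if np.any(self.activity < 0):
            raise ValueError("activities must be non-negative")
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,))
        self.voxel_size = tuple(float(v) for v in vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def phantom_geometry(
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float],
    n_lesions: int = 2,
) -> dict:
    """Deterministic phantom layout: aorta cylinder, liver ellipsoid, lesion
    spheres on a ring inside the liver (kept clear of the liver VOI centre)."""
    nx, ny, nz = shape
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    liver_center = np.array([0.62 * nx, 0.5 * ny, 0.5 * nz])
    lesion_centers = []
    ring_mm = 26.0
    for k in range(n_lesions):
        ang = 2 * np.pi * k / max(n_lesions, 1)
        off_mm = ring_mm * np.array([np.cos(ang), 0.0, np.sin(ang)])
        lesion_centers.append(liver_center + off_mm / vs)
    return {
        "aorta_axis_xy": (0.22 * nx, 0.5 * ny),
        "aorta_radius_mm": 12.0,
        "liver_center": liver_center,
        "liver_semiaxes_mm": np.array([0.30 * nx * vs[0], 0.28 * ny * vs[1], 0.30 * nz * vs[2]]),
        "lesion_centers": lesion_centers,
        "lesion_radius_mm": 8.0,
        "voxel_size": vs,
    }


def default_phantom_labels(
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float],
    n_lesions: int = 2,
) -> np.ndarray:
    """Integer label map for the default phantom layout."""
    geo = phantom_geometry(shape, voxel_size, n_lesions)
    vs = geo["voxel_size"]
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    labels = np.zeros(shape, dtype=np.int16)

    cx, cy = geo["aorta_axis_xy"]
    r2 = ((ix - cx) * vs[0]) ** 2 + ((iy - cy) * vs[1]) ** 2
    labels[r2 <= geo["aorta_radius_mm"] ** 2] = AORTA_LABEL

    lc = geo["liver_center"]
    sa = geo["liver_semiaxes_mm"]
    e = (((ix - lc[0]) * vs[0] / sa[0]) ** 2
         + ((iy - lc[1]) * vs[1] / sa[1]) ** 2
         + ((iz - lc[2]) * vs[2] / sa[2]) ** 2)
    labels[(e <= 1.0) & (labels == 0)] = LIVER_LABEL

    for k, c in enumerate(geo["lesion_centers"]):
        d2 = (((ix - c[0]) * vs[0]) ** 2 + ((iy - c[1]) * vs[1]) ** 2
              + ((iz - c[2]) * vs[2]) ** 2)
        labels[d2 <= geo["lesion_radius_mm"] ** 2] = FIRST_LESION_LABEL + k
    return labels


def build_phantom(
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float],
    truth: Mapping[int, TissueKinetics],
    params: InputFunctionParams,
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    seed: int = 0,
    labels: np.ndarray | None = None,
    partition: PartitionModel | None = None,
    grid_step: float = 0.01,
) -> DynamicPhantom:
    """Assemble a 4D dynamic phantom.

    Every voxel's frame series is the frame-sampled curve of its label, plus
    duration-scaled Gaussian noise.  The aortic tube (label 1) contains whole
    blood, i.e. plasma divided by the partition ratio p(t); all other labelled
    tissues are driven by the plasma curve through their kinetics.  Ground
    truth (kinetics, true Cp, partition, seed) is stored on the phantom.
    """
    partition = partition or PartitionModel()
    if labels is None:
        n_lesions = sum(1 for lab in truth if lab >= FIRST_LESION_LABEL)
        labels = default_phantom_labels(shape, voxel_size, n_lesions)
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist()) - {0}
    unknown = present - set(int(k) for k in truth)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} missing from the truth map")
    if AORTA_LABEL not in present or LIVER_LABEL not in present:
        raise ValueError("phantom labels must include an aorta tube (1) and a liver region (2)")

    t_end = schedule.end_times[-1] + 1.0
    cp = PlasmaInputFunction.from_params(params, t_end=t_end, grid_step=grid_step)

    activity = np.zeros(labels.shape + (schedule.n_frames,), dtype=float)
    for lab in sorted(present):
        if lab == AORTA_LABEL:
            curve = lambda t: cp(t) / np.asarray(partition(t), dtype=float)
            frames = sample_frames(curve, schedule, support=(cp.grid[0], cp.grid[-1]))
        else:
            frames = sample_frames(tissue_curve(truth[lab], cp), schedule,
                                   support=(cp.grid[0], cp.grid[-1]))
        activity[labels == lab] = frames
    activity = add_noise(activity, schedule, noise_scale, seed)
    return DynamicPhantom(
        activity=activity,
        labels=labels,
        truth=dict(truth),
        schedule=schedule,
        voxel_size=voxel_size if isinstance(voxel_size, tuple) else (float(voxel_size),) * 3,
        cp_truth=cp,
        partition=partition,
        if_params=params,
        noise_scale=noise_scale,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# lesion cohort
# ---------------------------------------------------------------------------


def lognormal_sigma(median: float, iqr: float) -> float:
    """Log-normal sigma whose distribution has the given median and IQR."""
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("iqr must be non-negative")
    return math.asinh(iqr / (2.0 * median)) / _Z75


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped lesion cohort: group sizes and the medians/IQRs of the
    true Ki and Vd distributions, log-normal per group.

    Defaults reproduce the study-shaped cohort: 60 cancer and 17
    inflammatory/infectious lesions, cancer Ki median 3.0e-2 mL/min/mL
    (IQR 2.2e-2) vs inflammatory 2.0e-2 (IQR 1.1e-2), Vd 0.9 (0.5) vs
    0.7 (0.4), liver Ki 1.0e-2 and Vd 1.1.  The reference patient
    (210 MBq / 82 kg) matches the cohort's mean injected activity and weight.
    """

    n_cancer: int = 60
    n_inflammatory: int = 17
    ki_median_cancer: float = 0.030
    ki_iqr_cancer: float = 0.022
    ki_median_inflammatory: float = 0.020
    ki_iqr_inflammatory: float = 0.011
    vd_median_cancer: float = 0.9
    vd_iqr_cancer: float = 0.5
    vd_median_inflammatory: float = 0.7
    vd_iqr_inflammatory: float = 0.4
    liver_ki_median: float = 0.010
    liver_vd_median: float = 1.1
    liver_log_sigma: float = 0.20
    noise_scale: float = 0.05
    dose_mbq: float = 210.0
    weight_kg: float = 82.0
    suv_window: tuple[float, float] = (55.0, 65.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_inflammatory < 0:
            raise ValueError("group counts must be non-negative")
        for name in ("ki_median_cancer", "ki_median_inflammatory",
                     "vd_median_cancer", "vd_median_inflammatory",
                     "liver_ki_median", "liver_vd_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortSample:
    """Generated cohort: truth table plus noisy per-lesion TACs.

    ``lesion_tacs``/``liver_tacs`` are (n_lesions, n_frames) frame activities;
    ``lesion_static``/``liver_static`` are noisy concentrations averaged over
    the static SUV window.  Each lesion carries its own liver reference,
    mimicking per-patient liver measurements.
    """

    records: pd.DataFrame
    lesion_tacs: np.ndarray
    liver_tacs: np.ndarray
    lesion_static: np.ndarray
    liver_static: np.ndarray
    schedule: FrameSchedule
    cp: PlasmaInputFunction
    spec: CohortSpec


def _window_averages(cp: PlasmaInputFunction, window: tuple[float, float]) -> tuple[float, float]:
    """Time-averages of the running integral and of Cp over a window."""
    w0, w1 = window
    sel = (cp.grid >= w0 - 1e-12) & (cp.grid <= w1 + 1e-12)
    g = cp.grid[sel]
    avg_cumint = float(np.trapezoid(cp.cumulative_integral[sel], g) / (g[-1] - g[0]))
    avg_cp = float((cp.cumint(w1) - cp.cumint(w0)) / (w1 - w0))
    return avg_cumint, avg_cp


def generate_cohort(
    spec: CohortSpec,
    schedule: FrameSchedule | None = None,
    if_params: InputFunctionParams | None = None,
    grid_step: float = 0.01,
) -> CohortSample:
    """Draw a lesion cohort and its noisy TACs, reproducibly under the seed.

    True Ki and Vd are drawn log-normally around the group medians with
    sigma derived from the group IQRs (zero IQR collapses the distribution
    onto the median).  Lesion TACs follow the macro Patlak identity, sampled
    into the schedule's frames, with duration-scaled Gaussian noise; a static
    window concentration is generated the same way for SUV.
    """
    schedule = schedule or make_study_schedule()
    if_params = if_params or InputFunctionParams()
    t_end = max(schedule.end_times[-1], spec.suv_window[1]) + 1.0
    cp = PlasmaInputFunction.from_params(if_params, t_end=t_end, grid_step=grid_step)

    rng = np.random.default_rng(spec.seed)
    n_c, n_i = spec.n_cancer, spec.n_inflammatory
    n = n_c + n_i

    def draw(median: float, iqr: float, size: int) -> np.ndarray:
        sigma = lognormal_sigma(median, iqr)
        return median * np.exp(sigma * rng.standard_normal(size))

    ki = np.concatenate([
        draw(spec.ki_median_cancer, spec.ki_iqr_cancer, n_c),
        draw(spec.ki_median_inflammatory, spec.ki_iqr_inflammatory, n_i),
    ])
    vd = np.concatenate([
        draw(spec.vd_median_cancer, spec.vd_iqr_cancer, n_c),
        draw(spec.vd_median_inflammatory, spec.vd_iqr_inflammatory, n_i),
    ])
    liver_ki = spec.liver_ki_median * np.exp(spec.liver_log_sigma * rng.standard_normal(n))
    liver_vd = spec.liver_vd_median * np.exp(spec.liver_log_sigma * rng.standard_normal(n))
    noise_seeds = rng.integers(0, 2**31 - 1, size=4)

    avg_cumint = sample_frames(lambda t: cp.cumint(t), schedule,
                               support=(cp.grid[0], cp.grid[-1]))
    avg_cp = sample_frames(cp, schedule)
    lesion_clean = ki[:, None] * avg_cumint[None, :] + vd[:, None] * avg_cp[None, :]
    liver_clean = liver_ki[:, None] * avg_cumint[None, :] + liver_vd[:, None] * avg_cp[None, :]
    lesion_tacs = add_noise(lesion_clean, schedule, spec.noise_scale, int(noise_seeds[0]))
    liver_tacs = add_noise(liver_clean, schedule, spec.noise_scale, int(noise_seeds[1]))

    win_cumint, win_cp = _window_averages(cp, spec.suv_window)
    win_dur = spec.suv_window[1] - spec.suv_window[0]
    win_sched = FrameSchedule(np.array([spec.suv_window[0]]), np.array([win_dur]))
    lesion_static = add_noise((ki * win_cumint + vd * win_cp)[:, None], win_sched,
                              spec.noise_scale, int(noise_seeds[2]))[:, 0]
    liver_static = add_noise((liver_ki * win_cumint + liver_vd * win_cp)[:, None], win_sched,
                             spec.noise_scale, int(noise_seeds[3]))[:, 0]

    records = pd.DataFrame({
        "lesion_id": np.arange(1, n + 1),
        "group": ["cancer"] * n_c + ["inflammatory"] * n_i,
        "true_ki": ki,
        "true_vd": vd,
        "liver_true_ki": liver_ki,
        "liver_true_vd": liver_vd,
    })
    return CohortSample(
        records=records,
        lesion_tacs=lesion_tacs,
        liver_tacs=liver_tacs,
        lesion_static=lesion_static,
        liver_static=liver_static,
        schedule=schedule,
        cp=cp,
        spec=spec,
    )
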