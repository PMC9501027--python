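"""Patlak graphical analysis: Ki/Vd estimation and parametric maps.

For irreversible FDG kinetics, past an equilibration time t* the tissue
curve obeys C_T(t) = Ki * int_0^t Cp(s) ds + Vd * Cp(t), with slope Ki (the
net influx rate) and intercept Vd (the apparent distribution volume).  The
fit is carried out in this un-divided multilinear form — response C_T,
regressors (int Cp, Cp) — rather than on the divided Patlak plot, which is
the same model without the noise amplification of dividing by Cp.

Weights are proportional to frame duration (the variance of a reconstructed
frame mean scales inversely with its duration).  Regressors are frame
time-averages, making the fit exactly consistent with frame-averaged data;
they agree with mid-time point evaluations to second order in the frame
duration.  Negative Ki or Vd estimates are reported, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics_sim import DynamicPhantom, FrameSchedule, PlasmaInputFunction, sample_frames

__all__ = [
    "PatlakDesign",
    "PatlakFit",
    "ParametricMaps",
    "SuvImage",
    "patlak_design",
    "fit_patlak",
    "fit_patlak_map",
    "static_suv_image",
]


@dataclass(frozen=True)
class PatlakDesign:
    """Regressor table for the Patlak fit over frames past t*."""

    mid_times: np.ndarray
    cp_integral: np.ndarray  # frame-averaged running integral of Cp
    cp: np.ndarray  # frame-averaged Cp
    weights: np.ndarray  # proportional to frame duration, normalized to sum 1
    frame_indices: np.ndarray  # indices of retained frames in the schedule
    t_star: float


@dataclass(frozen=True)
class PatlakFit:
    Ki: float  # mL/min/mL
    Vd: float  # mL/mL
    n_points_used: int
    t_star: float
    weighted_residual_norm: float
    r_squared: float


@dataclass
class ParametricMaps:
    """Voxelwise Ki/Vd maps with an r-squared quality-control map."""

    Ki_map: np.ndarray
    Vd_map: np.ndarray
    qc_map: np.ndarray
    t_star: float


@dataclass
class SuvImage:
    """Static SUV volume in g/mL, time-averaged over a frame window."""

    volume: np.ndarray
    source_window: tuple[float, float]


def patlak_design(
    cp: PlasmaInputFunction,
    schedule: FrameSchedule,
    t_star: float = 20.0,
    n_sub: int = 64,
) -> PatlakDesign:
    """Build the Patlak regressor table from the cached input function.

    Frames whose mid-time is at or past ``t_star`` are retained; for each,
    the regressors are the frame time-averages of the running integral of Cp
    and of Cp itself, with weights proportional to frame duration.
    """
    mids = schedule.mid_times
    keep = np.flatnonzero(mids >= t_star - 1e-9)
    if keep.size < 2:
        raise ValueError("need at least 2 frames at or past t_star")
    sub = FrameSchedule(
        frame_start=schedule.frame_start[keep],
        frame_duration=schedule.frame_duration[keep],
    )
    support = (float(cp.grid[0]), float(cp.grid[-1]))
    cp_avg = sample_frames(cp, sub, n_sub=n_sub, support=support)
    cumint_avg = sample_frames(lambda t: cp.cumint(t), sub, n_sub=n_sub, support=support)
    w = schedule.frame_duration[keep]
    return PatlakDesign(
        mid_times=mids[keep],
        cp_integral=cumint_avg,
        cp=cp_avg,
        weights=w / w.sum(),
        frame_indices=keep,
        t_star=float(t_star),
    )


def _normal_equations(design: PatlakDesign) -> tuple[float, float, float, float]:
    w, x1, x2 = design.weights, design.cp_integral, design.cp
    s11 = float(np.sum(w * x1 * x1))
    s12 = float(np.sum(w * x1 * x2))
    s22 = float(np.sum(w * x2 * x2))
    det = s11 * s22 - s12 * s12
    return s11, s12, s22, det


def fit_patlak(tissue: np.ndarray, design: PatlakDesign) -> PatlakFit:
    """Weighted multilinear Patlak fit of one TAC.

    Solves argmin over (Ki, Vd) of
    sum_k w_k (C_T(t_k) - Ki*intCp_k - Vd*Cp_k)^2 by the closed-form 2x2
    weighted normal equations.  Vd is not constrained to be non-negative.
    """
    y = np.asarray(tissue, dtype=float)
    if y.shape != design.mid_times.shape:
        raise ValueError("tissue frames must align with the design rows")
    s11, s12, s22, det = _normal_equations(design)
    if det <= 1e-12 * max(s11 * s22, 1e-300):
        raise ValueError("degenerate design: regressors are collinear")
    w, x1, x2 = design.weights, design.cp_integral, design.cp
    b1 = float(np.sum(w * x1 * y))
    b2 = float(np.sum(w * x2 * y))
    ki = (s22 * b1 - s12 * b2) / det
    vd = (s11 * b2 - s12 * b1) / det
    resid = y - ki * x1 - vd * x2
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    return PatlakFit(
        Ki=float(ki),
        Vd=float(vd),
        n_points_used=int(y.size),
        t_star=design.t_star,
        weighted_residual_norm=float(np.sqrt(ss_res)),
        r_squared=float(r2),
    )


def fit_patlak_many(tacs: np.ndarray, design: PatlakDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Patlak fit of many TACs sharing one design.

    ``tacs`` is (n_curves, n_frames_retained).  Returns (Ki, Vd, r2) arrays;
    curves with non-finite values yield (0, 0, 0).
    """
    y = np.asarray(tacs, dtype=float)
    if y.ndim != 2 or y.shape[1] != design.mid_times.size:
        raise ValueError("tacs must be (n_curves, n_design_rows)")
    s11, s12, s22, det = _normal_equations(design)
    if det <= 1e-12 * max(s11 * s22, 1e-300):
        raise ValueError("degenerate design: regressors are collinear")
    w, x1, x2 = design.weights, design.cp_integral, design.cp
    b1 = (y * (w * x1)).sum(axis=1)
    b2 = (y * (w * x2)).sum(axis=1)
    ki = (s22 * b1 - s12 * b2) / det
    vd = (s11 * b2 - s12 * b1) / det
    resid = y - ki[:, None] * x1 - vd[:, None] * x2
    ss_res = (w * resid**2).sum(axis=1)
    ybar = (w * y).sum(axis=1)
    ss_tot = (w * (y - ybar[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.where(ss_res < 1e-30, 1.0, 0.0))
    bad = ~(np.isfinite(ki) & np.isfinite(vd))
    ki[bad] = 0.0
    vd[bad] = 0.0
    r2[bad] = 0.0
    return ki, vd, r2


def fit_patlak_map(
    phantom: DynamicPhantom,
    cp: PlasmaInputFunction,
    t_star: float = 20.0,
) -> ParametricMaps:
    """Voxelwise Patlak fit producing Ki, Vd, and r-squared maps.

    Per-voxel failures (non-finite results) are recorded as zeros with a
    zero quality-control value rather than raised.  The result does not
    depend on voxel evaluation order.
    """
    design = patlak_design(cp, phantom.schedule, t_star=t_star)
    shape = phantom.shape
    y = phantom.activity.reshape(-1, phantom.schedule.n_frames)[:, design.frame_indices]
    ki, vd, r2 = fit_patlak_many(y, design)
    return ParametricMaps(
        Ki_map=ki.reshape(shape),
        Vd_map=vd.reshape(shape),
        qc_map=r2.reshape(shape),
        t_star=float(t_star),
    )


def static_suv_image(
    phantom: DynamicPhantom,
    window: tuple[float, float],
    dose_mbq: float,
    weight_kg: float,
) -> SuvImage:
    """Static SUV image: window-averaged activity normalized by injected
    activity per body weight (kBq/mL divided by kBq/g gives g/mL)."""
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    span0, span1 = phantom.schedule.span
    if w0 < span0 - 1e-9 or w1 > span1 + 1e-9:
        raise ValueError("window outside the phantom's time span")
    start = phantom.schedule.frame_start
    end = phantom.schedule.end_times
    overlap = np.clip(np.minimum(end, w1) - np.maximum(start, w0), 0.0, None)
    if overlap.sum() <= 0:
        raise ValueError("window overlaps no frames")
    conc = phantom.activity @ (overlap / overlap.sum())
    return SuvImage(volume=conc * weight_kg / dose_mbq, source_window=(float(w0), float(w1)))
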