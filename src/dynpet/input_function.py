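"""Image-derived input function (IDIF) estimation.

Pipeline: segment an aortic tube of interest (TOI) on an early-sum image,
extract the whole-blood time-activity curve, convert to plasma with a
time-varying plasma-to-whole-blood ratio, fit a double-exponential tail to
the sparse whole-body-dynamic part, reconstruct the early bolus with an
integral-preserving linear interpolation, and assemble the discretized final
plasma input function with its cached running integral.

Inter-frame TOI motion correction is exposed as a hook
(``recenter_mask_per_frame``) but disabled by default: the phantoms are
motion-free and registration of real data is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .kinetics_sim import (
    DynamicPhantom,
    InputFunctionParams,  # noqa: F401  (re-export: part of this module's surface)
    PartitionModel,
    PlasmaInputFunction,
)

__all__ = [
    "TubeOfInterest",
    "WholeBloodCurve",
    "PartitionModel",
    "PlasmaInputFunction",
    "segment_aorta_toi",
    "extract_whole_blood_tac",
    "to_plasma",
    "fit_double_exponential",
    "integral_preserving_interpolation",
    "InterpolatedCurve",
    "assemble_input_function",
    "estimate_input_function",
]


@dataclass
class TubeOfInterest:
    """Segmented aortic blood-pool mask, propagated unchanged to all frames."""

    mask: np.ndarray  # 3-D boolean
    n_voxels: int
    source_frame_span: tuple[float, float]  # minutes


@dataclass
class WholeBloodCurve:
    """Whole-blood activity samples at frame mid-times."""

    mid_times: np.ndarray
    values: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if np.any(np.diff(self.mid_times) <= 0):
            raise ValueError("mid-times must be increasing")
        if np.any(self.values < 0):
            raise ValueError("whole-blood activities must be non-negative")


def segment_aorta_toi(
    phantom: DynamicPhantom,
    early_window: float = 2.0,
    rel_threshold: float = 0.5,
    top_percentile: float = 0.1,
) -> TubeOfInterest:
    """Automatic aortic TOI segmentation on an early-sum image.

    The image covering the first ``early_window`` minutes is summed; voxels
    above ``rel_threshold`` of its robust maximum (the value at the
    100 - ``top_percentile`` percentile, which discards hot outliers) are kept,
    the largest connected component is selected, and the result is eroded by
    one voxel to suppress the partial-volume rim.  The threshold is relative,
    so the mask is invariant under global rescaling of the activity.
    """
    mids = phantom.schedule.mid_times
    sel = mids <= early_window
    if not np.any(sel):
        raise ValueError("early_window contains no frames")
    early = phantom.activity[..., sel].sum(axis=-1)
    if early.max() <= 0:
        raise ValueError("no blood pool found: early image is empty")
    robust_max = np.percentile(early, 100.0 - top_percentile)
    if robust_max <= 0:
        robust_max = early.max()
    mask = early >= rel_threshold * robust_max
    comp, n_comp = ndimage.label(mask)
    if n_comp == 0:
        raise ValueError("no blood pool found: threshold mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    largest = comp == (1 + int(np.argmax(sizes)))
    # border_value=1: the aorta continues beyond the field of view, so the
    # end slices of the tube are not eroded away
    eroded = ndimage.binary_erosion(largest, border_value=1)
    if not eroded.any():
        raise ValueError("no blood pool found: mask empty after erosion")
    return TubeOfInterest(
        mask=eroded,
        n_voxels=int(eroded.sum()),
        source_frame_span=(0.0, float(early_window)),
    )


def recenter_mask_per_frame(toi: TubeOfInterest, phantom: DynamicPhantom) -> TubeOfInterest:
    """Inter-frame motion hook: re-centre the mask on each frame.

    Disabled placeholder — synthetic data is motion-free, so the mask is
    returned unchanged.  Real-data registration is deliberately out of scope.
    """
    return toi


def extract_whole_blood_tac(phantom: DynamicPhantom, toi: TubeOfInterest) -> WholeBloodCurve:
    """Per-frame mean activity over the TOI mask."""
    if toi.mask.sum() == 0:
        raise ValueError("empty TOI")
    values = phantom.activity[toi.mask].mean(axis=0)
    return WholeBloodCurve(
        mid_times=phantom.schedule.mid_times,
        values=values,
        frame_durations=phantom.schedule.frame_duration,
    )


def to_plasma(wb: WholeBloodCurve, model: PartitionModel) -> np.ndarray:
    """Plasma samples: whole-blood values times the partition ratio p(t)."""
    return wb.values * np.asarray(model(wb.mid_times), dtype=float)


def _dexp(t: np.ndarray, a1: float, a2: float, l1: float, l2: float) -> np.ndarray:
    return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)


def fit_double_exponential(
    t: np.ndarray,
    values: np.ndarray,
    t_min: float = 10.0,
    weights: np.ndarray | None = None,
    n_starts: int = 10,
) -> tuple[float, float, float, float]:
    """Weighted least-squares fit of A1 e^(-l1 t) + A2 e^(-l2 t) to the tail.

    Samples at ``t >= t_min`` are used; weights default to uniform and are
    normally the frame durations.  Initialisation is a multi-start over decay
    pairs spanning 1e-3 to 1 /min with amplitudes profiled out linearly; the
    best start is refined by Levenberg-Marquardt.  Returns
    (A1, lambda1, A2, lambda2) with lambda1 > lambda2.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    keep = t >= t_min - 1e-12
    t, values, w = t[keep], values[keep], w[keep]
    if t.size < 6:
        raise ValueError("need at least 6 samples at t >= t_min")
    if np.all(values == 0):
        raise ValueError("all tail samples are zero")
    sw = np.sqrt(w / w.sum())

    lam_grid = np.geomspace(1e-3, 1.0, n_starts)
    best = None
    for i in range(n_starts):
        for j in range(i):
            l1, l2 = lam_grid[i], lam_grid[j]
            X = np.column_stack([np.exp(-l1 * t), np.exp(-l2 * t)]) * sw[:, None]
            amp, *_ = np.linalg.lstsq(X, values * sw, rcond=None)
            res = float(np.sum((X @ amp - values * sw) ** 2))
            if best is None or res < best[0]:
                best = (res, amp[0], amp[1], l1, l2)

    def resid(p: np.ndarray) -> np.ndarray:
        l1, l2 = np.exp(np.clip(p[2:4], -16.0, 3.0))
        return sw * (_dexp(t, p[0], p[1], l1, l2) - values)

    _, a1, a2, l1, l2 = best
    sol = optimize.least_squares(
        resid, x0=[a1, a2, np.log(l1), np.log(l2)], method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
    )
    a1, a2 = float(sol.x[0]), float(sol.x[1])
    l1, l2 = (float(v) for v in np.exp(np.clip(sol.x[2:4], -16.0, 3.0)))
    if l1 < l2:
        a1, a2, l1, l2 = a2, a1, l2, l1
    return a1, l1, a2, l2


@dataclass
class InterpolatedCurve:
    """Piecewise-linear curve on a fine grid plus its defining knots."""

    grid: np.ndarray
    values: np.ndarray
    knot_times: np.ndarray
    knot_values: np.ndarray

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.knot_times, self.knot_values)


def integral_preserving_interpolation(
    frame_start: np.ndarray,
    frame_duration: np.ndarray,
    frame_values: np.ndarray,
    grid_step: float = 0.01,
) -> InterpolatedCurve:
    """Continuous piecewise-linear curve whose average over each original
    frame equals that frame's value exactly.

    The knots sit at the frame boundaries; since the mean of a linear segment
    is the midpoint of its endpoint values, the knot values satisfy
    ``v[k+1] = 2*value[k] - v[k]`` with the endpoint condition v[0] = 0 (no
    tracer precedes injection).  Linear inputs are fixed points.
    """
    start = np.asarray(frame_start, dtype=float)
    dur = np.asarray(frame_duration, dtype=float)
    vals = np.asarray(frame_values, dtype=float)
    if start.size == 0:
        raise ValueError("no frames given")
    if np.any(np.abs(start[1:] - (start[:-1] + dur[:-1])) > 1e-9):
        raise ValueError("frames must be contiguous")
    knot_t = np.concatenate([start, [start[-1] + dur[-1]]])
    knot_v = np.empty(knot_t.size)
    knot_v[0] = 0.0
    for k in range(vals.size):
        knot_v[k + 1] = 2.0 * vals[k] - knot_v[k]
    grid = np.arange(knot_t[0], knot_t[-1] + grid_step / 2, grid_step)
    return InterpolatedCurve(
        grid=grid,
        values=np.interp(grid, knot_t, knot_v),
        knot_times=knot_t,
        knot_values=knot_v,
    )


def assemble_input_function(
    frame_start: np.ndarray,
    frame_duration: np.ndarray,
    plasma_values: np.ndarray,
    tail_params: tuple[float, float, float, float],
    switch_time: float = 10.0,
    grid_step: float = 0.01,
    t_end: float = 70.0,
    max_jump: float = 0.10,
) -> PlasmaInputFunction:
    """Discretized final plasma input function.

    For t < ``switch_time`` the curve is the integral-preserving
    interpolation of the early plasma frames; for t >= ``switch_time`` it is
    the fitted double exponential, with a continuity blend over one grid step.
    A relative discontinuity above ``max_jump`` at the switch signals
    inconsistent early/tail segments.
    """
    start = np.asarray(frame_start, dtype=float)
    dur = np.asarray(frame_duration, dtype=float)
    vals = np.asarray(plasma_values, dtype=float)
    early = start + dur <= switch_time + 1e-9
    if not np.any(early):
        raise ValueError("switch_time precedes all sampled frames")
    interp = integral_preserving_interpolation(start[early], dur[early], vals[early], grid_step)

    a1, l1, a2, l2 = tail_params
    grid = np.arange(0.0, t_end + grid_step / 2, grid_step)
    tail_at_switch = float(_dexp(np.asarray([switch_time]), a1, a2, l1, l2)[0])
    early_at_switch = float(interp(switch_time))
    ref = max(abs(tail_at_switch), 1e-12)
    if abs(early_at_switch - tail_at_switch) > max_jump * ref:
        raise ValueError("inconsistent early/tail segments at the switch time")

    values = np.where(
        grid < switch_time,
        interp(np.minimum(grid, interp.knot_times[-1])),
        _dexp(grid, a1, a2, l1, l2),
    )
    i = int(np.searchsorted(grid, switch_time - 1e-12))
    if 0 < i < grid.size:
        values[i] = 0.5 * (interp(grid[i]) + _dexp(np.asarray([grid[i]]), a1, a2, l1, l2)[0])
    values = np.clip(values, 0.0, None)
    return PlasmaInputFunction(grid=grid, values=values, tail_params=(a1, l1, a2, l2))


def estimate_input_function(
    phantom: DynamicPhantom,
    partition: PartitionModel | None = None,
    early_window: float = 2.0,
    switch_time: float = 10.0,
    grid_step: float = 0.01,
    t_end: float | None = None,
) -> tuple[PlasmaInputFunction, TubeOfInterest]:
    """End-to-end IDIF: phantom volume in, assembled plasma curve out."""
    partition = partition or phantom.partition or PartitionModel()
    toi = segment_aorta_toi(phantom, early_window=early_window)
    toi = recenter_mask_per_frame(toi, phantom)
    wb = extract_whole_blood_tac(phantom, toi)
    plasma = to_plasma(wb, partition)
    tail = fit_double_exponential(
        wb.mid_times, plasma, t_min=switch_time, weights=wb.frame_durations
    )
    sched = phantom.schedule
    if t_end is None:
        t_end = float(sched.end_times[-1] + 1.0)
    cp = assemble_input_function(
        sched.frame_start, sched.frame_duration, plasma, tail,
        switch_time=switch_time, grid_step=grid_step, t_end=t_end,
    )
    return cp, toi
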