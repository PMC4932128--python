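"""Dynamic-PET quantification: reference Logan DVR, frame-window averaging,
SUV and SUVR images.

The reference Logan graphical method regresses

    y(t) = int_0^t C(s) ds / C(t)   on   x(t) = int_0^t C_ref(s) ds / C(t)

over frames whose mid-time lies in the fit window (here 30-60 min for the
60-min tau acquisition); the slope estimates the distribution volume ratio
DVR = 1 + BP_ND.  The simplified form without the population-k2' correction
term is used, appropriate at late start times for tau and amyloid tracers.
Integrals are trapezoids on frame mid-times with a leading triangle from
(0, 0), matching frame-averaged data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TAC, DynamicImage


@dataclass(frozen=True)
class LoganFit:
    """Result of a reference Logan fit."""

    dvr: float
    intercept: float
    tstar_window: tuple[float, float]
    n_points_used: int
    n_points_dropped: int
    r_squared: float


@dataclass(frozen=True)
class SuvInputs:
    """Dose (MBq), body weight (kg) and averaging window (minutes) for
    standardised-uptake-value images."""

    dose_mbq: float
    weight_kg: float
    window_min: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self):
        if self.dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.weight_kg <= 0:
            raise ValueError("body weight must be positive")


def cumulative_integral(mid_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Running integral of a frame-sampled curve: trapezoid between frame
    mid-times plus an initial triangle from (0, 0) to the first mid-time.

    ``values`` may carry leading sample axes; time is the last axis.
    """
    mid = np.asarray(mid_min, dtype=float)
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[..., 0] = 0.5 * mid[0] * v[..., 0]
    dt = np.diff(mid)
    out[..., 1:] = 0.5 * (v[..., 1:] + v[..., :-1]) * dt
    return np.cumsum(out, axis=-1)


def frame_average(dyn: DynamicImage, window_min: tuple[float, float]) -> np.ndarray:
    """Duration-weighted mean of the frames overlapping a time window.

    Frames partially inside the window are weighted by their overlap
    length, so the result is the true time-average of the frame-wise step
    function over the window.
    """
    t0, t1 = float(window_min[0]), float(window_min[1])
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    start = dyn.schedule.start_s / 60.0
    end = dyn.schedule.end_s / 60.0
    overlap = np.minimum(end, t1) - np.maximum(start, t0)
    overlap = np.maximum(overlap, 0.0)
    if overlap.sum() <= 0:
        raise ValueError(f"window [{t0}, {t1}] min overlaps no frame")
    w = overlap / overlap.sum()
    return np.tensordot(dyn.data, w, axes=([3], [0]))


def _logan_xy(tac_values, ref_values, mid_min):
    """Logan coordinates; last axis is time."""
    int_t = cumulative_integral(mid_min, tac_values)
    int_r = cumulative_integral(mid_min, ref_values)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = int_t / tac_values
        x = int_r / tac_values
    return x, y


def logan_dvr(
    tac: TAC, ref_tac: TAC, tstar_window: tuple[float, float] = (30.0, 60.0)
) -> LoganFit:
    """Reference Logan DVR of one target TAC against a reference TAC.

    Both TACs must share the frame schedule.  Frames inside the window
    with non-positive target activity are dropped (not clipped) and
    counted; fewer than two usable frames is an error.
    """
    if len(tac) != len(ref_tac) or not np.allclose(tac.mid_min, ref_tac.mid_min):
        raise ValueError("target and reference TACs must share the frame schedule")
    t0, t1 = tstar_window
    if t0 >= t1:
        raise ValueError("invalid t* window")
    in_win = (tac.mid_min >= t0) & (tac.mid_min <= t1)
    if not in_win.any():
        raise ValueError("t* window contains no frames")

    x, y = _logan_xy(tac.values, ref_tac.values, tac.mid_min)
    usable = in_win & (tac.values > 0) & np.isfinite(x) & np.isfinite(y)
    n_drop = int(in_win.sum() - usable.sum())
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable frames in the Logan window")
    xs, ys = x[usable], y[usable]
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return LoganFit(
        dvr=float(slope),
        intercept=float(intercept),
        tstar_window=(float(t0), float(t1)),
        n_points_used=int(usable.sum()),
        n_points_dropped=n_drop,
        r_squared=r2,
    )


def logan_dvr_image(
    dyn: DynamicImage,
    ref_mask: np.ndarray,
    tstar_window: tuple[float, float] = (30.0, 60.0),
    missing_value: float = np.nan,
) -> np.ndarray:
    """Voxel-wise reference Logan DVR map.

    The reference TAC is the mean over ``ref_mask`` per frame.  Voxels
    with any non-positive activity inside the fit window get
    ``missing_value``.  Returns a 3D DVR array.
    """
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if not ref_mask.any():
        raise ValueError("reference mask is empty")
    ref = dyn.mask_tac(ref_mask)
    mid = dyn.schedule.mid_min
    t0, t1 = tstar_window
    in_win = (mid >= t0) & (mid <= t1)
    if in_win.sum() < 2:
        raise ValueError("t* window contains fewer than 2 frames")

    shape3d = dyn.shape3d
    flat = dyn.data.reshape(-1, dyn.schedule.n_frames)
    x, y = _logan_xy(flat, ref.values[None, :], mid)
    xs = x[:, in_win]
    ys = y[:, in_win]
    valid = (flat[:, in_win] > 0).all(axis=1)

    # closed-form OLS slope per voxel over the window frames
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = ((xs - xm) ** 2).sum(axis=1)
        sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
        slope = sxy / sxx
    valid &= np.isfinite(slope) & (sxx > 0)
    dvr = np.where(valid, slope, missing_value)
    return dvr.reshape(shape3d)


def suv_image(vol: np.ndarray, inputs: SuvInputs) -> np.ndarray:
    """SUV: radioactivity concentration (MBq/mL) divided by injected dose
    (MBq) per body weight (kg), i.e. ``C * weight / dose``; any implicit
    tissue-density scaling is left to the caller's concentration units."""
    return np.asarray(vol, dtype=float) * (inputs.weight_kg / inputs.dose_mbq)


def suvr_image(vol: np.ndarray, ref_mask: np.ndarray) -> np.ndarray:
    """SUVR: voxel-wise division by the unweighted mean over the reference
    mask (cerebellar GM for tau/amyloid, pons for FDG)."""
    vol = np.asarray(vol, dtype=float)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if not ref_mask.any():
        raise ValueError("reference mask is empty")
    ref = float(vol[ref_mask].mean())
    if ref <= 0:
        raise ValueError("reference-region mean must be positive")
    return vol / ref


def classify_amyloid(isocortical_suvr: float, threshold: float = 1.41) -> bool:
    """Amyloid positivity: isocortical SUVR above the 1.41 cut-off."""
    return bool(isocortical_suvr > threshold)
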