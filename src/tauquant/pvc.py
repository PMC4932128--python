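"""Muller-Gartner partial-volume correction of 3D parametric/static images.

The two-compartment Muller-Gartner correction removes white-matter
spill-in and divides out grey-matter spill-out:

    corrected = (vol - C_WM * (WM (x) PSF)) / (GM (x) PSF)

where (x) denotes convolution with the scanner's Gaussian point-spread
function, GM/WM are tissue-probability maps, and C_WM is a pure-WM
activity estimate taken from a deeply eroded high-probability WM region.
CSF is assumed activity-free (it is still accepted for masking).  Voxels
with GM probability below a reporting threshold are set to NaN; the
blurred-GM denominator is floored to avoid edge explosions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import psf_sigma_vox


@dataclass(frozen=True)
class PvcConfig:
    psf_fwhm_mm: float = 8.0
    gm_threshold: float = 0.3
    wm_erosion_mm: float = 6.0
    gm_denominator_floor: float = 0.1
    wm_probability_min: float = 0.99

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be non-negative")
        if not 0.0 <= self.gm_threshold <= 1.0:
            raise ValueError("gm_threshold must lie in [0, 1]")
        if self.wm_erosion_mm < 0:
            raise ValueError("wm_erosion_mm must be non-negative")


def _erode_mm(mask: np.ndarray, depth_mm: float, voxel_size_mm) -> np.ndarray:
    """Erode a boolean mask to voxels at least ``depth_mm`` (in mm) inside
    it, via the Euclidean distance transform."""
    if depth_mm <= 0:
        return mask
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size_mm)
    return dist >= depth_mm


def estimate_wm_value(
    vol: np.ndarray,
    wm_map: np.ndarray,
    config: PvcConfig = PvcConfig(),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> float:
    """Pure-WM activity: mean of ``vol`` over the high-probability WM mask
    (p >= 0.99) eroded by ``wm_erosion_mm``, where spill-in from GM is
    negligible."""
    vol = np.asarray(vol, dtype=float)
    wm_map = np.asarray(wm_map, dtype=float)
    if vol.shape != wm_map.shape:
        raise ValueError("vol and wm_map shapes differ")
    core = _erode_mm(wm_map >= config.wm_probability_min, config.wm_erosion_mm, voxel_size_mm)
    if not core.any():
        raise ValueError(
            "no WM voxels survive erosion; reduce wm_erosion_mm or the "
            "WM probability cut-off"
        )
    vals = vol[core]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("eroded WM region contains no finite voxels")
    return float(vals.mean())


def muller_gartner(
    vol: np.ndarray,
    gm_map: np.ndarray,
    wm_map: np.ndarray,
    config: PvcConfig = PvcConfig(),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    wm_value: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Muller-Gartner-corrected GM image.

    Returns ``(corrected, info)`` where ``info`` reports the WM estimate
    used and the counts of masked and denominator-floored voxels.
    Sub-threshold-GM voxels are NaN.  With a zero-width PSF the correction
    reduces to ``(vol - C_WM * wm) / gm`` (identity on pure-GM voxels).
    """
    vol = np.asarray(vol, dtype=float)
    gm_map = np.asarray(gm_map, dtype=float)
    wm_map = np.asarray(wm_map, dtype=float)
    if not (vol.shape == gm_map.shape == wm_map.shape):
        raise ValueError("vol/gm_map/wm_map shapes differ")
    if not (gm_map > 0).any():
        raise ValueError("GM map is all-zero")
    if wm_value is None:
        wm_value = estimate_wm_value(vol, wm_map, config, voxel_size_mm)

    if config.psf_fwhm_mm > 0:
        sigma = psf_sigma_vox(config.psf_fwhm_mm, voxel_size_mm)
        gm_blur = ndimage.gaussian_filter(gm_map, sigma=sigma, mode="constant")
        wm_blur = ndimage.gaussian_filter(wm_map, sigma=sigma, mode="constant")
    else:
        gm_blur, wm_blur = gm_map, wm_map

    floored = gm_blur < config.gm_denominator_floor
    denom = np.maximum(gm_blur, config.gm_denominator_floor)
    with np.errstate(invalid="ignore"):
        corrected = (vol - wm_value * wm_blur) / denom
    report = gm_map >= config.gm_threshold
    corrected = np.where(report, corrected, np.nan)

    info = {
        "wm_value": wm_value,
        "n_reported": int(report.sum()),
        "n_masked": int((~report).sum()),
        "n_floored_reported": int((floored & report).sum()),
    }
    return corrected, info
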