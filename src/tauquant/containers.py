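"""Shared data containers for dynamic PET quantification.

A dynamic PET acquisition is a 4D activity-concentration volume together
with a frame schedule (start time and duration per frame).  Time-activity
curves (TACs) are the per-frame mean concentrations of a region or voxel.
Internally all times are handled in *minutes* for kinetic modelling and in
*seconds* in the on-disk frame-timing sidecar, mirroring scanner exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition.

    Parameters
    ----------
    start_s : array of frame start times, seconds from injection.
    duration_s : array of frame durations, seconds.

    Frames must be contiguous and non-overlapping:
    ``start_s[i+1] == start_s[i] + duration_s[i]``.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_blocks(cls, blocks: list[tuple[int, float]], t0_s: float = 0.0) -> "FrameSchedule":
        """Build a schedule from ``(n_frames, duration_s)`` blocks."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = t0_s + np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def thk5317(cls) -> "FrameSchedule":
        """The 22-frame/60-min dynamic schedule used for [18F]THK5317:
        6x10 s, 3x20 s, 2x30 s, 2x60 s, 2x150 s, 4x300 s, 3x600 s."""
        return cls.from_blocks(
            [(6, 10), (3, 20), (2, 30), (2, 60), (2, 150), (4, 300), (3, 600)]
        )

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_span_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.start_s + 0.5 * self.duration_s) / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0


@dataclass
class TAC:
    """Time-activity curve: frame mid-times (min), durations (min) and the
    mean activity concentration per frame (declared unit, e.g. kBq/mL)."""

    mid_min: np.ndarray
    duration_min: np.ndarray
    values: np.ndarray
    unit: str = "kBq/mL"

    def __post_init__(self):
        self.mid_min = np.asarray(self.mid_min, dtype=float)
        self.duration_min = np.asarray(self.duration_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.mid_min.shape == self.duration_min.shape == self.values.shape):
            raise ValueError("mid_min, duration_min and values must share shape")
        if np.any(np.diff(self.mid_min) <= 0):
            raise ValueError("mid_min must be strictly increasing")
        if np.any(self.duration_min <= 0):
            raise ValueError("durations must be positive")

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, values: np.ndarray, unit: str = "kBq/mL") -> "TAC":
        return cls(schedule.mid_min, schedule.duration_min, values, unit)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) with its frame schedule.

    ``voxel_size_mm`` is the isotropic-or-not voxel edge length used by all
    mm-parameterised operations (PSF blur, smoothing, erosion); ``affine``
    is carried for NIfTI round-tripping and defaults to a scaled identity.
    """

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicImage data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.data.shape[3]}) does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_tac(self, i: int, j: int, k: int) -> TAC:
        return TAC.from_schedule(self.schedule, self.data[i, j, k, :])

    def mask_tac(self, mask: np.ndarray) -> TAC:
        """Mean TAC over a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape3d:
            raise ValueError("mask shape does not match image")
        if not mask.any():
            raise ValueError("mask is empty")
        return TAC.from_schedule(self.schedule, self.data[mask].mean(axis=0))
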