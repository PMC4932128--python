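"""Synthetic dynamic-PET phantom with known ground-truth kinetics.

The generator produces 4D dynamic images on the 22-frame/60-min acquisition
schedule, driven by a simplified-reference-tissue-model (SRTM) forward
model: a gamma-variate analytic reference curve ``C_R(t) = A t exp(-t/tau)``
stands in for cerebellar grey matter, and every target region follows

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) * (C_R conv exp(-k2a t)),
    k2a = k2 / (1 + BP_ND)

so its distribution volume ratio DVR = 1 + BP_ND is known exactly.  Frame
values are within-frame time averages (how scanners report frames), voxels
are tissue-probability-weighted mixes of regional curves, blurred by a
Gaussian PSF per frame, with additive Gaussian noise whose SD scales as
sqrt(value / frame duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import TAC, DynamicImage, FrameSchedule
from .roi import BRAAK_LIMBIC_MEMBERS, BRAAK_SPARED_ISOCORTEX

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class KineticParams:
    """SRTM parameters of one region: delivery ratio R1, reference efflux
    k2 (1/min) and binding potential BP_ND (unitless)."""

    r1: float = 0.9
    k2: float = 0.15
    bp_nd: float = 0.0

    def __post_init__(self):
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp_nd < 0:
            raise ValueError("BP_ND must be non-negative")

    @property
    def dvr(self) -> float:
        return 1.0 + self.bp_nd

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)

    def with_dvr(self, dvr: float) -> "KineticParams":
        if dvr < 1.0:
            raise ValueError("DVR must be >= 1")
        return KineticParams(self.r1, self.k2, dvr - 1.0)


def reference_curve(t_min: np.ndarray, amplitude: float, tau_min: float) -> np.ndarray:
    """Gamma-variate reference concentration ``A t exp(-t/tau)`` at times
    ``t_min`` (minutes).  Peaks at t = tau."""
    t = np.asarray(t_min, dtype=float)
    return amplitude * t * np.exp(-t / tau_min)


def _reference_antiderivative(t, amplitude, tau):
    # int A s exp(-s/tau) ds = -A tau (s + tau) exp(-s/tau)
    return -amplitude * tau * (t + tau) * np.exp(-t / tau)


def simulate_reference_tac(
    amplitude: float, tau_min: float, schedule: FrameSchedule
) -> TAC:
    """Analytic within-frame time-averages of the gamma-variate reference.

    ``amplitude`` may be zero (all-zero TAC) but not negative; ``tau_min``
    must be positive.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if tau_min <= 0:
        raise ValueError("tau must be positive")
    a = schedule.start_s / 60.0
    b = schedule.end_s / 60.0
    means = (
        _reference_antiderivative(b, amplitude, tau_min)
        - _reference_antiderivative(a, amplitude, tau_min)
    ) / (b - a)
    return TAC.from_schedule(schedule, np.maximum(means, 0.0))


def srtm_target_curve(
    t_min: np.ndarray, amplitude: float, tau_min: float, params: KineticParams
) -> np.ndarray:
    """Closed-form SRTM target concentration for the gamma-variate reference.

    The convolution integral I(t) = int_0^t C_R(s) exp(-k2a (t-s)) ds has
    the closed form (alpha = 1/tau, beta = k2a, g = beta - alpha):

        I(t) = A [ exp(-alpha t) (t/g - 1/g^2) + exp(-beta t) / g^2 ]

    with the degenerate limit A exp(-alpha t) t^2 / 2 when beta == alpha.
    """
    t = np.asarray(t_min, dtype=float)
    alpha = 1.0 / tau_min
    beta = params.k2a
    if beta <= 0:
        raise ValueError("k2a must be positive")
    g = beta - alpha
    if abs(g) < 1e-4:
        # series in g = beta - alpha; the generic branch cancels
        # catastrophically through its 1/g^2 terms near degeneracy
        conv = (
            amplitude
            * np.exp(-alpha * t)
            * (t**2 / 2.0 - g * t**3 / 6.0 + g**2 * t**4 / 24.0)
        )
    else:
        conv = amplitude * (
            np.exp(-alpha * t) * (t / g - 1.0 / g**2) + np.exp(-beta * t) / g**2
        )
    cr = reference_curve(t, amplitude, tau_min)
    return params.r1 * cr + (params.k2 - params.r1 * beta) * conv


def simulate_target_tac(
    amplitude: float,
    tau_min: float,
    params: KineticParams,
    schedule: FrameSchedule,
    samples_per_frame: int = 64,
) -> TAC:
    """Frame-averaged SRTM target TAC (noiseless, deterministic).

    Within-frame averages are taken by composite Simpson quadrature of the
    closed-form curve, accurate far beyond the frame-quantisation level.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    n = samples_per_frame + (samples_per_frame % 2)  # Simpson needs even panels
    a = schedule.start_s / 60.0
    b = schedule.end_s / 60.0
    # per-frame sample grid: (n_frames, n+1)
    frac = np.linspace(0.0, 1.0, n + 1)
    grid = a[:, None] + (b - a)[:, None] * frac[None, :]
    vals = srtm_target_curve(grid, amplitude, tau_min, params)
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    means = (vals * w).sum(axis=1) / w.sum()
    return TAC.from_schedule(schedule, means)


@dataclass
class PhantomScene:
    """Tissue maps, label atlas and ground-truth kinetics of one phantom.

    Probability maps are in [0, 1] and sum to <= 1 voxel-wise; every
    non-zero atlas label must have kinetic parameters; the reference region
    (cerebellar-GM surrogate) must have BP_ND = 0.
    """

    gm_map: np.ndarray
    wm_map: np.ndarray
    csf_map: np.ndarray
    atlas: np.ndarray
    region_params: dict[int, KineticParams]
    reference_label: int
    wm_params: KineticParams = field(
        default_factory=lambda: KineticParams(r1=0.4, k2=0.15, bp_nd=0.05)
    )
    region_names: dict[int, str] = field(default_factory=dict)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        shp = self.atlas.shape
        for name in ("gm_map", "wm_map", "csf_map"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != shp:
                raise ValueError(f"{name} shape {m.shape} != atlas shape {shp}")
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, m)
        if np.any(self.gm_map + self.wm_map + self.csf_map > 1.0 + 1e-9):
            raise ValueError("tissue probabilities exceed 1 voxel-wise")
        labels = set(np.unique(self.atlas)) - {0}
        missing = labels - set(self.region_params)
        if missing:
            raise ValueError(f"atlas labels without kinetic params: {sorted(missing)}")
        if self.reference_label not in self.region_params:
            raise ValueError("reference label has no kinetic params")
        if self.region_params[self.reference_label].bp_nd != 0:
            raise ValueError("reference region must have BP_ND = 0 (DVR = 1)")

    def true_dvr(self) -> dict[int, float]:
        return {lab: p.dvr for lab, p in self.region_params.items()}

    def with_dvrs(self, dvrs: dict[int, float]) -> "PhantomScene":
        params = {
            lab: (p.with_dvr(dvrs[lab]) if lab in dvrs else p)
            for lab, p in self.region_params.items()
        }
        return PhantomScene(
            self.gm_map, self.wm_map, self.csf_map, self.atlas, params,
            self.reference_label, self.wm_params, dict(self.region_names),
            self.voxel_size_mm,
        )


# -- default scene geometry ------------------------------------------------

_CORTICAL_REGIONS = (
    list(BRAAK_LIMBIC_MEMBERS)
    + [
        "frontal_cortex",
        "parietal_cortex",
        "occipital_cortex",
        "superior_temporal_gyrus",
        "insular_cortex",
    ]
    + list(BRAAK_SPARED_ISOCORTEX)
)
REFERENCE_REGION = "cerebellum_gm"


def default_scene(
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: float = 2.0,
) -> PhantomScene:
    """A small digital head: a cerebral sphere with a WM core, a cortical
    shell partitioned into the named regions, and a cerebellar reference
    slab beneath.  Binary tissue maps; 2-mm voxels by default."""
    nx, ny, nz = shape
    x, y, z = np.indices(shape).astype(float)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    cz_cer = 0.56 * nz  # cerebrum centre
    r_brain = 0.34 * min(shape)
    r_wm = 0.19 * min(shape)

    d_cer = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz_cer) ** 2)
    cerebrum = d_cer <= r_brain
    wm = d_cer <= r_wm
    cortex = cerebrum & ~wm

    # cerebellar reference slab: wide cylinder beneath the cerebrum, so its
    # eroded interior is unaffected by PSF spill-over
    r_cb = 0.30 * min(nx, ny)
    in_cyl = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) <= r_cb
    cerebellum = in_cyl & (z >= 0.04 * nz) & (z <= 0.17 * nz) & ~cerebrum

    # partition the cortical shell into angular sectors x 2 z-bands
    n_regions = len(_CORTICAL_REGIONS)
    n_sectors = (n_regions + 1) // 2
    theta = np.mod(np.arctan2(y - cy, x - cx), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    band = (z >= cz_cer).astype(int)
    cell = band * n_sectors + sector
    cell = np.minimum(cell, n_regions - 1)  # fold any spare cell into the last

    atlas = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    params: dict[int, KineticParams] = {}
    for i, name in enumerate(_CORTICAL_REGIONS):
        lab = i + 1
        atlas[cortex & (cell == i)] = lab
        names[lab] = name
        params[lab] = KineticParams(r1=0.9, k2=0.15, bp_nd=0.0)
    ref_lab = n_regions + 1
    atlas[cerebellum] = ref_lab
    names[ref_lab] = REFERENCE_REGION
    params[ref_lab] = KineticParams(r1=1.0, k2=0.15, bp_nd=0.0)

    gm = ((atlas > 0)).astype(float)
    wm_map = wm.astype(float)
    csf = np.zeros(shape)
    return PhantomScene(
        gm, wm_map, csf, atlas, params, ref_lab,
        region_names=names,
        voxel_size_mm=(voxel_size_mm,) * 3,
    )


# -- rendering -------------------------------------------------------------

def psf_sigma_vox(
    fwhm_mm: float | tuple[float, float, float],
    voxel_size_mm: tuple[float, float, float],
) -> tuple[float, float, float]:
    f = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(f < 0):
        raise ValueError("FWHM must be non-negative")
    return tuple(f * FWHM_TO_SIGMA / np.asarray(voxel_size_mm))


def render_dynamic_image(
    scene: PhantomScene,
    schedule: FrameSchedule,
    psf_fwhm_mm: float = 0.0,
    noise_scale: float = 0.0,
    seed: int | np.random.Generator = 0,
    amplitude: float = 50.0,
    tau_min: float = 10.0,
) -> DynamicImage:
    """Render one subject's 4D dynamic image from a scene.

    Each voxel's noiseless value is ``gm * C_label + wm * C_wm`` (CSF
    carries no activity), blurred frame-by-frame with a Gaussian PSF, then
    degraded with zero-mean Gaussian noise of SD
    ``noise_scale * sqrt(value / frame_duration_min)``.  The same seed
    yields a bit-identical image.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be non-negative")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    nf = schedule.n_frames
    shape = scene.atlas.shape
    data = np.zeros(shape + (nf,), dtype=float)

    tacs = {
        lab: simulate_target_tac(amplitude, tau_min, p, schedule).values
        for lab, p in scene.region_params.items()
    }
    wm_tac = simulate_target_tac(amplitude, tau_min, scene.wm_params, schedule).values

    for lab, vals in tacs.items():
        m = scene.atlas == lab
        if m.any():
            data[m] += scene.gm_map[m, None] * vals[None, :]
    data[scene.wm_map > 0] += (
        scene.wm_map[scene.wm_map > 0, None] * wm_tac[None, :]
    )

    if psf_fwhm_mm > 0:
        sigma = psf_sigma_vox(psf_fwhm_mm, scene.voxel_size_mm)
        for f in range(nf):
            data[..., f] = ndimage.gaussian_filter(
                data[..., f], sigma=sigma, mode="constant", cval=0.0
            )

    if noise_scale > 0:
        sd = noise_scale * np.sqrt(
            np.maximum(data, 0.0) / schedule.duration_min[None, None, None, :]
        )
        data = data + rng.standard_normal(data.shape) * sd

    return DynamicImage(data, schedule, voxel_size_mm=scene.voxel_size_mm)


# -- cohorts ---------------------------------------------------------------

@dataclass
class GroupSpec:
    """Per-group cohort parameters: size and regional DVR distributions
    (mean, SD) for the Braak limbic members, the vulnerable isocortex and
    everything else (spared cortex, cerebellum kept at DVR 1)."""

    n: int
    limbic_dvr: tuple[float, float] = (1.02, 0.03)
    isocortical_dvr: tuple[float, float] = (1.02, 0.03)
    other_dvr: tuple[float, float] = (1.01, 0.02)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("each group needs n >= 1")
        for m, _ in (self.limbic_dvr, self.isocortical_dvr, self.other_dvr):
            if m < 1.0:
                raise ValueError("DVR means must be >= 1")


def default_groups() -> dict[str, GroupSpec]:
    """Study-like three-group design: healthy controls near DVR 1, tau
    elevated in limbic then isocortical regions with disease stage."""
    return {
        "HC": GroupSpec(n=7, limbic_dvr=(1.03, 0.03), isocortical_dvr=(1.02, 0.03)),
        "prodromal_AD": GroupSpec(
            n=7, limbic_dvr=(1.25, 0.06), isocortical_dvr=(1.15, 0.06)
        ),
        "AD_dementia": GroupSpec(
            n=6, limbic_dvr=(1.30, 0.08), isocortical_dvr=(1.25, 0.08)
        ),
    }


@dataclass
class CohortConfig:
    groups: dict[str, GroupSpec] = field(default_factory=default_groups)
    noise_scale: float = 0.05
    psf_fwhm_mm: float = 5.0
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    amplitude: float = 50.0
    tau_min: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group required")


@dataclass
class Subject:
    subject_id: str
    group: str
    dose_mbq: float
    weight_kg: float
    image: DynamicImage
    scene: PhantomScene
    true_dvr: dict[str, float]  # region name -> ground-truth DVR


def _truncated_normal(rng, mean, sd, low=1.0, tries=100):
    if sd == 0:
        return max(mean, low)
    for _ in range(tries):
        v = rng.normal(mean, sd)
        if v >= low:
            return v
    return low


def make_cohort(
    config: CohortConfig, schedule: FrameSchedule | None = None
) -> list[Subject]:
    """Simulate a cohort: per-subject regional DVRs drawn from the group
    distributions (truncated at 1), rendered onto the default scene."""
    schedule = schedule or FrameSchedule.thk5317()
    rng = np.random.default_rng(config.seed)
    base = default_scene(config.shape, config.voxel_size_mm)
    name_of = base.region_names
    limbic = set(BRAAK_LIMBIC_MEMBERS)
    spared = set(BRAAK_SPARED_ISOCORTEX) | {REFERENCE_REGION}

    subjects = []
    idx = 0
    for group, spec in config.groups.items():
        for _ in range(spec.n):
            idx += 1
            dvrs: dict[int, float] = {}
            for lab, name in name_of.items():
                if name == REFERENCE_REGION:
                    dvrs[lab] = 1.0
                elif name in limbic:
                    dvrs[lab] = _truncated_normal(rng, *spec.limbic_dvr)
                elif name in spared:
                    dvrs[lab] = _truncated_normal(rng, *spec.other_dvr)
                else:
                    dvrs[lab] = _truncated_normal(rng, *spec.isocortical_dvr)
            scene = base.with_dvrs(dvrs)
            img = render_dynamic_image(
                scene,
                schedule,
                psf_fwhm_mm=config.psf_fwhm_mm,
                noise_scale=config.noise_scale,
                seed=rng,
                amplitude=config.amplitude,
                tau_min=config.tau_min,
            )
            subjects.append(
                Subject(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    dose_mbq=float(np.clip(rng.normal(212.0, 42.0), 50.0, None)),
                    weight_kg=float(np.clip(rng.normal(72.0, 12.0), 40.0, None)),
                    image=img,
                    scene=scene,
                    true_dvr={name_of[l]: d for l, d in dvrs.items()},
                )
            )
    return subjects
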