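# Methods

## Problem and scope

`tauquant` quantifies dynamic tau-PET acquisitions and runs the group
analyses typically built on top of them: reference Logan DVR at ROI and
voxel level, SUV/SUVR images, Müller-Gärtner partial-volume correction
(PVC), Braak-composite ROI tables, test-retest reproducibility metrics,
and nonparametric group statistics (ROC/AUC, rank tests, z-score
abnormality maps, permutation T-maps with FDR, voxel-wise cross-tracer
correlation).  Because patient images cannot be redistributed, the package
carries a synthetic dynamic-PET phantom whose ground-truth kinetics are
known exactly, so every stage has a parameter-recovery test surface.
MRI segmentation, spatial normalisation and scanner reconstruction are out
of scope: tissue-probability maps, label atlases and aligned 4D volumes
are inputs.

## Forward model (phantom)

The reference-region concentration is a gamma-variate
`C_R(t) = A·t·exp(−t/τ)` (defaults A = 50 kBq/mL·min⁻¹, τ = 10 min, so the
curve peaks at 10 min at ≈ 184 kBq/mL).  A full plasma-input model would
add parameters without adding testable structure; the gamma variate is the
simplest curve whose SRTM convolution has a cheap closed form, giving an
independent numerical-convolution oracle for tests.

Target regions follow the simplified reference tissue model (SRTM):

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·(C_R ⊗ e^(−k2a·t)),   k2a = k2/(1+BP_ND)

with closed-form convolution (a second-order series branch handles the
degenerate case k2a → 1/τ, where the generic expression cancels
catastrophically).  Ground-truth DVR is 1 + BP_ND by construction.
Regional defaults R1 = 0.9, k2 = 0.15 min⁻¹ are plausible mid-range values
for a reversible tau tracer; white matter uses R1 = 0.4, BP_ND = 0.05.

Frame values are **within-frame time averages** (Simpson quadrature of the
closed form), matching how scanners report frames and how the Logan
integrals are later assembled — not midpoint samples.  The default frame
schedule is the 22-frame/60-min acquisition (6×10, 3×20, 2×30, 2×60,
2×150, 4×300, 3×600 s).

Rendering mixes regional curves by tissue probability
(`gm·C_label + wm·C_WM`, CSF activity-free), blurs each frame with an
isotropic Gaussian PSF (default FWHM 5 mm, a typical reconstructed
resolution for the scanners emulated), and adds zero-mean Gaussian noise
with SD = `noise_scale·sqrt(value/frame_duration_min)` — the standard
approximation for reconstructed PET, where variance scales with activity
and inversely with frame duration; Poisson count statistics, scatter,
attenuation and motion are not modelled.  Default `noise_scale` 0.05
yields ≈ 1–2 % relative noise on late 600-s frames at cortical activity
levels.  All randomness flows from one integer seed through a single
`numpy` generator; no global state.

The default scene is a 48³ grid of 2-mm voxels: a cerebral sphere with a
white-matter core, a cortical shell partitioned into 16 named regions
(the nine limbic Braak III–IV members, five vulnerable isocortical
regions, and the spared pre-/postcentral gyri), and a wide cerebellar
reference slab beneath the cerebrum.  The slab is deliberately large so
that an eroded interior exists in which PSF spill-over is negligible —
with a small reference region, spill-out dilutes the reference TAC and
inflates every DVR in the image.  Tissue maps are binary; partial-volume
structure enters through the PSF, not through probabilistic maps.

Cohort defaults (config-overridable): controls with all regions near
DVR 1.0 (limbic 1.03 ± 0.03), prodromal subjects limbic 1.25 ± 0.06 /
isocortical 1.15 ± 0.06, dementia-stage 1.30 ± 0.08 / 1.25 ± 0.08, with
draws truncated at DVR 1.  These qualitatively mirror the published
group boxplots (controls ≈ 1.0–1.1, AD isocortex ≈ 1.1–1.4 before PVC);
no quantitative per-group distributions are published, so the defaults
are a judgement call made once.  Injected dose is drawn at 212 ± 42 MBq
and weight at 72 ± 12 kg.

## Kinetic quantification

Reference Logan regresses `∫₀ᵗC/C(t)` on `∫₀ᵗC_ref/C(t)` over frames whose
mid-time lies in the 30–60 min window (for the default schedule: the three
600-s frames); the slope is the DVR.  Integrals are trapezoids on frame
mid-times with a leading triangle from (0, 0).  The simplified form
without the population-k2′ term is used — standard at late t* for tau and
amyloid tracers, where the k2′ correction is negligible; a `k2prime`
extension is deliberately not offered rather than shipped untested.
Frames with non-positive target activity in the window are dropped and
counted, never clipped.  Voxel-wise maps use the closed-form OLS slope on
the same coordinates; voxels failing the positivity precondition get NaN.

Known bias: the Logan slope is slightly negative-biased when washout is
slow relative to the fit window (small k2a, i.e. high DVR with low k2).
With k2 = 0.15 min⁻¹ the bias stays under 2 % for DVR ≤ 2; at k2 = 0.1
and DVR = 2 it reaches ≈ 4 %.  This is a property of the estimator at
this window, not an implementation artefact.

SUV is `C·weight/dose` (printed-definition form; concentration units are
the caller's).  SUVR divides the 40–60-min average image by the unweighted
mean over the reference mask.  The pipeline erodes the reference mask by
2 voxels before TAC/mean extraction to guard against edge partial-volume
effects (configurable; disabled if erosion would empty the mask).

## Partial-volume correction

Two-compartment Müller-Gärtner:

    corrected = (vol − C_WM·(WM ⊗ PSF)) / (GM ⊗ PSF)

with C_WM estimated as the mean over high-probability WM (p ≥ 0.99) eroded
by 6 mm (distance-transform erosion), where GM spill-in is negligible.
CSF is assumed activity-free.  Voxels with GM probability below 0.3 are
reported as NaN (coverage/noise trade-off); the blurred-GM denominator is
floored at 0.1 and floored voxels are counted.  The PSF FWHM is not
published for the original processing; the default is 8 mm, matching the
smoothing kernel used elsewhere in the analysis chain, and is
configurable.  Applying MG to a DVR map treats the correction as acting on
an (approximately) linearly mixed parametric image; since Logan DVR is not
a linear functional of the dynamic data, corrected hot-region values
overshoot truth by a few percent on the phantom — the qualitative effect
(range widening, hot regions raised) matches what PVC does on real DVR
images.

## ROI analysis

Atlases are GM-masked by binarising the GM probability map at 0.5 — the
single most consequential unstated constant of this processing style; it
is surfaced in the configuration and logged.  ROI means are unweighted
over in-ROI finite voxels (consistent with binarised masking semantics);
non-finite voxels are excluded and counted.  The `limbic` (Braak III–IV)
composite pools hippocampus, amygdala, parahippocampal, fusiform,
middle-inferior temporal, orbital and straight frontal gyri, temporal
poles and parieto-temporo-occipital junctions; `isocortical` (Braak V–VI)
pools all isocortical regions except the pre- and postcentral gyri.
Missing members are reported and skipped.  The composite mean equals the
voxel-count-weighted mean of member means (tested as an exact identity).

## Test-retest metrics

Signed relative difference is `100·(retest − test)/test` (deliberately
asymmetric).  The summary rows are the mean and the **sample SD (n−1) of
the absolute** % differences — the signed-SD interpretation does not
reproduce the published cells.  The ICC is
`(BIMSS − WIMSS)/(BIMSS + WIMSS)` with `BIMSS = 2·Σ(m̄ᵢ−ḡ)²/(n−1)` over
pair means and `WIMSS = Σdᵢ²/(2n)` over pair differences; the exact df
convention is not printed at source, and this choice reproduces the
robust published cells (frontal cortex 0.98 → 0.97 from 2-decimal
inputs).  Low-variance ROIs are not recoverable: the posterior cingulate
ICC (printed 0.52) is dominated by rounding of the 2-decimal inputs and
is documented rather than targeted.  The packaged five-patient table
ships the printed per-subject % rows as well as the DVR pairs because the
% rows were computed from unrounded values and cannot be regenerated from
the printed DVRs.

## Group statistics

AUC uses the rank/Mann-Whitney identity with midrank tie handling.
Rank tests: Kruskal-Wallis omnibus with two-sided Mann-Whitney post-hocs
at a Bonferroni-corrected alpha of 0.05/6 ≈ 0.008 (three groups × two
composite ROIs).  Abnormality maps are one-sided z > 1.96 against the
control mean/SD (only abnormally *high* retention is flagged), binarised
and summed across patients.  Smoothing is Gaussian, FWHM 8 mm in all
directions, respecting voxel size, zero-padded at the volume edge.

Permutation contrasts use a pooled-variance two-sample T per voxel and
random group-label shuffles; the observed labelling is always part of the
null, so p ≥ 1/(n_used+1).  When the requested permutation count reaches
the number of distinct labelings, the test switches to exhaustive
enumeration (logged in the map metadata).  Two-sided by default for group
contrasts.  Multiple comparisons are controlled with Benjamini-Hochberg
FDR at q = 0.05 — the named procedure is generic, and BH is the standard
choice.  The null sweep is chunked so whole-brain grids at 10k
permutations stay within ordinary memory.  The analysis mask should
restrict to brain/GM voxels; background voxels would inflate the FDR
denominator.

Voxel-wise cross-tracer correlation computes per-voxel Pearson r across
subjects with parametric p, thresholds at p < 0.001/0.01/0.05
uncorrected, separates positive from negative correlations, and filters
connected components (26-connectivity, SPM-family convention) below a
20-voxel extent.

## What the phantom does and does not show

The phantom validates the estimators: schedule handling, Logan recovery,
PVC inversion, composite bookkeeping, and the statistical machinery's
type-I behaviour.  It does not emulate arterial input variability,
scatter/attenuation residuals, motion, inter-subject anatomy, registration
error, or spatially correlated reconstruction noise — so passing recovery
tests bounds algorithmic error, not total real-data error.  Group
separations in the synthetic cohort are configured, so discrimination
results (AUC ≈ 1, significant rank tests) demonstrate qualitative
concordance with the published pattern, not a reproduction of patient
statistics (published patient AUCs and p-values depend on the original
images, which are unavailable).

## Problem sizes and numerical choices

Default phantom 48³ × 22 frames (≈ 0.6 s to render, ≈ 0.25 s for a
whole-volume Logan map); cohorts of 20 subjects quantify end-to-end in
well under a minute.  The test suite's null-calibration study uses 100
Monte-Carlo repeats of 500 permutations on a 24³ grid; the acceptance
script uses 40 repeats.  Ties in the Logan window selection are closed
intervals on frame mid-times; all tolerances asserted in tests are stated
inline with the property they check.
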