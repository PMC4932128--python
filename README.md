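# tauquant

Dynamic tau-PET quantification and group analysis, with a synthetic
dynamic-PET phantom so the whole pipeline is testable without patient
data.

Quantifying a tau tracer from a 60-min dynamic acquisition involves a
chain of steps that are easy to get subtly wrong: building time-activity
curves from frame-averaged data, estimating the distribution volume ratio
(DVR) with the reference Logan graphical method, correcting grey-matter
values for partial-volume dilution, pooling regions into Braak-stage
composites, and running nonparametric statistics across small clinical
groups.  `tauquant` implements that chain for researchers working with
reversible tau/amyloid tracers (and FDG SUVR), and ships a phantom
generator whose ground-truth kinetics are known exactly, so every stage
has a parameter-recovery test.

## The core quantities

* **Reference Logan DVR** — for target and reference TACs `C(t)`,
  `C_ref(t)`, regress `∫₀ᵗC/C(t)` on `∫₀ᵗC_ref/C(t)` over frames with
  mid-time in 30–60 min; the slope estimates `DVR = 1 + BP_ND`.
* **SUV / SUVR** — `SUV = C / (dose/weight)`; SUVR divides a 40–60-min
  average image by the cerebellar-GM (or pons, for FDG) reference mean.
  An isocortical SUVR of 1.41 is the amyloid-positivity cut-off.
* **Müller-Gärtner PVC** —
  `corrected = (vol − C_WM·(WM⊗PSF)) / (GM⊗PSF)` on voxels with GM
  probability ≥ 0.3, with `C_WM` from eroded deep white matter.
* **Test-retest** — signed % difference `100·(R−T)/T`, mean/SD of the
  absolute differences per ROI, and the ICC
  `(BIMSS−WIMSS)/(BIMSS+WIMSS)`.
* **Group statistics** — rank-identity ROC/AUC, Kruskal-Wallis +
  Mann-Whitney at Bonferroni-corrected α = 0.008, one-sided z > 1.96
  abnormality maps, permutation two-sample T-maps with
  Benjamini-Hochberg FDR (q < 0.05), and voxel-wise cross-tracer Pearson
  maps with a 20-voxel cluster-extent filter.

The phantom drives every region with the simplified reference tissue
model (SRTM) against a gamma-variate reference curve, renders
tissue-probability-weighted 4D images on the 22-frame/60-min schedule,
blurs with a Gaussian PSF and adds duration-dependent Gaussian noise.
See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
import numpy as np
from tauquant import (
    FrameSchedule, KineticParams, logan_dvr,
    simulate_reference_tac, simulate_target_tac,
)

schedule = FrameSchedule.thk5317()          # 22 frames, 3600 s
ref = simulate_reference_tac(50.0, 10.0, schedule)
params = KineticParams(r1=0.9, k2=0.15, bp_nd=0.5)   # true DVR = 1.5
tac = simulate_target_tac(50.0, 10.0, params, schedule)
fit = logan_dvr(tac, ref, tstar_window=(30, 60))
print(f"DVR = {fit.dvr:.4f} (true 1.5), "
      f"{fit.n_points_used} frames, R^2 = {fit.r_squared:.5f}")
```

prints

```
DVR = 1.4874 (true 1.5), 3 frames, R^2 = 1.00000
```

i.e. the Logan slope over the three late 600-s frames recovers the true
DVR to within 0.9 % — the small negative bias is the known behaviour of
the graphical method when washout is slow relative to the fit window.

The same machinery scales to cohorts.  `analysis/` contains numbered
drivers that narrate the full study flow — simulate a three-group cohort,
quantify DVR/SUVR, apply PVC, summarise test-retest reproducibility, and
run the group statistics — writing tidy tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_kinetics.py
python analysis/03_partial_volume_correction.py
python analysis/04_test_retest.py
python analysis/05_group_statistics.py
python analysis/06_cross_tracer_correlation.py
```

A `tauquant` console script exposes the per-stage operations
(`simulate`, `dvr`, `suv`, `suvr`, `pvc`, `trt`, `group`, `run`) for use
on on-disk NIfTI + TSV data; `tauquant run --out DIR --seed 1` executes
the default end-to-end pipeline.

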