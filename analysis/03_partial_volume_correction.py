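#!/usr/bin/env python
"""Partial-volume correction stage.

Two demonstrations: (i) the controlled two-tissue phantom (GM 1.4, WM 1.0,
8-mm PSF) where Muller-Gartner must restore the GM value; (ii) the cohort
ROI table, where correction should widen the DVR range and raise hot-region
values relative to the uncorrected quantification.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from tauquant.phantom import FWHM_TO_SIGMA, default_scene
from tauquant.pvc import PvcConfig, muller_gartner

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    scene = default_scene()
    gm, wm = scene.gm_map, scene.wm_map
    truth = 1.4 * gm + 1.0 * wm
    sigma = [8.0 * FWHM_TO_SIGMA / v for v in scene.voxel_size_mm]
    blurred = ndimage.gaussian_filter(truth, sigma=sigma, mode="constant")
    corrected, info = muller_gartner(
        blurred, gm, wm, PvcConfig(psf_fwhm_mm=8.0), scene.voxel_size_mm
    )
    sel = gm >= 0.5
    phantom_rows = pd.DataFrame(
        [
            {"quantity": "true_gm_value", "value": 1.4},
            {"quantity": "uncorrected_gm_mean", "value": float(blurred[sel].mean())},
            {"quantity": "corrected_gm_mean", "value": float(np.nanmean(corrected[sel]))},
            {"quantity": "wm_estimate", "value": info["wm_value"]},
        ]
    ).round(4)
    phantom_rows.to_csv(results / "pvc_phantom_recovery.tsv", sep="\t", index=False)
    print("two-tissue phantom:")
    print(phantom_rows.to_string(index=False))

    roi_path = results / "roi_values.tsv"
    if roi_path.exists():
        table = pd.read_csv(roi_path, sep="\t")
        comp = table[table["roi_name"].isin(["limbic", "isocortical"])]
        spread = (
            comp.groupby(["roi_name", "quantification"])["value"]
            .agg(["min", "max", "mean"])
            .round(4)
        )
        spread["range"] = (spread["max"] - spread["min"]).round(4)
        spread.to_csv(results / "pvc_range_comparison.tsv", sep="\t")
        print("\ncomposite-ROI value spread (dvr vs dvr_pvc):")
        print(spread.to_string())
    else:
        print("\n(roi_values.tsv not found; run 02_quantify_kinetics.py first)")


if __name__ == "__main__":
    main()
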