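"""ROI- and voxel-level group statistics.

ROI level: ROC/AUC discrimination per region, Kruskal-Wallis omnibus with
Bonferroni-corrected Mann-Whitney post-hocs (corrected alpha 0.05/6 = 0.008
for the three-group x two-composite-ROI design), and Pearson correlation
matrices across tracers.

Voxel level: z-score abnormality maps against a control mean/SD (one-sided,
z > 1.96), their binarised sums, Gaussian smoothing (FWHM 8 mm), two-sample
permutation T-maps with Benjamini-Hochberg FDR (q < 0.05), and voxel-wise
cross-tracer Pearson correlation with a cluster-extent filter
(26-connectivity, default 20 voxels).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .phantom import FWHM_TO_SIGMA

BONFERRONI_ALPHA_3G_2ROI = 0.05 / 6  # three groups x two composite ROIs


@dataclass
class StatMap:
    """A 3D statistic volume with its thresholding metadata."""

    values: np.ndarray
    kind: str  # z | t | r | p | count
    threshold: float | None = None
    correction: str = "none"  # none | fdr | bonferroni
    cluster_extent_voxels: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.kind == "p" and np.nanmax(self.values, initial=0.0) > 1.0:
            raise ValueError("p-map values must lie in [0, 1]")
        if self.kind == "r":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
                raise ValueError("r-map values must lie in [-1, 1]")


# -- ROI-level -------------------------------------------------------------

def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for discriminating ``labels == 1`` from
    ``labels == 0`` by ``values``, via the rank (Mann-Whitney U) identity;
    tied value pairs contribute one half."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)  # midranks handle ties
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roi_auc_table(table: pd.DataFrame, design: dict[str, str], positive_groups: set[str]) -> pd.DataFrame:
    """Per-ROI AUC for discriminating the positive groups (e.g. all AD)
    from the rest, from a tidy ROI table (subject_id, roi_name, value)."""
    rows = []
    for roi, sub in table.groupby("roi_name", sort=False):
        labs = np.array([1 if design[s] in positive_groups else 0 for s in sub["subject_id"]])
        rows.append({"roi_name": roi, "auc": roc_auc(sub["value"].to_numpy(), labs),
                     "n_pos": int(labs.sum()), "n_neg": int((1 - labs).sum())})
    return pd.DataFrame(rows)


def kruskal_mannwhitney(
    groups: dict[str, np.ndarray], alpha_corrected: float = BONFERRONI_ALPHA_3G_2ROI
) -> dict:
    """Kruskal-Wallis omnibus over >= 2 groups plus pairwise two-sided
    Mann-Whitney tests flagged at the Bonferroni-corrected alpha."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    kw_stat, kw_p = stats.kruskal(*arrays.values())
    pairwise = {}
    for a, b in itertools.combinations(arrays, 2):
        res = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        pairwise[(a, b)] = {
            "u": float(res.statistic),
            "p": float(res.pvalue),
            "significant": bool(res.pvalue < alpha_corrected),
        }
    return {
        "kruskal_h": float(kw_stat),
        "kruskal_p": float(kw_p),
        "alpha_corrected": float(alpha_corrected),
        "pairwise": pairwise,
    }


def roi_correlation_matrix(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and p) between every ROI of modality A and every ROI of
    modality B across their shared subjects."""
    pa = table_a.pivot(index="subject_id", columns="roi_name", values="value")
    pb = table_b.pivot(index="subject_id", columns="roi_name", values="value")
    shared = pa.index.intersection(pb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared subjects")
    pa, pb = pa.loc[shared], pb.loc[shared]
    r = pd.DataFrame(index=pa.columns, columns=pb.columns, dtype=float)
    p = r.copy()
    for ra in pa.columns:
        for rb in pb.columns:
            res = stats.pearsonr(pa[ra], pb[rb])
            r.loc[ra, rb] = res.statistic
            p.loc[ra, rb] = res.pvalue
    return r, p


# -- voxel-level -----------------------------------------------------------

def zscore_map(
    patient_vol: np.ndarray,
    control_mean: np.ndarray,
    control_sd: np.ndarray,
    z_threshold: float = 1.96,
    sd_floor: float = 1e-6,
) -> tuple[StatMap, np.ndarray]:
    """Patient-vs-controls z map and its one-sided abnormally-high mask
    (z > threshold).  Zero-SD voxels are floored to avoid infinities."""
    patient_vol = np.asarray(patient_vol, dtype=float)
    if patient_vol.shape != np.shape(control_mean) or patient_vol.shape != np.shape(control_sd):
        raise ValueError("patient/control volumes must share shape")
    sd = np.maximum(np.asarray(control_sd, dtype=float), sd_floor)
    z = (patient_vol - np.asarray(control_mean, dtype=float)) / sd
    return (
        StatMap(z, kind="z", threshold=z_threshold, correction="none"),
        z > z_threshold,
    )


def abnormality_count_map(binary_maps: list[np.ndarray]) -> StatMap:
    """Voxel-wise sum of per-subject binarised abnormality maps."""
    if not binary_maps:
        raise ValueError("no maps given")
    shape = np.shape(binary_maps[0])
    total = np.zeros(shape, dtype=int)
    for m in binary_maps:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("binary maps must share shape")
        total += m.astype(bool).astype(int)
    return StatMap(total, kind="count", meta={"n_subjects": len(binary_maps)})


def smooth_image(
    vol: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> np.ndarray:
    """Gaussian smoothing with the given FWHM (mm) in all directions,
    respecting voxel size.  Zero-padded boundaries (activity leaks out at
    the edge of the field of view, as in scanner space)."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(vol, dtype=float)
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), sigma=sigma, mode="constant")


def _tstat_two_sample(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample T per voxel; data is (n_subjects, n_vox),
    ``is_a`` a boolean label vector (may be 2-D: (n_perm, n_subjects))."""
    is_a = np.atleast_2d(is_a)
    n = data.shape[0]
    na = is_a.sum(axis=1, keepdims=True).astype(float)
    nb = n - na
    sum_all = data.sum(axis=0)[None, :]
    sumsq_all = (data**2).sum(axis=0)[None, :]
    sum_a = is_a.astype(float) @ data
    sumsq_a = is_a.astype(float) @ (data**2)
    sum_b = sum_all - sum_a
    sumsq_b = sumsq_all - sumsq_a
    mean_a = sum_a / na
    mean_b = sum_b / nb
    ss_a = sumsq_a - na * mean_a**2
    ss_b = sumsq_b - nb * mean_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss_a + ss_b) / (na + nb - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def permutation_twosample(
    images_a: list[np.ndarray],
    images_b: list[np.ndarray],
    mask: np.ndarray | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    fdr_q: float = 0.05,
    two_sided: bool = True,
) -> dict[str, StatMap]:
    """Voxel-wise two-sample permutation test with FDR correction.

    The null distribution is built from random group-label shuffles and
    always includes the observed labelling, so p >= 1/(n_used + 1).  If
    ``n_permutations`` meets or exceeds the number of distinct labelings,
    the test switches to exhaustive enumeration.  Returns 't', 'p' and
    'mask' (Benjamini-Hochberg significance at ``fdr_q``) StatMaps.
    """
    na, nb = len(images_a), len(images_b)
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    shape = np.shape(images_a[0])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    data = np.stack([np.asarray(v, dtype=float)[mask] for v in images_a + images_b])
    n = na + nb
    observed = np.zeros(n, dtype=bool)
    observed[:na] = True

    n_distinct = math.comb(n, na)
    exhaustive = n_permutations >= n_distinct
    if exhaustive:
        labelings = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), na)):
            labelings[i, list(idx)] = True
    else:
        rng = np.random.default_rng(seed)
        labelings = np.zeros((n_permutations + 1, n), dtype=bool)
        labelings[0] = observed  # the observed labelling counts in the null
        for i in range(1, n_permutations + 1):
            labelings[i, rng.choice(n, size=na, replace=False)] = True

    t_obs = _tstat_two_sample(data, observed)[0]
    # chunk the null sweep: a full (n_perm x n_voxel) T matrix would not fit
    # in memory for whole-brain grids at 10k permutations
    n_lab = labelings.shape[0]
    exceed_counts = np.zeros(data.shape[1], dtype=np.int64)
    chunk = max(1, int(2e7 // max(data.shape[1], 1)))
    for lo in range(0, n_lab, chunk):
        t_null = _tstat_two_sample(data, labelings[lo : lo + chunk])
        if two_sided:
            exceed_counts += (
                np.abs(t_null) >= np.abs(t_obs)[None, :] - 1e-12
            ).sum(axis=0)
        else:
            exceed_counts += (t_null >= t_obs[None, :] - 1e-12).sum(axis=0)
    p = exceed_counts / n_lab

    reject, _, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")[:4]

    def to_vol(flat, fill=np.nan, dtype=float):
        out = np.full(shape, fill, dtype=dtype)
        out[mask] = flat
        return out

    meta = {
        "n_permutations_used": int(labelings.shape[0]),
        "exhaustive": exhaustive,
        "two_sided": two_sided,
    }
    return {
        "t": StatMap(to_vol(t_obs), kind="t", meta=meta),
        "p": StatMap(to_vol(p, fill=1.0), kind="p", meta=meta),
        "mask": StatMap(
            to_vol(reject, fill=False, dtype=bool),
            kind="p",
            threshold=fdr_q,
            correction="fdr",
            meta=meta,
        ),
    }


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def cluster_filter(
    sig: np.ndarray, cluster_extent: int, stat: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep 26-connected components of a significance mask with extent >=
    ``cluster_extent`` voxels; returns the filtered mask and a cluster
    table (cluster_id, size, peak statistic, peak voxel index)."""
    sig = np.asarray(sig, dtype=bool)
    labelled, n = ndimage.label(sig, structure=_CONN26)
    keep = np.zeros_like(sig)
    rows = []
    cid = 0
    for lab in range(1, n + 1):
        comp = labelled == lab
        size = int(comp.sum())
        if size < cluster_extent:
            continue
        cid += 1
        keep |= comp
        if stat is not None:
            vals = np.where(comp, np.asarray(stat, dtype=float), np.nan)
            peak_idx = np.unravel_index(np.nanargmax(np.abs(vals)), vals.shape)
            peak = float(vals[peak_idx])
        else:
            peak_idx, peak = tuple(int(i[0]) for i in np.nonzero(comp)), float("nan")
        rows.append(
            {
                "cluster_id": cid,
                "size_voxels": size,
                "peak_stat": peak,
                "peak_i": int(peak_idx[0]),
                "peak_j": int(peak_idx[1]),
                "peak_k": int(peak_idx[2]),
            }
        )
    return keep, pd.DataFrame(
        rows, columns=["cluster_id", "size_voxels", "peak_stat", "peak_i", "peak_j", "peak_k"]
    )


def voxelwise_correlation(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    mask: np.ndarray | None = None,
    p_thresholds: tuple[float, ...] = (0.001, 0.01, 0.05),
    cluster_extent: int = 20,
) -> dict:
    """Voxel-wise cross-modality Pearson correlation across subjects.

    For each uncorrected p threshold, positively and negatively correlated
    voxels are thresholded separately and filtered by 26-connected cluster
    extent.  Returns r and p StatMaps plus per-threshold signed masks and
    cluster tables.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("modalities must cover the same subjects, in order")
    n = len(maps_a)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    shape = np.shape(maps_a[0])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    a = np.stack([np.asarray(v, dtype=float)[mask] for v in maps_a])
    b = np.stack([np.asarray(v, dtype=float)[mask] for v in maps_b])

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=0) / np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-15))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    def to_vol(flat, fill=np.nan):
        out = np.full(shape, fill)
        out[mask] = flat
        return out

    r_vol, p_vol = to_vol(r), to_vol(p, fill=1.0)
    results = {
        "r": StatMap(r_vol, kind="r"),
        "p": StatMap(p_vol, kind="p"),
        "thresholded": {},
    }
    for thr in p_thresholds:
        sig = (p_vol < thr) & np.isfinite(r_vol)
        out_signed = {}
        for sign, m in (("positive", sig & (r_vol > 0)), ("negative", sig & (r_vol < 0))):
            kept, table = cluster_filter(m, cluster_extent, stat=r_vol)
            out_signed[sign] = {
                "mask": StatMap(
                    kept, kind="p", threshold=thr, correction="none",
                    cluster_extent_voxels=cluster_extent,
                ),
                "clusters": table,
            }
        results["thresholded"][thr] = out_signed
    return results
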