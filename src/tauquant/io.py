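"""File I/O: NIfTI volumes, frame-timing sidecars, manifests, provenance.

Conventions: NIfTI-1 with an RAS affine; frame timing as a TSV sidecar with
columns ``frame_index, start_s, duration_s``; all tables tidy TSV; voxel
indices 0-based; world coordinates in mm.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import DynamicImage, FrameSchedule
from .phantom import Subject
from .roi import LabelAtlas


def write_volume(vol: np.ndarray, path: str | Path, affine: np.ndarray | None = None,
                 voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_timing(schedule: FrameSchedule, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame_index": np.arange(schedule.n_frames),
            "start_s": schedule.start_s,
            "duration_s": schedule.duration_s,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_timing(path: str | Path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t").sort_values("frame_index")
    return FrameSchedule(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def write_dynamic_image(img: DynamicImage, nifti_path: str | Path) -> tuple[Path, Path]:
    """Write a 4D NIfTI plus its ``*_timing.tsv`` sidecar."""
    nifti_path = Path(nifti_path)
    nib.save(
        nib.Nifti1Image(img.data.astype(np.float32), img.affine), str(nifti_path)
    )
    stem = nifti_path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    timing_path = nifti_path.with_name(stem + "_timing.tsv")
    write_timing(img.schedule, timing_path)
    return nifti_path, timing_path


def read_dynamic_image(
    nifti_path: str | Path, timing_path: str | Path
) -> DynamicImage:
    img = nib.load(str(nifti_path))
    schedule = read_timing(timing_path)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(
        np.asarray(img.get_fdata(), dtype=float), schedule,
        voxel_size_mm=voxel, affine=np.asarray(img.affine),
    )


def write_atlas(atlas: LabelAtlas, nifti_path: str | Path, names_path: str | Path,
                voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> None:
    """Label volume as int NIfTI; name table as TSV (label, name,
    composite memberships as a comma-joined column)."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(nifti_path))
    member_of = {
        lab: ",".join(sorted(c for c, mem in atlas.composites.items() if lab in mem))
        for lab in atlas.names
    }
    pd.DataFrame(
        [
            {"label": lab, "name": name, "composites": member_of[lab]}
            for lab, name in sorted(atlas.names.items())
        ]
    ).to_csv(names_path, sep="\t", index=False)


def read_atlas(nifti_path: str | Path, names_path: str | Path) -> LabelAtlas:
    labels = np.asarray(nib.load(str(nifti_path)).get_fdata()).astype(np.int32)
    df = pd.read_csv(names_path, sep="\t").fillna({"composites": ""})
    names = {int(r.label): str(r.name) for r in df.itertuples()}
    composites: dict[str, set[int]] = {}
    for r in df.itertuples():
        for c in str(r.composites).split(","):
            if c:
                composites.setdefault(c, set()).add(int(r.label))
    return LabelAtlas(labels, names, {c: frozenset(m) for c, m in composites.items()})


def write_cohort(subjects: list[Subject], outdir: str | Path) -> Path:
    """Write per-subject 4D NIfTI + timing sidecars, shared tissue maps and
    atlas, per-subject ground-truth DVR tables, and a cohort manifest TSV.
    Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    scene0 = subjects[0].scene
    vox = scene0.voxel_size_mm
    affine = np.diag(list(vox) + [1.0])
    for name, arr in (
        ("gm_prob", scene0.gm_map),
        ("wm_prob", scene0.wm_map),
        ("csf_prob", scene0.csf_map),
    ):
        write_volume(arr, outdir / f"{name}.nii.gz", affine=affine)
    nib.save(
        nib.Nifti1Image(scene0.atlas.astype(np.int16), affine),
        str(outdir / "atlas.nii.gz"),
    )
    pd.DataFrame(
        [{"label": lab, "name": n} for lab, n in sorted(scene0.region_names.items())]
    ).to_csv(outdir / "atlas_names.tsv", sep="\t", index=False)

    for sub in subjects:
        nii, timing = write_dynamic_image(
            sub.image, outdir / f"{sub.subject_id}_dyn.nii.gz"
        )
        truth = outdir / f"{sub.subject_id}_truth.tsv"
        pd.DataFrame(
            [{"roi_name": r, "true_dvr": d} for r, d in sub.true_dvr.items()]
        ).to_csv(truth, sep="\t", index=False)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "dose_MBq": round(sub.dose_mbq, 2),
                "weight_kg": round(sub.weight_kg, 2),
                "dynamic_nifti": nii.name,
                "timing_tsv": timing.name,
                "truth_tsv": truth.name,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "dynamic_nifti", "timing_tsv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_provenance(outdir: str | Path, config: dict, seed: int) -> Path:
    from . import __version__

    path = Path(outdir) / "provenance.json"
    record = {
        "package": "tauquant",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
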