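"""Grey-matter-masked atlases, Braak-stage composite ROIs, and per-subject
ROI value tables.

The composite ROIs follow the neuropathological staging of tau spread:
``limbic`` (Braak III-IV) pools the hippocampi, amygdalae, parahippocampal,
fusiform, middle-inferior temporal, orbital and straight frontal gyri,
temporal poles and parieto-temporo-occipital junctions; ``isocortical``
(Braak V-VI) pools all isocortical regions except the precentral and
postcentral gyri, which are typically spared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Region names of the limbic (Braak III-IV) composite, as used by the
# phantom atlas; for a real probabilistic atlas the mapping is user-supplied.
BRAAK_LIMBIC_MEMBERS = (
    "hippocampus",
    "amygdala",
    "parahippocampal_gyrus",
    "fusiform_gyrus",
    "middle_inferior_temporal_gyrus",
    "orbitofrontal_cortex",
    "straight_frontal_gyrus",
    "temporal_pole",
    "parietotemporooccipital_junction",
)

# Isocortical regions excluded from the Braak V-VI composite.
BRAAK_SPARED_ISOCORTEX = ("precentral_gyrus", "postcentral_gyrus")


@dataclass
class LabelAtlas:
    """Integer label volume with a name table and optional composites.

    Label 0 is reserved for background.  ``composites`` maps a composite
    name to the set of member labels.
    """

    labels: np.ndarray
    names: dict[int, str]
    composites: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        for cname, members in self.composites.items():
            unknown = set(members) - set(self.names)
            if unknown:
                raise ValueError(f"composite {cname!r} references unknown labels {unknown}")

    @property
    def label_of(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    def mask(self, roi: str) -> np.ndarray:
        """Boolean mask of a named region or composite."""
        if roi in self.composites:
            return np.isin(self.labels, list(self.composites[roi]))
        lab = self.label_of.get(roi)
        if lab is None:
            raise KeyError(f"unknown ROI {roi!r}")
        return self.labels == lab


def build_gm_atlas(
    atlas: LabelAtlas, gm_map: np.ndarray, gm_binarise_threshold: float = 0.5
) -> LabelAtlas:
    """GM-mask an atlas: keep labels only where the binarised GM
    probability is at or above threshold.  ROIs emptied by the masking are
    reported with a warning; masking never adds voxels."""
    if not 0.0 <= gm_binarise_threshold <= 1.0:
        raise ValueError("gm_binarise_threshold must lie in [0, 1]")
    gm_map = np.asarray(gm_map, dtype=float)
    if gm_map.shape != atlas.labels.shape:
        raise ValueError("gm_map shape does not match atlas")
    keep = gm_map >= gm_binarise_threshold
    masked = np.where(keep, atlas.labels, 0)
    emptied = [
        name
        for lab, name in atlas.names.items()
        if (atlas.labels == lab).any() and not (masked == lab).any()
    ]
    if emptied:
        warnings.warn(f"ROIs emptied by GM masking: {emptied}", stacklevel=2)
    return LabelAtlas(masked, dict(atlas.names), dict(atlas.composites))


def composite_rois(
    atlas: LabelAtlas,
    limbic_members: tuple[str, ...] = BRAAK_LIMBIC_MEMBERS,
    isocortical_excluded: tuple[str, ...] = BRAAK_SPARED_ISOCORTEX,
    isocortical_members: tuple[str, ...] | None = None,
) -> LabelAtlas:
    """Add the ``limbic`` and ``isocortical`` Braak composites.

    ``isocortical_members`` defaults to every named region that is neither
    a limbic member, an excluded (spared) region, nor a cerebellar/brainstem
    reference.  Missing members are reported and skipped; a composite with
    zero available members is an error.
    """
    label_of = atlas.label_of
    missing = [m for m in limbic_members if m not in label_of]
    if missing:
        warnings.warn(f"limbic members absent from atlas: {missing}", stacklevel=2)
    limbic = frozenset(label_of[m] for m in limbic_members if m in label_of)
    if not limbic:
        raise ValueError("no limbic members available in atlas")

    if isocortical_members is None:
        non_iso = set(limbic_members) | set(isocortical_excluded)
        non_iso |= {n for n in label_of if "cerebell" in n or "pons" in n}
        isocortical_members = tuple(n for n in label_of if n not in non_iso)
    else:
        isocortical_members = tuple(
            n for n in isocortical_members if n not in set(isocortical_excluded)
        )
    iso = frozenset(
        label_of[m] for m in isocortical_members if m in label_of
    )
    if not iso:
        raise ValueError("no isocortical members available in atlas")

    composites = dict(atlas.composites)
    composites["limbic"] = limbic
    composites["isocortical"] = iso
    return LabelAtlas(atlas.labels, dict(atlas.names), composites)


def extract_roi_means(
    vol: np.ndarray,
    atlas: LabelAtlas,
    subject_id: str = "",
    quantification: str = "dvr",
) -> pd.DataFrame:
    """Unweighted per-ROI means of a 3D image over finite in-ROI voxels.

    Returns a tidy table with one row per (subject_id, roi_name):
    columns subject_id, roi_name, value, n_voxels, n_missing,
    quantification.  Empty ROIs are omitted with a warning; non-finite
    voxels are excluded and counted in ``n_missing``.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.shape != atlas.labels.shape:
        raise ValueError("image shape does not match atlas")
    rows = []
    rois = [(name, atlas.labels == lab) for lab, name in atlas.names.items()]
    rois += [(cname, atlas.mask(cname)) for cname in atlas.composites]
    for name, mask in rois:
        vals = vol[mask]
        finite = np.isfinite(vals)
        if not finite.any():
            if mask.any():
                warnings.warn(f"ROI {name!r} has no finite voxels; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "roi_name": name,
                "value": float(vals[finite].mean()),
                "n_voxels": int(finite.sum()),
                "n_missing": int((~finite).sum()),
                "quantification": quantification,
            }
        )
    return pd.DataFrame(rows)
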