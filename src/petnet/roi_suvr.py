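"""ROI SUV extraction from spatially normalized PET volumes, and SUVR.

Per-ROI SUV is the unweighted arithmetic mean of finite PET voxel values
under each atlas label; SUVR divides every ROI mean by the mean over the
whole-cerebellum reference labels, removing global-uptake variation.

Inputs must already live on the atlas grid: registration, smoothing and
skull stripping are upstream, third-party steps and are deliberately out of
scope here — only grid compatibility is checked.  No partial-volume
correction is applied.

The shipped 109-region label table (``data/atlas_labels_109.tsv``) is a
reconstruction of a bilateral cortical + subcortical parcellation in the
Harvard-Oxford style, with left/right cerebellum as the reference labels;
users with their own atlas supply their own table.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "LabelAtlas",
    "SUVVector",
    "load_atlas",
    "default_label_table",
    "extract_roi_means",
    "to_suvr",
    "tabulate_cohort",
    "make_phantom",
    "write_phantom_nifti",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelAtlas:
    """Integer label volume plus the ordered ROI list and reference labels.

    Label 0 is background by convention.  The reference set (whole
    cerebellum) need not be disjoint from the analysis ROIs, but any overlap
    is logged.
    """

    label_volume: np.ndarray
    roi_labels: list[tuple[int, str]]
    reference_label_ids: frozenset[int]

    def __post_init__(self) -> None:
        vol = np.asarray(self.label_volume)
        if not np.issubdtype(vol.dtype, np.integer):
            if not np.allclose(vol, np.round(vol)):
                raise ValueError("label volume must contain integer labels")
            vol = np.round(vol).astype(np.int32)
        self.label_volume = vol
        self.reference_label_ids = frozenset(int(i) for i in self.reference_label_ids)
        if not self.reference_label_ids:
            raise ValueError("reference_label_ids must be nonempty")
        present = set(np.unique(vol).tolist())
        missing = [lid for lid, _ in self.roi_labels if lid not in present]
        if missing:
            raise ValueError(f"atlas labels absent from label volume: {missing[:10]}")
        missing_ref = self.reference_label_ids - present
        if missing_ref:
            raise ValueError(f"reference labels absent from label volume: {sorted(missing_ref)}")
        overlap = self.reference_label_ids & {lid for lid, _ in self.roi_labels}
        if overlap:
            logger.warning(
                "reference labels overlap analysis ROIs: %s", sorted(overlap)
            )

    @property
    def roi_names(self) -> list[str]:
        return [name for _, name in self.roi_labels]


@dataclass
class SUVVector:
    """Per-ROI mean SUV and the reference-region mean."""

    suv: np.ndarray
    reference_suv: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=float)
        if self.reference_suv <= 0:
            raise ValueError("reference SUV must be positive")


def default_label_table() -> pd.DataFrame:
    """The packaged 109-ROI label table (columns label_id, roi_name,
    is_reference)."""
    ref = importlib.resources.files("petnet") / "data" / "atlas_labels_109.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_atlas(
    atlas_path,
    labels: pd.DataFrame | None = None,
    reference_label_ids: set[int] | None = None,
) -> LabelAtlas:
    """Read a NIfTI label volume; labels default to the packaged table.

    Reference ids default to rows with ``is_reference == 1`` in the table.
    """
    table = labels if labels is not None else default_label_table()
    if reference_label_ids is None:
        if "is_reference" not in table.columns:
            raise ValueError("label table has no is_reference column and no "
                             "reference ids were given")
        reference_label_ids = set(
            table.loc[table["is_reference"] == 1, "label_id"].astype(int)
        )
    roi_rows = table[~table["label_id"].isin(reference_label_ids)] \
        if "is_reference" not in table.columns else table[table["is_reference"] == 0]
    roi_labels = list(
        zip(roi_rows["label_id"].astype(int), roi_rows["roi_name"].astype(str))
    )
    vol = np.asanyarray(nib.load(str(atlas_path)).dataobj)
    return LabelAtlas(vol, roi_labels, frozenset(reference_label_ids))


def extract_roi_means(pet_volume: np.ndarray, atlas: LabelAtlas) -> SUVVector:
    """Mean finite PET value per atlas ROI, plus the reference-region mean.

    NaN voxels (outside the brain) are excluded from every mean.  An ROI
    with no finite voxel, a grid mismatch, or a non-positive reference mean
    is an error.
    """
    pet = np.asarray(pet_volume, dtype=float)
    labels = atlas.label_volume
    if pet.shape != labels.shape:
        raise ValueError(
            f"PET grid {pet.shape} does not match atlas grid {labels.shape}"
        )
    finite = np.isfinite(pet)

    def region_mean(label_ids, what: str) -> float:
        mask = np.isin(labels, list(label_ids)) & finite
        if not mask.any():
            raise ValueError(f"no finite voxels in {what}")
        return float(pet[mask].mean())

    means = np.array(
        [region_mean([lid], f"ROI {name!r} (label {lid})") for lid, name in atlas.roi_labels]
    )
    ref = region_mean(atlas.reference_label_ids, "reference region")
    if ref <= 0:
        raise ValueError(f"reference mean SUV is non-positive ({ref})")
    return SUVVector(means, ref, atlas.roi_names)


def to_suvr(suv: SUVVector) -> np.ndarray:
    """SUVR = SUV_ROI / SUV_reference, elementwise."""
    out = suv.suv / suv.reference_suv
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite SUVR values")
    return out


def tabulate_cohort(image_manifest, atlas: LabelAtlas) -> CohortTable:
    """Extract SUVR for every subject in a manifest into one cohort table.

    ``image_manifest`` is a DataFrame (or path to CSV) with columns
    ``subject_id, group, age, sex, pet_path``.  ROI column order comes from
    the atlas ROI list.  Any per-subject failure aborts, naming the subject.
    """
    if not isinstance(image_manifest, pd.DataFrame):
        image_manifest = pd.read_csv(image_manifest)
    if image_manifest.empty:
        raise ValueError("no subjects in manifest")
    required = {"subject_id", "group", "age", "sex", "pet_path"}
    missing = required - set(image_manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for rec in image_manifest.itertuples(index=False):
        try:
            pet = np.asanyarray(nib.load(str(rec.pet_path)).dataobj, dtype=float)
            suvr = to_suvr(extract_roi_means(pet, atlas))
        except Exception as exc:
            raise ValueError(f"subject {rec.subject_id!r}: {exc}") from exc
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "age": rec.age, "sex": rec.sex, **dict(zip(atlas.roi_names, suvr))}
        )
    return CohortTable(pd.DataFrame(rows))


# --------------------------------------------------------------------- #
# synthetic phantom fixtures


def make_phantom(
    shape: tuple[int, int, int] = (10, 10, 10),
    n_rois: int = 4,
    roi_values: np.ndarray | None = None,
    reference_value: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, LabelAtlas]:
    """Synthetic PET volume + atlas pair with known per-ROI intensities.

    The grid is split into ``n_rois`` analysis slabs (labels 1..n) plus one
    reference slab (label ``n+1``); voxels in ROI k take ``roi_values[k]``
    exactly, so expected SUV means and SUVR ratios are known in closed form.
    Intended for tests and worked examples, not as a realistic scan.
    """
    rng = np.random.default_rng(seed)
    if roi_values is None:
        roi_values = rng.uniform(1.0, 5.0, size=n_rois)
    roi_values = np.asarray(roi_values, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    nx_ = shape[0]
    slabs = np.array_split(np.arange(nx_), n_rois + 1)
    for k, slab in enumerate(slabs[:-1]):
        labels[slab, :, :] = k + 1
    labels[slabs[-1], :, :] = n_rois + 1
    pet = np.zeros(shape, dtype=float)
    for k in range(n_rois):
        pet[labels == k + 1] = roi_values[k]
    pet[labels == n_rois + 1] = reference_value
    roi_labels = [(k + 1, f"phantom_roi_{k + 1}") for k in range(n_rois)]
    atlas = LabelAtlas(labels, roi_labels, frozenset({n_rois + 1}))
    return pet, atlas


def write_phantom_nifti(
    out_dir,
    shape: tuple[int, int, int] = (10, 10, 10),
    n_rois: int = 4,
    roi_values: np.ndarray | None = None,
    reference_value: float = 2.0,
    seed: int = 0,
) -> tuple[str, str, str]:
    """Write a phantom PET volume, its atlas, and a label TSV to disk;
    returns (pet_path, atlas_path, labels_path)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    pet, atlas = make_phantom(shape, n_rois, roi_values, reference_value, seed)
    affine = np.eye(4)
    pet_path = os.path.join(out_dir, "phantom_pet.nii.gz")
    atlas_path = os.path.join(out_dir, "phantom_atlas.nii.gz")
    labels_path = os.path.join(out_dir, "phantom_labels.tsv")
    nib.Nifti1Image(pet.astype(np.float32), affine).to_filename(pet_path)
    nib.Nifti1Image(atlas.label_volume.astype(np.int16), affine).to_filename(atlas_path)
    rows = [
        {"label_id": lid, "roi_name": name, "is_reference": 0}
        for lid, name in atlas.roi_labels
    ]
    rows.append(
        {"label_id": n_rois + 1, "roi_name": "phantom_reference", "is_reference": 1}
    )
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)
    return pet_path, atlas_path, labels_path
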