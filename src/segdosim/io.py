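"""NIfTI and manifest I/O.

Masks are stored as NIfTI-1 unsigned 8-bit {0,1} volumes, dose maps as 32-bit
float Gy, with voxel spacing carried in the header (a diagonal affine).
A reads manifest is a CSV with columns
lesion_id, reader_id, round, mask_path, dosemap_path.

Inputs are assumed co-registered; if a mask grid differs from its dose-map
grid, the mask is resampled onto the dose grid by nearest neighbour (logged),
and all mask-vs-mask comparisons then happen on the dose grid.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .dosimetry import DoseMap
from .masks import ReadRecord, VoxelMask, mask_volume, recist_diameter
from .synthetic import SyntheticCohort

logger = logging.getLogger("segdosim")

MANIFEST_COLUMNS = ("lesion_id", "reader_id", "round", "mask_path", "dosemap_path")


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_mask(mask: VoxelMask, path) -> None:
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, os.fspath(path))


def write_dose_map(dose_map: DoseMap, path) -> None:
    img = nib.Nifti1Image(dose_map.dose.astype(np.float32), _affine(dose_map.spacing_mm))
    nib.save(img, os.fspath(path))


def _spacing_from(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(s) for s in z)


def read_mask(path) -> VoxelMask:
    """Read a binary mask, normalizing label dialects like {0, 255} to {0, 1}."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    vals = np.unique(data)
    if vals.size > 2 or (vals.size == 2 and not np.all(np.isin(vals, (0, 1)))):
        nonzero = vals[vals != 0]
        if vals.size > 2:
            raise ValueError(f"{path}: non-binary mask with values {vals[:10]}")
        warnings.warn(f"{path}: mask values {{0, {nonzero[0]}}} normalized to {{0, 1}}")
    return VoxelMask(data != 0, _spacing_from(img))


def read_dose_map(path) -> DoseMap:
    img = nib.load(os.fspath(path))
    return DoseMap(np.asarray(img.dataobj, dtype=float), _spacing_from(img))


def resample_mask_to(mask: VoxelMask, target_shape, target_spacing) -> VoxelMask:
    """Nearest-neighbour resampling of a mask onto a target grid.

    Grids are assumed to share their physical origin (co-registered, axis
    aligned); only the voxel lattice differs.
    """
    scale = [ts / ms for ts, ms in zip(target_spacing, mask.spacing_mm)]
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(target_shape, scale)], indexing="ij"
    )
    out = map_coordinates(mask.occupancy.astype(np.uint8), coords, order=0, mode="constant")
    return VoxelMask(out.astype(bool), tuple(float(s) for s in target_spacing))


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort as NIfTI files plus a reads manifest CSV.

    Returns the manifest path; layout is one dose map per lesion and one mask
    per read under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dose_paths = {}
    for lid, dm in cohort.dose_maps.items():
        p = out / f"{lid}_dose.nii.gz"
        write_dose_map(dm, p)
        dose_paths[lid] = p
    rows = []
    for r in cohort.reads:
        p = out / f"{r.lesion_id}_{r.reader_id}_r{r.round}_mask.nii.gz"
        write_mask(r.mask, p)
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "reader_id": r.reader_id,
                "round": r.round,
                "mask_path": str(p),
                "dosemap_path": str(dose_paths[r.lesion_id]),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def load_reads(manifest_csv) -> tuple[list[ReadRecord], dict[str, DoseMap]]:
    """Load reads and dose maps from a manifest CSV.

    Masks whose grid differs from their lesion's dose-map grid are resampled
    onto the dose grid by nearest neighbour (logged). Returns the read
    records (with masks attached and volume/diameter measured on the final
    grid) and a dose map per lesion.
    """
    df = pd.read_csv(manifest_csv)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dose_maps: dict[str, DoseMap] = {}
    reads: list[ReadRecord] = []
    for row in df.itertuples(index=False):
        lid = str(row.lesion_id)
        if lid not in dose_maps:
            dose_maps[lid] = read_dose_map(row.dosemap_path)
        dm = dose_maps[lid]
        mask = read_mask(row.mask_path)
        if mask.occupancy.shape != dm.dose.shape or not np.allclose(
            mask.spacing_mm, dm.spacing_mm
        ):
            logger.info(
                "lesion %s read (%s, round %s): mask grid %s/%s resampled to dose grid %s/%s",
                lid, row.reader_id, row.round,
                mask.occupancy.shape, mask.spacing_mm, dm.dose.shape, dm.spacing_mm,
            )
            mask = resample_mask_to(mask, dm.dose.shape, dm.spacing_mm)
        reads.append(
            ReadRecord(
                lesion_id=lid,
                reader_id=str(row.reader_id),
                round=int(row.round),
                volume_ml=mask_volume(mask),
                diameter_mm=recist_diameter(mask) if mask.n_voxels else 0.0,
                mask=mask,
            )
        )
    return reads, dose_maps
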