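"""Reading and writing volumes, masks, feature tables and run reports.

Volumes and masks travel as NIfTI-1 (float32 data for volumes, uint8 0/1
for masks, spacing carried in the affine); feature tables as CSV with a
stable column order (subject id, label, optional motor score, then the
canonical 105-feature roster); run reports as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .config import DegenerateVoiError, IncompleteTableError, ShapeMismatchError
from .features import FEATURE_NAMES, VoiMask, VoxelGrid

logger = logging.getLogger(__name__)

ID_COLUMN = "subject_id"
LABEL_COLUMN = "label"
MOTOR_COLUMN = "motor_score"


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a susceptibility volume as float32 NIfTI-1."""
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    nib.save(img, str(path))


def write_mask(mask: VoiMask, path: str | Path,
               spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary VOI mask as uint8 NIfTI-1."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_volume_and_mask(
    volume_path: str | Path, mask_path: str | Path
) -> Tuple[VoxelGrid, VoiMask]:
    """Load a co-registered volume + VOI mask pair.

    Raises ``ShapeMismatchError`` when dimensions or affines disagree and
    ``DegenerateVoiError`` when the mask is empty.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asanyarray(vol_img.dataobj, dtype=np.float64)
    msk = np.asanyarray(mask_img.dataobj)
    if vol.shape != msk.shape:
        raise ShapeMismatchError(
            f"volume {vol.shape} vs mask {msk.shape}"
        )
    if not np.allclose(vol_img.affine, mask_img.affine, atol=1e-4):
        raise ShapeMismatchError("volume and mask affines differ")
    uniq = np.unique(msk)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be in {0, 1}")
    if not msk.any():
        raise DegenerateVoiError(f"mask {mask_path} selects no voxels")
    spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
    return VoxelGrid(values=vol, spacing=spacing), VoiMask(data=msk.astype(np.uint8))


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise IncompleteTableError(
            f"feature table is missing {len(missing)} canonical features "
            f"(first missing: {missing[0]})"
        )
    if LABEL_COLUMN not in table.columns:
        raise IncompleteTableError("feature table lacks a label column")
    if table[FEATURE_NAMES].isna().any().any():
        raise IncompleteTableError("feature table contains missing values")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject feature table to CSV in canonical column order."""
    _validate_table(table)
    lead = [ID_COLUMN, LABEL_COLUMN]
    if MOTOR_COLUMN in table.columns:
        lead.append(MOTOR_COLUMN)
    ordered = table[lead + FEATURE_NAMES]
    # full float precision so a write->read round trip is lossless
    ordered.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV, validating the canonical roster."""
    table = pd.read_csv(path, float_precision="round_trip")
    _validate_table(table)
    return table


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
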