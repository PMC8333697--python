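"""NIfTI and table I/O plus provenance records.

All volumes are NIfTI-1 (.nii / .nii.gz) via nibabel; tables are
tab-separated with a header row; configuration and provenance are JSON.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .images import BoldSeries, VolumeMap

PHENOTYPE_COLUMNS = [
    "subject_id", "group", "age", "sex", "education", "SLEDAI", "MoCA", "BDI",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; return ``(data, affine)`` as float64 arrays."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        affine = np.asarray(img.affine, dtype=np.float64)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, affine


def write_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    img.to_filename(str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D mask; nonzero voxels are True."""
    data, affine = read_volume(path)
    if data.ndim != 3:
        raise FormatError(f"mask {path} must be 3D, got ndim={data.ndim}")
    return data != 0, affine


def read_bold(path, tr: float) -> BoldSeries:
    data, affine = read_volume(path)
    if data.ndim != 4:
        raise FormatError(f"BOLD file {path} must be 4D, got ndim={data.ndim}")
    return BoldSeries(data=data, affine=affine, tr=tr)


def write_map(path, vmap: VolumeMap) -> None:
    write_volume(path, vmap.data, vmap.affine)


def read_phenotype_table(path) -> pd.DataFrame:
    """Read the tab-separated phenotype table and validate key columns."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", "group") if c not in table.columns]
    if missing:
        raise FormatError(f"phenotype table {path} lacks columns {missing}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"duplicate subject_id values: {dupes}")
    return table


def write_phenotype_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_nuisance(path) -> np.ndarray:
    """Read a delimited nuisance file (one column per regressor)."""
    arr = np.asarray(pd.read_csv(path, sep=r"\s+", header=None).values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, *, stage: str, config_dict: dict, seed=None, extra=None) -> dict:
    """Write a JSON provenance record for one pipeline stage and return it."""
    from . import __version__

    record = {
        "stage": stage,
        "package": "netdc",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config_dict,
        "config_hash": config_hash(config_dict),
        "seed": seed,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
    return record
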