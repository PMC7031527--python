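"""NIfTI and CSV input/output helpers.

All volumes (label phantoms, MRI-like images, binary masks, field
magnitudes) travel as NIfTI with a millimetre affine; tissue property
tables travel as CSV with columns (label, name, f_hz, sigma_S_per_m,
eps_r).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import PemfDoseError
from .tissues import TissueProperties

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_tissue_table",
    "read_tissue_table",
]


def write_volume(path, data, affine, dtype=None):
    """Write a 3-D (or 4-D component) volume as NIfTI."""
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    try:
        img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
        img.header.set_zooms(tuple(np.abs(np.diag(affine)[:arr.ndim])))
        nib.save(img, str(path))
    except OSError as exc:  # surface the offending path
        raise PemfDoseError(f"failed to write NIfTI volume {path}: {exc}") from exc
    return path


def read_volume(path):
    """Read a NIfTI volume; returns (array, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except (OSError, nib.filebasedimages.ImageFileError) as exc:
        raise PemfDoseError(f"failed to read NIfTI volume {path}: {exc}") from exc
    return np.asanyarray(img.dataobj), img.affine


def write_mask(path, mask, affine):
    """Write a binary mask as uint8 NIfTI; warns if the mask is empty."""
    mask = np.asarray(mask)
    if not np.any(mask):
        warnings.warn(f"writing empty lesion mask to {path}", stacklevel=2)
    return write_volume(path, mask.astype(np.uint8), affine, dtype=np.uint8)


def read_mask(path):
    """Read a binary mask NIfTI; returns (bool array, affine)."""
    data, affine = read_volume(path)
    return data.astype(bool), affine


def write_tissue_table(path, table: dict):
    """Write {label: TissueProperties} as a long-format CSV."""
    rows = []
    for label, props in sorted(table.items()):
        for f, s, e in zip(props.frequencies_hz,
                           props.conductivity_S_per_m,
                           props.relative_permittivity):
            rows.append(
                {"label": label, "name": props.name, "f_hz": f,
                 "sigma_S_per_m": s, "eps_r": e}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_tissue_table(path) -> dict:
    """Read a tissue-table CSV back into {label: TissueProperties}."""
    df = pd.read_csv(path)
    required = {"label", "name", "f_hz", "sigma_S_per_m", "eps_r"}
    missing = required - set(df.columns)
    if missing:
        raise PemfDoseError(f"tissue table {path} lacks columns {sorted(missing)}")
    table = {}
    for label, group in df.groupby("label"):
        group = group.sort_values("f_hz")
        table[int(label)] = TissueProperties(
            name=str(group["name"].iloc[0]),
            frequencies_hz=group["f_hz"].to_numpy(),
            conductivity_S_per_m=group["sigma_S_per_m"].to_numpy(),
            relative_permittivity=group["eps_r"].to_numpy(),
        )
    return table
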