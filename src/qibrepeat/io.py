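"""Reading and writing the package's file formats.

Measurement tables are plain CSV with the exact header
``subject_id,lesion_class,lesion_diameter_mm,map,reader,replicate,roi_mean,roi_sd,roi_area_mm2``;
phantom maps and masks are NIfTI (one file per map, mask as uint8, pixel
spacing in the affine).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import CompletenessError, ConfigurationError
from .synthetic import TABLE_COLUMNS, PhantomBundle


def write_measurement_table(table: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a measurement table as schema-exact CSV.

    Numbers are serialised at full ``repr`` precision, so rewriting the
    same table is byte-identical. Optional run metadata (seed, config
    digest) goes to a ``<path>.meta.json`` sidecar — the CSV header is
    part of the schema and cannot carry comments.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"table is missing columns {missing}")
    table[list(TABLE_COLUMNS)].to_csv(path, index=False)
    if meta is not None:
        sidecar = Path(str(path) + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")


def read_measurement_table(path) -> pd.DataFrame:
    """Read and validate a measurement-table CSV.

    Raises a parse error naming the offending line for malformed rows, and
    a :class:`ConfigurationError` for header or value-domain violations.
    """
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ConfigurationError(f"failed to parse {path}: {exc}") from exc
    if list(table.columns) != list(TABLE_COLUMNS):
        raise ConfigurationError(
            f"{path}: header {list(table.columns)} does not match schema {list(TABLE_COLUMNS)}"
        )
    for column, allowed in (
        ("lesion_class", {"small", "large"}),
        ("map", {"ADC", "FF"}),
    ):
        bad = set(table[column].unique()) - allowed
        if bad:
            rows = table.index[table[column].isin(bad)] + 2  # 1-based + header
            raise ConfigurationError(
                f"{path}: invalid {column} values {sorted(bad)} (first at line {rows[0]})"
            )
    for column, allowed in (("reader", {1, 2}), ("replicate", {1, 2})):
        if not table[column].isin(allowed).all():
            bad_line = int(table.index[~table[column].isin(allowed)][0]) + 2
            raise ConfigurationError(f"{path}: invalid {column} value at line {bad_line}")
    r2 = table[table["reader"] == 2]
    if (r2["replicate"] != 1).any():
        bad_line = int(r2.index[r2["replicate"] != 1][0]) + 2
        raise ConfigurationError(f"{path}: reader 2 may only have replicate 1 (line {bad_line})")
    if (table["roi_area_mm2"] <= 0).any():
        bad_line = int(table.index[table["roi_area_mm2"] <= 0][0]) + 2
        raise ConfigurationError(f"{path}: roi_area_mm2 must be > 0 (line {bad_line})")
    if (table["roi_sd"] < 0).any():
        bad_line = int(table.index[table["roi_sd"] < 0][0]) + 2
        raise ConfigurationError(f"{path}: roi_sd must be >= 0 (line {bad_line})")
    return table


def validate_completeness(table: pd.DataFrame) -> None:
    """Check every subject x class x map has exactly the 3 expected estimates."""
    expected = {(1, 1), (1, 2), (2, 1)}
    problems: List[str] = []
    for (sid, cls, map_type), group in table.groupby(
        ["subject_id", "lesion_class", "map"], sort=False, observed=True
    ):
        got = set(zip(group["reader"], group["replicate"]))
        if got != expected:
            problems.append(f"{sid}/{cls}/{map_type}: has {sorted(got)}")
    if problems:
        raise CompletenessError("incomplete measurement table: " + "; ".join(problems))


def table_digest(table: pd.DataFrame) -> str:
    """Stable SHA-256 digest of a table's CSV serialisation."""
    return hashlib.sha256(table.to_csv(index=False).encode()).hexdigest()


# ---------------------------------------------------------------------------
# NIfTI


def _affine(pixel_spacing) -> np.ndarray:
    dy, dx = pixel_spacing
    aff = np.eye(4)
    aff[0, 0] = dy
    aff[1, 1] = dx
    return aff


def save_map_nifti(image: np.ndarray, pixel_spacing, path) -> None:
    """Write a 2-D map as NIfTI with the pixel spacing in the affine."""
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float64), _affine(pixel_spacing))
    nib.save(img, str(path))


def save_mask_nifti(mask: np.ndarray, pixel_spacing, path) -> None:
    """Write a binary mask as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(pixel_spacing))
    nib.save(img, str(path))


def load_map_nifti(path):
    """Load a NIfTI map; returns (array, (dy, dx))."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return np.asarray(img.dataobj), (float(zooms[0]), float(zooms[1]))


def save_phantom(bundle: PhantomBundle, outdir, prefix: str = "phantom") -> List[Path]:
    """Write all maps and the true mask of a phantom bundle as NIfTI files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in (
        ("adc", bundle.adc_map),
        ("fo", bundle.fo_map),
        ("wo", bundle.wo_map),
        ("ff", bundle.ff_map),
    ):
        path = outdir / f"{prefix}_{name}.nii.gz"
        save_map_nifti(arr, bundle.pixel_spacing, path)
        written.append(path)
    mask_path = outdir / f"{prefix}_mask.nii.gz"
    save_mask_nifti(bundle.true_mask, bundle.pixel_spacing, mask_path)
    written.append(mask_path)
    return written
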