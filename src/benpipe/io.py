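"""NIfTI, manifest and motion-parameter I/O."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .preprocess import BoldSeries

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "edss",
    "mfis5",
    "pasat",
)


def load_bold(path, tr_fallback_s: float | None = None) -> BoldSeries:
    """Load a 4D NIfTI-1/2 file into a :class:`BoldSeries`.

    TR is taken from the header's 4th zoom; a missing/zero TR falls back to
    ``tr_fallback_s`` with a warning.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        if tr_fallback_s is None:
            raise FormatError(f"{path}: no TR in header and no fallback given")
        warnings.warn(f"{path}: no TR in header; using fallback {tr_fallback_s}s")
        tr = tr_fallback_s
    if not np.all(np.isfinite(data)):
        raise DataError(f"{path}: non-finite voxel values")
    return BoldSeries(
        data=data,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        tr_s=tr,
        affine=np.asarray(img.affine, dtype=float),
        provenance=[],
    )


def save_bold(series: BoldSeries, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D map; returns (data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    return data, np.asarray(img.affine, dtype=float)


def save_map(values: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))
    return path


def load_motion(path, dialect: str = "spm_rad") -> np.ndarray:
    """Load a 6-column motion-parameter file; rotations returned in degrees.

    ``spm_rad`` is the SPM rp_*.txt dialect (3 translations mm, 3 rotations
    radians); ``deg`` for degree-native files.
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise DataError(f"{path}: motion file must have 6 columns, got {arr.shape}")
    if dialect == "spm_rad":
        out = arr.copy()
        out[:, 3:] = np.rad2deg(out[:, 3:])
        return out
    if dialect == "deg":
        return arr
    raise DataError(f"unknown motion dialect {dialect!r}")


def load_manifest(path, root=None, require_files: bool = True) -> pd.DataFrame:
    """Load a subject manifest TSV and validate its structure.

    Requires unique subject ids; when ``require_files`` is set, any
    bold_path/motion_path columns are resolved against ``root`` (defaulting
    to the manifest's directory) and must exist.
    """
    path = Path(path)
    root = Path(root) if root is not None else path.parent
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if df["subject_id"].duplicated().any():
        raise DataError(f"{path}: duplicate subject ids")
    if require_files:
        for col in ("bold_path", "motion_path"):
            if col in df.columns:
                for rel in df[col]:
                    if not (root / rel).exists():
                        raise DataError(f"{path}: referenced file missing: {rel}")
    return df
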