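"""Reading and writing 3D Doppler volumes, region masks and result tables.

All in-memory grids use a fixed (z, y, x) axis order, slowest to fastest,
with 0-based voxel indices; the physical position of voxel (k, j, i) is
(k*sz, j*sy, i*sx) at the voxel centre.  Readers reorder on load so that
NIfTI (x, y, z on disk), multi-page TIFF (already z, y, x) and MetaImage
all traverse identically.  Spacing is always (sz, sy, sx) in millimetres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .errors import IntensityRangeError, MissingSpacingError, ShapeMismatchError

logger = logging.getLogger(__name__)

#: The seven morphologic characteristics, in reporting order.
CHARACTERISTIC_COLUMNS = [
    "n_end",
    "n_vessel",
    "n_bif",
    "n_cross",
    "total_length_mm",
    "avg_vessel_length_mm",
    "avg_thickness_mm",
]

#: Density-ratio columns: each characteristic per cm3 of PV, then per cm3 of uPVV.
RATIO_COLUMNS = [f"{c}_per_pv" for c in CHARACTERISTIC_COLUMNS] + [
    f"{c}_per_upvv" for c in CHARACTERISTIC_COLUMNS
]

#: Fixed column order of result tables.
RESULT_COLUMNS = ["id", "ga_weeks", "pv_cm3", "upvv_cm3"] + CHARACTERISTIC_COLUMNS + RATIO_COLUMNS


def _as_spacing(spacing) -> tuple[float, float, float]:
    sz, sy, sx = (float(s) for s in spacing)
    for s in (sz, sy, sx):
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return (sz, sy, sx)


@dataclass(frozen=True)
class DopplerVolume:
    """A 3D 8-bit power-Doppler magnitude grid with physical voxel spacing.

    Parameters
    ----------
    intensities
        Integer array of shape (nz, ny, nx) with values in [0, 255].
    spacing
        Voxel spacing (sz, sy, sx) in mm, each strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"expected a 3D grid with >=1 voxel per axis, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr[np.isfinite(arr)], 1) == 0):
                raise IntensityRangeError("intensities must be integral")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise IntensityRangeError(
                f"intensities outside [0, 255]: min={arr.min()}, max={arr.max()}"
            )
        object.__setattr__(self, "intensities", arr.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


@dataclass(frozen=True)
class RegionMask:
    """A binary region-of-interest mask co-registered with a DopplerVolume.

    ``role`` tags the anatomical meaning: ``"vascular-ROI"`` for the manual
    segmentation of decidua + placenta (embryo and myometrium removed), or
    ``"placenta"`` for a placental-tissue mask used to supply PV.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "vascular-ROI"

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "mask", arr.astype(bool))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# format dispatch

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_META_SUFFIXES = (".mha", ".mhd")


def _format_of(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_TIFF_SUFFIXES):
        return "tiff"
    if name.endswith(_META_SUFFIXES):
        return "metaimage"
    raise ValueError(f"cannot infer format of '{path}'; pass format_hint")


def _read_array(path, format_hint=None):
    """Return (array in (z,y,x) order, spacing (sz,sy,sx) in mm or None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format_hint)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D NIfTI data, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]  # (sx, sy, sz)
        return data.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if fmt == "tiff":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            spacing = _tiff_spacing(tf)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got {data.ndim}D")
        return data, spacing
    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        if data.ndim != 3:
            raise ValueError(f"expected 3D MetaImage data, got {data.ndim}D")
        sx, sy, sz = img.GetSpacing()
        return data, (float(sz), float(sy), float(sx))
    raise ValueError(f"unsupported format '{fmt}'")


def _tiff_spacing(tf: tifffile.TiffFile):
    """Spacing from ImageJ-style TIFF metadata, or None if absent."""
    ij = tf.imagej_metadata
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if ij is None or "spacing" not in ij or xres is None or yres is None:
        return None
    sz = float(ij["spacing"])
    sx = xres.value[1] / xres.value[0]
    sy = yres.value[1] / yres.value[0]
    return (sz, float(sy), float(sx))


def read_volume(path, format_hint: str | None = None, spacing_override=None) -> DopplerVolume:
    """Read a 3D Doppler magnitude volume from NIfTI, TIFF or MetaImage.

    Out-of-range intensities raise :class:`IntensityRangeError` rather than
    being clamped.  Missing spacing metadata raises
    :class:`MissingSpacingError` unless ``spacing_override`` (sz, sy, sx in
    mm) is given, which always wins over header metadata.
    """
    data, spacing = _read_array(path, format_hint)
    if spacing_override is not None:
        spacing = _as_spacing(spacing_override)
    if spacing is None:
        raise MissingSpacingError(f"missing spacing metadata in '{path}' and no override given")
    return DopplerVolume(intensities=data, spacing=spacing)


def write_volume(vol: DopplerVolume, path) -> None:
    """Write a DopplerVolume to NIfTI, TIFF (ImageJ metadata) or MetaImage."""
    path = Path(path)
    fmt = _format_of(path, None)
    sz, sy, sx = vol.spacing
    if fmt == "nifti":
        img = nib.Nifti1Image(vol.intensities.transpose(2, 1, 0), np.diag([sx, sy, sz, 1.0]))
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
    elif fmt == "tiff":
        tifffile.imwrite(
            str(path),
            vol.intensities,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "mm", "axes": "ZYX"},
        )
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(vol.intensities)
        img.SetSpacing((sx, sy, sz))
        sitk.WriteImage(img, str(path))
    else:  # pragma: no cover - _format_of already raises
        raise ValueError(fmt)


def read_mask(path, paired: DopplerVolume, role: str = "vascular-ROI",
              format_hint: str | None = None) -> RegionMask:
    """Read a binary mask co-registered with ``paired``.

    Any nonzero stored value maps to 1.  A shape mismatch raises
    :class:`ShapeMismatchError`; an empty mask is allowed but logged.
    """
    data, _ = _read_array(path, format_hint)
    if data.shape != paired.shape:
        raise ShapeMismatchError(
            f"mask shape {data.shape} does not match volume shape {paired.shape}"
        )
    mask = RegionMask(mask=data != 0, spacing=paired.spacing, role=role)
    if mask.voxel_count == 0:
        logger.warning("mask '%s' is empty", path)
        warnings.warn(f"mask '{path}' is empty", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# result tables


def _ordered_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("records must be non-empty")
    known = [c for c in RESULT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    return df[known + extra]


def write_results(records, path) -> None:
    """Write per-volume characteristic records as CSV or JSON.

    Columns follow the fixed documented order (id, GA, PV, uPVV, the seven
    characteristics, the fourteen density ratios); unknown columns are
    appended after.  ``records`` may be a DataFrame or a list of dicts and
    must be non-empty.
    """
    df = _ordered_frame(records)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1, default=float))
    else:
        df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _ordered_frame(json.loads(path.read_text()))
    return pd.read_csv(path)
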