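"""Intensity thresholding of Doppler volumes into vascular volumes (uPVV).

A voxel belongs to the vascular volume iff its power-Doppler magnitude is at
or above the threshold (default 100 of 255) AND it lies inside the manual
region-of-interest segmentation.  No connected-component filtering is applied
by default; artefact removal in the source protocol is manual, so an optional
minimum-component-size filter is provided for phantom experiments only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .io_volumes import DopplerVolume, RegionMask

#: Default lower power-Doppler intensity threshold (8-bit scale).
DEFAULT_THRESHOLD = 100

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VesselVolume:
    """Binary selection of supra-threshold voxels inside the ROI.

    ``upvv_cm3`` is exactly voxel count x voxel volume (mm3) / 1000.
    """

    selection: np.ndarray
    spacing: tuple[float, float, float]
    threshold_used: int

    def __post_init__(self):
        object.__setattr__(self, "selection", np.asarray(self.selection).astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.selection.shape

    @property
    def voxel_count(self) -> int:
        return int(self.selection.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def upvv_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


def apply_threshold(
    vol: DopplerVolume,
    roi: RegionMask,
    tau: int = DEFAULT_THRESHOLD,
    inclusive: bool = True,
    min_component_voxels: int = 0,
) -> VesselVolume:
    """Select voxels with intensity >= tau (or > tau) inside the ROI.

    Parameters
    ----------
    tau
        Lower intensity threshold in [0, 255].
    inclusive
        If True (default), a voxel exactly at ``tau`` is selected; the
        protocol describes the included voxels as those between the
        threshold and 255.
    min_component_voxels
        If > 0, drop 26-connected components smaller than this many voxels.
        Off by default.
    """
    if not (0 <= tau <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {tau}")
    if vol.shape != roi.shape:
        raise ShapeMismatchError(f"volume shape {vol.shape} != ROI shape {roi.shape}")
    if inclusive:
        sel = (vol.intensities >= tau) & roi.mask
    else:
        sel = (vol.intensities > tau) & roi.mask
    if min_component_voxels > 0 and sel.any():
        labels, n = ndimage.label(sel, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_voxels
        keep[0] = False
        sel = keep[labels]
    return VesselVolume(selection=sel, spacing=vol.spacing, threshold_used=int(tau))


def mask_volume(mask: RegionMask) -> float:
    """Volume of a binary mask in cm3 (voxel count x voxel volume).

    Used to supply the placental volume (PV) when a placenta mask is given
    instead of a scalar.  An empty mask yields 0 with a warning.
    """
    sz, sy, sx = mask.spacing
    n = mask.voxel_count
    if n == 0:
        warnings.warn("mask is empty; volume is 0 cm3", stacklevel=2)
    return n * sz * sy * sx / 1000.0
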