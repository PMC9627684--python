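"""End-to-end orchestration: volume + ROI (+ PV) -> characteristics row.

Deterministic for fixed inputs and configuration.  Each run emits a
provenance block recording the configuration, SHA-256 checksums of the
inputs, and stage-wise voxel counts (including the excluded isolated and
cluster voxels, which would otherwise vanish silently from the analysis).
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from pathlib import Path

from . import __version__
from .config import RunConfig
from .errors import PipelineStageError
from .io_volumes import read_mask, read_volume
from .morphology import (characterize_stages, density_ratios)
from .segmentation import apply_threshold, mask_volume

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, volume_path, roi_path,
                 pv_path=None, pv_cm3: float | None = None,
                 subject_id: str = "volume", ga_weeks: float | None = None,
                 spacing_override=None):
    """Run the full characterization pipeline on one scan.

    PV may come from a placenta mask file (``pv_path``) or a scalar
    (``pv_cm3``); if neither is given the uPVS:PV ratios are undefined.
    Returns ``(record, provenance)`` where ``record`` is a flat dict in the
    result-table schema and ``provenance`` documents config, input
    checksums and per-stage counts.  Any stage error raises
    :class:`PipelineStageError` naming the stage.
    """
    stage = "read_volume"
    try:
        vol = read_volume(volume_path, spacing_override=spacing_override)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    stage = "segmentation"
    try:
        roi = read_mask(roi_path, paired=vol, role="vascular-ROI")
        vv = apply_threshold(vol, roi, tau=config.threshold,
                             inclusive=config.threshold_inclusive,
                             min_component_voxels=config.min_component_voxels)
        if pv_path is not None:
            pv = mask_volume(read_mask(pv_path, paired=vol, role="placenta"))
        elif pv_cm3 is not None:
            pv = float(pv_cm3)
        else:
            pv = math.nan
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    stage = "morphology"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mc, cls, n_segments = characterize_stages(
                vv, radius_mode=config.radius_mode, length_mode=config.length_mode)
            ratios = density_ratios(mc, 0.0 if math.isnan(pv) else pv, vv.upvv_cm3)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    record = {"id": subject_id, "ga_weeks": ga_weeks,
              "pv_cm3": pv, "upvv_cm3": vv.upvv_cm3}
    record.update(mc.as_dict())
    record.update(ratios.as_dict())
    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "volume": {"path": str(volume_path), "sha256": _sha256(volume_path)},
            "roi": {"path": str(roi_path), "sha256": _sha256(roi_path)},
            "pv": ({"path": str(pv_path), "sha256": _sha256(pv_path)}
                   if pv_path is not None else {"scalar_cm3": pv}),
        },
        "stages": {
            "n_roi_voxels": roi.voxel_count,
            "n_selected_voxels": vv.voxel_count,
            "upvv_cm3": vv.upvv_cm3,
            "n_skeleton_voxels": cls.n_total,
            "n_end": cls.n_end, "n_vessel": cls.n_vessel,
            "n_bif": cls.n_bif, "n_cross": cls.n_cross,
            "n_isolated_excluded": cls.n_isolated,
            "n_cluster_excluded": cls.n_cluster,
            "n_segments": n_segments,
        },
    }
    logger.info("pipeline stages: %s", provenance["stages"])
    return record, provenance
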