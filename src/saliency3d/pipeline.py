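"""End-to-end orchestration: sequences in, saliency map and evaluation out.

The detection pipeline runs: conform -> per-channel 8-bit normalization and
pseudo-colour composition -> CIE L*a*b* -> per-scale cube decomposition,
colour saliency and distance weighting -> trilinear upscaling -> weighted
fusion across scales -> median smoothing.  Everything is deterministic for
fixed inputs and configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .color_pipeline import compose_pseudo_rgb, rgb_to_lab
from .errors import ValidationError
from .evaluation import EvalSummary, auc, summary_frame, sweep_curve
from .saliency_core import (
    MultiScaleConfig,
    SaliencyMap,
    cube_decompose,
    fuse_scales,
    median_smooth,
    spatial_weighted_saliency,
    upscale_map,
)
from .volume_io import (
    ConformRecord,
    LabelVolume,
    SequenceSet,
    conform_set,
    read_label_volume,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration: the multi-scale settings plus evaluation flags."""

    multiscale: MultiScaleConfig = field(default_factory=MultiScaleConfig)
    brain_mask: bool = False  # restrict evaluation to nonzero-FLAIR voxels
    verbosity: int = 0


def compute_saliency(
    seqs: SequenceSet, config: RunConfig | MultiScaleConfig | None = None
) -> tuple[SaliencyMap, ConformRecord]:
    """Run the full volumetric saliency pipeline on one subject.

    Returns the final map in conformed space (values in [0, 255]) together
    with the conform record needed to crop back to the input shape.
    """
    if config is None:
        config = RunConfig()
    if isinstance(config, MultiScaleConfig):
        config = RunConfig(multiscale=config)
    ms = config.multiscale

    t0 = time.perf_counter()
    conformed, record = conform_set(seqs, ms.divisor)
    log.info(
        "conform: %s -> %s (pad %s)",
        record.original_shape,
        record.conformed_shape,
        record.pad_amounts,
    )
    rgb = compose_pseudo_rgb(conformed)
    lab = rgb_to_lab(rgb)

    per_scale: dict[int, np.ndarray] = {}
    for k in ms.scales:
        grid = cube_decompose(lab, k)
        s = spatial_weighted_saliency(grid, ms.eq3_mode)
        full = upscale_map(s, k, lab.shape)
        per_scale[k] = full
        log.info("scale k=%d: cube dims %s, saliency range [%g, %g]", k, grid.dims, s.min(), s.max())

    fused = fuse_scales(per_scale, ms)
    final = median_smooth(fused, ms.median_kernel)
    log.info("pipeline done in %.2f s", time.perf_counter() - t0)
    return final, record


def evaluate_map(
    saliency: SaliencyMap | np.ndarray,
    gt: LabelVolume,
    subject_id: str = "",
    brain_mask: np.ndarray | None = None,
):
    """Threshold-sweep the map against ground truth; optionally restrict the
    evaluation domain to a brain mask (both map and labels subset)."""
    data = np.asarray(getattr(saliency, "data", saliency))
    labels = np.asarray(gt.data)
    if brain_mask is not None:
        if brain_mask.shape != data.shape:
            raise ValidationError("brain mask shape mismatch")
        # flatten the masked voxels into a 1D pseudo-volume
        data = data[brain_mask].reshape(-1, 1, 1)
        labels = labels[brain_mask].reshape(-1, 1, 1)
    curve = sweep_curve(data, labels)
    return curve, auc(curve, subject_id=subject_id)


def run_eval(
    map_path: str | Path,
    gt_path: str | Path,
    out_prefix: str | Path,
    brain_mask_path: str | Path | None = None,
) -> EvalSummary:
    """Evaluate a saliency NIfTI against a ground-truth NIfTI and write CSVs.

    Writes ``<prefix>_curve.csv`` (one row per threshold) and
    ``<prefix>_summary.csv``.
    """
    import nibabel as nib

    map_img = nib.load(str(map_path))
    saliency = np.asarray(map_img.dataobj, dtype=float)
    gt = read_label_volume(gt_path)
    if saliency.shape != gt.shape:
        raise ValidationError(f"map shape {saliency.shape} != ground truth shape {gt.shape}")
    mask = None
    if brain_mask_path is not None:
        mask = np.asarray(nib.load(str(brain_mask_path)).dataobj) > 0
    subject = Path(map_path).stem.split(".")[0]
    curve, summary = evaluate_map(saliency, gt, subject_id=subject, brain_mask=mask)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    curve.to_csv(f"{prefix}_curve.csv")
    summary_frame([summary]).to_csv(f"{prefix}_summary.csv", index=False)
    return summary
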