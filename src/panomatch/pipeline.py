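"""End-to-end reconstruction: CT volume in, finalized PR-like image out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import ArchCurve, SliceScore, extract_arch
from .mpr import (
    ParametricCurve,
    ReconSettings,
    finalize_pr_like,
    fit_curve_bspline,
    project_slab,
    realign_teeth,
    sample_curved_slab,
)
from .rotation import (
    OcclusalEstimate,
    RotationStep,
    apply_base_rotation,
    apply_rotation_step,
    estimate_occlusal_slope,
)
from .volume_io import Image2D, VoxelVolume

__all__ = ["ReconReport", "rotated_curve", "reconstruct_pr_like"]


@dataclass(frozen=True)
class ReconReport:
    """Traceability record of one reconstruction."""

    slice_score: SliceScore | None
    occlusal: OcclusalEstimate | None
    curve: ArchCurve
    settings: ReconSettings


def rotated_curve(
    curve: ArchCurve,
    rotation: str | int,
    occlusal: OcclusalEstimate | None,
    increment: float | None = None,
) -> ArchCurve:
    """Apply the requested rotation variant to a standard curve."""
    if rotation == "standard":
        return curve
    if occlusal is None:
        raise ValueError("occlusal estimate required for non-standard rotations")
    base = apply_base_rotation(curve, occlusal)
    if rotation == "base":
        return base
    step = RotationStep(int(rotation)) if increment is None else RotationStep(int(rotation), increment)
    return apply_rotation_step(base, step)


def reconstruct_pr_like(
    volume: VoxelVolume,
    settings: ReconSettings | None = None,
    arch_curve: ArchCurve | None = None,
    occlusal: OcclusalEstimate | None = None,
    return_report: bool = False,
) -> Image2D | tuple[Image2D, ReconReport]:
    """Reconstruct one PR-like image from a CT volume.

    ``arch_curve`` and ``occlusal`` may be supplied to reuse work across
    settings (they are deterministic per volume); otherwise they are
    computed here.  The realignment pass runs for non-standard rotations
    only, matching the method's single second-pass refinement.
    """
    settings = settings or ReconSettings()
    slice_score = None
    if arch_curve is None:
        arch_curve, slice_score = extract_arch(volume)
    if settings.rotation != "standard" and occlusal is None:
        occlusal = estimate_occlusal_slope(volume)
    curve = rotated_curve(arch_curve, settings.rotation, occlusal, increment=settings.rotation_increment)
    pcurve = fit_curve_bspline(curve)
    slab = sample_curved_slab(volume, pcurve, settings)
    image = project_slab(slab, settings.highpass_hu)
    if settings.rotation != "standard" and settings.realign:
        image = realign_teeth(volume, pcurve, image, settings)
    final = finalize_pr_like(image, settings)
    if return_report:
        return final, ReconReport(slice_score, occlusal, curve, settings)
    return final
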