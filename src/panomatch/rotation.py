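"""Occlusal-plane estimation and rotation adjustment of the arch curve.

Head tilt about the left-right axis is the dominant pose nuisance when
synthesizing panoramic views from CT.  It is estimated from the volume
itself: a strong 3000 HU high-pass isolates the teeth, the mask is
flattened along the frontal (x) axis into a sagittal side view, and an
ordinary least-squares line fitted through the foreground pixel centers
gives the occlusal slope dz/dy.  Subtracting that slope from the curve's
z coordinates (anchored at the most anterior point, the incisor region)
yields the pose-independent base configuration ``r_base``; integer
rotation steps R then tilt the reconstruction on purpose, each step
shifting posterior points proportionally to their anteroposterior
distance from the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import ArchCurve
from .volume_io import VoxelVolume, hu_threshold

TEETH_HU = 3000.0
DEFAULT_SLOPE_INCREMENT = 0.04  # dz/dy per rotation step, ~2.3 degrees

__all__ = [
    "OcclusalEstimate",
    "RotationStep",
    "estimate_occlusal_slope",
    "apply_base_rotation",
    "apply_rotation_step",
    "anchor_index",
]


@dataclass(frozen=True)
class OcclusalEstimate:
    """Slope (dimensionless dz/dy) of the occlusal plane in side view."""

    slope: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("non-finite occlusal slope")
        if self.n_pixels <= 0:
            raise ValueError("occlusal fit needs at least one pixel")


@dataclass(frozen=True)
class RotationStep:
    """Integer rotation parameter R.

    Positive R lowers the posterior curve (forward tilt of the image),
    negative R raises it.  Each unit changes the applied occlusal slope
    by ``slope_increment_per_step``, so displacement is exactly linear
    in R.
    """

    R: int
    slope_increment_per_step: float = DEFAULT_SLOPE_INCREMENT

    def __post_init__(self) -> None:
        if int(self.R) != self.R:
            raise ValueError("rotation parameter R must be an integer")
        if self.slope_increment_per_step <= 0:
            raise ValueError("slope increment must be positive")


def estimate_occlusal_slope(volume: VoxelVolume, teeth_hu: float = TEETH_HU) -> OcclusalEstimate:
    """Fit the occlusal plane slope from the teeth-only sagittal silhouette.

    The line is fitted through the foreground pixel centers as the
    principal (major) axis of their (y, z) scatter.  Unlike a plain
    least-squares fit of z on y, the principal axis is not attenuated by
    the vertical thickness of the two tooth rows: rotating the head by
    theta rotates the silhouette rigidly and the fitted slope tracks
    tan(theta) without bias.
    """
    mask = hu_threshold(volume, teeth_hu)
    if not mask.any():
        raise ValueError(
            f"no voxel above {teeth_hu:.0f} HU; teeth not found - consider a lower teeth threshold"
        )
    present = mask.any(axis=0)  # flatten along frontal (x) axis -> (y, z)
    iy, iz = np.nonzero(present)
    y = volume.origin_mm[1] + iy * volume.spacing_mm[1]
    z = volume.origin_mm[2] + iz * volume.spacing_mm[2]
    if np.ptp(y) == 0:
        raise ValueError("degenerate side view: all teeth pixels at one y position")
    cov = np.cov(np.vstack([y, z]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = eigvecs[:, np.argmax(eigvals)]
    if major[0] == 0:
        raise ValueError("degenerate side view: major axis vertical")
    slope = float(major[1] / major[0])
    return OcclusalEstimate(slope=slope, n_pixels=len(y))


def anchor_index(curve: ArchCurve) -> int:
    """Index of the rotation anchor: the most anterior (max y) point.

    Exact ties are broken toward the middle of the point list, which for
    a symmetric arch is the incisor region.
    """
    y = curve.points_mm[:, 1]
    ties = np.flatnonzero(y == y.max())
    mid = (len(y) - 1) / 2.0
    return int(ties[np.argmin(np.abs(ties - mid))])


def _shear_z(curve: ArchCurve, slope: float, provenance: str) -> ArchCurve:
    pts = curve.points_mm.copy()
    ya = pts[anchor_index(curve), 1]
    pts[:, 2] = pts[:, 2] - slope * (ya - pts[:, 1])
    return ArchCurve(pts, provenance)


def apply_base_rotation(curve: ArchCurve, est: OcclusalEstimate) -> ArchCurve:
    """Align the curve with the estimated occlusal plane (-> ``r_base``).

    The anchor (incisor) keeps its height; every other point's z is
    adjusted by the occlusal slope times its y distance from the anchor,
    making the reconstruction independent of head orientation.
    """
    if curve.provenance != "standard":
        raise ValueError(f"base rotation expects a standard curve, got {curve.provenance!r}")
    return _shear_z(curve, est.slope, "r_base")


def apply_rotation_step(curve: ArchCurve, step: RotationStep) -> ArchCurve:
    """Apply an integer rotation step R on top of ``r_base``."""
    if curve.provenance != "r_base":
        raise ValueError(f"rotation steps apply to r_base curves, got {curve.provenance!r}")
    if step.R == 0:
        return curve
    return _shear_z(curve, step.R * step.slope_increment_per_step, f"rotated({step.R})")
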