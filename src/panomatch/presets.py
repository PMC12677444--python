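"""Problem-size presets used by the examples, tests and acceptance script.

The method's native sampling (0.10 mm in plane, 0.35 mm in depth, CT
voxels around 0.5 mm) is what a clinical deployment would use; the
presets here are the package's own reduced study sizes for routine
verification runs, chosen so a full cohort evaluation completes in
minutes on one CPU while leaving every algorithmic step intact.  See
docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from .matching import MatchConfig
from .mpr import ReconSettings
from .phantom import PhantomSpec

#: Cohort-scale evaluation: realistic anatomy, coarsened sampling.
COHORT_SPEC = PhantomSpec(voxel_spacing_mm=(0.7, 0.7, 0.8))
COHORT_RECON = ReconSettings(
    resolution_mm_per_pixel=0.40,
    native_inplane_mm=0.40,
    native_depth_mm=1.0,
    realign=True,
)
COHORT_MATCH = MatchConfig(n_keypoints=400)

#: Miniature phantoms for exercising the full 756-setting parameter grid.
#: The native sampling stays finer than the finest final resolution of the
#: grid (as in the full-size method), and the edge gain is raised because
#: the coarse 1 mm voxels spread tooth edges over several final pixels.
TINY_SPEC = PhantomSpec(
    arch_width_mm=44.0,
    arch_depth_mm=42.0,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
    noise_sd_hu=20.0,
)
TINY_RECON = ReconSettings(
    resolution_mm_per_pixel=0.115,
    native_inplane_mm=0.25,
    native_depth_mm=1.4,
    slab_height_above_mm=35.0,
    slab_height_below_mm=15.0,
    slab_halfwidth_mm=12.0,
    realign=True,
)
TINY_MATCH = MatchConfig(
    crop_width_mm=60.0,
    crop_height_mm=40.0,
    edge_gain=6.0,
    n_keypoints=150,
    fast_threshold=0.02,
)
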