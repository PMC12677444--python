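"""Parametric jaw phantoms: synthetic CT volumes with known ground truth.

Each phantom is a voxelized HU scene built from analytic primitives so
every downstream stage (arch extraction, occlusal estimation, curved
MPR, matching) can be tested against exact ground truth:

* two parabolic dental arches of discrete capped-cylinder teeth
  (enamel-like, 3100 HU) with per-tooth size/position jitter,
* mandible and maxilla bone bands following the arches (900 HU),
* a soft-tissue ellipsoid (50 HU) in an air background (-1000 HU),
* optional very-high-HU restorations on chosen teeth,
* controllable head tilt about the left-right axis and controllable
  vertical overlap between the upper and lower tooth rows,
* additive Gaussian HU noise.

The generator also renders a geometrically consistent ground-truth
panoramic reference of the same dentition: the untilted scene is
projected along the true arch with the package's own curved-MPR rule,
then independently degraded (blur + noise) so reference and PR-like
images share structure but not pixels - the cross-modality gap the
matcher has to bridge.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .arch import ArchCurve, N_CURVE_POINTS
from .mpr import ReconSettings, fit_curve_bspline, finalize_pr_like, project_slab, sample_curved_slab
from .volume_io import AIR_HU, Image2D, VoxelVolume, to_uint8

SOFT_HU = 50.0
BONE_HU = 900.0
TOOTH_HU = 3100.0

#: Inter-arch vertical gap (mm) per overlap level; negative = interpenetration.
OVERLAP_GAP_MM = {"none": 3.0, "partial": 0.0, "strong": -1.0}

#: Fractional half-range of the parabolic bone bands relative to the tooth
#: arch.  In an axial slice the bony outline of the jaw ends short of the
#: distal molars, so the arch-extraction stage must extrapolate its curve
#: ends to cover the full dentition.
BONE_ARCH_EXTENT = 0.90

#: Default rendering of the ground-truth panoramic reference.
REFERENCE_RENDER = ReconSettings(
    highpass_hu=500.0,
    resolution_mm_per_pixel=0.25,
    rotation="standard",
    native_inplane_mm=0.25,
    native_depth_mm=0.70,
    realign=False,
)

__all__ = [
    "SOFT_HU",
    "BONE_HU",
    "TOOTH_HU",
    "OVERLAP_GAP_MM",
    "REFERENCE_RENDER",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic jaw.

    ``n_teeth`` is the per-arch tooth count; fewer than 6 per arch is
    rejected, mirroring the method's inclusion requirement of at least
    12 intact teeth in total.  ``restorations`` lists
    ``(tooth_index, hu)`` pairs where indices 0..n_teeth-1 address the
    lower arch (patient-right to left) and n_teeth..2*n_teeth-1 the
    upper arch.
    """

    identity_id: str = "phantom-000"
    n_teeth: int = 14
    arch_width_mm: float = 60.0
    arch_depth_mm: float = 55.0
    tooth_height_mm: float = 9.0
    tooth_radius_mm: float = 3.0
    head_tilt_deg: float = 0.0
    overlap_level: str = "none"
    restorations: tuple[tuple[int, float], ...] = ()
    noise_sd_hu: float = 25.0
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_teeth < 6:
            raise ValueError(f"n_teeth={self.n_teeth}: need at least 6 teeth per arch")
        for name in ("arch_width_mm", "arch_depth_mm", "tooth_height_mm", "tooth_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.overlap_level not in OVERLAP_GAP_MM:
            raise ValueError(f"overlap_level must be one of {sorted(OVERLAP_GAP_MM)}, got {self.overlap_level!r}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel_spacing_mm must be three positive lengths, got {self.voxel_spacing_mm}")
        resto = tuple((int(i), float(hu)) for i, hu in self.restorations)
        for i, hu in resto:
            if not 0 <= i < 2 * self.n_teeth:
                raise ValueError(f"restorations: tooth_index {i} out of range 0..{2 * self.n_teeth - 1}")
            if hu <= TOOTH_HU:
                raise ValueError(f"restorations: HU {hu} must exceed tooth HU {TOOTH_HU}")
        object.__setattr__(self, "restorations", resto)
        object.__setattr__(self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm))


@dataclass(frozen=True)
class PhantomOutput:
    """One synthetic subject: CT volume, reference panoramic, true curve."""

    volume: VoxelVolume
    reference_pr: Image2D
    true_arch: ArchCurve
    spec: PhantomSpec = field(compare=False)


# ---------------------------------------------------------------------------
# analytic arch geometry


def _arch_polyline(width: float, depth: float, n: int = 1024, t_max: float = 1.0) -> np.ndarray:
    """Parabolic arch (x, y), apex anterior at y = 0.35*depth, ends at -0.65*depth.

    ``t_max`` < 1 truncates the arch symmetrically; the bone bands use it
    because in an axial slice the bony jaw outline ends short of the last
    molars, which is what makes the extraction's end-point extrapolation
    necessary in the first place.
    """
    t = np.linspace(-t_max, t_max, n)
    return np.column_stack([t * width / 2.0, 0.35 * depth - depth * t * t])


def _equal_arc_stations(poly: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = fractions * arc[-1]
    return np.column_stack([np.interp(targets, arc, poly[:, k]) for k in range(poly.shape[1])])


def _tooth_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Per-tooth centers, radii, heights and z offsets for both arches."""
    n = spec.n_teeth
    gap = OVERLAP_GAP_MM[spec.overlap_level]
    arches = {}
    for name, width_scale in (("lower", 1.0), ("upper", 1.04)):
        poly = _arch_polyline(spec.arch_width_mm * width_scale, spec.arch_depth_mm)
        frac = (np.arange(n) + 0.5) / n
        # station jitter small enough that neighboring crowns keep a gap
        # and the separation cap below almost never shrinks a crown
        frac = frac + rng.uniform(-0.12, 0.12, n) / n
        centers = _equal_arc_stations(poly, np.clip(frac, 0.0, 1.0))
        t = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
        # mild molar-vs-incisor taper; kept shallow so every crown stays
        # well above the 60%-of-maximum brightness cut in the projection
        radii = spec.tooth_radius_mm * (0.92 + 0.16 * np.abs(t)) * (1.0 + rng.uniform(-0.08, 0.08, n))
        # keep crowns as separate connected components: cap each radius at
        # 42% of the distance to the nearest neighboring crown center
        if n > 1:
            gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
            nearest = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
            radii = np.minimum(radii, 0.42 * nearest)
        heights = spec.tooth_height_mm * (1.0 + rng.uniform(-0.08, 0.08, n))
        zoff = rng.uniform(-0.5, 0.5, n)
        arches[name] = dict(centers=centers, radii=radii, heights=heights, zoff=zoff)
    arches["lower"]["z_top"] = -gap / 2.0 + arches["lower"]["zoff"]
    arches["upper"]["z_bot"] = gap / 2.0 + arches["upper"]["zoff"]
    return arches


def _tilt_arrays(spec: PhantomSpec, y: np.ndarray, z: np.ndarray, yc: float) -> tuple[np.ndarray, np.ndarray]:
    """Anatomy-frame (y, z) coordinates of each world (y, z) grid point."""
    th = np.deg2rad(spec.head_tilt_deg)
    c, s = np.cos(th), np.sin(th)
    yy, zz = np.meshgrid(y - yc, z, indexing="ij")
    return c * yy + s * zz + yc, -s * yy + c * zz


def _build_volume(spec: PhantomSpec, tilt_deg: float, geometry: dict, noise_rng: np.random.Generator) -> VoxelVolume:
    dx, dy, dz = spec.voxel_spacing_mm
    w = spec.arch_width_mm * 1.04
    d = spec.arch_depth_mm
    xmax = w / 2.0 + 20.0
    # center the FOV on the arch-band centroid, as a scan of the jaw would be
    band = _arch_polyline(spec.arch_width_mm, d, t_max=BONE_ARCH_EXTENT)
    seg = np.linalg.norm(np.diff(band, axis=0), axis=1)
    yc_band = float(np.average((band[:-1, 1] + band[1:, 1]) / 2.0, weights=seg))
    half_y = (d + 42.0) / 2.0
    ymin, ymax = yc_band - half_y, yc_band + half_y
    zmin, zmax = -34.0, 28.0
    nx = int(np.floor((2 * xmax) / dx)) + 1
    ny = int(np.floor((ymax - ymin) / dy)) + 1
    nz = int(np.floor((zmax - zmin) / dz)) + 1
    origin = (-xmax, ymin, zmin)
    x = origin[0] + dx * np.arange(nx)
    y = origin[1] + dy * np.arange(ny)
    z = origin[2] + dz * np.arange(nz)
    yc = 0.35 * d - d / 2.0  # tilt pivot: arch center at occlusal height
    tilted = replace(spec, head_tilt_deg=tilt_deg)
    ya, za = _tilt_arrays(tilted, y, z, yc)  # (ny, nz) anatomy coords

    vol = np.full((nx, ny, nz), AIR_HU, dtype=np.float32)

    # soft tissue ellipsoid (anatomy frame, so it tilts with the head)
    rx, ry, rz = xmax - 2.0, d / 2.0 + 19.0, 34.0
    e = (
        (x[:, None, None] / rx) ** 2
        + ((ya[None, :, :] - yc) / ry) ** 2
        + ((za[None, :, :] + 2.0) / rz) ** 2
    )
    vol[e <= 1.0] = SOFT_HU

    # bone bands following each arch
    gap = OVERLAP_GAP_MM[spec.overlap_level]
    h = spec.tooth_height_mm
    # the mandible band sits clearly below the deepest crown bottom so the
    # arch-localization slices see a clean bony arch without tooth dots
    low_top = -gap / 2.0 - 1.35 * h
    bands = (
        (_arch_polyline(spec.arch_width_mm, d, t_max=BONE_ARCH_EXTENT), low_top - 15.0, low_top, False),
        (_arch_polyline(spec.arch_width_mm * 1.04, d, t_max=BONE_ARCH_EXTENT), gap / 2.0 + h - 1.0, gap / 2.0 + h + 14.0, True),
    )
    for poly, zlo, zhi, fill_palate in bands:
        tree = cKDTree(poly)
        sel = np.nonzero((za >= zlo) & (za <= zhi))
        if len(sel[0]) == 0:
            continue
        m = len(sel[0])
        px = np.repeat(x, m)
        py = np.tile(ya[sel], nx)
        dist, _ = tree.query(np.column_stack([px, py]), workers=-1)
        band = dist <= 3.5
        if fill_palate:
            # the hard palate fills the bowl of the upper arch, so axial
            # slices of the maxilla are closed plates, not open bands
            wb = poly[:, 0].max() * 2.0
            y_curve = 0.35 * d - d * (2.0 * px / (wb / BONE_ARCH_EXTENT)) ** 2
            band |= (py <= y_curve) & (py >= poly[0, 1]) & (np.abs(px) <= wb / 2.0)
        band = band.reshape(nx, m)
        sub = vol[:, sel[0], sel[1]]
        sub[band] = BONE_HU
        vol[:, sel[0], sel[1]] = sub

    # teeth: capped cylinders, evaluated inside per-tooth bounding boxes
    def _fill_cylinder(cx: float, cy: float, z0: float, z1: float, r: float, hu: float) -> None:
        margin = 1.0
        ix = np.searchsorted(x, [cx - r - margin, cx + r + margin])
        # bounding box of the tilted (y, z) extent
        th = np.deg2rad(tilt_deg)
        c, s = np.cos(th), np.sin(th)
        corners_y, corners_z = [], []
        for ay in (cy - r, cy + r):
            for az in (z0, z1):
                corners_y.append(yc + c * (ay - yc) - s * az)
                corners_z.append(s * (ay - yc) + c * az)
        iy = np.searchsorted(y, [min(corners_y) - margin, max(corners_y) + margin])
        iz = np.searchsorted(z, [min(corners_z) - margin, max(corners_z) + margin])
        sx = slice(max(ix[0] - 1, 0), min(ix[1] + 1, nx))
        sy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, ny))
        sz = slice(max(iz[0] - 1, 0), min(iz[1] + 1, nz))
        ya_s = ya[sy, sz][None, :, :]
        za_s = za[sy, sz][None, :, :]
        x_s = x[sx][:, None, None]
        inside = ((x_s - cx) ** 2 + (ya_s - cy) ** 2 <= r * r) & (za_s >= z0) & (za_s <= z1)
        block = vol[sx, sy, sz]
        block[inside] = hu
        vol[sx, sy, sz] = block

    low, up = geometry["lower"], geometry["upper"]
    for i in range(spec.n_teeth):
        zt = low["z_top"][i]
        _fill_cylinder(low["centers"][i, 0], low["centers"][i, 1], zt - low["heights"][i], zt, low["radii"][i], TOOTH_HU)
        zb = up["z_bot"][i]
        _fill_cylinder(up["centers"][i, 0], up["centers"][i, 1], zb, zb + up["heights"][i], up["radii"][i], TOOTH_HU)

    # restorations: occlusal-third inserts of the named teeth
    for idx, hu in spec.restorations:
        arch, i = ("lower", idx) if idx < spec.n_teeth else ("upper", idx - spec.n_teeth)
        gdat = geometry[arch]
        r = gdat["radii"][i] * 0.7
        if arch == "lower":
            zt = gdat["z_top"][i]
            z0, z1 = zt - 0.4 * gdat["heights"][i], zt
        else:
            zb = gdat["z_bot"][i]
            z0, z1 = zb, zb + 0.4 * gdat["heights"][i]
        _fill_cylinder(gdat["centers"][i, 0], gdat["centers"][i, 1], z0, z1, r, hu)

    if spec.noise_sd_hu > 0:
        vol += noise_rng.normal(0.0, spec.noise_sd_hu, vol.shape).astype(np.float32)
    return VoxelVolume(vol, spec.voxel_spacing_mm, origin)


def _true_arch(spec: PhantomSpec, tilt_deg: float) -> ArchCurve:
    """14 equal-arc-length points on the lower arch midline at occlusal height."""
    poly = _arch_polyline(spec.arch_width_mm, spec.arch_depth_mm)
    frac = np.linspace(0.0, 1.0, N_CURVE_POINTS)
    xy = _equal_arc_stations(poly, frac)
    pts = np.column_stack([xy, np.zeros(len(xy))])
    th = np.deg2rad(tilt_deg)
    c, s = np.cos(th), np.sin(th)
    yc = 0.35 * spec.arch_depth_mm - spec.arch_depth_mm / 2.0
    yw = yc + c * (pts[:, 1] - yc) - s * pts[:, 2]
    zw = s * (pts[:, 1] - yc) + c * pts[:, 2]
    out = np.column_stack([pts[:, 0], yw, zw])
    if out[0, 0] > out[-1, 0]:
        out = out[::-1]
    return ArchCurve(out, provenance="truth")


def _render_reference(
    volume: VoxelVolume,
    truth: ArchCurve,
    settings: ReconSettings,
    rng: np.random.Generator,
) -> Image2D:
    """Ground-truth panoramic: curved-MPR projection plus independent degradation."""
    from scipy.ndimage import gaussian_filter

    pcurve = fit_curve_bspline(truth)
    slab = sample_curved_slab(volume, pcurve, settings)
    img = project_slab(slab, settings.highpass_hu)
    px = np.asarray(img.pixels, dtype=np.float64)
    px = gaussian_filter(px, sigma=0.8)  # panoramic focal blur is wider than CT
    span = px.max() - px.min()
    if span > 0:
        px = px + rng.normal(0.0, 0.02 * span, px.shape)
    blurred = Image2D(px, img.resolution_mm_per_pixel)
    final = finalize_pr_like(blurred, settings)
    return Image2D(final.pixels, final.resolution_mm_per_pixel, meta={"kind": "reference_pr"})


def generate_phantom(spec: PhantomSpec, reference_settings: ReconSettings | None = None) -> PhantomOutput:
    """Build one phantom: tilted CT volume + untilted reference panoramic.

    The reference is rendered from the untilted twin of the same
    dentition (a panoramic machine positions the head upright), using
    the true arch curve, and then degraded independently of the CT
    noise.  Identical spec implies bit-identical outputs.
    """
    reference_settings = reference_settings or REFERENCE_RENDER
    ss = np.random.SeedSequence([zlib.crc32(spec.identity_id.encode()), spec.rng_seed])
    geom_rng, noise_rng, ref_noise_rng, ref_pix_rng = (np.random.default_rng(s) for s in ss.spawn(4))
    geometry = _tooth_geometry(spec, geom_rng)
    volume = _build_volume(spec, spec.head_tilt_deg, geometry, noise_rng)
    if spec.head_tilt_deg == 0:
        ref_volume = volume
    else:
        ref_volume = _build_volume(spec, 0.0, geometry, ref_noise_rng)
    truth_flat = _true_arch(spec, 0.0)
    reference = _render_reference(ref_volume, truth_flat, reference_settings, ref_pix_rng)
    return PhantomOutput(
        volume=volume,
        reference_pr=reference,
        true_arch=_true_arch(spec, spec.head_tilt_deg),
        spec=spec,
    )


def make_cohort(
    n_identities: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    reference_settings: ReconSettings | None = None,
) -> list[PhantomOutput]:
    """Draw a cohort of distinct identities around ``base_spec``.

    Arch geometry, tooth count and sizes, small head tilts and
    restoration patterns are drawn from fixed uniform/Poisson ranges
    chosen to mimic inter-patient dental variability; everything else
    (spacing, noise, overlap level) is inherited from ``base_spec``.
    """
    if n_identities < 2:
        raise ValueError("identification needs impostors: n_identities must be >= 2")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    outputs = []
    for i in range(n_identities):
        n_teeth = int(rng.integers(12, 17))
        n_resto = min(int(rng.poisson(1.5)), 4)
        idxs = rng.choice(2 * n_teeth, size=n_resto, replace=False) if n_resto else np.array([], dtype=int)
        restorations = tuple((int(j), float(rng.uniform(4000, 9000))) for j in idxs)
        spec = replace(
            base,
            identity_id=f"id{i:03d}",
            n_teeth=n_teeth,
            arch_width_mm=float(rng.uniform(52, 68)),
            arch_depth_mm=float(rng.uniform(48, 62)),
            tooth_height_mm=float(rng.uniform(8, 11)),
            tooth_radius_mm=float(rng.uniform(2.6, 3.3)),
            head_tilt_deg=base.head_tilt_deg + float(rng.uniform(-2.5, 2.5)),
            restorations=restorations,
            rng_seed=int(rng.integers(2**31)),
        )
        outputs.append(generate_phantom(spec, reference_settings=reference_settings))
    return outputs
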