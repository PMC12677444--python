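"""Lower dental arch localization and the 14-point centerline curve.

The curved MPR is driven by a planar curve traced along the lower dental
arch.  The steps mirror the classical morphological recipe: pick the
axial slice whose 500-HU binarization best resembles a parabolic arch
template, clean it by opening/closing, skeletonize, prune the skeleton
to its longest geodesic path, and sample 12 equally spaced points plus
one linearly extrapolated point at each end (14 in total).  The curve is
finally shifted 20 mm cranially so the lower arch sits below the image
center, as on a clinical panoramic radiograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label
from skimage.morphology import closing, ellipse, opening, skeletonize

from .volume_io import VoxelVolume, hu_threshold

N_CURVE_POINTS = 14
N_INTERIOR_POINTS = 12
CRANIAL_SHIFT_MM = 20.0
ARCH_DETECT_HU = 500.0

__all__ = [
    "ArchCurve",
    "SliceScore",
    "reference_arch_mask",
    "select_best_slice",
    "clean_mask",
    "skeleton_centerline",
    "sample_arch_points",
    "extract_arch",
]


@dataclass(frozen=True)
class ArchCurve:
    """Ordered 14-point 3-D polyline (mm) tracing the dental arch.

    ``provenance`` records where the curve is in the rotation pipeline:
    ``"standard"`` (planar, straight from slice extraction, cranially
    shifted), ``"r_base"`` (adjusted to the occlusal plane),
    ``"rotated(R)"`` (an integer rotation step applied on top of r_base)
    or ``"truth"`` (the generating curve of a synthetic phantom).
    """

    points_mm: np.ndarray
    provenance: str = "standard"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=float)
        if pts.shape != (N_CURVE_POINTS, 3):
            raise ValueError(f"arch curve must have exactly {N_CURVE_POINTS} 3-D points, got {pts.shape}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive curve points must be distinct")
        if self.provenance == "standard" and not np.allclose(pts[:, 2], pts[0, 2], atol=1e-9):
            raise ValueError("standard curve must be planar (constant z)")
        object.__setattr__(self, "points_mm", pts)

    def with_points(self, points_mm: np.ndarray, provenance: str) -> "ArchCurve":
        return ArchCurve(points_mm, provenance)


@dataclass(frozen=True)
class SliceScore:
    slice_index: int
    correlation: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError(f"correlation out of [-1, 1]: {self.correlation}")


def _parabola_polyline(width_mm: float, depth_mm: float, n: int = 512) -> np.ndarray:
    """Open-posterior parabolic arch in local coordinates, apex at (0, 0)."""
    t = np.linspace(-1.0, 1.0, n)
    return np.column_stack([t * width_mm / 2.0, -depth_mm * t * t])


def reference_arch_mask(
    shape: tuple[int, int],
    spacing_mm: tuple[float, float],
    width_mm: float = 60.0,
    depth_mm: float = 50.0,
    band_mm: float = 8.0,
) -> np.ndarray:
    """Parametric binary template of a well-aligned lower dental arch.

    The template is a parabolic band (open posteriorly) of typical arch
    dimensions, centered in the frame with the apex pointing anteriorly
    (+y).  It is generated from code, so it only needs to *rank* axial
    slices by similarity, not to match any particular patient.

    ``shape`` is (nx, ny) matching the in-package axial slice layout,
    ``spacing_mm`` is (dx, dy).
    """
    nx, ny = shape
    if nx < 64 or ny < 64:
        raise ValueError(f"frame too small for arch template: {shape}")
    dx, dy = spacing_mm
    cx = (nx - 1) / 2.0 * dx
    cy = (ny - 1) / 2.0 * dy
    # Apex placed forward of center so the band straddles the frame center.
    poly = _parabola_polyline(width_mm, depth_mm) + np.array([cx, cy + 0.35 * depth_mm])
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, _ = cKDTree(poly).query(pts, workers=-1)
    return (dist <= band_mm / 2.0).reshape(nx, ny)


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape arrays."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def select_best_slice(volume: VoxelVolume, template: np.ndarray | None = None) -> SliceScore:
    """Rank axial slices by arch-likeness of their 500-HU binarization.

    Each slice is binarized at 500 HU (bones and teeth) and compared with
    the parabolic arch template by zero-normalized cross-correlation at
    fixed, centered alignment.  Ties go to the caudal-most slice.
    """
    nx, ny, nz = volume.shape
    if nz < 10:
        raise ValueError(f"volume too thin to span the jaw: {nz} slices")
    dx, dy, _ = volume.spacing_mm
    if template is None:
        template = reference_arch_mask((nx, ny), (dx, dy))
    mask3d = hu_threshold(volume, ARCH_DETECT_HU)
    if not mask3d.any():
        raise ValueError("no jaw found: no voxel above 500 HU")
    tmpl = template.astype(np.float64)
    best_iz, best_score = -1, -np.inf
    for iz in range(nz):  # ascending z: first (caudal-most) slice wins ties
        sl = mask3d[:, :, iz]
        if not sl.any():
            continue
        score = _zncc(sl, tmpl)
        if score > best_score:
            best_iz, best_score = iz, score
    return SliceScore(best_iz, best_score)


def clean_mask(
    mask: np.ndarray,
    spacing_mm: tuple[float, float],
    radius_mm: float = 2.0,
) -> np.ndarray:
    """Morphological opening then closing; keep the largest component.

    The structuring element is an ellipse of ~2 mm radius converted to
    pixels via the slice spacing: small enough to preserve inter-tooth
    structure, large enough to drop speckle noise and close small gaps
    along the arch outline.
    """
    if not mask.any():
        raise ValueError("empty mask")
    dx, dy = spacing_mm
    rx = max(1, round(radius_mm / dx))
    ry = max(1, round(radius_mm / dy))
    selem = ellipse(rx, ry)  # (rows, cols) = (x, y) in our slice layout
    out = opening(mask, selem)
    out = closing(out, selem)
    if not out.any():
        raise ValueError("mask empty after morphological cleaning")
    labels = label(out, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = np.argwhere(skel)
    pix = set(map(tuple, coords))
    for i, j in pix:
        g.add_node((i, j))
        for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (i + di, j + dj)
            if nb in pix:
                g.add_edge((i, j), nb, weight=np.hypot(di, dj))
    return g


def _farthest(g: nx.Graph, source) -> tuple[tuple[int, int], float]:
    dist = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    dmax = max(dist.values())
    # among equal distances prefer the lexicographically smallest pixel
    cands = sorted(node for node, d in dist.items() if d >= dmax - 1e-9)
    return cands[0], dmax


def skeleton_centerline(mask: np.ndarray) -> np.ndarray:
    """Skeletonize and prune to the longest geodesic path.

    The skeleton's 8-connected pixel graph (diagonal steps weighted
    sqrt(2)) is reduced to its diameter path found by a double sweep:
    Dijkstra from an arbitrary pixel to the farthest pixel u, then from
    u to the farthest pixel v; the u-v geodesic is returned.  This
    removes protruding spurs while keeping the arch run intact.
    """
    if label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must be a single connected component")
    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("empty skeleton")
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 1:
        return np.argwhere(skel)
    components = list(nx.connected_components(g))
    if len(components) > 1:  # keep the largest skeleton piece
        g = g.subgraph(max(components, key=len)).copy()
    start = min(g.nodes)
    u, _ = _farthest(g, start)
    v, _ = _farthest(g, u)
    path = nx.dijkstra_path(g, u, v, weight="weight")
    return np.asarray(path, dtype=int)


def _resample_polyline(points: np.ndarray, arc: np.ndarray, targets: np.ndarray) -> np.ndarray:
    out = np.empty((len(targets), points.shape[1]))
    for k in range(points.shape[1]):
        out[:, k] = np.interp(targets, arc, points[:, k])
    return out


def sample_arch_points(
    path: np.ndarray,
    spacing_mm: tuple[float, float],
    z_mm: float,
    origin_mm: tuple[float, float] = (0.0, 0.0),
    cranial_shift_mm: float = CRANIAL_SHIFT_MM,
) -> ArchCurve:
    """Turn a pixel path into the 14-point planar arch curve (mm).

    Twelve points are placed at equal arc length along the path
    (endpoints included); one extra point is appended at each end by
    extrapolating the last segment direction at the same arc spacing.
    The curve is ordered patient-right to patient-left, set to the
    slice's z, and shifted 20 mm cranially.
    """
    path = np.asarray(path, dtype=float)
    dx, dy = spacing_mm
    pts_mm = np.column_stack([origin_mm[0] + path[:, 0] * dx, origin_mm[1] + path[:, 1] * dy])
    seg = np.linalg.norm(np.diff(pts_mm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < 20.0:
        raise ValueError(f"arch path too short: {total:.1f} mm < 20 mm")
    targets = np.linspace(0.0, total, N_INTERIOR_POINTS)
    inner = _resample_polyline(pts_mm, arc, targets)
    step = total / (N_INTERIOR_POINTS - 1)

    def _extrapolate(p_end: np.ndarray, p_prev: np.ndarray) -> np.ndarray:
        d = p_end - p_prev
        return p_end + d / np.linalg.norm(d) * step

    first = _extrapolate(inner[0], inner[1])
    last = _extrapolate(inner[-1], inner[-2])
    xy = np.vstack([first, inner, last])
    if xy[0, 0] > xy[-1, 0]:  # orient patient-right (smaller x) first
        xy = xy[::-1]
    z = np.full(len(xy), z_mm + cranial_shift_mm)
    return ArchCurve(np.column_stack([xy, z]), provenance="standard")


def extract_arch(volume: VoxelVolume, template: np.ndarray | None = None) -> tuple[ArchCurve, SliceScore]:
    """Full extraction: best slice -> clean -> skeleton -> 14 points."""
    score = select_best_slice(volume, template=template)
    iz = score.slice_index
    sl = hu_threshold(volume, ARCH_DETECT_HU)[:, :, iz]
    dx, dy, dz = volume.spacing_mm
    cleaned = clean_mask(sl, (dx, dy))
    path = skeleton_centerline(cleaned)
    z_mm = volume.origin_mm[2] + iz * dz
    curve = sample_arch_points(path, (dx, dy), z_mm, origin_mm=volume.origin_mm[:2])
    return curve, score
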