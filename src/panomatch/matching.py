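"""Keypoint-based identity matching between PR-like images and panoramics.

Both query (PR-like) and database (panoramic) images pass through the
same preprocessing: 8-bit normalization, center crop/pad to a fixed
180 x 100 mm field, edge enhancement by the maximum response over eight
directional Sobel masks (0..315 deg in 45 deg steps, gain 1.8), and a
light Gaussian smoothing.  Multi-scale keypoints with 256-bit binary
descriptors are then extracted (ORB: FAST corners + rotated BRIEF).

Two feature sets A (query) and B (database entry) are compared in both
directions with a nearest/second-nearest ratio test on squared
Euclidean descriptor distance, and combined into the similarity score

    score = (matches_AB + matches_BA) / (2 * |A|) * 100 %

which is 0 for unrelated images and 100 for identical ones.  Identities
are ranked by their best database-image score; rank-k identification
asks whether the true identity is among the k best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import convolve, gaussian_filter
from scipy.spatial.distance import cdist
from skimage.feature import ORB

from .volume_io import Image2D, to_uint8

__all__ = [
    "MatchConfig",
    "FeatureSet",
    "ScoreReport",
    "RankedCandidates",
    "GroupComparison",
    "preprocess",
    "extract_features",
    "count_matches",
    "score",
    "rank_identities",
    "combine_variants",
    "compare_score_groups",
]


@dataclass(frozen=True)
class MatchConfig:
    """Tunable preprocessing / detection / matching parameters."""

    crop_width_mm: float = 180.0
    crop_height_mm: float = 100.0
    edge_gain: float = 1.8
    smoothing_sigma_px: float = 1.0
    n_keypoints: int = 500
    fast_threshold: float = 0.05
    ratio: float = 0.8  # nearest/second-nearest acceptance on squared distance
    metric: str = "sqeuclidean"  # or "hamming"; identical ranking for binary descriptors


@dataclass(frozen=True)
class FeatureSet:
    """Keypoints + binary descriptors extracted from one image."""

    keypoints: np.ndarray  # (n, 4): x, y, scale, orientation
    descriptors: np.ndarray  # (n, 256) uint8 in {0, 1}
    source_id: str = ""
    identity_id: str = ""

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float).reshape(-1, 4)
        de = np.asarray(self.descriptors, dtype=np.uint8)
        de = de.reshape(len(kp), -1) if kp.size else de.reshape(0, 0)
        if len(kp) != len(de):
            raise ValueError("keypoints and descriptors must have equal length")
        object.__setattr__(self, "keypoints", kp)
        object.__setattr__(self, "descriptors", de)

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass(frozen=True)
class ScoreReport:
    matches_ab: int
    matches_ba: int
    n_features_query: int

    @property
    def score_percent(self) -> float:
        if self.n_features_query == 0:
            return 0.0
        return (self.matches_ab + self.matches_ba) / (2.0 * self.n_features_query) * 100.0


# Four antisymmetric 3x3 directional masks; together with their negations
# they form the eight 45-degree-step compass Sobel masks, and the maximum
# over all eight equals the maximum absolute response over these four.
_SOBEL_0 = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_45 = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=np.float64)
_SOBEL_90 = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)
_SOBEL_135 = np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=np.float64)
_DIRECTIONAL_MASKS = (_SOBEL_0, _SOBEL_45, _SOBEL_90, _SOBEL_135)


def _center_crop_pad(pixels: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Center crop and/or zero-pad to the target (rows, cols)."""
    out = np.zeros(target, dtype=pixels.dtype)
    r, c = pixels.shape
    tr, tc = target
    src_r0 = max(0, (r - tr) // 2)
    src_c0 = max(0, (c - tc) // 2)
    dst_r0 = max(0, (tr - r) // 2)
    dst_c0 = max(0, (tc - c) // 2)
    nr = min(r, tr)
    nc = min(c, tc)
    out[dst_r0 : dst_r0 + nr, dst_c0 : dst_c0 + nc] = pixels[src_r0 : src_r0 + nr, src_c0 : src_c0 + nc]
    return out


def preprocess(image: Image2D, config: MatchConfig | None = None) -> Image2D:
    """Normalize, crop to a fixed physical field, and enhance edges."""
    config = config or MatchConfig()
    res_r, res_c = image.resolution_mm_per_pixel
    arr = image.pixels if image.pixels.dtype == np.uint8 else to_uint8(image.pixels)
    target = (round(config.crop_height_mm / res_r), round(config.crop_width_mm / res_c))
    arr = _center_crop_pad(arr, target)
    f = arr.astype(np.float64)
    responses = [np.abs(convolve(f, k, mode="nearest")) for k in _DIRECTIONAL_MASKS]
    edges = np.clip(np.max(responses, axis=0) * config.edge_gain / 8.0, 0.0, 255.0)
    smoothed = gaussian_filter(edges, sigma=config.smoothing_sigma_px)
    return Image2D(
        np.floor(smoothed + 0.5).astype(np.uint8),
        (res_r, res_c),
        meta={**image.meta, "preprocessed": True},
    )


def extract_features(
    image: Image2D,
    config: MatchConfig | None = None,
    source_id: str = "",
    identity_id: str = "",
) -> FeatureSet:
    """Multi-scale binary keypoint features of a preprocessed image.

    Deterministic for a fixed image and configuration.  A featureless
    (e.g. blank) image yields an empty set with a warning; downstream
    scores treat it as 0.
    """
    config = config or MatchConfig()
    detector = ORB(n_keypoints=config.n_keypoints, fast_threshold=config.fast_threshold)
    try:
        detector.detect_and_extract(np.asarray(image.pixels, dtype=np.float64) / 255.0)
        kp = np.column_stack(
            [
                detector.keypoints[:, 1],  # x = column
                detector.keypoints[:, 0],  # y = row
                detector.scales,
                detector.orientations,
            ]
        )
        desc = detector.descriptors.astype(np.uint8)
    except (RuntimeError, ValueError):
        warnings.warn(f"no keypoints detected in image {source_id!r}", stacklevel=2)
        kp = np.empty((0, 4))
        desc = np.empty((0, 0), dtype=np.uint8)
    return FeatureSet(kp, desc, source_id=source_id, identity_id=identity_id)


def _pairwise_sq_binary(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Exact squared Euclidean distances between 0/1 descriptor matrices.

    For binary vectors ||a-b||^2 = sum(a) + sum(b) - 2 a.b, evaluated
    with one matrix product; all involved integers stay far below the
    float32 exact range.
    """
    a = da.astype(np.float32)
    b = db.astype(np.float32)
    return a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - 2.0 * (a @ b.T)


def _directed_matches(da: np.ndarray, db: np.ndarray, ratio: float, metric: str) -> int:
    """Count descriptors of A accepted against B by the ratio test."""
    if len(da) == 0 or len(db) == 0:
        return 0
    if metric == "sqeuclidean" and da.dtype == np.uint8 and da.max(initial=0) <= 1 and db.max(initial=0) <= 1:
        d = _pairwise_sq_binary(da, db)
    else:
        d = cdist(da.astype(np.float64), db.astype(np.float64), metric)
    if d.shape[1] == 1:
        # no second neighbor to disambiguate against: accept every nearest hit
        return d.shape[0]
    part = np.partition(d, 1, axis=1)
    d1, d2 = part[:, 0], part[:, 1]
    return int(np.count_nonzero(d1 <= ratio * d2))


def count_matches(a: FeatureSet, b: FeatureSet, config: MatchConfig | None = None) -> tuple[int, int]:
    """Bidirectional matching-point counts (A against B, B against A)."""
    config = config or MatchConfig()
    return (
        _directed_matches(a.descriptors, b.descriptors, config.ratio, config.metric),
        _directed_matches(b.descriptors, a.descriptors, config.ratio, config.metric),
    )


def score(a: FeatureSet, b: FeatureSet, config: MatchConfig | None = None) -> ScoreReport:
    """Bidirectional similarity score of query A against database entry B."""
    mab, mba = count_matches(a, b, config)
    return ScoreReport(matches_ab=mab, matches_ba=mba, n_features_query=len(a))


@dataclass(frozen=True)
class RankedCandidates:
    """Per-identity best scores, sorted descending.

    Ranks are 1-based; tied scores all share the worst rank of the tie
    group (pessimistic), while the listing order stays stable in the
    database's identity order.
    """

    identity_ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.identity_ids) != len(self.scores):
            raise ValueError("identity_ids and scores must align")
        order = sorted(
            range(len(self.scores)),
            key=lambda i: (-self.scores[i], i),
        )
        object.__setattr__(self, "identity_ids", tuple(self.identity_ids[i] for i in order))
        object.__setattr__(self, "scores", tuple(self.scores[i] for i in order))

    def score_of(self, identity_id: str) -> float:
        return self.scores[self.identity_ids.index(identity_id)]

    def rank_of(self, identity_id: str) -> int:
        s = self.score_of(identity_id)
        return sum(1 for v in self.scores if v >= s)  # worst tied rank

    def top(self, k: int) -> list[tuple[str, float]]:
        return list(zip(self.identity_ids[:k], self.scores[:k]))


def rank_identities(
    query: FeatureSet,
    db: list[FeatureSet],
    config: MatchConfig | None = None,
) -> RankedCandidates:
    """Score the query against every database image and rank identities.

    An identity with several database images gets its best (maximum)
    image score.
    """
    if not db:
        raise ValueError("database is empty")
    best: dict[str, float] = {}
    for entry in db:
        s = score(query, entry, config).score_percent
        key = entry.identity_id
        if key not in best or s > best[key]:
            best[key] = s
    ids = tuple(best.keys())
    return RankedCandidates(ids, tuple(best[i] for i in ids))


def combine_variants(variants: list[RankedCandidates]) -> RankedCandidates:
    """Combine the four fixed reconstruction variants per identity.

    The combined identity score is the mean of its two highest
    per-variant scores, trading robustness (one variant may align badly)
    against discrimination (one lucky variant is not enough).
    """
    if len(variants) != 4:
        raise ValueError(f"combined scoring expects exactly 4 variants, got {len(variants)}")
    id_sets = [set(v.identity_ids) for v in variants]
    if any(s != id_sets[0] for s in id_sets[1:]):
        raise ValueError("variants must cover the same identity set")
    ids = variants[0].identity_ids
    combined = []
    for ident in ids:
        per = sorted((v.score_of(ident) for v in variants), reverse=True)
        combined.append((per[0] + per[1]) / 2.0)
    return RankedCandidates(ids, tuple(combined))


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of same- vs different-identity scores."""

    u_statistic: float
    p_value: float
    mean_same: float
    sd_same: float
    mean_diff: float
    sd_diff: float

    def summary(self) -> str:
        return (
            f"same {self.mean_same:.2f} +/- {self.sd_same:.2f} % vs "
            f"different {self.mean_diff:.2f} +/- {self.sd_diff:.2f} % "
            f"(U = {self.u_statistic:.0f}, p = {self.p_value:.3g})"
        )


def compare_score_groups(same: list[float], diff: list[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test between the two score groups."""
    same = np.asarray(same, dtype=float)
    diff = np.asarray(diff, dtype=float)
    if len(same) < 2 or len(diff) < 2:
        raise ValueError("each score group needs at least 2 values")
    res = stats.mannwhitneyu(same, diff, alternative="two-sided")
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_same=float(same.mean()),
        sd_same=float(same.std(ddof=1)),
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)),
    )
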