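"""Systematic parameter variation and identification-rate summaries.

The sweep explores the full reconstruction grid - 7 high-pass values
(0..1500 HU, step 250), 9 final resolutions (0.090..0.140 mm/pixel) and
12 rotations (standard, base, R = +7..+1 and -1..-3) - giving 756
settings per subject, and scores each resulting PR-like image against
the subject's own reference panoramic.  ``R_best`` is the per-subject
setting maximizing the matching-point count.  The inner loops are
factored so that each curved slab is sampled once per rotation, each
projection computed once per high-pass value, and only the cheap
finalization/feature steps run per resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .arch import extract_arch
from .matching import MatchConfig, count_matches, extract_features, preprocess
from .mpr import (
    HIGHPASS_GRID_HU,
    RESOLUTION_GRID_MM,
    ReconSettings,
    finalize_pr_like,
    fit_curve_bspline,
    project_slab,
    realign_offsets,
    sample_curved_slab,
)
from .phantom import PhantomOutput
from .pipeline import rotated_curve
from .rotation import estimate_occlusal_slope

#: The 12 rotation settings: standard alignment, the occlusal base, and
#: integer steps +7..+1 and -1..-3 (R = 0 is the base itself).
ROTATION_ROSTER: tuple[str | int, ...] = ("standard", "base", 7, 6, 5, 4, 3, 2, 1, -1, -2, -3)

__all__ = ["ROTATION_ROSTER", "SweepGrid", "run_sweep", "best_settings", "setting_means", "summarize_rates"]


@dataclass(frozen=True)
class SweepGrid:
    highpass_values: tuple[float, ...] = HIGHPASS_GRID_HU
    resolutions: tuple[float, ...] = RESOLUTION_GRID_MM
    rotations: tuple[str | int, ...] = ROTATION_ROSTER

    @property
    def n_settings(self) -> int:
        return len(self.highpass_values) * len(self.resolutions) * len(self.rotations)

    def settings(self, base: ReconSettings | None = None):
        """Yield one ReconSettings per grid cell (rotation-major order)."""
        base = base or ReconSettings()
        for rot, hp, res in product(self.rotations, self.highpass_values, self.resolutions):
            yield replace(base, rotation=rot, highpass_hu=hp, resolution_mm_per_pixel=res)

    def n_comparisons(self, n_subjects: int) -> int:
        return self.n_settings * n_subjects


def run_sweep(
    cohort: list[PhantomOutput],
    grid: SweepGrid | None = None,
    base_settings: ReconSettings | None = None,
    match_config: MatchConfig | None = None,
) -> pd.DataFrame:
    """Reconstruct and score every (subject, setting) pair.

    Returns one row per comparison with columns ``subject``,
    ``rotation``, ``highpass_hu``, ``resolution_mm_per_pixel``,
    ``matching_points`` ((AB+BA)/2) and ``score_percent``.  A failing
    setting is recorded with NaNs rather than aborting the sweep.  The
    realignment pass for non-standard rotations is computed once per
    rotation at the base high-pass value; see the methods note.
    """
    grid = grid or SweepGrid()
    base_settings = base_settings or ReconSettings()
    match_config = match_config or MatchConfig()
    rows = []
    for subject in cohort:
        volume = subject.volume
        ident = subject.spec.identity_id
        ref_features = extract_features(
            preprocess(subject.reference_pr, match_config), match_config, identity_id=ident
        )
        curve, _ = extract_arch(volume)
        try:
            occlusal = estimate_occlusal_slope(volume)
        except ValueError:
            occlusal = None
        for rot in grid.rotations:
            slab = None
            try:
                rcurve = rotated_curve(curve, rot, occlusal, increment=base_settings.rotation_increment)
                pcurve = fit_curve_bspline(rcurve)
                rot_settings = replace(base_settings, rotation=rot)
                slab = sample_curved_slab(volume, pcurve, rot_settings)
                if rot != "standard" and base_settings.realign:
                    offsets = realign_offsets(
                        project_slab(slab, base_settings.highpass_hu), pcurve, rot_settings
                    )
                    if offsets is not None:
                        slab = sample_curved_slab(volume, pcurve, rot_settings, z_offsets_mm=offsets)
            except ValueError:
                slab = None
            for hp in grid.highpass_values:
                image = project_slab(slab, hp) if slab is not None else None
                for res in grid.resolutions:
                    rec = {
                        "subject": ident,
                        "rotation": str(rot),
                        "highpass_hu": hp,
                        "resolution_mm_per_pixel": res,
                        "matching_points": np.nan,
                        "score_percent": np.nan,
                    }
                    if image is not None:
                        settings = replace(
                            base_settings, rotation=rot, highpass_hu=hp, resolution_mm_per_pixel=res
                        )
                        final = finalize_pr_like(image, settings)
                        feats = extract_features(preprocess(final, match_config), match_config)
                        mab, mba = count_matches(feats, ref_features, match_config)
                        rec["matching_points"] = (mab + mba) / 2.0
                        rec["score_percent"] = (
                            (mab + mba) / (2.0 * len(feats)) * 100.0 if len(feats) else 0.0
                        )
                    rows.append(rec)
    return pd.DataFrame(rows)


def best_settings(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-subject R_best row: the setting with the most matching points.

    Ties resolve to the first row in sweep order, which is deterministic.
    """
    valid = sweep.dropna(subset=["matching_points"])
    idx = valid.groupby("subject")["matching_points"].idxmax()
    return sweep.loc[idx].reset_index(drop=True)


def setting_means(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean matching points over subjects and rotations, by (high-pass, resolution)."""
    return (
        sweep.pivot_table(
            index="highpass_hu",
            columns="resolution_mm_per_pixel",
            values="matching_points",
            aggfunc="mean",
        )
    )


def summarize_rates(ranks: dict[str, int], ks: list[int]) -> pd.DataFrame:
    """Cumulative rank-k identification rates.

    ``ranks`` maps each subject to the rank of its true identity; for
    each k the fraction of subjects with rank <= k is reported as
    count/total and percent.
    """
    if list(ks) != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    total = len(ranks)
    rows = []
    for k in ks:
        count = sum(1 for r in ranks.values() if r <= k)
        rows.append(
            {
                "k": k,
                "identified": count,
                "total": total,
                "rate_percent": 100.0 * count / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
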