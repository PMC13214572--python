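"""Topographic similarity of activation maps within and between
localizer versions.

Two complementary metrics:

* masked voxelwise Pearson correlation of contrast effect maps,
  Fisher-transformed (atanh) so values can be averaged across parcels
  and compared across comparisons;
* Dice overlap of top-fraction fROIs at one or more selection
  thresholds.

Within-version similarity correlates the two runs of a version;
between-version similarity averages the four pairwise run combinations
(standard run i vs. speeded run j), matching the amount of data in the
two comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .firstlevel import ContrastMap
from .froi import FROI, FROIConfig, define_froi
from .synthsubject import ParcelAtlas

__all__ = [
    "SimilarityResult",
    "masked_correlation",
    "fisher_z",
    "version_similarity",
    "dice",
    "dice_profile",
    "FISHER_CLIP_EPS",
]

FISHER_CLIP_EPS = 1e-7

COMPARISONS = ("within_standard", "within_speeded", "between")


@dataclass(frozen=True)
class SimilarityResult:
    comparison: str
    metric: str  # "fisher_z" | "dice"
    per_parcel: dict[str, float]
    aggregate: float
    subject: str = ""
    fraction: float | None = None  # dice only


def masked_correlation(
    map_a: ContrastMap | np.ndarray,
    map_b: ContrastMap | np.ndarray,
    mask: np.ndarray,
) -> float:
    """Pearson correlation of effect values over the masked voxels."""
    a = np.asarray(getattr(map_a, "effect", map_a)).ravel()
    b = np.asarray(getattr(map_b, "effect", map_b)).ravel()
    if a.shape != b.shape:
        raise ValueError("maps do not share a grid")
    idx = np.asarray(mask)
    idx = np.flatnonzero(idx.ravel()) if idx.dtype == bool else idx.ravel()
    if idx.size < 3:
        raise ValueError("mask must contain at least 3 voxels")
    x, y = a[idx], b[idx]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate correlation: zero variance within mask")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform, z = atanh(r), with |r|
    clipped to 1 − 1e-7 so degenerate (perfect) correlations stay finite."""
    if abs(r) > 1:
        raise ValueError(f"|r| = {abs(r)} > 1")
    return float(np.arctanh(np.clip(r, -1 + FISHER_CLIP_EPS, 1 - FISHER_CLIP_EPS)))


def _parcel_masks(atlas: ParcelAtlas, parcels: Sequence[str]) -> dict[str, np.ndarray]:
    return {p: atlas.parcel_indices(p) for p in parcels}


def _require_runs(contrast_maps: Mapping[tuple[str, str], ContrastMap]) -> None:
    for version in ("standard", "speeded"):
        for run in ("1", "2"):
            if (version, run) not in contrast_maps:
                raise KeyError(f"missing map for version {version!r}, run {run!r}")


def version_similarity(
    contrast_maps: Mapping[tuple[str, str], ContrastMap],
    atlas: ParcelAtlas,
    parcels: Sequence[str],
    subject: str = "",
) -> list[SimilarityResult]:
    """Fisher-z map similarity within and between localizer versions.

    ``contrast_maps`` is keyed by (version, run) with versions
    "standard"/"speeded" and runs "1"/"2".  Within-version values are
    z(corr(run1, run2)) per parcel; the between value averages the four
    pairwise z values per parcel; the aggregate is the mean over parcels.
    """
    _require_runs(contrast_maps)
    masks = _parcel_masks(atlas, parcels)
    results = []
    for comparison in COMPARISONS:
        per_parcel = {}
        for parcel, idx in masks.items():
            if comparison == "between":
                zs = [
                    fisher_z(
                        masked_correlation(
                            contrast_maps[("standard", ri)],
                            contrast_maps[("speeded", rj)],
                            idx,
                        )
                    )
                    for ri in ("1", "2")
                    for rj in ("1", "2")
                ]
                per_parcel[parcel] = float(np.mean(zs))
            else:
                version = comparison.removeprefix("within_")
                per_parcel[parcel] = fisher_z(
                    masked_correlation(
                        contrast_maps[(version, "1")],
                        contrast_maps[(version, "2")],
                        idx,
                    )
                )
        results.append(
            SimilarityResult(
                comparison=comparison,
                metric="fisher_z",
                per_parcel=per_parcel,
                aggregate=float(np.mean(list(per_parcel.values()))),
                subject=subject,
            )
        )
    return results


def dice(froi_a: FROI, froi_b: FROI) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two fROIs of the same parcel."""
    if froi_a.parcel_name != froi_b.parcel_name:
        raise ValueError(
            f"cannot compare fROIs of different parcels "
            f"({froi_a.parcel_name!r} vs {froi_b.parcel_name!r})"
        )
    a, b = froi_a.index_set(), froi_b.index_set()
    return 2.0 * len(a & b) / (len(a) + len(b))


def dice_profile(
    tmaps: Mapping[tuple[str, str], ContrastMap],
    atlas: ParcelAtlas,
    parcels: Sequence[str],
    fractions: Sequence[float] = (0.1, 0.2, 0.3),
    subject: str = "",
) -> list[SimilarityResult]:
    """Within- and between-version Dice overlap of top-fraction fROIs.

    For each selection fraction: within-version Dice compares the fROIs
    defined on the two runs of a version; between-version Dice averages
    the four pairwise between-run comparisons.
    """
    _require_runs(tmaps)
    results = []
    for fraction in fractions:
        cfg = FROIConfig(fraction=fraction, parcel_names=tuple(parcels))
        frois = {
            key: {p: define_froi(m, atlas, p, cfg) for p in parcels}
            for key, m in tmaps.items()
        }
        for comparison in COMPARISONS:
            per_parcel = {}
            for p in parcels:
                if comparison == "between":
                    vals = [
                        dice(frois[("standard", ri)][p], frois[("speeded", rj)][p])
                        for ri in ("1", "2")
                        for rj in ("1", "2")
                    ]
                    per_parcel[p] = float(np.mean(vals))
                else:
                    version = comparison.removeprefix("within_")
                    per_parcel[p] = dice(
                        frois[(version, "1")][p], frois[(version, "2")][p]
                    )
            results.append(
                SimilarityResult(
                    comparison=comparison,
                    metric="dice",
                    per_parcel=per_parcel,
                    aggregate=float(np.mean(list(per_parcel.values()))),
                    subject=subject,
                    fraction=fraction,
                )
            )
    return results


def similarity_table(results: Sequence[SimilarityResult]) -> pd.DataFrame:
    """Tidy long-format table of similarity results."""
    rows = []
    for res in results:
        for parcel, value in res.per_parcel.items():
            rows.append(
                {
                    "subject": res.subject,
                    "comparison": res.comparison,
                    "metric": res.metric,
                    "fraction": res.fraction if res.fraction is not None else np.nan,
                    "parcel": parcel,
                    "value": value,
                }
            )
        rows.append(
            {
                "subject": res.subject,
                "comparison": res.comparison,
                "metric": res.metric,
                "fraction": res.fraction if res.fraction is not None else np.nan,
                "parcel": "__aggregate__",
                "value": res.aggregate,
            }
        )
    return pd.DataFrame(rows)
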