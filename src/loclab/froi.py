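"""Parcel-constrained subject-specific fROIs and cross-validated responses.

Group-constrained subject-specific (GSS) definition: within each fixed
parcel, select the top fraction (default 10%) of voxels by the defining
contrast's t value.  Response magnitudes for the conditions that define
the fROI are extracted with across-runs cross-validation — one run
defines the fROI, the other run provides the condition effect values,
and the two folds are averaged — so selection and measurement never use
the same data (avoiding circular-selection bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .firstlevel import ContrastMap
from .synthsubject import GeometryError, ParcelAtlas, VolumeGrid

__all__ = [
    "FROIConfig",
    "FROI",
    "define_froi",
    "mirror_parcels",
    "crossval_response",
    "RESPONSE_COLUMNS",
]

#: long-format schema consumed by the group statistics module
RESPONSE_COLUMNS = (
    "subject",
    "version",
    "froi",
    "hemisphere",
    "condition",
    "response",
    "n_voxels",
)


@dataclass(frozen=True)
class FROIConfig:
    fraction: float = 0.10
    parcel_names: tuple[str, ...] = (
        "LIFG",
        "LIFGorb",
        "LMFG",
        "LAntTemp",
        "LPostTemp",
    )
    tie_break: str = "linear_index"

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.tie_break != "linear_index":
            raise ValueError(f"unknown tie-break rule {self.tie_break!r}")


@dataclass(frozen=True)
class FROI:
    """Top-fraction voxel set of one parcel for one subject."""

    parcel_name: str
    voxel_indices: tuple[int, ...]  # 0-based linear indices, ascending t rank
    defining_contrast: str
    defining_run: str | None
    n_parcel_voxels: int

    @property
    def size(self) -> int:
        return len(self.voxel_indices)

    def index_set(self) -> frozenset[int]:
        return frozenset(self.voxel_indices)


def froi_size(fraction: float, n_parcel_voxels: int) -> int:
    """Selected-voxel count: floor(fraction × n), with a floor of 1."""
    return max(1, int(np.floor(fraction * n_parcel_voxels)))


def define_froi(
    tmap: ContrastMap,
    atlas: ParcelAtlas,
    parcel: str,
    config: FROIConfig | None = None,
) -> FROI:
    """Select the top-fraction voxels of a parcel by t value.

    Voxels are ordered by (t descending, linear index ascending); the
    linear-index tie-break makes the selection deterministic across
    platforms and enumeration orders.
    """
    cfg = config or FROIConfig()
    t = np.asarray(tmap.t)
    if t.shape != atlas.labels.shape:
        raise ValueError("t map and atlas do not share a grid")
    idx = atlas.parcel_indices(parcel)
    if idx.size == 0:
        raise ValueError(f"parcel {parcel!r} is empty")
    tvals = t.ravel()[idx]
    if np.all(np.isnan(tvals)):
        raise ValueError(f"all t values in parcel {parcel!r} are NaN")
    k = froi_size(cfg.fraction, idx.size)
    # sort by (-t, linear index); NaNs sink to the end
    key_t = np.where(np.isnan(tvals), -np.inf, tvals)
    order = np.lexsort((idx, -key_t))
    chosen = idx[order[:k]]
    return FROI(
        parcel_name=parcel,
        voxel_indices=tuple(int(i) for i in chosen),
        defining_contrast=tmap.contrast_name,
        defining_run=tmap.source_run,
        n_parcel_voxels=int(idx.size),
    )


_MIRROR_SUFFIX = "_mirror"


def mirror_parcels(atlas: ParcelAtlas) -> ParcelAtlas:
    """Reflect parcel labels across the mid-sagittal plane (world x → −x).

    Requires a grid whose affine makes voxel reflection i → nx−1−i the
    world-x sign flip; otherwise a :class:`GeometryError` is raised.
    Mirroring twice returns the original atlas (names toggle a suffix).
    """
    grid = atlas.grid
    A = np.asarray(grid.affine)
    nx = grid.shape[0]
    if np.any(np.abs(A[0, 1:3]) > 1e-9) or np.any(np.abs(A[1:3, 0]) > 1e-9):
        raise GeometryError("affine has x cross-terms; cannot mirror by axis flip")
    x0 = A[0, 3]
    x_end = A[0, 0] * (nx - 1) + A[0, 3]
    if abs(x0 + x_end) > 1e-6:
        raise GeometryError(
            "grid is not symmetric about the world x = 0 plane "
            f"(edges at {x0} and {x_end} mm)"
        )
    labels = atlas.labels[::-1, :, :].copy()
    names = {
        lab: (
            n[: -len(_MIRROR_SUFFIX)]
            if n.endswith(_MIRROR_SUFFIX)
            else n + _MIRROR_SUFFIX
        )
        for lab, n in atlas.names.items()
    }
    return ParcelAtlas(grid=grid, labels=labels, names=names)


def _hemisphere(parcel_name: str) -> str:
    if parcel_name.endswith(("_R", "_RH")) or parcel_name.endswith(_MIRROR_SUFFIX):
        return "RH"
    return "LH"


def crossval_response(
    maps_by_run: Mapping[str, Mapping[str, object]],
    atlas: ParcelAtlas,
    config: FROIConfig | None = None,
    subject: str = "",
    version: str = "",
) -> pd.DataFrame:
    """Across-runs cross-validated condition responses.

    ``maps_by_run`` maps a run id to ``{"defining": ContrastMap,
    "conditions": {name: ContrastMap}}``.  Exactly two runs are
    required.  For each fold, the fROI is defined on one run's t map and
    per-condition effect values of the held-out run are averaged over
    the fROI voxels; the two folds are then averaged into a single value
    per (fROI, condition).
    """
    cfg = config or FROIConfig()
    runs = sorted(maps_by_run)
    if len(runs) != 2:
        raise ValueError(f"exactly 2 runs required for cross-validation, got {runs}")
    for r in runs:
        entry = maps_by_run[r]
        if "defining" not in entry or "conditions" not in entry:
            raise ValueError(f"run {r!r} is missing defining/condition maps")
    rows = []
    for parcel in cfg.parcel_names:
        fold_values: dict[str, list[float]] = {}
        n_vox = None
        for define_run, extract_run in (runs, runs[::-1]):
            froi = define_froi(maps_by_run[define_run]["defining"], atlas, parcel, cfg)
            n_vox = froi.size
            sel = np.asarray(froi.voxel_indices)
            for cond, cmap in maps_by_run[extract_run]["conditions"].items():
                val = float(np.asarray(cmap.effect).ravel()[sel].mean())
                fold_values.setdefault(cond, []).append(val)
        for cond, vals in fold_values.items():
            rows.append(
                {
                    "subject": subject,
                    "version": version,
                    "froi": parcel,
                    "hemisphere": _hemisphere(parcel),
                    "condition": cond,
                    "response": float(np.mean(vals)),
                    "n_voxels": n_vox,
                }
            )
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))
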