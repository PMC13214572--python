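"""NIfTI and events-file input/output.

Volumes are written as NIfTI-1 with the grid affine; BOLD series as
32-bit float with the repetition time carried in the header's fourth
pixel dimension, label volumes as 16-bit integers.  Events files are
tab-separated with 0-based onsets in seconds and a period decimal
separator (a BIDS-events-compatible dialect).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .paradigm import FIXATION, TimedEvent
from .synthsubject import ParcelAtlas, TimeSeriesImage, VolumeGrid

__all__ = [
    "FormatError",
    "write_bold",
    "read_bold",
    "write_volume",
    "read_volume",
    "write_atlas",
    "read_atlas",
    "read_events",
    "events_dataframe",
    "LooseSchedule",
    "schedule_from_events",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    affine = np.asarray(img.affine)
    voxel = float(np.abs(affine[0, 0]))
    return VolumeGrid(shape=tuple(img.shape[:3]), voxel_size_mm=voxel, affine=affine)


def write_bold(ts: TimeSeriesImage, path: str | Path) -> None:
    img = nib.Nifti1Image(ts.data.astype(np.float32), np.asarray(ts.grid.affine))
    zooms = list(img.header.get_zooms())
    zooms[3] = ts.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path: str | Path) -> TimeSeriesImage:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D BOLD volume, got {img.ndim}-D")
    tr = float(img.header.get_zooms()[3])
    return TimeSeriesImage(
        grid=_grid_from_img(img),
        data=np.asarray(img.dataobj, dtype=np.float32),
        tr_s=tr,
    )


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(grid.affine))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), _grid_from_img(img)


def write_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    """Label volume as int16 NIfTI plus a sidecar TSV of label names."""
    img = nib.Nifti1Image(
        atlas.labels.astype(np.int16), np.asarray(atlas.grid.affine)
    )
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
    names = pd.DataFrame(
        sorted(atlas.names.items()), columns=["label", "name"]
    )
    names.to_csv(f"{sidecar}_labels.tsv", sep="\t", index=False)


def read_atlas(path: str | Path) -> ParcelAtlas:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    names_df = pd.read_csv(f"{sidecar}_labels.tsv", sep="\t")
    names = {int(r.label): str(r.name) for r in names_df.itertuples()}
    return ParcelAtlas(grid=_grid_from_img(img), labels=labels, names=names)


@dataclass(frozen=True)
class _EventConditions:
    conditions: tuple[str, ...]


@dataclass(frozen=True)
class LooseSchedule:
    """Duck-typed schedule built from an events file: enough structure
    (events, conditions, total duration) to drive design-matrix
    construction without the full run invariants."""

    version: _EventConditions
    events: tuple[TimedEvent, ...]
    total_duration_s: float


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events TSV.

    Onsets/durations must be numeric seconds; rows must be sorted and
    non-overlapping.  Violations are reported with 1-based data row
    numbers.  Durations suspiciously large (> 3600) trigger an explicit
    unit error (milliseconds written where seconds are expected).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("onset", "duration"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    if (df["duration"] > 3600).any() or (df["onset"] > 36000).any():
        raise FormatError(
            f"{path}: onset/duration values exceed plausible seconds; "
            "are these milliseconds?"
        )
    bad_rows = []
    end = -np.inf
    for i, row in enumerate(df.itertuples(), start=1):
        if row.onset < end - 1e-6:
            bad_rows.append(i)
        end = max(end, row.onset + row.duration)
    if bad_rows:
        raise FormatError(
            f"{path}: overlapping or unsorted events at data rows {bad_rows}"
        )
    return df


def events_dataframe(path: str | Path) -> pd.DataFrame:
    return read_events(path)


def schedule_from_events(path: str | Path) -> LooseSchedule:
    df = read_events(path)
    events = tuple(
        TimedEvent(
            onset_s=float(r.onset),
            duration_s=float(r.duration),
            condition=str(r.trial_type),
            block_index=0,
        )
        for r in df.itertuples()
    )
    conditions = tuple(
        sorted(c for c in df["trial_type"].unique() if c != FIXATION)
    )
    total = float((df["onset"] + df["duration"]).max())
    return LooseSchedule(
        version=_EventConditions(conditions=conditions),
        events=events,
        total_duration_s=total,
    )
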