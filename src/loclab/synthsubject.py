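"""Synthetic multi-subject BOLD data with known ground truth.

The generator emulates the ingredients the localizer-validation analysis
relies on: fixed spherical parcels shared across subjects, a
subject-specific population of "selective" voxels inside each parcel
whose location jitters across subjects (mimicking inter-individual
variability in the precise locations of functional areas), condition
amplitudes in percent signal change with sentences > nonwords in
language voxels and hard > easy in Multiple-Demand voxels, a
low-frequency cosine drift, and temporally autocorrelated AR(1) noise
that controls run-to-run reliability.

The forward model shares the HRF/convolution code with the first-level
GLM module, so a noiseless simulation is fit exactly by the GLM — the
round-trip recovery tests exploit this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import firstlevel
from .paradigm import FIXATION, RunSchedule

__all__ = [
    "VolumeGrid",
    "ParcelAtlas",
    "GroundTruthSubject",
    "NoiseSpec",
    "TimeSeriesImage",
    "GeometryError",
    "make_grid",
    "make_atlas",
    "default_atlas",
    "DEFAULT_EFFECTS",
    "LANGUAGE_PARCELS",
    "MD_PARCELS",
    "make_subject_truth",
    "simulate_bold",
]


class GeometryError(ValueError):
    """A requested geometric construction does not fit the grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid with a world affine (RAS+, mm)."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape components must be >= 1")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (np.asarray(self.affine) @ hom.T).T[:, :3]


def make_grid(shape=(24, 24, 24), voxel_size_mm: float = 2.0) -> VolumeGrid:
    """Isotropic RAS grid with the world origin at the grid center, so the
    mid-sagittal plane is a voxel-symmetry plane (x index i ↔ nx−1−i)."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return VolumeGrid(shape=tuple(shape), voxel_size_mm=voxel_size_mm, affine=affine)


@dataclass(frozen=True)
class ParcelAtlas:
    grid: VolumeGrid
    labels: np.ndarray  # int16, 0 = background
    names: dict[int, str]

    def label_of(self, name: str) -> int:
        for lab, n in self.names.items():
            if n == name:
                return lab
        raise KeyError(f"no parcel named {name!r}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def parcel_indices(self, name: str) -> np.ndarray:
        """0-based linear voxel indices of a parcel, ascending."""
        return np.flatnonzero(self.labels.ravel() == self.label_of(name))


def make_atlas(
    grid: VolumeGrid,
    parcel_spec: Sequence[tuple[str, tuple[float, float, float], float]],
    seed: int = 0,
) -> ParcelAtlas:
    """Disjoint spherical parcels on a grid.

    ``parcel_spec`` entries are (name, center in voxel coordinates,
    radius in voxels).  Overlapping requests are resolved by first-come
    priority; out-of-bounds centers raise :class:`GeometryError`.
    ``seed`` is accepted for interface uniformity (the construction is
    deterministic).
    """
    del seed
    labels = np.zeros(grid.shape, dtype=np.int16)
    names: dict[int, str] = {}
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
    for lab, (name, center, radius) in enumerate(parcel_spec, start=1):
        c = np.asarray(center, dtype=float)
        if np.any(c < 0) or np.any(c > np.asarray(grid.shape) - 1):
            raise GeometryError(f"parcel {name!r} center {center} outside grid")
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        ball = d2 <= radius**2 + 1e-9
        labels[ball & (labels == 0)] = lab
        names[lab] = name
        if not np.any(labels == lab):
            raise GeometryError(f"parcel {name!r} labeled no voxels")
    return ParcelAtlas(grid=grid, labels=labels, names=names)


#: Language-network parcel names (left-hemisphere core set; the angular
#: gyrus parcel is deliberately absent from the default language set).
LANGUAGE_PARCELS = ("LIFG", "LIFGorb", "LMFG", "LAntTemp", "LPostTemp")
MD_PARCELS = ("MDfront_L", "MDpost_L", "MDfront_R", "MDpost_R")

_DEFAULT_SPEC = [
    ("LIFG", (5.0, 5.0, 10.0), 3.0),
    ("LIFGorb", (5.0, 5.0, 17.0), 3.0),
    ("LMFG", (5.0, 12.0, 13.0), 3.0),
    ("LAntTemp", (5.0, 19.0, 10.0), 3.0),
    ("LPostTemp", (5.0, 19.0, 17.0), 3.0),
    ("MDfront_L", (8.0, 8.0, 4.0), 3.0),
    ("MDpost_L", (8.0, 16.0, 4.0), 3.0),
    ("MDfront_R", (15.0, 8.0, 4.0), 3.0),
    ("MDpost_R", (15.0, 16.0, 4.0), 3.0),
]


def default_atlas(shape=(24, 24, 24), voxel_size_mm: float = 2.0) -> ParcelAtlas:
    """The default synthetic atlas: five left-hemisphere "language"
    spheres and four "MD" spheres (two per hemisphere) on a 24³ grid."""
    return make_atlas(make_grid(shape, voxel_size_mm), _DEFAULT_SPEC)


#: Default true amplitudes in percent signal change, keyed
#: network → (condition, version).  Language voxels respond more to
#: sentences than nonwords, with a larger contrast in the speeded
#: version (sentences up, nonwords down); MD voxels respond hard > easy
#: and show the reverse-then-null pattern for the reading conditions.
DEFAULT_EFFECTS: dict[str, dict[tuple[str, str], float]] = {
    "language": {
        ("sentences", "standard"): 3.8,
        ("nonwords", "standard"): 1.0,
        ("sentences", "speeded"): 4.4,
        ("nonwords", "speeded"): 0.2,
    },
    "md": {
        ("hard", "spatialWM"): 4.0,
        ("easy", "spatialWM"): 1.4,
        ("sentences", "standard"): 0.4,
        ("nonwords", "standard"): 1.0,
        ("sentences", "speeded"): 0.9,
        ("nonwords", "speeded"): 0.8,
    },
}

_KNOWN_CONDITIONS = {"sentences", "nonwords", "hard", "easy"}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of the simulated scanner series."""

    sigma: float = 3.0  # percent-signal units
    ar_rho: float = 0.2
    drift_amplitude: float = 0.5  # percent of baseline
    drift_period_s: float = 200.0
    baseline: float = 1000.0
    spatial_fwhm_mm: float = 0.0  # 0 = spatially independent noise

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not abs(self.ar_rho) < 1:
            raise ValueError("|ar_rho| must be < 1")


@dataclass(frozen=True)
class GroundTruthSubject:
    """Known truth for one simulated subject.

    ``amplitude`` maps (condition, version) to a full 3-D volume of true
    response amplitudes (percent signal change; zero outside selective
    voxels).  ``selective`` maps (parcel name, version) to the boolean
    volume of that subject's selective voxels, always inside the parcel.
    """

    subject_id: str
    amplitude: dict[tuple[str, str], np.ndarray]
    selective: dict[tuple[str, str], np.ndarray]
    jitter_seed: int

    def amplitude_for(self, condition: str, version: str) -> np.ndarray:
        key = (condition, version)
        if key in self.amplitude:
            return self.amplitude[key]
        shape = next(iter(self.amplitude.values())).shape
        return np.zeros(shape)


def _network_of(parcel_name: str) -> str:
    return "md" if parcel_name.startswith("MD") else "language"


def _weight_field(
    grid: VolumeGrid,
    parcel_mask: np.ndarray,
    center_vox: np.ndarray,
    rng: np.random.Generator,
    jitter_sd_vox: float,
    version_shift_vox: np.ndarray,
    n_blobs: int = 2,
    blob_sd_vox: float = 2.5,
) -> np.ndarray:
    """Smooth random Gaussian-blob mixture over a parcel, displaced by
    per-subject jitter (and a small per-version shift)."""
    subject_shift = rng.normal(0.0, jitter_sd_vox, size=3)
    offsets = rng.normal(0.0, 1.5, size=(n_blobs, 3))
    weights = rng.uniform(0.5, 1.0, size=n_blobs)
    idx = np.argwhere(parcel_mask).astype(float)
    w = np.zeros(len(idx))
    for off, amp in zip(offsets, weights):
        c = center_vox + subject_shift + version_shift_vox + off
        d2 = ((idx - c) ** 2).sum(axis=1)
        w += amp * np.exp(-d2 / (2.0 * blob_sd_vox**2))
    field = np.zeros(grid.shape)
    field[parcel_mask] = w
    return field


def make_subject_truth(
    atlas: ParcelAtlas,
    effect_config: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    selective_fraction: float = 0.2,
    jitter_sd_mm: float = 4.0,
    seed: int = 0,
    version_jitter_sd_mm: float = 1.0,
    subject_gain_sd: float = 0.15,
    subject_id: str | None = None,
) -> GroundTruthSubject:
    """Draw one subject's selective-voxel topography and amplitudes.

    Within each parcel a smooth random weight field (a Gaussian-blob
    mixture centered near the parcel center, displaced by a per-subject
    jitter of standard deviation ``jitter_sd_mm``) is thresholded so the
    top ``selective_fraction`` of parcel voxels are selective.  A small
    additional per-version displacement (``version_jitter_sd_mm``) makes
    the topography version-specific, so within-version similarity
    exceeds between-version similarity in expectation.  Selective voxels
    carry the configured (condition, version) amplitudes scaled by a
    per-subject lognormal gain (sd ``subject_gain_sd`` on the log scale,
    emulating between-subject response-magnitude variability);
    everything else is zero (fixation is implicitly zero).
    """
    if not 0 < selective_fraction <= 1:
        raise ValueError("selective_fraction must be in (0, 1]")
    effects = effect_config if effect_config is not None else DEFAULT_EFFECTS
    for network, table in effects.items():
        for (cond, _version) in table:
            if cond not in _KNOWN_CONDITIONS:
                raise KeyError(f"unknown condition {cond!r} in effect config")
    versions = sorted({v for table in effects.values() for (_c, v) in table})
    grid = atlas.grid
    jitter_vox = jitter_sd_mm / grid.voxel_size_mm
    version_jitter_vox = version_jitter_sd_mm / grid.voxel_size_mm

    gain_rng = np.random.default_rng([seed, 3])
    gain = float(np.exp(gain_rng.normal(0.0, subject_gain_sd))) if subject_gain_sd else 1.0

    selective: dict[tuple[str, str], np.ndarray] = {}
    amplitude: dict[tuple[str, str], np.ndarray] = {}
    for lab, name in atlas.names.items():
        mask = atlas.labels == lab
        center = np.argwhere(mask).mean(axis=0)
        n_in = int(mask.sum())
        k = max(1, int(np.floor(selective_fraction * n_in)))
        # one subject-level RNG per parcel; version shifts drawn from a
        # parallel stream so versions share the subject's base topography
        for vi, version in enumerate(versions):
            rng = np.random.default_rng([seed, lab, 7])
            shift_rng = np.random.default_rng([seed, lab, 11, vi])
            vshift = (
                shift_rng.normal(0.0, version_jitter_vox, size=3)
                if version_jitter_vox > 0
                else np.zeros(3)
            )
            field = _weight_field(grid, mask, center, rng, jitter_vox, vshift)
            vals = field[mask]
            order = np.argsort(-vals, kind="stable")
            sel_local = np.zeros(n_in, dtype=bool)
            sel_local[order[:k]] = True
            sel = np.zeros(grid.shape, dtype=bool)
            sel[mask] = sel_local
            selective[(name, version)] = sel
        network = _network_of(name)
        table = effects.get(network, {})
        for (cond, version), amp in table.items():
            key = (cond, version)
            vol = amplitude.setdefault(key, np.zeros(grid.shape))
            vol[selective[(name, version)]] += amp * gain
    return GroundTruthSubject(
        subject_id=subject_id or f"sub-{seed:04d}",
        amplitude=amplitude,
        selective=selective,
        jitter_seed=seed,
    )


@dataclass(frozen=True)
class TimeSeriesImage:
    """4-D voxel grid (x, y, z, t) with a repetition time."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError("data must be 4-D with t >= 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contain non-finite values")

    @property
    def n_scans(self) -> int:
        return int(self.data.shape[3])


def _ar1_noise(
    rng: np.random.Generator,
    n_voxels: int,
    n_scans: int,
    rho: float,
    dtype=np.float32,
) -> np.ndarray:
    """Stationary unit-variance AR(1) series per voxel, (n_voxels, t).

    Generated recursively (x_t = ρ x_{t−1} + √(1−ρ²) e_t) with the first
    sample drawn from the stationary N(0, 1) distribution.
    """
    from scipy.signal import lfilter

    innov = rng.standard_normal((n_voxels, n_scans), dtype=dtype)
    innov[:, 1:] *= dtype(np.sqrt(1.0 - rho**2))
    return lfilter([1.0], [1.0, -rho], innov, axis=1).astype(dtype, copy=False)


def simulate_bold(
    truth: GroundTruthSubject,
    schedule: RunSchedule,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    tr_s: float = 2.0,
    grid: VolumeGrid | None = None,
    hrf_params: firstlevel.HRFParams | None = None,
    oversample_dt_s: float = 0.1,
    dtype=np.float32,
) -> TimeSeriesImage:
    """Forward-simulate one run of BOLD data.

    Each voxel's series is
    ``baseline · (1 + Σ_c amp_c/100 · reg_c(t) + drift(t)/100·drift_amp
    + σ/100 · AR1(t))`` where ``reg_c`` is the unit-peak convolved
    condition boxcar shared with the GLM module.  The acquisition clock
    starts at schedule time 0: pre-steady-state scans are never
    generated, mirroring their exclusion in a real analysis.
    """
    ns = noise or NoiseSpec()
    version = schedule.version.name
    any_amp = next(iter(truth.amplitude.values()))
    shape = any_amp.shape
    if grid is not None and tuple(grid.shape) != tuple(shape):
        raise ValueError(
            f"grid shape {grid.shape} does not match truth volumes {shape}"
        )
    n_scans = int(np.floor(schedule.total_duration_s / tr_s + 1e-9))
    t = np.arange(n_scans) * tr_s

    nvox = int(np.prod(shape))
    rng = np.random.default_rng(seed)
    # accumulate in voxels × time; float32 by default (the scanner's depth),
    # float64 available for high-precision round-trip checks
    data = _ar1_noise(rng, nvox, n_scans, ns.ar_rho, dtype=dtype)
    if ns.spatial_fwhm_mm > 0 and grid is not None:
        data = firstlevel.gaussian_smooth(
            data.reshape(shape + (n_scans,)), ns.spatial_fwhm_mm, grid.voxel_size_mm
        ).reshape(nvox, n_scans)
        data /= data.std()
    data *= dtype(ns.sigma / 100.0)
    drift = (ns.drift_amplitude / 100.0) * np.cos(2.0 * np.pi * t / ns.drift_period_s)
    data += drift.astype(dtype)[None, :]
    data += dtype(1.0)
    for cond in schedule.version.conditions:
        amp = truth.amplitude_for(cond, version)
        if not np.any(amp):
            continue
        reg = firstlevel.condition_regressor(
            schedule, cond, n_scans, tr_s, oversample_dt_s, hrf_params
        )
        data += np.outer(amp.ravel() / 100.0, reg).astype(dtype)
    data *= dtype(ns.baseline)
    return TimeSeriesImage(
        grid=grid if grid is not None else make_grid(shape),
        data=data.reshape(shape + (n_scans,)),
        tr_s=tr_s,
    )
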