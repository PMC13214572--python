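"""First-level GLM for blocked BOLD data with AR(1) prewhitening.

The model follows the conventional single-run localizer analysis chain:
condition boxcars convolved with the canonical double-gamma HRF (sampled
on an oversampled grid, then read out at scan onsets), optional temporal
derivatives, a discrete-cosine drift basis implementing high-pass
filtering with a 128-s cutoff, a constant, and user-supplied nuisance
regressors.  Data are scaled to percent of each voxel's temporal mean
before fitting, and both data and design are premultiplied by a
fixed-coefficient AR(1) whitening matrix (default a = 0.2, with the
stationary-variance correction on the first row) so ordinary least
squares on the whitened system is the generalized-least-squares
estimator under that noise model.

Convolved condition regressors are rescaled to unit peak within the run,
so a beta of ``b`` means a peak response of ``b`` percent signal change —
directly commensurable with the amplitudes injected by the simulator,
which shares this code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .paradigm import FIXATION, RunSchedule

__all__ = [
    "HRFParams",
    "GLMOptions",
    "DesignMatrix",
    "GLMFit",
    "ContrastMap",
    "RankError",
    "canonical_hrf",
    "condition_regressor",
    "dct_drift_basis",
    "n_drift_columns",
    "build_design_matrix",
    "whitening_matrix",
    "fit_glm",
    "contrast",
    "gaussian_smooth",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class RankError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (the de facto canonical form)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion_s <= 0 or self.undershoot_dispersion_s <= 0:
            raise ValueError("HRF dispersions must be positive")


@dataclass(frozen=True)
class GLMOptions:
    highpass_cutoff_s: float = 128.0
    ar_coef: float = 0.2
    include_derivatives: bool = True
    hrf: HRFParams = field(default_factory=HRFParams)
    oversample_dt_s: float = 0.1
    smoothing_fwhm_mm: float | None = 4.0

    def __post_init__(self) -> None:
        if not abs(self.ar_coef) < 1:
            raise ValueError("|ar_coef| must be < 1")


def canonical_hrf(dt_s: float, params: HRFParams | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s`` on [0, length].

    Difference of two gamma densities (shape = delay/dispersion,
    scale = dispersion), the undershoot scaled down by the
    peak:undershoot ratio; peak-normalized to 1.  With the default
    parameters the kernel peaks near 5 s.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.length_s + dt_s / 2, dt_s)
    peak = gamma_dist.pdf(
        t, a=p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s
    )
    under = gamma_dist.pdf(
        t,
        a=p.undershoot_delay_s / p.undershoot_dispersion_s,
        scale=p.undershoot_dispersion_s,
    )
    h = peak - under / p.peak_undershoot_ratio
    return h / h.max()


def _boxcar(
    schedule: RunSchedule, condition: str, duration_s: float, dt_s: float
) -> np.ndarray:
    n = int(np.ceil(duration_s / dt_s))
    box = np.zeros(n)
    for ev in schedule.events:
        if ev.condition != condition:
            continue
        i0 = int(round(ev.onset_s / dt_s))
        i1 = int(round((ev.onset_s + ev.duration_s) / dt_s))
        box[i0:min(i1, n)] = 1.0
    return box


def condition_regressor(
    schedule: RunSchedule,
    condition: str,
    n_scans: int,
    tr_s: float,
    dt_s: float = 0.1,
    hrf_params: HRFParams | None = None,
    normalize_peak: bool = True,
) -> np.ndarray:
    """Boxcar ⊛ HRF for one condition, sampled at scan onsets.

    The regressor is rescaled to unit peak within the run (see module
    docstring); set ``normalize_peak=False`` for the raw convolution.
    """
    h = canonical_hrf(dt_s, hrf_params)
    box = _boxcar(schedule, condition, n_scans * tr_s, dt_s)
    conv = np.convolve(box, h)[: len(box)] * dt_s
    scan_idx = np.round(np.arange(n_scans) * tr_s / dt_s).astype(int)
    reg = conv[scan_idx]
    if normalize_peak:
        peak = np.abs(reg).max()
        if peak > 0:
            reg = reg / peak
    return reg


def n_drift_columns(n_scans: int, tr_s: float, cutoff_s: float) -> int:
    """Number of DCT drift regressors (excluding the constant) whose full
    period exceeds the high-pass cutoff: floor(2 T / cutoff)."""
    return int(np.floor(2.0 * n_scans * tr_s / cutoff_s))


def dct_drift_basis(n_scans: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Unit-norm DCT-II basis columns with period 2T/k > cutoff, k ≥ 1."""
    k_max = n_drift_columns(n_scans, tr_s, cutoff_s)
    i = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * i + 1) * k / (2 * n_scans))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray
    names: tuple[str, ...]
    condition_columns: dict[str, int]
    nuisance_columns: tuple[int, ...]
    tr_s: float

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.names)).to_csv(
            path, sep="\t", index=False
        )


def build_design_matrix(
    schedule: RunSchedule,
    n_scans: int,
    tr_s: float,
    options: GLMOptions | None = None,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the single-run design matrix.

    Columns: one convolved boxcar per condition (fixation is modeled
    implicitly and gets no column), optional temporal derivatives
    (centered finite differences, orthogonalized against their parent so
    condition betas stay interpretable), DCT drift columns, a constant,
    and any user-supplied nuisance matrix.
    """
    opts = options or GLMOptions()
    if schedule.total_duration_s + 1e-9 < n_scans * tr_s:
        raise ValueError(
            f"schedule covers {schedule.total_duration_s}s < "
            f"{n_scans} scans × {tr_s}s"
        )
    conditions = [c for c in schedule.version.conditions]
    cols: list[np.ndarray] = []
    names: list[str] = []
    cond_cols: dict[str, int] = {}
    for cond in conditions:
        reg = condition_regressor(
            schedule, cond, n_scans, tr_s, opts.oversample_dt_s, opts.hrf
        )
        cond_cols[cond] = len(cols)
        cols.append(reg)
        names.append(cond)
    nuis_idx: list[int] = []
    if opts.include_derivatives:
        for cond in conditions:
            reg = cols[cond_cols[cond]]
            d = np.gradient(reg, tr_s)
            # orthogonalize against the parent regressor
            denom = reg @ reg
            if denom > 0:
                d = d - (d @ reg) / denom * reg
            nuis_idx.append(len(cols))
            cols.append(d)
            names.append(f"{cond}_derivative")
    drift = dct_drift_basis(n_scans, tr_s, opts.highpass_cutoff_s)
    for k in range(drift.shape[1]):
        nuis_idx.append(len(cols))
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    nuis_idx.append(len(cols))
    cols.append(np.ones(n_scans))
    names.append("constant")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance matrix does not match n_scans")
        for k in range(nuisance.shape[1]):
            nuis_idx.append(len(cols))
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k + 1}")
    X = np.column_stack(cols)
    _check_rank(X, names)
    return DesignMatrix(
        values=X,
        names=tuple(names),
        condition_columns=cond_cols,
        nuisance_columns=tuple(nuis_idx),
        tr_s=tr_s,
    )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise RankError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns include: {', '.join(bad)}"
        )


def whitening_matrix(n: int, rho: float) -> np.ndarray:
    """AR(1) prewhitening matrix W with W y decorrelating lag-1 noise of
    coefficient ``rho``: row i is y_i − rho·y_{i−1}, the first row scaled
    by √(1 − rho²) (stationary-variance correction)."""
    W = np.eye(n)
    W[0, 0] = np.sqrt(1.0 - rho**2)
    idx = np.arange(1, n)
    W[idx, idx - 1] = -rho
    return W


@dataclass(frozen=True)
class GLMFit:
    beta: np.ndarray  # (n_voxels, p)
    sigma2: np.ndarray  # (n_voxels,)
    dof: int
    xtx_inv: np.ndarray  # (p, p), of the whitened design
    design: DesignMatrix
    grid: "object" = None  # VolumeGrid when fit on an image
    shape3d: tuple[int, int, int] | None = None
    voxel_mask: np.ndarray | None = None


@dataclass(frozen=True)
class ContrastMap:
    """Per-voxel effect size and t statistic for a named contrast."""

    effect: np.ndarray
    t: np.ndarray
    contrast_name: str
    grid: "object" = None
    source_run: str | None = None


def fit_glm(
    data: np.ndarray,
    X: DesignMatrix,
    options: GLMOptions | None = None,
    grid=None,
) -> GLMFit:
    """Fit the prewhitened GLM voxelwise.

    ``data`` may be 2-D (n_scans × n_voxels) or a 4-D volume
    (x, y, z, t).  Each voxel's series is scaled to percent of its
    temporal mean, then data and design are premultiplied by the AR(1)
    whitening matrix and solved by ordinary least squares.
    """
    opts = options or GLMOptions()
    shape3d = None
    if data.ndim == 4:
        shape3d = data.shape[:3]
        Yv = data.reshape(-1, data.shape[3])  # voxels × time, contiguous
    elif data.ndim == 2:
        Yv = np.ascontiguousarray(np.asarray(data).T)
    else:
        raise ValueError("data must be 2-D (t × voxels) or 4-D (x,y,z,t)")
    if not np.all(np.isfinite(Yv)):
        raise ValueError("data contain non-finite values")
    if Yv.shape[1] != X.n_scans:
        raise ValueError(f"data have {Yv.shape[1]} scans, design has {X.n_scans}")
    work_dtype = Yv.dtype if Yv.dtype == np.float32 else np.float64
    mean = Yv.mean(axis=1, keepdims=True)
    mean = np.where(mean == 0, 1.0, mean)
    Yv = (100.0 / mean).astype(work_dtype) * Yv
    W = whitening_matrix(X.n_scans, opts.ar_coef)
    Xw = W @ X.values
    rank = np.linalg.matrix_rank(Xw)
    dof = X.n_scans - rank
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    # whiten on the right (voxels-first) and solve the normal equations;
    # everything is a dense GEMM, which keeps whole-brain fits fast
    Yw = Yv @ W.T.astype(work_dtype)
    beta = (Yw @ Xw.astype(work_dtype)) @ xtx_inv.T.astype(work_dtype)
    resid = Yw - beta @ Xw.T.astype(work_dtype)
    sigma2 = np.einsum("vt,vt->v", resid, resid, dtype=np.float64) / dof
    return GLMFit(
        beta=np.asarray(beta, dtype=np.float64),
        sigma2=sigma2,
        dof=dof,
        xtx_inv=xtx_inv,
        design=X,
        grid=grid,
        shape3d=shape3d,
    )


def contrast(
    fit: GLMFit,
    weights: Mapping[str, float],
    name: str | None = None,
    source_run: str | None = None,
) -> ContrastMap:
    """Linear contrast of condition betas.

    t = cᵀβ / √(σ̂² · cᵀ(XᵀX)⁻¹c) on the whitened fit.  The reported
    effect is expressed as percent of each voxel's *estimated baseline*
    (cᵀβ normalized by the constant-term coefficient, × 100): unlike
    raw percent-of-temporal-mean betas this removes the small
    multiplicative bias the task signal itself induces on the temporal
    mean, so injected simulator amplitudes are recovered exactly in the
    noiseless limit.  The t statistic is invariant to this per-voxel
    rescaling convention and is computed from the raw contrast.
    """
    p = fit.beta.shape[1]
    c = np.zeros(p)
    for cond, w in weights.items():
        if cond not in fit.design.condition_columns:
            raise KeyError(f"unknown condition {cond!r} in contrast")
        c[fit.design.condition_columns[cond]] = w
    raw = fit.beta @ c
    var_unit = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = raw / np.sqrt(fit.sigma2 * var_unit)
    t = np.where(fit.sigma2 > 0, t, 0.0)
    b0 = fit.beta[:, fit.design.names.index("constant")]
    effect = np.where(np.abs(b0) > 1e-3, 100.0 * raw / np.where(b0 == 0, 1, b0), raw)
    if name is None:
        name = "+".join(f"{w:+g}*{k}" for k, w in weights.items())
    if fit.shape3d is not None:
        effect = effect.reshape(fit.shape3d)
        t = t.reshape(fit.shape3d)
    return ContrastMap(
        effect=effect, t=t, contrast_name=name, grid=fit.grid, source_run=source_run
    )


def gaussian_smooth(
    data: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3-D or 4-D array.

    sigma = fwhm / (2 √(2 ln 2)) per axis, in mm, converted to voxels;
    fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return data
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    if data.ndim == 4:
        return ndimage.gaussian_filter(
            data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="nearest"
        )
    raise ValueError("expected a 3-D or 4-D array")
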