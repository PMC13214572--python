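"""Shared fixtures: paradigm materials/schedules, small simulation grids,
and toy GLM problems used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from loclab import firstlevel, paradigm, synthsubject


@pytest.fixture(scope="session")
def materials():
    return paradigm.generate_placeholder_materials(seed=7)


@pytest.fixture(scope="session")
def standard_schedule(materials):
    r1, _ = paradigm.counterbalance_orders(16, paradigm.STANDARD.conditions, seed=11)
    return paradigm.build_run_schedule(paradigm.STANDARD, 1, r1, materials, subject_seed=0)


@pytest.fixture(scope="session")
def speeded_schedule(materials):
    r1, _ = paradigm.counterbalance_orders(16, paradigm.SPEEDED.conditions, seed=11)
    return paradigm.build_run_schedule(paradigm.SPEEDED, 1, r1, materials, subject_seed=0)


@pytest.fixture(scope="session")
def default_atlas():
    return synthsubject.default_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """One language-style parcel on a small grid, for fast simulations."""
    grid = synthsubject.make_grid((12, 12, 12), 2.0)
    return synthsubject.make_atlas(grid, [("LIFG", (5.5, 5.5, 5.5), 3.0)])


def toy_design(n: int, p_extra: int, rng: np.random.Generator, tr_s: float = 2.0):
    """Small design with one condition column, extra noise regressors,
    and a constant, wrapped as a DesignMatrix."""
    cols = [rng.standard_normal(n)]
    names = ["cond"]
    for j in range(p_extra):
        cols.append(rng.standard_normal(n))
        names.append(f"x{j}")
    cols.append(np.ones(n))
    names.append("constant")
    X = np.column_stack(cols)
    return firstlevel.DesignMatrix(
        values=X,
        names=tuple(names),
        condition_columns={"cond": 0},
        nuisance_columns=tuple(range(1, len(names))),
        tr_s=tr_s,
    )


def ar1_covariance(n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) correlation matrix, marginal variance 1."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def percent_scale(y: np.ndarray) -> np.ndarray:
    return 100.0 * y / y.mean(axis=0, keepdims=True)


def dense_gls(y, X, rho):
    """Independent GLS oracle: explicit inverse of the AR(1) covariance.

    Returns beta, per-coefficient t statistics, and the residual
    variance estimate on the whitened scale (the (1−ρ²) factors cancel
    inside t, so t is comparable with the prewhitened-OLS fit).
    """
    n, p = X.shape
    Sigma = ar1_covariance(n, rho)
    Si = np.linalg.inv(Sigma)
    A = X.T @ Si @ X
    beta = np.linalg.solve(A, X.T @ Si @ y)
    r = y - X @ beta
    s2 = (r @ Si @ r) / (n - p)
    cov = s2 * np.linalg.inv(A)
    t = beta / np.sqrt(np.diag(cov))
    return beta, t, s2
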