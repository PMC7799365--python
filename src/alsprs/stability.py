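"""Penalty selection and bootstrap/permutation stabilisation of sparse CCA.

Three stages:

* ``grid_search`` — evaluate the canonical correlation on the full data over
  a 10 x 10 grid of L1 penalty pairs and pick the argmax (sparsest pair on
  ties).
* ``bootstrap_scca`` — refit at the chosen penalties on repeated 75%
  subsamples (drawn without replacement by default), restandardising within
  each subsample; summarise by the median canonical correlation, median
  per-feature weights, and per-feature selection percentages (share of
  iterations with a non-zero weight).
* ``permutation_null`` — identical resampling, but the rows of each dataset
  are independently permuted before fitting, destroying any clinical-genetic
  linkage; the p-value of the observed median correlation is its exceedance
  probability under this null.

Medians, not means, are used throughout to resist outlying iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scca import fit_scca

logger = logging.getLogger(__name__)

__all__ = ["GridResult", "BootstrapSummary", "NullSummary", "grid_search", "bootstrap_scca", "permutation_null"]

DEFAULT_PENALTIES = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass
class GridResult:
    rho: pd.DataFrame  # index t_x, columns t_z
    chosen: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return int(self.rho.size)


@dataclass
class BootstrapSummary:
    median_rho: float
    rho_ci: tuple[float, float]  # 2.5th / 97.5th percentiles
    rho_distribution: np.ndarray
    clinical_median_weights: pd.Series
    genetic_median_weights: pd.Series
    clinical_selection_pct: pd.Series
    genetic_selection_pct: pd.Series
    B: int
    frac: float
    seed: int
    penalties: tuple[float, float]
    n_failed: int = 0
    clinical_weights: np.ndarray | None = field(default=None, repr=False)  # B x p archive
    genetic_weights: np.ndarray | None = field(default=None, repr=False)  # B x q archive


@dataclass
class NullSummary:
    rho_distribution: np.ndarray
    clinical_selection_pct: pd.Series
    genetic_selection_pct: pd.Series
    p_value: float | None
    p_value_add_one: float | None
    B: int
    frac: float
    seed: int
    penalties: tuple[float, float]
    n_failed: int = 0


def _as_frame(m, prefix: str) -> pd.DataFrame:
    if isinstance(m, pd.DataFrame):
        return m
    m = np.asarray(m, float)
    return pd.DataFrame(m, columns=[f"{prefix}{i}" for i in range(m.shape[1])])


def grid_search(
    X,
    Z,
    penalties: tuple[float, ...] = DEFAULT_PENALTIES,
    tie_tol: float = 1e-12,
) -> GridResult:
    """Full-data canonical correlation over every penalty pair.

    The chosen pair attains the maximum rho; ties within ``tie_tol`` are
    broken toward sparsity (smallest t_x + t_z, then smallest t_x).
    """
    X = _as_frame(X, "clin")
    Z = _as_frame(Z, "gen")
    surface = pd.DataFrame(index=pd.Index(penalties, name="t_x"), columns=pd.Index(penalties, name="t_z"), dtype=float)
    for tx in penalties:
        for tz in penalties:
            try:
                fit = fit_scca(X.to_numpy(), Z.to_numpy(), tx, tz)
            except Exception as exc:
                raise RuntimeError(f"grid cell (t_x={tx}, t_z={tz}) failed: {exc}") from exc
            surface.loc[tx, tz] = fit.rho
    best = surface.max().max()
    ties = [
        (tx, tz)
        for tx in penalties
        for tz in penalties
        if best - surface.loc[tx, tz] <= tie_tol
    ]
    chosen = min(ties, key=lambda c: (c[0] + c[1], c[0]))
    return GridResult(rho=surface, chosen=chosen)


def _resample_indices(rng: np.random.Generator, n: int, m: int, replace: bool) -> np.ndarray:
    if replace:
        return rng.integers(0, n, size=m)
    return rng.choice(n, size=m, replace=False)


def bootstrap_scca(
    X,
    Z,
    t_x: float,
    t_z: float,
    B: int = 10_000,
    frac: float = 0.75,
    seed: int = 0,
    replace: bool = False,
    keep_weights: bool = True,
    max_fail_frac: float = 0.01,
) -> BootstrapSummary:
    """Bootstrap-stabilised sparse CCA at a fixed penalty pair.

    Each iteration draws ``floor(frac * n)`` distinct subjects (set
    ``replace=True`` for a classical with-replacement bootstrap),
    restandardises columns within the subsample, fits, and applies the risk
    sign convention.  More than ``max_fail_frac`` failed iterations aborts.
    """
    X = _as_frame(X, "clin")
    Z = _as_frame(Z, "gen")
    n = len(X)
    m = int(np.floor(frac * n))
    if m < 10:
        raise ValueError(f"subsample size {m} < 10; increase n or frac")
    rng = np.random.default_rng(seed)
    Xa, Za = X.to_numpy(), Z.to_numpy()
    p, q = Xa.shape[1], Za.shape[1]
    rhos = np.full(B, np.nan)
    U = np.zeros((B, p))
    V = np.zeros((B, q))
    n_failed = 0
    for b in range(B):
        idx = _resample_indices(rng, n, m, replace)
        try:
            fit = fit_scca(Xa[idx], Za[idx], t_x, t_z)
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap iteration %d failed: %s", b, exc)
            if n_failed > max_fail_frac * B:
                raise RuntimeError(f"more than {100 * max_fail_frac:.0f}% of bootstrap fits failed") from exc
            continue
        rhos[b] = fit.rho
        U[b] = fit.u
        V[b] = fit.v
    ok = ~np.isnan(rhos)
    rho_ok = rhos[ok]
    summary = BootstrapSummary(
        median_rho=float(np.median(rho_ok)),
        rho_ci=(float(np.percentile(rho_ok, 2.5)), float(np.percentile(rho_ok, 97.5))),
        rho_distribution=rho_ok,
        clinical_median_weights=pd.Series(np.median(U[ok], axis=0), index=X.columns),
        genetic_median_weights=pd.Series(np.median(V[ok], axis=0), index=Z.columns),
        clinical_selection_pct=pd.Series(100.0 * (U[ok] != 0).mean(axis=0), index=X.columns),
        genetic_selection_pct=pd.Series(100.0 * (V[ok] != 0).mean(axis=0), index=Z.columns),
        B=B,
        frac=frac,
        seed=seed,
        penalties=(t_x, t_z),
        n_failed=n_failed,
        clinical_weights=U[ok] if keep_weights else None,
        genetic_weights=V[ok] if keep_weights else None,
    )
    return summary


def permutation_null(
    X,
    Z,
    t_x: float,
    t_z: float,
    B: int = 10_000,
    frac: float = 0.75,
    seed: int = 0,
    observed_rho: float | None = None,
    replace: bool = False,
    max_fail_frac: float = 0.01,
) -> NullSummary:
    """Permutation null for the bootstrapped canonical correlation.

    Per iteration, after subsampling, the rows of each dataset are shuffled
    by independent permutations (severing the subject-level X-Z linkage)
    before fitting.  With ``observed_rho`` given, the p-value is the share
    of null correlations >= observed (plus the never-zero (b+1)/(B+1)
    variant).
    """
    X = _as_frame(X, "clin")
    Z = _as_frame(Z, "gen")
    n = len(X)
    m = int(np.floor(frac * n))
    if m < 10:
        raise ValueError(f"subsample size {m} < 10; increase n or frac")
    rng = np.random.default_rng(seed)
    Xa, Za = X.to_numpy(), Z.to_numpy()
    p, q = Xa.shape[1], Za.shape[1]
    rhos = np.full(B, np.nan)
    U = np.zeros((B, p))
    V = np.zeros((B, q))
    n_failed = 0
    for b in range(B):
        idx = _resample_indices(rng, n, m, replace)
        xs = Xa[idx][rng.permutation(m)]
        zs = Za[idx][rng.permutation(m)]
        try:
            fit = fit_scca(xs, zs, t_x, t_z)
        except Exception as exc:
            n_failed += 1
            logger.warning("null iteration %d failed: %s", b, exc)
            if n_failed > max_fail_frac * B:
                raise RuntimeError(f"more than {100 * max_fail_frac:.0f}% of null fits failed") from exc
            continue
        rhos[b] = fit.rho
        U[b] = fit.u
        V[b] = fit.v
    ok = ~np.isnan(rhos)
    rho_ok = rhos[ok]
    if observed_rho is not None:
        exceed = int((rho_ok >= observed_rho).sum())
        p_value = exceed / len(rho_ok)
        p_add_one = (exceed + 1) / (len(rho_ok) + 1)
    else:
        p_value = p_add_one = None
    return NullSummary(
        rho_distribution=rho_ok,
        clinical_selection_pct=pd.Series(100.0 * (U[ok] != 0).mean(axis=0), index=X.columns),
        genetic_selection_pct=pd.Series(100.0 * (V[ok] != 0).mean(axis=0), index=Z.columns),
        p_value=p_value,
        p_value_add_one=p_add_one,
        B=B,
        frac=frac,
        seed=seed,
        penalties=(t_x, t_z),
        n_failed=n_failed,
    )
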