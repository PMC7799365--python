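"""Sparse canonical correlation via penalized matrix decomposition.

Finds a single pair of sparse weight vectors (u, v) maximising the sample
correlation between the composites Xu and Zv of a clinical matrix X
(subjects x p) and a genetic matrix Z (subjects x q), subject to

    ||u||_2 <= 1,  ||u||_1 <= c_x,      ||v||_2 <= 1,  ||v||_1 <= c_z.

The L1 budgets are parameterised by penalties t in (0, 1] with
c = max(1, t * sqrt(dim)); t = 1 leaves the L1 constraint inactive, small t
forces a near-single-coordinate solution (the budget cannot drop below 1,
the L1 norm of any unit-L2 vector).  The solver alternates the two
rank-one subproblems, each solved in closed form by soft-thresholding and
renormalisation, with the threshold found by bisection.

Only the first canonical variate pair is computed; no deflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SccaFit", "soft_threshold", "l1_constrained_unit", "fit_scca", "standardize_columns"]


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise soft-thresholding: sign(a) * max(|a| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def l1_constrained_unit(a: np.ndarray, c: float, tol: float = 1e-8) -> np.ndarray:
    """Maximise w'a subject to ||w||_2 <= 1 and ||w||_1 <= c.

    The solution is w = S(a, delta) / ||S(a, delta)||_2 with delta = 0 when
    the plain unit vector already satisfies the L1 budget, otherwise with
    delta chosen by bisection so that ||w||_1 = c (to within ``tol``).

    When the top |a_i| are exactly tied the L1/L2 ratio of the thresholded
    vector cannot fall below sqrt(#ties); if the budget is unattainable the
    tie is broken deterministically by giving all mass to the lowest index
    among the tied maxima.
    """
    a = np.asarray(a, dtype=float)
    norm_a = np.linalg.norm(a)
    if norm_a == 0 or not np.isfinite(norm_a):
        raise ValueError("undefined direction: input vector is all zero or non-finite")
    if c < 1:
        raise ValueError(f"L1 budget c={c} < 1 is infeasible for a unit-L2 vector")

    w = a / norm_a
    if np.abs(w).sum() <= c + tol:
        return w

    lo, hi = 0.0, float(np.max(np.abs(a)))

    def ratio(delta: float) -> float:
        s = soft_threshold(a, delta)
        n2 = np.linalg.norm(s)
        return np.inf if n2 == 0 else float(np.abs(s).sum() / n2)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ratio(mid) > c:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-15 * max(1.0, hi):
            break

    s = soft_threshold(a, hi)
    n2 = np.linalg.norm(s)
    if n2 > 0 and ratio(hi) <= c + max(tol, 1e-6 * c):
        w = s / n2
        # bisection can leave coordinates carrying ~1e-8 of mass right at a
        # breakpoint; they are numerically zero and must not register as
        # selected features
        w[np.abs(w) <= 1e-8] = 0.0
        return w / np.linalg.norm(w)
    # Bisection degenerated: exactly tied |a_i| make the budget unreachable.
    w = np.zeros_like(a)
    i = int(np.argmax(np.abs(a)))  # argmax returns the lowest index on ties
    w[i] = np.sign(a[i])
    return w


def standardize_columns(m: np.ndarray, zero_constant: bool = False) -> np.ndarray:
    """Column-wise z-scoring with the sample (n-1) SD.

    With ``zero_constant`` a constant column becomes all zeros (useful inside
    bootstrap subsamples where a rare allele may not vary); otherwise a
    constant column raises.
    """
    m = np.asarray(m, dtype=float)
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any() and not zero_constant:
        raise ValueError(f"constant column(s) at indices {np.flatnonzero(flat).tolist()}")
    sd = np.where(flat, 1.0, sd)
    out = (m - mu) / sd
    if flat.any():
        out[:, flat] = 0.0
    return out


@dataclass
class SccaFit:
    """Result of a single sparse-CCA fit.

    ``rho`` is the Pearson correlation of the fitted composites Xu and Zv on
    the data the model was fit to.  The sign convention orients the pair as
    a risk score: (u, v) are flipped jointly so that sum(u) <= 0, i.e. a
    higher genetic composite corresponds to worse (lower) clinical scores.
    """

    u: np.ndarray
    v: np.ndarray
    rho: float
    iterations: int
    converged: bool
    objective_path: list = field(default_factory=list, repr=False)


def _leading_right_singular_vector(m: np.ndarray, iters: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Power iteration on M'M from a fixed deterministic start."""
    q = m.shape[1]
    v = np.ones(q) / np.sqrt(q)
    for _ in range(iters):
        w = m.T @ (m @ v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            # M'M v = 0 from the symmetric start: fall back to first basis vector
            v = np.zeros(q)
            v[0] = 1.0
            return v
        w /= nrm
        if np.linalg.norm(w - v) < tol:
            return w
        v = w
    return v


def fit_scca(
    X: np.ndarray,
    Z: np.ndarray,
    t_x: float,
    t_z: float,
    max_iter: int = 100,
    tol: float = 1e-6,
    standardize: bool = True,
    check_monotone: bool = False,
) -> SccaFit:
    """Fit the first sparse canonical variate pair of (X, Z).

    Parameters
    ----------
    X, Z
        subjects x p clinical and subjects x q genetic matrices with equal
        row counts.  With ``standardize`` (default) columns are z-scored
        first (constant columns are zeroed out and can never be selected).
    t_x, t_z
        L1 penalties in (0, 1]; mapped to budgets max(1, t * sqrt(dim)).
    check_monotone
        Assert at every iteration that the bilinear objective u'Mv does not
        decrease (debug aid).
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim != 2 or Z.ndim != 2 or X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z must be 2-D with equal row counts")
    if not (0 < t_x <= 1 and 0 < t_z <= 1):
        raise ValueError("penalties must lie in (0, 1]")
    n, p = X.shape
    q = Z.shape[1]
    if standardize:
        X = standardize_columns(X, zero_constant=True)
        Z = standardize_columns(Z, zero_constant=True)

    M = X.T @ Z
    if not np.any(M):
        raise ValueError("X and Z are exactly uncorrelated; canonical direction undefined")
    c_x = max(1.0, t_x * np.sqrt(p))
    c_z = max(1.0, t_z * np.sqrt(q))

    v = _leading_right_singular_vector(M)
    u = np.zeros(p)
    obj_prev = -np.inf
    path: list[float] = []
    converged = False
    iterations = max_iter
    for it in range(1, max_iter + 1):
        u_new = l1_constrained_unit(M @ v, c_x)
        v_new = l1_constrained_unit(M.T @ u_new, c_z)
        obj = float(u_new @ M @ v_new)
        path.append(obj)
        if check_monotone and obj < obj_prev - 1e-9 * max(1.0, abs(obj_prev)):
            raise AssertionError(f"objective decreased: {obj_prev} -> {obj} at iteration {it}")
        delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(v_new - v)))
        u, v = u_new, v_new
        obj_prev = obj
        if delta < tol:
            converged = True
            iterations = it
            break
    if not converged:
        # the converged flag on the returned fit carries this; resampling
        # loops hit it routinely on permuted data
        logger.debug("sCCA did not converge in %d iterations (last step change > %g)", max_iter, tol)

    # Risk-score orientation: higher genetic composite <-> worse clinical scores.
    if u.sum() > 0:
        u, v = -u, -v

    xu = X @ u
    zv = Z @ v
    sx, sz = xu.std(), zv.std()
    rho = float(np.corrcoef(xu, zv)[0, 1]) if sx > 0 and sz > 0 else 0.0
    return SccaFit(u=u, v=v, rho=rho, iterations=iterations, converged=converged, objective_path=path)
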