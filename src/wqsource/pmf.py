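"""Uncertainty-weighted positive matrix factorization (PMF).

A receptor model decomposing a sample x species concentration matrix into
nonnegative factor contributions and profiles,

    X = G @ F + E,    G >= 0, F >= 0,

by minimizing the uncertainty-weighted objective

    Q = sum_ij ((X - G F)_ij / U_ij)^2 .

The optimizer alternates exact nonnegative weighted least-squares solves
for the rows of G and the columns of F (each half-step solves its
subproblem to optimality, so Q is non-increasing).  Multiple random
nonnegative starts are run and the lowest-Q solution kept.  Solutions are
reported in a canonical form: profile rows are scaled to unit sum (the
mass lives in G) and factors are ordered by total modeled mass,
descending.

Entry uncertainties follow the usual receptor-modelling convention:
``u = sqrt((error_fraction * x)^2 + (mdl/2)^2)`` for measured values and
``u = (5/6) * mdl`` for below-detection entries reported as mdl/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "PMFResult",
    "build_uncertainty",
    "fit_pmf",
    "q_statistic",
    "contribution_matrix",
    "factor_count_scan",
    "match_factors",
    "matched_contribution_correlation",
]


def build_uncertainty(
    X: np.ndarray,
    mdl: np.ndarray | Sequence[float] | float,
    error_fraction: np.ndarray | Sequence[float] | float,
    censored: np.ndarray | None = None,
) -> np.ndarray:
    """Per-entry measurement uncertainty for the weighted objective.

    ``mdl`` and ``error_fraction`` are scalars or per-species vectors.
    ``censored`` marks below-detection entries (already substituted by
    mdl/2); their uncertainty is (5/6) * mdl.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    mdl_v = np.broadcast_to(np.asarray(mdl, dtype=float), (m,)).astype(float)
    ef_v = np.broadcast_to(np.asarray(error_fraction, dtype=float), (m,)).astype(float)
    if np.any(mdl_v < 0) or np.any(ef_v < 0):
        raise ValueError("detection limits and error fractions must be >= 0")
    if np.any((mdl_v == 0) & (ef_v == 0)):
        raise ValueError("every species needs a positive error fraction or detection limit")
    u = np.sqrt((ef_v[None, :] * X) ** 2 + (mdl_v[None, :] / 2.0) ** 2)
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        u = np.where(censored, (5.0 / 6.0) * mdl_v[None, :], u)
    if np.any(u <= 0):
        raise ValueError("zero uncertainty encountered; check error fractions and MDLs")
    return u


def q_statistic(X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    """Weighted sum of squared residuals Q = sum(((X - G F) / U)^2)."""
    E = np.asarray(X, dtype=float) - np.asarray(G, dtype=float) @ np.asarray(F, dtype=float)
    return float(np.sum((E / np.asarray(U, dtype=float)) ** 2))


@dataclass
class PMFResult:
    G: np.ndarray                 # (n, p) contributions, >= 0
    F: np.ndarray                 # (p, m) profiles, >= 0, rows sum to 1
    E: np.ndarray                 # residuals X - G F
    Q: float
    p: int
    q_per_start: list[float]
    q_history: list[float]        # Q trace of the winning start
    converged: bool
    dof: int

    @property
    def q_over_dof(self) -> float:
        return self.Q / self.dof if self.dof > 0 else float("nan")

    def contributions_frame(self, index=None) -> pd.DataFrame:
        cols = [f"F{j + 1}" for j in range(self.p)]
        return pd.DataFrame(self.G, index=index, columns=cols)

    def profiles_frame(self, species: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(species) if species is not None else [f"s{i}" for i in range(self.F.shape[1])]
        return pd.DataFrame(self.F, index=[f"F{j + 1}" for j in range(self.p)], columns=cols)


def _solve_rows(A: np.ndarray, B: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted NNLS: minimize ||(B_i - g A) * W_i|| over g >= 0 per row."""
    n = B.shape[0]
    p = A.shape[0]
    out = np.empty((n, p))
    for i in range(n):
        w = W[i]
        out[i], _ = nnls((A * w[None, :]).T, B[i] * w)
    return out


def _nndsvd_init(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double-SVD initialization on the column-scaled matrix.

    Deterministic and usually close to the dominant basin; used as the
    first start.  Columns are scaled to unit maximum before the SVD so
    species on very different concentration scales contribute comparably.
    """
    scale = X.max(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = X / scale[None, :]
    u_mat, s, vt = np.linalg.svd(Xs, full_matrices=False)
    n, m = Xs.shape
    G = np.zeros((n, p))
    F = np.zeros((p, m))
    G[:, 0] = np.sqrt(s[0]) * np.abs(u_mat[:, 0])
    F[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, min(p, s.size)):
        u, v = u_mat[:, j], vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        uu, vv, nrm = (up, vp, pos) if pos >= neg else (un, vn, neg)
        if nrm > 0:
            G[:, j] = np.sqrt(s[j] * nrm) * uu / np.linalg.norm(uu)
            F[j] = np.sqrt(s[j] * nrm) * vv / np.linalg.norm(vv)
    floor = 1e-6 * Xs.mean()
    return np.maximum(G, floor), np.maximum(F, floor) * scale[None, :]


def fit_pmf(
    X: np.ndarray,
    U: np.ndarray,
    p: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> PMFResult:
    """Factorize X into p nonnegative sources, keeping the best of n_starts.

    Convergence is declared when the relative change of Q between
    iterations drops below ``tol``.  A run hitting ``max_iter`` without
    converging is kept but flagged via ``converged=False`` if it wins.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if X.shape != U.shape:
        raise ValueError("X and U must have the same shape")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative (apply censoring substitution first)")
    if np.any(U <= 0):
        raise ValueError("U must be strictly positive")
    n, m = X.shape
    if not (1 <= p < min(n, m)):
        raise ValueError(f"factor count must satisfy 1 <= p < min(n, m) = {min(n, m)}")
    if n_starts < 1:
        raise ValueError("need at least one start")

    W = 1.0 / U
    scale = float(np.mean(X))
    best: tuple[float, np.ndarray, np.ndarray, list[float], bool] | None = None
    q_per_start: list[float] = []
    root = np.random.SeedSequence(seed)
    for k, child in enumerate(root.spawn(n_starts)):
        rng = np.random.default_rng(child)
        if k == 0:
            # deterministic SVD-based start; the remaining starts seed the
            # profiles from random data rows, which probes distinct basins
            G, F = _nndsvd_init(X, p)
        else:
            rows = rng.choice(n, size=p, replace=False)
            F = np.maximum(X[rows], 1e-6 * max(scale, 1e-300))
            G = rng.uniform(0.1, 1.0, size=(n, p))
        q_prev = q_statistic(X, U, G, F)
        history = [q_prev]
        converged = False
        for _ in range(max_iter):
            G = _solve_rows(F, X, W)
            # column-wise update of F via the transposed problem
            F = _solve_rows(G.T, X.T, W.T).T
            q = q_statistic(X, U, G, F)
            history.append(q)
            if q_prev - q <= tol * max(q_prev, 1e-300):
                converged = True
                break
            q_prev = q
        q_final = history[-1]
        q_per_start.append(q_final)
        if best is None or q_final < best[0]:
            best = (q_final, G, F, history, converged)

    q_final, G, F, history, converged = best
    G, F = _canonicalize(G, F)
    E = X - G @ F
    dof = n * m - p * (n + m)
    return PMFResult(
        G=G, F=F, E=E, Q=q_final, p=p, q_per_start=q_per_start,
        q_history=history, converged=converged, dof=dof,
    )


def _canonicalize(G: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sum profile rows, factors ordered by total modeled mass descending."""
    row_mass = F.sum(axis=1)
    keep = row_mass > 0
    scale = np.where(keep, row_mass, 1.0)
    F = F / scale[:, None]
    G = G * scale[None, :]
    total = G.sum(axis=0) * F.sum(axis=1)  # total modeled mass per factor
    order = np.argsort(-total, kind="stable")
    return G[:, order], F[order]


def contribution_matrix(result: PMFResult | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Share of each species' modeled mass attributed to each factor.

    ``c[j, i] = sum_n G[n, j] F[j, i] / sum_j' sum_n G[n, j'] F[j', i]``;
    columns sum to one.  Columns of species with zero modeled mass are NaN
    (undefined) rather than raising.
    """
    if isinstance(result, PMFResult):
        G, F = result.G, result.F
    else:
        G, F = result
    mass = G.sum(axis=0)[:, None] * F  # (p, m)
    col = mass.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(col > 0, mass / col, np.nan)
    return c


def factor_count_scan(
    X: np.ndarray,
    U: np.ndarray,
    p_values: Sequence[int],
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Helper sweep over candidate factor counts, reporting Q and Q/dof."""
    rows = []
    for k, p in enumerate(p_values):
        res = fit_pmf(X, U, p, n_starts=n_starts, seed=seed + k, tol=tol, max_iter=max_iter)
        rows.append({"p": p, "Q": res.Q, "dof": res.dof, "Q_over_dof": res.q_over_dof})
    return pd.DataFrame(rows)


def match_factors(c_est: np.ndarray, c_true: np.ndarray) -> np.ndarray:
    """Best one-to-one assignment of estimated to true factors.

    Maximizes the summed per-pair Pearson correlation between factor rows
    via the Hungarian algorithm; returns the permutation ``perm`` such that
    ``c_est[perm]`` aligns with ``c_true``.
    """
    from scipy.optimize import linear_sum_assignment

    p = c_true.shape[0]
    if c_est.shape[0] != p:
        raise ValueError("factor counts differ")
    corr = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            x, ytrue = c_est[a], c_true[b]
            sx, sy = np.std(x), np.std(ytrue)
            corr[a, b] = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, ytrue)[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(p, dtype=int)
    perm[cols] = rows
    return perm


def matched_contribution_correlation(c_est: np.ndarray, c_true: np.ndarray) -> float:
    """Pearson correlation of the flattened matrices after best factor matching."""
    perm = match_factors(c_est, c_true)
    a = c_est[perm].ravel()
    b = c_true.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def uncertainty_from_specs(
    values: pd.DataFrame,
    censored: pd.DataFrame,
    mdl: Mapping[str, float],
    error_fraction: Mapping[str, float] | float = 0.1,
) -> pd.DataFrame:
    """Uncertainty table for a monitoring frame from per-parameter settings."""
    cols = list(values.columns)
    mdl_v = np.array([float(mdl.get(c, 0.0)) for c in cols])
    if isinstance(error_fraction, Mapping):
        ef_v = np.array([float(error_fraction.get(c, 0.1)) for c in cols])
    else:
        ef_v = np.full(len(cols), float(error_fraction))
    u = build_uncertainty(values.to_numpy(dtype=float), mdl_v, ef_v,
                          censored.to_numpy(dtype=bool))
    return pd.DataFrame(u, index=values.index, columns=cols)
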