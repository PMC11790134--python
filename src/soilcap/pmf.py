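"""Positive matrix factorization receptor model with uncertainty weighting.

Solves X ~ G.F with G (n x p site contributions) and F (p x m source
profiles) nonnegative, minimizing the uncertainty-scaled objective

    Q = sum_ij ((X_ij - (GF)_ij) / u_ij)^2

by multiplicative updates with cell weights 1/u^2 (monotone in Q and
nonnegativity-preserving), restarted from multiple seeded random
initializations; the lowest-Q run is kept. Per-cell uncertainties follow
the EPA convention:

    u_ij = 5/6 * MDL_j                         if x_ij <= MDL_j
    u_ij = sqrt((sigma_j x_ij)^2 + (MDL_j/2)^2) otherwise

with below-detection concentrations replaced by MDL/2. After fitting, G
columns are rescaled to mean 1 (so F rows are mean apportioned
concentration profiles); the reconstruction GF is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MetalReference, SoilSurvey, default_references

_EPS = 1e-12


@dataclass
class UncertaintyMatrix:
    u: np.ndarray  # n x m, strictly positive
    substituted: np.ndarray  # n x m booleans: below-MDL replacement applied

    def __post_init__(self) -> None:
        if not np.all(self.u > 0):
            raise ValueError("uncertainties must be strictly positive")


def build_uncertainty(survey: SoilSurvey,
                      references: Mapping[str, MetalReference] | None = None,
                      ) -> tuple[np.ndarray, UncertaintyMatrix]:
    """EPA-style uncertainty matrix and the MDL-adjusted concentration matrix."""
    refs = references or default_references()
    X = survey.X.copy()
    n, m = X.shape
    u = np.empty_like(X)
    substituted = np.zeros_like(X, dtype=bool)
    for j, metal in enumerate(survey.metals):
        if metal not in refs:
            raise KeyError(f"no reference constants for metal {metal!r}")
        r = refs[metal]
        if r.error_fraction_sigma is None:
            raise KeyError(f"missing error fraction sigma for {metal!r}")
        below = X[:, j] <= r.mdl
        u[below, j] = (5.0 / 6.0) * r.mdl
        X[below, j] = r.mdl / 2.0
        substituted[below, j] = True
        above = ~below
        u[above, j] = np.sqrt((r.error_fraction_sigma * X[above, j]) ** 2
                              + (0.5 * r.mdl) ** 2)
    return X, UncertaintyMatrix(u=u, substituted=substituted)


@dataclass
class PMFSolution:
    G: np.ndarray  # n x p, >= 0, columns scaled to mean 1
    F: np.ndarray  # p x m, >= 0, concentration units
    Q: float
    q_per_run: list[float]
    q_history: np.ndarray  # per-iteration Q of the winning run
    converged: bool
    r2_per_metal: dict[str, float] = field(default_factory=dict)
    metals: tuple = ()
    X: np.ndarray | None = None
    U: np.ndarray | None = None

    @property
    def n_factors(self) -> int:
        return self.G.shape[1]

    @property
    def Xhat(self) -> np.ndarray:
        return self.G @ self.F

    @property
    def scaled_residuals(self) -> np.ndarray:
        return (self.X - self.Xhat) / self.U


def _q_value(X, U, G, F) -> float:
    return float((((X - G @ F) / U) ** 2).sum())


def _multiplicative_fit(X, W, G, F, max_iter, tol):
    """Weighted-NMF multiplicative updates; returns (G, F, q_history, converged)."""
    WX = W * X
    history = []
    q_prev = np.inf
    converged = False
    for _ in range(max_iter):
        GF = G @ F
        G *= (WX @ F.T) / ((W * GF) @ F.T + _EPS)
        GF = G @ F
        F *= (G.T @ WX) / (G.T @ (W * GF) + _EPS)
        q = float((W * (X - G @ F) ** 2).sum())
        history.append(q)
        if q_prev < np.inf and abs(q_prev - q) <= tol * max(q_prev, _EPS):
            converged = True
            break
        q_prev = q
    return G, F, np.array(history), converged


def fit(X: np.ndarray, U: np.ndarray, p: int, n_runs: int = 20,
        seed: int = 0, max_iter: int = 5000, tol: float = 1e-6,
        metals=None) -> PMFSolution:
    """Multistart weighted nonnegative factorization; lowest-Q run wins.

    Each run draws G, F from seeded uniform initializations (F scaled to
    the column means of X) and iterates multiplicative updates until the
    relative change in Q falls below ``tol`` or ``max_iter`` is reached.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    n, m = X.shape
    if p >= min(n, m):
        raise ValueError(f"p={p} must be < min(n, m)={min(n, m)}")
    if p * (n + m) >= n * m:
        raise ValueError(
            f"p={p} over-parameterizes an {n}x{m} matrix "
            f"(p*(n+m)={p * (n + m)} >= n*m={n * m}: no degrees of freedom)")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative (apply MDL substitution first)")
    if np.any(U <= 0):
        raise ValueError("uncertainties must be strictly positive")
    W = 1.0 / U ** 2
    col_scale = np.maximum(X.mean(axis=0), _EPS)

    best = None
    q_per_run = []
    conv_flags = []
    rng_master = np.random.default_rng(seed)
    for _ in range(n_runs):
        rng = np.random.default_rng(rng_master.integers(0, 2 ** 31 - 1))
        G0 = rng.uniform(0.1, 1.0, (n, p))
        F0 = rng.uniform(0.1, 1.0, (p, m)) * col_scale[None, :] / p
        G1, F1, hist, conv = _multiplicative_fit(X, W, G0, F0, max_iter, tol)
        q = _q_value(X, U, G1, F1)
        q_per_run.append(q)
        conv_flags.append(conv)
        if best is None or q < best[0]:
            best = (q, G1, F1, hist, conv)
    q, G, F, hist, conv = best
    if not any(conv_flags):
        warnings.warn("no PMF run converged; returning best available")

    # scale fix: G columns to mean 1, F carries concentration units
    g_mean = G.mean(axis=0)
    keep = g_mean > _EPS
    G[:, keep] = G[:, keep] / g_mean[keep][None, :]
    F[keep, :] = F[keep, :] * g_mean[keep][:, None]

    metals = tuple(metals) if metals is not None else tuple(range(m))
    Xhat = G @ F
    r2 = {}
    for j, metal in enumerate(metals):
        obs, pred = X[:, j], Xhat[:, j]
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            r2[metal] = np.nan
        else:
            r2[metal] = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return PMFSolution(G=G, F=F, Q=q, q_per_run=q_per_run, q_history=hist,
                       converged=conv, r2_per_metal=r2, metals=metals,
                       X=X, U=U)


def fit_survey(survey: SoilSurvey, p: int, references=None, **kwargs
               ) -> PMFSolution:
    """Convenience: build uncertainties from a survey, then factorize."""
    X, um = build_uncertainty(survey, references)
    return fit(X, um.u, p, metals=survey.metals, **kwargs)


def contributions(solution: PMFSolution, basis: str = "mass"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(factor_contribution_pct, species_share_pct) from a fitted solution.

    ``species_share_pct[k, j]`` is the percent of metal j's reconstructed
    mass carried by factor k (columns sum to 100). With ``basis="mass"``
    the factor contribution is each factor's share of the total
    reconstructed mass; with ``basis="mean_normalized"`` it is the share of
    the summed normalized contributions (mean of G columns).
    """
    G, F = solution.G, solution.F
    mass_kj = G.mean(axis=0)[:, None] * F  # p x m mean apportioned mass
    col_tot = mass_kj.sum(axis=0)
    species = 100.0 * mass_kj / np.where(col_tot > 0, col_tot, 1.0)[None, :]
    if basis == "mass":
        per_factor = mass_kj.sum(axis=1)
    elif basis == "mean_normalized":
        per_factor = G.mean(axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    total = per_factor.sum()
    if total <= 0:
        raise ValueError("degenerate solution: zero total contribution")
    if np.any(per_factor <= 0):
        warnings.warn("factor with zero contribution")
    return 100.0 * per_factor / total, species


def diagnostics(solutions: Mapping[int, PMFSolution]) -> pd.DataFrame:
    """Factor-count comparison table: Q, Q/Qexpected, residual and R2 summary.

    Qexpected = n*m - p*(n+m), the degrees of freedom of the fit; the
    elbow of Q/Qexpected over p flags the supported factor count.
    """
    if len(solutions) < 2:
        raise ValueError("need at least two candidate factor counts")
    rows = []
    for p, sol in sorted(solutions.items()):
        n, m = sol.X.shape
        q_exp = n * m - p * (n + m)
        resid = sol.scaled_residuals
        outside = 100.0 * float(np.mean(np.abs(resid) > 3.0))
        row = {"p": p, "Q": sol.Q,
               "Q_over_Qexp": sol.Q / q_exp if q_exp > 0 else np.inf,
               "pct_residuals_outside_3": outside,
               "r2_min": np.nanmin(list(sol.r2_per_metal.values())),
               "r2_median": np.nanmedian(list(sol.r2_per_metal.values()))}
        for metal, r2 in sol.r2_per_metal.items():
            row[f"r2_{metal}"] = r2
        rows.append(row)
    return pd.DataFrame(rows)


def match_factors(F_est: np.ndarray, F_true: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Permutation-match estimated profiles to truth by cosine similarity.

    Returns (permutation applied to estimated rows, mean matched cosine).
    Uses Hungarian assignment on the pairwise cosine-similarity matrix.
    """
    from scipy.optimize import linear_sum_assignment

    def unit(M):
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.where(nrm > 0, nrm, 1.0)

    sim = unit(F_true) @ unit(F_est).T  # true x est
    row, col = linear_sum_assignment(-sim)
    return col, float(sim[row, col].mean())
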