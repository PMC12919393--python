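"""Uncertainty-weighted positive matrix factorization (PMF).

The receptor model decomposes the n x m concentration matrix X into k
non-negative latent sources, X ~ G F with site contributions G (n x k) and
source profiles F (k x m), by minimising the uncertainty-weighted objective

    Q = sum_ij ((x_ij - (GF)_ij) / u_ij)^2 .

Optimisation uses multiplicative updates adapted to elementwise weights
w_ij = 1/u_ij^2 (the weighted Lee-Seung rules), which preserve
non-negativity and never increase Q, with multi-start over random
initialisations.  A robust mode mirrors the EPA convention of capping the
influence of outlying cells: after a converged sweep, any cell with scaled
residual |e/u| > 4 has its effective uncertainty inflated to |e|/4 and the
fit resumes.

Stability diagnostics are simplified re-implementations of the EPA
bootstrap (BS) and displacement (DISP) procedures: BS refits on row
resamples and maps factors back to the base case by cosine similarity;
DISP perturbs strong profile entries, refits with the entry held, and
checks that the objective and the factor identities survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import ELEMENTS, SoilDataset

_EPS = 1e-12

#: Scaled-residual cap used by the robust mode.
ROBUST_CAP = 4.0


class PMFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# uncertainty matrix


@dataclass
class UncertaintyMatrix:
    """Per-cell measurement uncertainties Unc_ij (mg kg^-1, strictly > 0).

    For concentrations above the detection limit the EPA PMF 5.0 formula
    sqrt((EF * c)^2 + (0.5 * MDL)^2) applies; at or below the limit the
    uncertainty is (5/6) * MDL.  Elements flagged *weak* carry tripled
    uncertainty (the EPA down-weighting convention).
    """

    U: np.ndarray
    mdl: dict[str, float]
    error_fraction: dict[str, float]
    weak: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(self.U > 0):
            raise PMFError("uncertainty matrix must be strictly positive")


def build_uncertainty_matrix(
    ds: SoilDataset | np.ndarray,
    error_fraction: Mapping[str, float] | float = 0.1,
    mdl: Mapping[str, float] | None = None,
    weak: Sequence[str] = (),
) -> UncertaintyMatrix:
    """Build Unc_ij for a dataset (or a raw (n, 9) concentration matrix)."""
    if isinstance(ds, SoilDataset):
        X = ds.concentrations()
        mdl_map = dict(mdl) if mdl is not None else dict(ds.mdl)
    else:
        X = np.asarray(ds, float)
        mdl_map = dict(mdl) if mdl is not None else {}
    if isinstance(error_fraction, (int, float)):
        ef_map = {el: float(error_fraction) for el in ELEMENTS}
    else:
        ef_map = {el: float(error_fraction[el]) for el in ELEMENTS}
    for el, v in ef_map.items():
        if v <= 0:
            raise PMFError(f"error fraction must be positive ({el})")
    U = np.empty_like(X)
    for j, el in enumerate(ELEMENTS):
        m = float(mdl_map.get(el, 0.0))
        if m < 0:
            raise PMFError(f"negative MDL for {el}")
        c = X[:, j]
        below = c <= m
        if m == 0.0 and below.any():
            raise PMFError(
                f"{el}: concentration <= MDL with MDL = 0 gives zero uncertainty"
            )
        ef = ef_map[el]
        U[:, j] = np.where(below, (5.0 / 6.0) * m,
                           np.sqrt((ef * c) ** 2 + (0.5 * m) ** 2))
    for el in weak:
        if el not in ELEMENTS:
            raise PMFError(f"unknown weak element {el!r}")
        U[:, ELEMENTS.index(el)] *= 3.0
    return UncertaintyMatrix(U, mdl_map, ef_map, tuple(weak))


def q_value(X: np.ndarray, GF: np.ndarray, U: np.ndarray) -> float:
    """The PMF objective: sum of squared uncertainty-scaled residuals."""
    X, GF, U = (np.asarray(a, float) for a in (X, GF, U))
    if X.shape != GF.shape or X.shape != U.shape:
        raise PMFError("shape mismatch")
    if not np.all(U > 0):
        raise PMFError("uncertainties must be strictly positive")
    return float(np.sum(((X - GF) / U) ** 2))


def flag_outlier_samples(ds: SoilDataset, k_iqr: float = 1.5) -> np.ndarray:
    """Boolean per-sample flags for the interquartile-range pre-screen: a
    sample is flagged when any element concentration falls outside
    [Q1 - k*IQR, Q3 + k*IQR] for that element."""
    X = ds.concentrations()
    q1, q3 = np.percentile(X, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k_iqr * iqr, q3 + k_iqr * iqr
    return ((X < lo) | (X > hi)).any(axis=1)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PMFSolution:
    G: np.ndarray
    F: np.ndarray
    Q: float
    Q_expected: float
    Q_true: float
    converged: bool
    seed: int | None
    n_starts: int
    U_effective: np.ndarray
    robust: bool
    q_history: np.ndarray = field(repr=False, default=None)

    @property
    def residuals(self) -> np.ndarray:
        """e_ij = x_ij - (GF)_ij, available once X is re-supplied via
        :meth:`scaled_residuals`; stored model is G F."""
        return self.G @ self.F

    def scaled_residuals(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.G @ self.F) / self.U_effective

    def normalized(self) -> "PMFSolution":
        """Resolve the scale ambiguity: G columns scaled to mean one, F rows
        scaled inversely so profiles carry concentration units.  GF and Q
        are unchanged."""
        m = self.G.mean(axis=0)
        if np.any(m <= 0):
            raise PMFError("cannot normalize: zero-mean contribution column")
        sol = PMFSolution(
            G=self.G / m, F=self.F * m[:, None],
            Q=self.Q, Q_expected=self.Q_expected, Q_true=self.Q_true,
            converged=self.converged, seed=self.seed, n_starts=self.n_starts,
            U_effective=self.U_effective, robust=self.robust,
            q_history=self.q_history,
        )
        return sol


def _mu_iterate(X, W, G, F, max_iter, tol, hold: tuple[int, int, float] | None = None):
    """Weighted multiplicative updates until relative dQ < tol.

    ``hold`` optionally pins one F entry (factor, element, value) after each
    update (used by the displacement diagnostic).  Returns (G, F, q_history,
    converged).
    """
    WX = W * X
    qs = []
    q_prev = np.inf
    converged = False
    for _ in range(max_iter):
        GF = G @ F
        G *= (WX @ F.T) / np.maximum((W * GF) @ F.T, _EPS)
        GF = G @ F
        F *= (G.T @ WX) / np.maximum(G.T @ (W * GF), _EPS)
        if hold is not None:
            fk, el, val = hold
            F[fk, el] = val
        q = float(np.sum(W * (X - G @ F) ** 2))
        qs.append(q)
        if q_prev - q <= tol * max(q_prev, 1.0) and np.isfinite(q_prev):
            converged = True
            break
        q_prev = q
    return G, F, np.array(qs), converged


def fit_pmf(
    X: np.ndarray,
    U: np.ndarray | UncertaintyMatrix,
    k: int,
    n_starts: int = 20,
    seed: int | None = None,
    robust: bool = True,
    max_iter: int = 20_000,
    tol: float = 1e-8,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> PMFSolution:
    """Best-of-``n_starts`` uncertainty-weighted factorization.

    Parameters
    ----------
    X, U:
        Concentrations and uncertainties, both (n, m); U strictly positive.
    k:
        Number of factors, 1 <= k < min(n, m).
    robust:
        When true, cells with scaled residual beyond +-4 get effective
        uncertainty |e|/4 and the fit resumes (up to five reweighting
        rounds).  Q is reported against the final effective uncertainties;
        ``Q_true`` against the input ones.
    init:
        Optional (G0, F0) used as an additional (first) start.
    """
    if isinstance(U, UncertaintyMatrix):
        U = U.U
    X = np.asarray(X, float)
    U = np.asarray(U, float)
    if X.shape != U.shape:
        raise PMFError("X and U must share a shape")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(U))):
        raise PMFError("non-finite inputs")
    if np.any(X < 0) or np.any(U <= 0):
        raise PMFError("X must be >= 0 and U > 0")
    n, m = X.shape
    if not 1 <= k < min(n, m):
        raise PMFError(f"k={k} out of range for {n}x{m} data")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max(n_starts, 1))
    scale = max(X.mean(), _EPS)

    best = None
    for s in range(max(n_starts, 1)):
        rng = np.random.default_rng(child_seeds[s])
        if init is not None and s == 0:
            G = np.asarray(init[0], float).copy()
            F = np.asarray(init[1], float).copy()
        else:
            G = rng.uniform(0.1, 1.0, (n, k))
            F = rng.uniform(0.1, 1.0, (k, m)) * scale / (0.55 * 0.55 * k)
        U_eff = U.copy()
        histories = []
        converged = False
        rounds = 5 if robust else 1
        for _ in range(rounds):
            W = 1.0 / U_eff**2
            G, F, qs, converged = _mu_iterate(X, W, G, F, max_iter, tol)
            histories.append(qs)
            if not robust:
                break
            e = X - G @ F
            over = np.abs(e / U_eff) > ROBUST_CAP
            if not over.any():
                break
            U_eff = np.where(over, np.abs(e) / ROBUST_CAP, U_eff)
        q_eff = q_value(X, G @ F, U_eff)
        if best is None or q_eff < best[0]:
            best = (q_eff, G, F, U_eff, converged, np.concatenate(histories))

    q_eff, G, F, U_eff, converged, hist = best
    return PMFSolution(
        G=G, F=F, Q=q_eff,
        Q_expected=float(n * m - k * (n + m)),
        Q_true=q_value(X, G @ F, U),
        converged=converged, seed=seed, n_starts=n_starts,
        U_effective=U_eff, robust=robust, q_history=hist,
    )


def select_factor_count(
    X: np.ndarray,
    U: np.ndarray | UncertaintyMatrix,
    k_range: Sequence[int],
    n_starts: int = 10,
    seed: int | None = None,
    robust: bool = True,
    rel_tol: float = 0.10,
    abs_floor: float = 1e-3,
) -> tuple[int, pd.DataFrame]:
    """Fit every k in ``k_range`` and pick the factor count.

    Rule: the smallest k whose Q/Q_expected is within ``rel_tol`` of the
    minimum over the range.  ``abs_floor`` treats near-exact fits (Q/Qexp
    differing by less than the floor) as equivalent so that noise-free data
    select the true rank rather than the largest k.
    """
    rows = []
    sols = {}
    for k in k_range:
        sol = fit_pmf(X, U, k, n_starts=n_starts, seed=seed, robust=robust)
        scaled = sol.scaled_residuals(X)
        rows.append({
            "k": k,
            "Q": sol.Q,
            "Q_expected": sol.Q_expected,
            "Q_norm": sol.Q / sol.Q_expected,
            "frac_scaled_resid_gt3": float(np.mean(np.abs(scaled) > 3)),
            "converged": sol.converged,
        })
        sols[k] = sol
    table = pd.DataFrame(rows)
    qn = table["Q_norm"].to_numpy()
    threshold = max((1.0 + rel_tol) * qn.min(), qn.min() + abs_floor)
    selected = int(table.loc[qn <= threshold, "k"].min())
    return selected, table


# ---------------------------------------------------------------------------
# factor matching and diagnostics


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    return An @ Bn.T


def match_factors(F_a: np.ndarray, F_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one factor assignment by summed cosine similarity.

    Returns ``(perm, cosines)`` where row i of ``F_a`` is matched to row
    ``perm[i]`` of ``F_b`` and ``cosines[i]`` is their cosine similarity.
    """
    F_a, F_b = np.asarray(F_a, float), np.asarray(F_b, float)
    if F_a.shape != F_b.shape:
        raise PMFError("factor matrices must share a shape")
    C = _cosine_matrix(F_a, F_b)
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]


@dataclass
class StabilityReport:
    """Bootstrap / displacement stability summary for a base solution."""

    bs_runs: int = 0
    bs_skipped: int = 0
    bs_mapped_pct: dict[int, float] = field(default_factory=dict)
    disp_probes: int = 0
    disp_max_dq_pct: float = 0.0
    disp_swaps: int = 0
    disp_stable: bool = True
    sensitive_elements: list[str] = field(default_factory=list)


def bootstrap_diagnostic(
    X: np.ndarray,
    U: np.ndarray | UncertaintyMatrix,
    base: PMFSolution,
    n_runs: int = 50,
    map_threshold: float = 0.6,
    seed: int | None = None,
    max_iter: int = 500,
) -> StabilityReport:
    """Row-resampling bootstrap: refit on each resample (warm-started from
    the base solution) and count how often each base factor is recovered
    with matched-profile cosine >= ``map_threshold``."""
    if n_runs < 1:
        raise PMFError("n_runs must be >= 1")
    if isinstance(U, UncertaintyMatrix):
        U = U.U
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    k = base.F.shape[0]
    mapped = np.zeros(k)
    skipped = 0
    for _ in range(n_runs):
        idx = rng.integers(0, X.shape[0], X.shape[0])
        Xb, Ub = X[idx], U[idx]
        if np.all(Xb == Xb[0]):
            skipped += 1
            continue
        sol = fit_pmf(Xb, Ub, k, n_starts=1, seed=int(rng.integers(2**31)),
                      robust=base.robust, max_iter=max_iter,
                      init=(base.G[idx], base.F))
        _, cosines = match_factors(base.F, sol.F)
        mapped += cosines >= map_threshold
    effective = n_runs - skipped
    pct = {f: (100.0 * mapped[f] / effective if effective else 0.0) for f in range(k)}
    return StabilityReport(bs_runs=n_runs, bs_skipped=skipped, bs_mapped_pct=pct)


def disp_diagnostic(
    X: np.ndarray,
    U: np.ndarray | UncertaintyMatrix,
    base: PMFSolution,
    perturbation_grid: Sequence[float] = (0.1, 0.25),
    seed: int | None = None,
    max_iter: int = 500,
    match_threshold: float = 0.6,
) -> StabilityReport:
    """Displacement diagnostic (simplified).

    For each factor the strongest profile entry is displaced up and down by
    each fractional step of the grid, the model is refit from the perturbed
    solution with that entry held, and the probe records the relative drop
    in Q (a drop means the base was not the global optimum) and whether the
    factor identities survive matching.  Stable iff the maximum Q reduction
    is below 1% and no factor swaps occur.
    """
    if not base.converged:
        raise PMFError("displacement requires a converged base solution")
    if isinstance(U, UncertaintyMatrix):
        U = U.U
    X = np.asarray(X, float)
    k, m = base.F.shape
    # floor of one scaled-residual unit keeps the relative drop meaningful
    # for near-exact fits (Q ~ 0)
    q_base = max(base.Q, 1.0)
    max_drop = 0.0
    swaps = 0
    probes = 0
    sensitive: set[str] = set()
    for fk in range(k):
        j = int(np.argmax(base.F[fk]))
        for step in perturbation_grid:
            for sign in (+1.0, -1.0):
                val = base.F[fk, j] * (1.0 + sign * step)
                if val < 0:
                    continue
                G = base.G.copy()
                F = base.F.copy()
                F[fk, j] = val
                W = 1.0 / base.U_effective**2
                G, F, _, _ = _mu_iterate(X, W, G, F, max_iter, 1e-10,
                                         hold=(fk, j, val))
                probes += 1
                q_p = float(np.sum(W * (X - G @ F) ** 2))
                drop = 100.0 * (base.Q - q_p) / q_base
                max_drop = max(max_drop, drop)
                perm, cosines = match_factors(base.F, F)
                if (perm != np.arange(k)).any() or (cosines < match_threshold).any():
                    swaps += 1
                    sensitive.add(ELEMENTS[j] if j < len(ELEMENTS) else str(j))
    return StabilityReport(
        disp_probes=probes, disp_max_dq_pct=max_drop, disp_swaps=swaps,
        disp_stable=(max_drop < 1.0 and swaps == 0),
        sensitive_elements=sorted(sensitive),
    )


# ---------------------------------------------------------------------------
# contribution summaries


def element_contribution_percent(F: np.ndarray) -> np.ndarray:
    """Column-normalised profile matrix: percentage of each element carried
    by each factor (columns sum to 100)."""
    F = np.asarray(F, float)
    if np.any(F < 0):
        raise PMFError("profiles must be non-negative")
    colsum = F.sum(axis=0)
    if np.any(colsum <= 0):
        raise PMFError("all-zero element column")
    return 100.0 * F / colsum


def factor_total_share(G: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Percentage of the total modelled mass attributed to each factor."""
    G, F = np.asarray(G, float), np.asarray(F, float)
    mass = G.mean(axis=0) * F.sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise PMFError("all-zero solution")
    return 100.0 * mass / total


def normalize_contributions(G: np.ndarray) -> np.ndarray:
    """Scale each contribution column to mean one (the convention used for
    mapping factor-contribution surfaces)."""
    G = np.asarray(G, float)
    m = G.mean(axis=0)
    if np.any(m <= 0):
        raise PMFError("zero-mean contribution column")
    return G / m
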