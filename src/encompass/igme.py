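"""Metastable lumping and integrative generalized master equation fitting.

The long-time propagator of a lumped (memory-bearing) process is modeled as

    T(n*tau) ~= A . T_hat^n

where ``A`` absorbs time-integrated memory effects and ``T_hat`` is the
long-time propagator per lag. Both matrices are obtained by least squares
over a fit window [n0, n0+L-1] of lag multiples; a hyperparameter scan over
(n0, L) keeps the top fraction of models by RMSE.

The fit exploits the identity T((n+1)tau) = T(n*tau) . T_hat, which makes the
estimation of T_hat a linear least-squares problem; A then follows from a
second linear solve, and an optional Gauss-Newton refinement polishes both.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .msm import TPM, CKResult, DiscreteTrajectorySet, count_matrix, estimate_tpm
from .synthetic import TPMSeries

logger = logging.getLogger(__name__)


@dataclass
class Lumping:
    """Fuzzy microstate -> macrostate memberships plus hard argmax labels."""

    n_micro: int
    n_macro: int
    memberships: np.ndarray
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.memberships.shape != (self.n_micro, self.n_macro):
            raise ValueError("memberships must be (n_micro, n_macro)")
        if np.any(self.memberships < -1e-12):
            raise ValueError("memberships must be non-negative")
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("membership rows must sum to 1 within 1e-10")
        if len(np.unique(self.assignment)) != self.n_macro:
            raise ValueError("every macrostate must be non-empty under hard assignment")


@dataclass
class IGMEModel:
    """One fitted (A, T_hat) pair with derived thermodynamics and kinetics."""

    A: np.ndarray
    T_hat: np.ndarray
    fit_window: tuple[int, int]  # (n0, L)
    rmse: float
    tau: int
    frame_interval: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.T_hat.shape[0]

    def predict(self, n: int) -> np.ndarray:
        """Predicted T(n*tau) = A . T_hat^n."""
        return self.A @ np.linalg.matrix_power(self.T_hat, n)

    @property
    def stationary(self) -> np.ndarray:
        vals, vecs = scipy.linalg.eig(self.T_hat.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        if pi.sum() < 0:
            pi = -pi
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    @property
    def timescales(self) -> np.ndarray:
        vals = scipy.linalg.eigvals(self.T_hat)
        order = np.lexsort((-vals.real, -np.abs(vals)))
        mods = np.abs(vals[order])[1:]
        if mods.size and mods.max() > 1 + 1e-6:
            warnings.warn("T_hat spectral radius exceeds 1; clipping for timescales",
                          RuntimeWarning)
        mods = np.clip(mods, 1e-300, 1 - 1e-15)
        return -self.tau * self.frame_interval / np.log(mods)


@dataclass
class IGMEEnsemble:
    """Hyperparameter-scan ensemble; summary statistics over the top models."""

    models: list[IGMEModel]
    retained: list[IGMEModel]
    top_fraction: float
    summary: dict


@dataclass
class IGMECKResult:
    """CK comparison of IGME predictions and the MSM baseline beyond the window."""

    factors: list[int]
    rmse_igme: dict[int, float]
    rmse_msm: dict[int, float]
    predicted_igme: dict[int, np.ndarray]
    predicted_msm: dict[int, np.ndarray]
    estimated: dict[int, np.ndarray]


# ---------------------------------------------------------------------------
# PCCA+ lumping
# ---------------------------------------------------------------------------

def _inner_simplex_vertices(x: np.ndarray) -> np.ndarray:
    """Deuflhard-style vertex search: rows of x spanning the largest simplex."""
    n, m = x.shape
    idx = np.zeros(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(x, axis=1)))
    work = x - x[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(work, axis=1)
        idx[j] = int(np.argmax(norms))
        v = work[idx[j]] / norms[idx[j]]
        work = work - np.outer(work @ v, v)
    return idx


def pcca_lump(tpm: TPM, n_macro: int, imag_tol: float = 1e-6) -> Lumping:
    """Robust Perron cluster lumping of microstates into metastable macrostates.

    Operates on the dominant right eigenvectors of the microstate TPM via the
    inner simplex algorithm; memberships are clipped to the probability
    simplex. Deterministic.
    """
    n_micro = tpm.n_states
    if not 2 <= n_macro <= n_micro:
        raise ValueError("need 2 <= n_macro <= n_micro")
    if n_macro == n_micro:
        return Lumping(
            n_micro=n_micro,
            n_macro=n_macro,
            memberships=np.eye(n_micro),
            assignment=np.arange(n_micro),
        )
    vals, vecs = scipy.linalg.eig(tpm.matrix)
    order = np.lexsort((-vals.real, -np.abs(vals)))
    top_vals = vals[order[:n_macro]]
    top_vecs = vecs[:, order[:n_macro]]
    if np.max(np.abs(top_vals.imag)) > imag_tol or np.max(np.abs(top_vecs.imag)) > imag_tol:
        raise ValueError(
            "dominant eigenvectors are complex beyond tolerance; use a reversible "
            "TPM estimate or a smaller n_macro"
        )
    x = np.real(top_vecs)
    x[:, 0] = 1.0  # Perron eigenvector is constant; pin it exactly
    idx = _inner_simplex_vertices(x)
    chi = x @ np.linalg.pinv(x[idx])
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1, keepdims=True)
    if np.any(rowsum <= 0):
        raise ValueError("degenerate memberships; PCCA+ failed on this TPM")
    chi = chi / rowsum
    assignment = np.argmax(chi, axis=1)
    if len(np.unique(assignment)) != n_macro:
        raise ValueError(
            "PCCA+ produced an empty macrostate; try a smaller n_macro"
        )
    return Lumping(
        n_micro=n_micro, n_macro=n_macro, memberships=chi, assignment=assignment
    )


def lump_dtrajs(
    dtrajs: DiscreteTrajectorySet, lumping: Lumping, active_set: np.ndarray | None = None
) -> DiscreteTrajectorySet:
    """Map microstate trajectories to macrostate labels via hard assignment.

    ``active_set`` translates TPM-internal indices back to original labels
    when ergodic trimming dropped states (dropped states map to the macrostate
    of their nearest retained label is NOT attempted; they must be absent).
    """
    mapping = np.full(dtrajs.n_states, -1, dtype=int)
    if active_set is None:
        active_set = np.arange(lumping.n_micro)
    mapping[np.asarray(active_set, int)] = lumping.assignment
    if any(np.any(mapping[t] < 0) for t in dtrajs.trajectories):
        raise ValueError("trajectories visit microstates outside the lumped active set")
    return dtrajs.map_labels(mapping, lumping.n_macro)


# ---------------------------------------------------------------------------
# Macro TPM series and IGME least squares
# ---------------------------------------------------------------------------

def macro_tpm_series(
    dtrajs_macro: DiscreteTrajectorySet, tau: int, K: int
) -> TPMSeries:
    """Independently estimated T(k*tau), k = 1..K, at macrostate resolution."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K * tau >= dtrajs_macro.min_length:
        raise ValueError("K*tau must be smaller than the shortest trajectory")
    matrices, counts = [], []
    for k in range(1, K + 1):
        c = count_matrix(dtrajs_macro, k * tau, mode="sliding")
        rowsum = c.sum(axis=1)
        if np.any(rowsum == 0):
            raise ValueError(f"no outgoing counts for some state at lag {k * tau}")
        matrices.append(c / rowsum[:, None])
        counts.append(c)
    return TPMSeries(
        tau=tau,
        matrices=matrices,
        frame_interval=dtrajs_macro.frame_interval,
        counts=counts,
    )


def _window_residuals(a: np.ndarray, t_hat: np.ndarray, series: TPMSeries,
                      n0: int, L: int) -> np.ndarray:
    res = []
    power = np.linalg.matrix_power(t_hat, n0)
    for n in range(n0, n0 + L):
        res.append((a @ power - series.matrix(n)).ravel())
        power = power @ t_hat
    return np.concatenate(res)


def igme_lsf(
    series: TPMSeries,
    n0: int,
    L: int,
    refine: bool = True,
    refine_tol: float = 1e-12,
) -> IGMEModel:
    """Least-squares fit of T(n*tau) ~= A . T_hat^n over lags n0..n0+L-1.

    T_hat solves the stacked linear system T(n) T_hat = T(n+1) across the
    window; A follows from a second linear solve. When the linear solution
    leaves residuals above ``refine_tol`` and ``refine`` is set, both matrices
    are polished jointly with a bounded Gauss-Newton pass.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if L < 2:
        raise ValueError("L must be >= 2")
    if n0 + L - 1 > series.K:
        raise ValueError(f"fit window [{n0}, {n0 + L - 1}] exceeds series length {series.K}")
    n = series.n_states
    lhs = np.vstack([series.matrix(m) for m in range(n0, n0 + L - 1)])
    rhs = np.vstack([series.matrix(m + 1) for m in range(n0, n0 + L - 1)])
    t_hat, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    # A from min sum_n ||A T_hat^n - T(n)||_F^2  (normal equations, per row)
    powers = [np.linalg.matrix_power(t_hat, m) for m in range(n0, n0 + L)]
    gram = sum(p @ p.T for p in powers)
    cross = sum(p @ series.matrix(n0 + i).T for i, p in enumerate(powers))
    a = scipy.linalg.lstsq(gram, cross)[0].T
    method = "linear"
    rmse = float(np.sqrt(np.mean(_window_residuals(a, t_hat, series, n0, L) ** 2)))
    if refine and rmse > refine_tol:
        x0 = np.concatenate([a.ravel(), t_hat.ravel()])

        def fun(x):
            ax = x[: n * n].reshape(n, n)
            tx = x[n * n:].reshape(n, n)
            return _window_residuals(ax, tx, series, n0, L)

        sol = scipy.optimize.least_squares(fun, x0, method="lm", max_nfev=200 * len(x0))
        refined_rmse = float(np.sqrt(np.mean(sol.fun**2)))
        if refined_rmse < rmse:
            a = sol.x[: n * n].reshape(n, n)
            t_hat = sol.x[n * n:].reshape(n, n)
            rmse = refined_rmse
            method = "linear+refine"
    # soft stochasticity check over the window
    power = np.linalg.matrix_power(t_hat, n0)
    worst = 0.0
    for m in range(n0, n0 + L):
        worst = max(worst, float(np.max(np.abs((a @ power).sum(axis=1) - 1.0))))
        power = power @ t_hat
    if worst > 1e-3:
        logger.warning("A.T_hat^n row sums deviate from 1 by up to %.2e in window", worst)
    elif worst > 1e-6:
        logger.debug("A.T_hat^n row sums deviate from 1 by up to %.2e in window", worst)
    return IGMEModel(
        A=a,
        T_hat=t_hat,
        fit_window=(n0, L),
        rmse=rmse,
        tau=series.tau,
        frame_interval=series.frame_interval,
        provenance={"method": method, "row_sum_deviation": worst},
    )


def igme_scan(
    series: TPMSeries,
    grid: list[tuple[int, int]],
    top_fraction: float = 0.05,
    refine: bool = True,
) -> IGMEEnsemble:
    """Fit every (n0, L) grid point and retain the top fraction by RMSE.

    Ranking is ascending RMSE, ties broken by smaller n0 then smaller L. The
    summary holds mean and sd of stationary populations, timescales and MFPTs
    over the retained models only.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    models, failures = [], []
    for n0, L in grid:
        try:
            models.append(igme_lsf(series, n0, L, refine=refine))
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"(n0={n0}, L={L}): {exc}")
    if not models:
        raise ValueError("all IGME fits failed: " + "; ".join(failures))
    if failures:
        logger.warning("%d/%d IGME fits failed", len(failures), len(grid))
    models.sort(key=lambda m: (m.rmse, m.fit_window[0], m.fit_window[1]))
    n_keep = math.ceil(top_fraction * len(models))
    retained = models[:n_keep]
    pops = np.array([m.stationary for m in retained])
    tscales = np.array([m.timescales for m in retained])
    mfpts = np.array([model_kinetics(m)["mfpt"] for m in retained])
    summary = {
        "population_mean": pops.mean(axis=0),
        "population_sd": pops.std(axis=0),
        "timescale_mean": tscales.mean(axis=0),
        "timescale_sd": tscales.std(axis=0),
        "mfpt_mean": mfpts.mean(axis=0),
        "mfpt_sd": mfpts.std(axis=0),
        "rmse": np.array([m.rmse for m in retained]),
    }
    return IGMEEnsemble(
        models=models, retained=retained, top_fraction=top_fraction, summary=summary
    )


def model_kinetics(model: IGMEModel) -> dict:
    """Timescales and the mean-first-passage-time matrix of the fitted chain.

    MFPTs are solved on a row-renormalized copy of T_hat at time step
    ``tau * frame_interval``; diagonal entries are 0.
    """
    t = np.clip(model.T_hat, 0.0, None)
    rowsum = t.sum(axis=1, keepdims=True)
    if np.max(np.abs(rowsum - 1.0)) > 1e-6:
        logger.warning("renormalizing T_hat rows for MFPT (max deviation %.2e)",
                       float(np.max(np.abs(rowsum - 1.0))))
    t = t / rowsum
    n = t.shape[0]
    step = model.tau * model.frame_interval
    mfpt = np.zeros((n, n))
    for target in range(n):
        others = [i for i in range(n) if i != target]
        q = t[np.ix_(others, others)]
        m = np.linalg.solve(np.eye(n - 1) - q, step * np.ones(n - 1))
        for row, i in enumerate(others):
            mfpt[i, target] = m[row]
    return {"timescales": model.timescales, "mfpt": mfpt, "stationary": model.stationary}


def igme_ck(model: IGMEModel, series: TPMSeries) -> IGMECKResult:
    """Compare A.T_hat^n and the MSM baseline T(tau)^n against estimated T(n*tau).

    Evaluated at every series lag beyond the fit window.
    """
    n0, L = model.fit_window
    start = n0 + L
    factors = list(range(start, series.K + 1))
    if not factors:
        raise ValueError("series does not extend beyond the fit window")
    t1 = series.matrix(1)
    rmse_igme, rmse_msm = {}, {}
    pred_i, pred_m, est = {}, {}, {}
    for k in factors:
        target = series.matrix(k)
        pi = model.predict(k)
        pm = np.linalg.matrix_power(t1, k)
        rmse_igme[k] = float(np.sqrt(np.mean((pi - target) ** 2)))
        rmse_msm[k] = float(np.sqrt(np.mean((pm - target) ** 2)))
        pred_i[k], pred_m[k], est[k] = pi, pm, target
    return IGMECKResult(
        factors=factors,
        rmse_igme=rmse_igme,
        rmse_msm=rmse_msm,
        predicted_igme=pred_i,
        predicted_msm=pred_m,
        estimated=est,
    )
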