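"""Microstate Markov model estimation and validation.

Clustering of projected coordinates into microstates, transition probability
matrix (TPM) estimation with ergodic trimming, implied timescales,
Chapman-Kolmogorov (CK) tests and GMRQ cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

logger = logging.getLogger(__name__)


@dataclass
class DiscreteTrajectorySet:
    """A set of integer state sequences sharing one state space."""

    trajectories: list[np.ndarray]
    n_states: int
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.trajectories = [np.asarray(t, dtype=int) for t in self.trajectories]
        if not self.trajectories:
            raise ValueError("trajectory set is empty")
        for i, traj in enumerate(self.trajectories):
            if traj.ndim != 1 or len(traj) < 2:
                raise ValueError(f"trajectory {i} must be 1-D with length >= 2")
            if traj.min() < 0 or traj.max() >= self.n_states:
                raise ValueError(
                    f"trajectory {i} has labels outside [0, {self.n_states})"
                )

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def min_length(self) -> int:
        return min(len(t) for t in self.trajectories)

    @property
    def total_frames(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.trajectories)

    def map_labels(self, mapping: np.ndarray, n_states: int) -> "DiscreteTrajectorySet":
        """Apply a per-state relabeling (e.g. lumping into macrostates)."""
        mapping = np.asarray(mapping, dtype=int)
        return DiscreteTrajectorySet(
            trajectories=[mapping[t] for t in self.trajectories],
            n_states=n_states,
            frame_interval=self.frame_interval,
        )

    def occupancy(self) -> np.ndarray:
        counts = np.bincount(self.concatenated(), minlength=self.n_states)
        return counts / counts.sum()


@dataclass
class TPM:
    """Row-stochastic transition probability matrix with its count matrix."""

    lag: int
    matrix: np.ndarray
    counts: np.ndarray
    active_set: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.active_set = np.asarray(self.active_set, dtype=int)
        rowsums = self.matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-10):
            raise ValueError("TPM rows must sum to 1 within 1e-10")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        return stationary_distribution(self.matrix)


@dataclass
class CKResult:
    """Chapman-Kolmogorov comparison of propagated vs directly estimated TPMs."""

    lag_base: int
    factors: list[int]
    predicted: dict[int, np.ndarray]
    estimated: dict[int, np.ndarray]
    rmse: dict[int, float]
    set_labels: list | None = None
    self_transition_predicted: dict[int, np.ndarray] = field(default_factory=dict)
    self_transition_estimated: dict[int, np.ndarray] = field(default_factory=dict)

    def aggregate_rmse(self) -> float:
        vals = [v for v in self.rmse.values() if np.isfinite(v)]
        return float(np.sqrt(np.mean(np.square(vals)))) if vals else float("nan")


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution as the normalized left Perron eigenvector."""
    matrix = np.asarray(matrix, dtype=float)
    vals, vecs = scipy.linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.clip(pi, 0.0, None) if pi.sum() >= 0 else np.clip(-pi, 0.0, None)
    total = pi.sum()
    if total <= 0:
        raise ValueError("could not extract a stationary distribution")
    return pi / total


def kmeans_cluster(
    projection: np.ndarray | list[np.ndarray],
    n_clusters: int,
    seed: int,
    frame_interval: float = 1.0,
) -> tuple[DiscreteTrajectorySet, np.ndarray]:
    """K-means microstate clustering with canonical center ordering.

    Accepts a single ``(frames, d)`` array or a list of per-trajectory arrays.
    Centers are sorted by first coordinate and assignments relabeled
    accordingly so output is invariant to k-means internal label order.
    """
    if isinstance(projection, np.ndarray):
        blocks = [np.atleast_2d(np.asarray(projection, dtype=float))]
    else:
        blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in projection]
    blocks = [b.reshape(len(b), -1) for b in blocks]
    data = np.vstack(blocks)
    n_frames = len(data)
    if n_clusters > n_frames:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_frames={n_frames}")
    n_unique = len(np.unique(data, axis=0))
    k_eff = min(n_clusters, n_unique)
    if k_eff < n_clusters:
        logger.warning(
            "only %d unique frames; reducing n_clusters from %d", n_unique, n_clusters
        )
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    labels = km.fit_predict(data)
    order = np.lexsort(km.cluster_centers_.T[::-1])  # sort by first coord, then next
    centers = km.cluster_centers_[order]
    relabel = np.empty(k_eff, dtype=int)
    relabel[order] = np.arange(k_eff)
    labels = relabel[labels]
    out, start = [], 0
    for b in blocks:
        out.append(labels[start : start + len(b)])
        start += len(b)
    dtrajs = DiscreteTrajectorySet(out, n_states=k_eff, frame_interval=frame_interval)
    return dtrajs, centers


def count_matrix(
    dtrajs: DiscreteTrajectorySet, lag: int, mode: str = "sliding"
) -> np.ndarray:
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= dtrajs.min_length:
        raise ValueError(
            f"lag {lag} not smaller than shortest trajectory ({dtrajs.min_length})"
        )
    n = dtrajs.n_states
    counts = np.zeros((n, n), dtype=float)
    for traj in dtrajs.trajectories:
        if mode == "sliding":
            src, dst = traj[:-lag], traj[lag:]
        elif mode == "strided":
            sub = traj[::lag]
            src, dst = sub[:-1], sub[1:]
        else:
            raise ValueError(f"unknown count mode {mode!r}")
        np.add.at(counts, (src, dst), 1.0)
    return counts


def _largest_component(counts: np.ndarray, connection: str = "weak") -> np.ndarray:
    adjacency = (counts > 0).astype(int)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adjacency, directed=True, connection=connection
    )
    # keep the component with the most observed counts
    best, best_weight = 0, -1.0
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        w = counts[np.ix_(members, members)].sum()
        if w > best_weight:
            best, best_weight = c, w
    return np.flatnonzero(labels == best)


def reversible_mle(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    """Maximum-likelihood reversible TPM via the standard fixed-point iteration."""
    c_sym = counts + counts.T
    x = c_sym.copy()
    x[x == 0] = 0.0
    c_row = counts.sum(axis=1)
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        if np.max(np.abs(x_new - x)) < tol * max(1.0, np.max(np.abs(x))):
            x = x_new
            break
        x = x_new
    t = x / x.sum(axis=1, keepdims=True)
    return t


def estimate_tpm(
    dtrajs: DiscreteTrajectorySet,
    lag: int,
    mode: str = "sliding",
    reversible: bool = False,
    connectivity: str = "weak",
) -> TPM:
    """Estimate a TPM at the given lag with connectivity trimming.

    Counts use a sliding window by default; the matrix is restricted to the
    largest connected set (weak by default, ``connectivity="strong"`` for
    strictly ergodic estimation) and row-normalized (non-reversible) unless
    ``reversible`` requests the detailed-balance MLE.
    """
    counts = count_matrix(dtrajs, lag, mode=mode)
    if counts.sum() == 0:
        raise ValueError(f"no transitions observed at lag {lag}")
    active = _largest_component(counts, connection=connectivity)
    dropped = dtrajs.n_states - len(active)
    if dropped:
        logger.warning("ergodic trimming dropped %d states at lag %d", dropped, lag)
    sub = counts[np.ix_(active, active)]
    rowsum = sub.sum(axis=1)
    if np.any(rowsum == 0):
        # states with no outgoing counts (possible under weak connectivity)
        logger.warning("%d states have no outgoing counts; treated as absorbing",
                       int((rowsum == 0).sum()))
        sub = sub + np.diag((rowsum == 0).astype(float))
    if reversible:
        matrix = reversible_mle(sub)
    else:
        matrix = sub / sub.sum(axis=1, keepdims=True)
    return TPM(
        lag=lag,
        matrix=matrix,
        counts=sub,
        active_set=active,
        frame_interval=dtrajs.frame_interval,
    )


def _sorted_eigenvalues(matrix: np.ndarray) -> np.ndarray:
    vals = scipy.linalg.eigvals(matrix)
    if np.max(np.abs(vals.imag)) > 1e-8:
        warnings.warn(
            "complex TPM eigenvalues beyond tolerance; reporting moduli", RuntimeWarning
        )
    order = np.lexsort((-vals.real, -np.abs(vals)))
    return vals[order]


def implied_timescales(
    dtrajs: DiscreteTrajectorySet,
    lags: list[int],
    n_timescales: int | None = None,
    mode: str = "sliding",
    reversible: bool = False,
) -> dict[int, np.ndarray]:
    """Implied timescales t_i = -lag * frame_interval / ln|lambda_i| per lag.

    The stationary eigenvalue is excluded; eigenvalues sorted by modulus
    descending.
    """
    result: dict[int, np.ndarray] = {}
    for lag in lags:
        tpm = estimate_tpm(dtrajs, lag, mode=mode, reversible=reversible)
        if tpm.n_states < 2:
            raise ValueError(f"fewer than 2 states after trimming at lag {lag}")
        vals = _sorted_eigenvalues(tpm.matrix)[1:]
        mods = np.abs(vals)
        k = len(mods) if n_timescales is None else min(n_timescales, len(mods))
        mods = np.clip(mods[:k], 1e-300, 1 - 1e-15)
        result[lag] = -lag * dtrajs.frame_interval / np.log(mods)
    return result


def _lump_matrix(matrix: np.ndarray, pi: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    """Stationary-weighted lumping of a TPM onto a coarse partition."""
    n_sets = len(sets)
    out = np.zeros((n_sets, n_sets))
    for a, sa in enumerate(sets):
        wa = pi[sa]
        denom = wa.sum()
        for b, sb in enumerate(sets):
            out[a, b] = (wa[:, None] * matrix[np.ix_(sa, sb)]).sum() / denom
    return out


def ck_test(
    dtrajs: DiscreteTrajectorySet,
    lag_base: int,
    factors: list[int],
    sets: list | None = None,
    mode: str = "sliding",
) -> CKResult:
    """Chapman-Kolmogorov test: T(lag)^k against directly estimated T(k*lag).

    When ``sets`` (a list of microstate index arrays) is given, both matrices
    are lumped with stationary weights before comparison. Factors whose lag
    exceeds the data are reported as NaN rather than raising.
    """
    base = estimate_tpm(dtrajs, lag_base, mode=mode)
    pi = base.stationary_distribution()
    if sets is not None:
        # translate to positions within the active set
        pos = {s: i for i, s in enumerate(base.active_set)}
        sets_idx = [
            np.array([pos[s] for s in grp if s in pos], dtype=int) for grp in sets
        ]
        sets_idx = [s for s in sets_idx if len(s)]
    predicted, estimated, rmse = {}, {}, {}
    self_pred, self_est = {}, {}
    for k in factors:
        pred_full = np.linalg.matrix_power(base.matrix, k)
        if lag_base * k >= dtrajs.min_length:
            rmse[k] = float("nan")
            continue
        est_tpm = estimate_tpm(dtrajs, lag_base * k, mode=mode)
        common = np.intersect1d(base.active_set, est_tpm.active_set)
        sel_b = np.searchsorted(base.active_set, common)
        sel_e = np.searchsorted(est_tpm.active_set, common)
        pred = pred_full[np.ix_(sel_b, sel_b)]
        pred = pred / pred.sum(axis=1, keepdims=True)
        est = est_tpm.matrix[np.ix_(sel_e, sel_e)]
        est = est / est.sum(axis=1, keepdims=True)
        if sets is not None:
            pi_c = pi[sel_b] / pi[sel_b].sum()
            grp = [
                np.array([np.searchsorted(common, base.active_set[i]) for i in s
                          if base.active_set[i] in common], dtype=int)
                for s in sets_idx
            ]
            grp = [g for g in grp if len(g)]
            pred = _lump_matrix(pred, pi_c, grp)
            est = _lump_matrix(est, pi_c, grp)
        predicted[k], estimated[k] = pred, est
        self_pred[k], self_est[k] = np.diag(pred).copy(), np.diag(est).copy()
        rmse[k] = float(np.sqrt(np.mean((pred - est) ** 2)))
    return CKResult(
        lag_base=lag_base,
        factors=list(factors),
        predicted=predicted,
        estimated=estimated,
        rmse=rmse,
        set_labels=None if sets is None else list(range(len(sets))),
        self_transition_predicted=self_pred,
        self_transition_estimated=self_est,
    )


def _gmrq_score(
    train_dtrajs: DiscreteTrajectorySet,
    eval_dtrajs: DiscreteTrajectorySet,
    lag: int,
    n_eigen: int,
) -> float:
    """GMRQ: Rayleigh trace of train eigenvectors under eval correlation matrices."""
    tpm = estimate_tpm(train_dtrajs, lag)
    vals = scipy.linalg.eig(tpm.matrix)[0]
    order = np.lexsort((-vals.real, -np.abs(vals)))
    _, vecs = scipy.linalg.eig(tpm.matrix)
    vecs = np.real(vecs[:, order[:n_eigen]])
    # eval correlation matrices on the train active set, symmetrized
    n_active = len(tpm.active_set)
    state_map = -np.ones(eval_dtrajs.n_states, dtype=int)
    state_map[tpm.active_set[tpm.active_set < eval_dtrajs.n_states]] = np.arange(
        n_active
    )[tpm.active_set < eval_dtrajs.n_states]
    c0 = np.zeros((n_active, n_active))
    ct = np.zeros((n_active, n_active))
    for traj in eval_dtrajs.trajectories:
        mapped = state_map[traj]
        src, dst = mapped[:-lag], mapped[lag:]
        ok = (src >= 0) & (dst >= 0)
        src, dst = src[ok], dst[ok]
        np.add.at(ct, (src, dst), 0.5)
        np.add.at(ct, (dst, src), 0.5)
        np.add.at(c0, (src, src), 0.5)
        np.add.at(c0, (dst, dst), 0.5)
    if c0.sum() == 0:
        raise ValueError("evaluation data visits no training state")
    a = vecs.T @ c0 @ vecs
    b = vecs.T @ ct @ vecs
    return float(np.trace(scipy.linalg.solve(a, b)))


def gmrq_cv(
    projections: list[np.ndarray],
    hyperparameter_grid: list[dict],
    n_folds: int,
    seed: int,
    lag: int = 1,
    n_eigen: int = 2,
    frame_interval: float = 1.0,
) -> dict:
    """Cross-validated GMRQ over a clustering hyperparameter grid.

    Folds are whole trajectories. Each grid entry is a dict with at least
    ``n_clusters``; optional keys ``lag`` and ``n_eigen`` override the
    defaults. Returns ``{"table": [...], "best": entry}`` where each table row
    carries mean/sd train and test scores.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(projections) < n_folds:
        raise ValueError("need at least one trajectory per fold")
    if not hyperparameter_grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(projections))
    folds = np.array_split(order, n_folds)
    table = []
    for entry in hyperparameter_grid:
        k = entry["n_clusters"]
        entry_lag = entry.get("lag", lag)
        entry_m = entry.get("n_eigen", n_eigen)
        train_scores, test_scores = [], []
        for fold in folds:
            test_idx = set(int(i) for i in fold)
            train = [projections[i] for i in range(len(projections)) if i not in test_idx]
            test = [projections[i] for i in test_idx]
            if not train or not test:
                continue
            try:
                dtrajs_train, centers = kmeans_cluster(
                    train, k, seed=seed, frame_interval=frame_interval
                )
                test_labels = [
                    pairwise_distances_argmin(
                        np.atleast_2d(np.asarray(t, float)).reshape(len(t), -1), centers
                    )
                    for t in test
                ]
                dtrajs_test = DiscreteTrajectorySet(
                    test_labels, n_states=len(centers), frame_interval=frame_interval
                )
                train_scores.append(
                    _gmrq_score(dtrajs_train, dtrajs_train, entry_lag, entry_m)
                )
                test_scores.append(
                    _gmrq_score(dtrajs_train, dtrajs_test, entry_lag, entry_m)
                )
            except ValueError as exc:
                logger.warning("fold skipped for %r: %s", entry, exc)
        if not test_scores:
            table.append({**entry, "train_mean": np.nan, "train_sd": np.nan,
                          "test_mean": np.nan, "test_sd": np.nan})
            continue
        table.append(
            {
                **entry,
                "train_mean": float(np.mean(train_scores)),
                "train_sd": float(np.std(train_scores)),
                "test_mean": float(np.mean(test_scores)),
                "test_sd": float(np.std(test_scores)),
            }
        )
    valid = [row for row in table if np.isfinite(row["test_mean"])]
    if not valid:
        raise ValueError("all folds skipped for every grid entry")
    best = max(valid, key=lambda row: row["test_mean"])
    return {"table": table, "best": best}
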