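"""Featurization: interchain Ca-Ca distances, greedy Nystrom column selection
(spectral-oASIS-style), and tICA projection onto slow collective variables."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .ensemble import StructureEnsemble

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Frames x features distance matrix with named feature pairs."""

    values: np.ndarray
    feature_index: list[tuple[int, int]]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if len(self.feature_index) != self.values.shape[1]:
            raise ValueError("feature_index length must equal column count")
        if len(set(self.feature_index)) != len(self.feature_index):
            raise ValueError("duplicate feature pairs")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_index=[self.feature_index[i] for i in idx],
            frame_interval=self.frame_interval,
        )


@dataclass
class TICAModel:
    """Time-lagged independent component model.

    ``components`` are stored column-wise (features x n_components) and are
    C0-orthonormal; ``eigenvalues`` are the time-lagged autocorrelations,
    sorted descending.
    """

    lag: int
    n_components: int
    components: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray

    def timescales(self, frame_interval: float = 1.0) -> np.ndarray:
        vals = np.clip(np.abs(self.eigenvalues), 1e-300, 1 - 1e-15)
        return -self.lag * frame_interval / np.log(vals)


def interchain_ca_distances(
    ensemble: StructureEnsemble, stride_chainB: int = 1
) -> FeatureMatrix:
    """All chain-A Ca atoms against every ``stride_chainB``-th chain-B Ca atom.

    Feature order is chain-A residue-major, chain-B residue ascending within.
    """
    if stride_chainB < 1:
        raise ValueError("stride_chainB must be >= 1")
    atoms = ensemble.atoms
    ca_a = atoms.index[(atoms["chain"] == "A") & atoms["is_ca"]].to_numpy()
    ca_b_all = atoms.index[(atoms["chain"] == "B") & atoms["is_ca"]].to_numpy()
    if len(ca_a) == 0 or len(ca_b_all) == 0:
        missing = "A" if len(ca_a) == 0 else "B"
        raise ValueError(f"chain {missing} has no Ca-designated atoms")
    # deterministic order: ascending residue index
    ca_a = ca_a[np.argsort(atoms.loc[ca_a, "residue_index"].to_numpy(), kind="stable")]
    ca_b_all = ca_b_all[
        np.argsort(atoms.loc[ca_b_all, "residue_index"].to_numpy(), kind="stable")
    ]
    ca_b = ca_b_all[::stride_chainB]
    xa = ensemble.coords[:, ca_a, :]  # (frames, nA, 3)
    xb = ensemble.coords[:, ca_b, :]
    diff = xa[:, :, None, :] - xb[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    values = dist.reshape(ensemble.n_frames, -1)
    res_a = atoms.loc[ca_a, "residue_index"].to_numpy()
    res_b = atoms.loc[ca_b, "residue_index"].to_numpy()
    feature_index = [(int(ra), int(rb)) for ra in res_a for rb in res_b]
    return FeatureMatrix(
        values=values, feature_index=feature_index, frame_interval=ensemble.frame_interval
    )


def _nystrom_error(cov: np.ndarray, selected: np.ndarray) -> float:
    k = cov[:, selected]
    w = cov[np.ix_(selected, selected)]
    approx = k @ np.linalg.pinv(w, rcond=1e-12) @ k.T
    return float(np.linalg.norm(cov - approx, ord="fro"))


def oasis_select(
    features: FeatureMatrix | np.ndarray,
    n_select: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Greedy Nystrom column selection on the feature covariance matrix.

    At each step the column with the largest residual diagonal of the Schur
    complement is added (ties -> lowest index), which maximally reduces the
    Nystrom approximation error. Returns sorted column indices and the final
    Frobenius reconstruction error. Deterministic; ``seed`` is accepted for
    interface symmetry but unused because ties break by index.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n_features = values.shape[1]
    if not 1 <= n_select <= n_features:
        raise ValueError(f"n_select must be in [1, {n_features}]")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / max(len(values) - 1, 1)
    residual_diag = np.diag(cov).astype(float).copy()
    selected: list[int] = []
    # running Cholesky-style factor of C[S,S]^{-1} applied to C[:,S]
    g = np.zeros((n_features, 0))
    for _ in range(n_select):
        masked = residual_diag.copy()
        masked[selected] = -np.inf
        pick = int(np.argmax(masked))  # argmax returns lowest index on ties
        d = residual_diag[pick]
        col = cov[:, pick] - g @ g[pick]
        if d <= 1e-14:
            # covariance numerically exhausted; keep filling by index order
            remaining = [i for i in range(n_features) if i not in selected]
            selected.extend(remaining[: n_select - len(selected)])
            break
        gnew = col / np.sqrt(d)
        g = np.column_stack([g, gnew])
        residual_diag = residual_diag - gnew**2
        residual_diag = np.clip(residual_diag, 0.0, None)
        selected.append(pick)
    selected_arr = np.sort(np.asarray(selected[:n_select], dtype=int))
    error = _nystrom_error(cov, selected_arr)
    return selected_arr, error


def _lagged_covariances(
    values: np.ndarray, lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x0 = values[:-lag]
    xt = values[lag:]
    mean = 0.5 * (x0.mean(axis=0) + xt.mean(axis=0))
    x0 = x0 - mean
    xt = xt - mean
    n = len(x0)
    c0 = 0.5 * (x0.T @ x0 + xt.T @ xt) / n
    ct = 0.5 * (x0.T @ xt + xt.T @ x0) / n
    return c0, ct, mean


def tica_fit(
    features: FeatureMatrix | np.ndarray,
    lag: int,
    n_components: int,
    epsilon: float = 1e-10,
) -> TICAModel:
    """Fit tICA with the symmetrized (reversible) covariance estimator.

    Solves the generalized eigenproblem ``Ct v = lambda C0 v``; a diagonal
    ridge of ``epsilon`` is added when C0 is rank-deficient (with a warning).
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    values = np.atleast_2d(values)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= len(values):
        raise ValueError("lag must be smaller than the number of frames")
    n_features = values.shape[1]
    if n_components > n_features:
        raise ValueError("n_components cannot exceed n_features")
    if len(values) - lag <= n_features:
        warnings.warn(
            "fewer lagged pairs than features; tICA estimates will be noisy",
            RuntimeWarning,
        )
    c0, ct, mean = _lagged_covariances(values, lag)
    # regularize if rank-deficient
    eigmin = scipy.linalg.eigvalsh(c0)[0]
    if eigmin < epsilon:
        warnings.warn("singular instantaneous covariance; adding diagonal ridge",
                      RuntimeWarning)
        c0 = c0 + max(epsilon, abs(eigmin) + epsilon) * np.eye(n_features)
    vals, vecs = scipy.linalg.eigh(ct, c0)
    order = np.argsort(vals)[::-1][:n_components]
    eigenvalues = vals[order]
    components = vecs[:, order]
    # eigh(b=...) returns C0-orthonormal vectors already; enforce sign convention
    signs = np.sign(components[np.argmax(np.abs(components), axis=0), np.arange(len(order))])
    signs[signs == 0] = 1.0
    components = components * signs
    return TICAModel(
        lag=lag,
        n_components=n_components,
        components=components,
        eigenvalues=eigenvalues,
        mean=mean,
    )


def tica_transform(model: TICAModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project frames onto the fitted components after mean-centering."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    return (np.atleast_2d(values) - model.mean) @ model.components
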