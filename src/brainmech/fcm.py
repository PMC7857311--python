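"""Fuzzy C-means clustering with the Gustafson-Kessel distance.

Each record holds a graded membership in every cluster (the C x N matrix
U, columns summing to one) and clustering minimizes the weighted cost

    J(U, V) = sum_i sum_k  u_ik^Q  d^2(x_k, v_i)

by alternating closed-form updates of memberships, prototypes, and
per-cluster covariances.  The Gustafson-Kessel distance

    d^2 = (x - v)^T A_i (x - v),   A_i = (rho_i det F_i)^(1/n) F_i^{-1}

normalizes each cluster's fuzzy covariance F_i to a fixed hyper-volume
rho_i, so clusters may be ellipsoids of differing orientation but not of
runaway size.  The fuzzifier Q (default 2, the conventional midpoint
between crisp and soft partitions) controls softness.

The cluster count is chosen by a membership-confidence rule: the largest
C in the searched range for which at least a majority of points still
claim a maximum membership above 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_REG_SCALE = 1e-6


@dataclass
class FuzzyPartition:
    U: np.ndarray                    # C x N memberships, columns sum to 1
    V: np.ndarray                    # C x p prototypes
    F: np.ndarray                    # C x p x p fuzzy covariances
    rho: np.ndarray                  # per-cluster volume constants
    Q: float
    C: int
    cost_trace: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.U, axis=0)

    @property
    def max_memberships(self) -> np.ndarray:
        return np.max(self.U, axis=0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "C": self.C, "Q": self.Q, "seed": self.seed,
            "U": self.U.tolist(), "V": self.V.tolist(),
            "F": self.F.tolist(), "rho": self.rho.tolist(),
            "cost_trace": self.cost_trace,
        }
        Path(path).write_text(json.dumps(payload))


def _regularize(F: np.ndarray) -> np.ndarray:
    """Nudge a symmetric matrix to condition number <= 1e10 by adding gamma*I."""
    n = F.shape[0]
    F = 0.5 * (F + F.T)
    for _ in range(60):
        w = np.linalg.eigvalsh(F)
        w_max, w_min = w[-1], w[0]
        if w_min > 0 and w_max / w_min <= _COND_LIMIT:
            return F
        gamma = _REG_SCALE * (np.trace(F) / n if np.trace(F) > 0 else 1.0)
        F = F + gamma * np.eye(n)
    return F


def gk_distance(x: np.ndarray, v: np.ndarray, F: np.ndarray, rho: float = 1.0) -> float:
    """Squared Gustafson-Kessel distance between a point and a prototype."""
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    F = _regularize(np.asarray(F, float))
    n = F.shape[0]
    A = (rho * np.linalg.det(F)) ** (1.0 / n) * np.linalg.inv(F)
    d = x - v
    return float(d @ A @ d)


def _distance_matrix(X: np.ndarray, V: np.ndarray, F: np.ndarray,
                     rho: np.ndarray, gk: bool) -> np.ndarray:
    """C x N matrix of squared distances."""
    C, N = V.shape[0], X.shape[0]
    D = np.empty((C, N))
    n = X.shape[1]
    for i in range(C):
        diff = X - V[i]
        if gk:
            Fi = _regularize(F[i])
            A = (rho[i] * np.linalg.det(Fi)) ** (1.0 / n) * np.linalg.inv(Fi)
            D[i] = np.einsum("kj,jl,kl->k", diff, A, diff)
        else:
            D[i] = (diff ** 2).sum(1)
    return np.maximum(D, 0.0)


def update_memberships(D: np.ndarray, Q: float = 2.0) -> np.ndarray:
    """Membership update minimizing J for fixed distances.

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(Q-1)); points at zero distance
    from one or more prototypes split full membership evenly among those.
    """
    if Q <= 1.0:
        raise ValueError("fuzzifier Q must be > 1")
    D = np.asarray(D, float)
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    C, N = D.shape
    U = np.zeros((C, N))
    zero_cols = np.any(D == 0.0, axis=0)
    if np.any(zero_cols):
        Z = D[:, zero_cols] == 0.0
        U[:, zero_cols] = Z / Z.sum(axis=0)
    ok = ~zero_cols
    if np.any(ok):
        # D holds squared distances, so the 2/(Q-1) exponent on d becomes 1/(Q-1)
        expo = 1.0 / (Q - 1.0)
        ratios = (D[:, ok][None, :, :] / D[:, ok][:, None, :]) ** expo  # j,i,k
        U[:, ok] = 1.0 / ratios.sum(axis=0)
    return U


def update_centers(X: np.ndarray, U: np.ndarray, Q: float = 2.0) -> np.ndarray:
    """v_i = sum_k u_ik^Q x_k / sum_k u_ik^Q."""
    W = U ** Q
    denom = W.sum(axis=1)
    return (W @ X) / denom[:, None]


def cluster_covariance(X: np.ndarray, U: np.ndarray, Q: float,
                       V: np.ndarray) -> np.ndarray:
    """Fuzzy scatter F_i = sum_k u_ik^Q (x_k-v_i)(x_k-v_i)^T / sum_k u_ik^Q,
    regularized to condition number <= 1e10."""
    C, N = U.shape
    p = X.shape[1]
    W = U ** Q
    F = np.empty((C, p, p))
    for i in range(C):
        diff = X - V[i]
        Fi = (W[i][:, None] * diff).T @ diff / W[i].sum()
        F[i] = _regularize(Fi)
    return F


def fit(X: np.ndarray, C: int, Q: float = 2.0, tol: float = 1e-5,
        max_iter: int = 200, seed: int = 0, rho: np.ndarray | float = 1.0,
        gk: bool = True) -> FuzzyPartition:
    """Alternating optimization of the fuzzy partition.

    Starts from a random valid membership matrix; iterates prototype,
    covariance, distance and membership updates until the largest
    membership change falls below ``tol`` or ``max_iter``; the cost J is
    recorded every iteration.  ``gk=False`` fixes all covariances to the
    identity (plain fuzzy C-means with Euclidean distances).
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    N, p = X.shape
    if not 1 <= C < N:
        raise ValueError(f"need 1 <= C < N, got C={C}, N={N}")
    rng = np.random.default_rng(seed)
    rho_arr = np.full(C, float(rho)) if np.isscalar(rho) else np.asarray(rho, float)

    U = rng.uniform(size=(C, N))
    U /= U.sum(axis=0)
    F = np.broadcast_to(np.eye(p), (C, p, p)).copy()
    cost_trace: list[float] = []
    V = update_centers(X, U, Q)
    for _ in range(max_iter):
        weights = (U ** Q).sum(axis=1)
        dead = weights < 1e-12 * N
        if np.any(dead):
            logger.warning("re-seeding %d degenerate cluster(s)", int(dead.sum()))
            V[dead] = X[rng.integers(N, size=int(dead.sum()))]
        if gk and C >= 1:
            F = cluster_covariance(X, U, Q, V)
        D = _distance_matrix(X, V, F, rho_arr, gk)
        cost_trace.append(float(((U ** Q) * D).sum()))
        U_new = update_memberships(D, Q)
        delta = float(np.abs(U_new - U).max())
        U = U_new
        V = update_centers(X, U, Q)
        if delta < tol:
            break
    return FuzzyPartition(U=U, V=V, F=F, rho=rho_arr, Q=Q, C=C,
                          cost_trace=cost_trace, seed=seed)


def select_cluster_count(X: np.ndarray, C_range=range(2, 7), Q: float = 2.0,
                         seeds: int = 10, majority_threshold: float = 0.5,
                         seed: int = 0, **fit_kw) -> tuple[int, dict[int, FuzzyPartition]]:
    """Largest C whose best-of-restarts fit keeps a majority of points confident.

    For each C the fit is restarted ``seeds`` times (seeded deterministically
    from ``seed``) and the lowest-cost partition kept; C qualifies when the
    fraction of points with maximum membership above 0.5 is at least
    ``majority_threshold``.  Falls back to the smallest C (with a warning)
    if none qualify.  Returns the chosen C and all best partitions.
    """
    C_range = sorted(C_range)
    if not C_range:
        raise ValueError("C_range is empty")
    ss = np.random.SeedSequence(seed).generate_state(seeds) % (2 ** 31)
    best: dict[int, FuzzyPartition] = {}
    qualifying = []
    for C in C_range:
        parts = [fit(X, C, Q=Q, seed=int(s), **fit_kw) for s in ss]
        part = min(parts, key=lambda pr: pr.cost_trace[-1])
        best[C] = part
        frac = float((part.max_memberships > 0.5).mean())
        logger.info("C=%d: confident fraction %.3f", C, frac)
        if frac >= majority_threshold:
            qualifying.append(C)
    if qualifying:
        return max(qualifying), best
    warnings.warn("no cluster count met the membership rule; "
                  f"falling back to C={C_range[0]}")
    return C_range[0], best


def cluster_summary(partition: FuzzyPartition, denormalized: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster means of the original (denormalized) variables.

    Rows are clusters (hard, argmax-membership assignment); useful for
    characterizations like 'cluster 1 sits at 0.9 1/s and 14 mm diameter'.
    """
    labels = partition.hard_labels
    out = denormalized.groupby(labels).mean()
    out.index.name = "cluster"
    out.insert(0, "n_points", pd.Series(labels).value_counts().sort_index())
    return out
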