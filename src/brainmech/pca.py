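"""Principal component analysis by covariance eigendecomposition.

Operates on the already peak-normalized matrices: center each column,
eigendecompose the sample covariance (divisor N-1), sort components by
descending eigenvalue.  The number of retained components is the smallest
k explaining at least 85% of total variance, capped at 3 for the
clustering stage (ellipsoidal fuzzy clusters are fitted, and plotted, in
at most three dimensions); when the cap bites, the shortfall is logged
rather than silently accepted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_THRESHOLD = 0.85
DEFAULT_COMPONENT_CAP = 3


@dataclass
class PcaModel:
    means: np.ndarray
    eigenvalues: np.ndarray      # descending, >= 0 (tiny negatives clipped)
    eigenvectors: np.ndarray     # orthonormal columns, one per component
    cum_var_fraction: np.ndarray
    k_retained: int | None = None

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "means": self.means.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "cum_var_fraction": self.cum_var_fraction.tolist(),
            "k_retained": self.k_retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(means=np.asarray(d["means"]),
                   eigenvalues=np.asarray(d["eigenvalues"]),
                   eigenvectors=np.asarray(d["eigenvectors"]),
                   cum_var_fraction=np.asarray(d["cum_var_fraction"]),
                   k_retained=d["k_retained"])


def fit_pca(X: np.ndarray) -> PcaModel:
    """Center columns, eigendecompose the sample covariance, sort descending.

    Sign convention: each component's largest-magnitude loading is made
    positive.  Rank-deficient input simply yields (near-)zero eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    means = X.mean(axis=0)
    C = np.cov(X - means, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)     # ascending for symmetric matrices
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    total = evals.sum()
    cum = np.cumsum(evals) / total if total > 0 else np.ones_like(evals)
    cum[-1] = 1.0
    return PcaModel(means=means, eigenvalues=evals, eigenvectors=evecs,
                    cum_var_fraction=cum)


def select_components(model: PcaModel, threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                      cap: int | None = DEFAULT_COMPONENT_CAP) -> int:
    """Smallest k whose components explain >= threshold of variance, capped.

    With ``cap=None`` the rule is applied uncapped.  When the uncapped k
    exceeds the cap, the cap is returned and the unmet threshold logged.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    k = int(np.searchsorted(model.cum_var_fraction, threshold - 1e-12) + 1)
    k = min(k, model.n_components)
    if cap is not None and k > cap:
        logger.warning(
            "variance threshold %.0f%% needs %d components; capping at %d "
            "(%.1f%% explained)", 100 * threshold, k, cap,
            100 * model.cum_var_fraction[cap - 1])
        k = cap
    model.k_retained = k
    return k


def transform(model: PcaModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project centered rows onto the first k components (N x k scores)."""
    X = np.asarray(X, dtype=float)
    if k is None:
        k = model.k_retained or model.n_components
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds {model.n_components} components")
    if X.shape[-1] != model.means.size:
        raise ValueError("column count does not match the fitted model")
    return (X - model.means) @ model.eigenvectors[:, :k]
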