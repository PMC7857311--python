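"""Kohonen self-organizing map and leave-one-feature-out sensitivity ranking.

A SOM maps the normalized records onto a small 2-D neuron lattice
(default 10x10) so that nearby neurons capture similar records.  Training
is the classic online scheme: for every sample the best-matching unit
(BMU) wins the *competition* (smallest Euclidean distance), a Gaussian
neighborhood on the lattice *cooperates*, and the *adaptation* step pulls
the neighborhood's weights toward the sample, with learning rate and
neighborhood radius decaying exponentially over epochs.

Feature importance is measured by how much the map's organisation of the
target response (true strain by default) changes when a feature is
withheld from training: features whose removal reorganises the strain
component plane are the ones structuring the dataset.  The change is
quantified as one minus the Pearson correlation between the strain plane
values looked up at each sample's BMU in the reference map versus the
reduced map, averaged over seeded restarts.  Spatial coherence of a
single plane ("clustering tendency") is quantified by Moran's I with rook
adjacency on the lattice.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compilation import CompiledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SomTrainParams:
    """Online-training schedule.  The fairly wide final neighborhood
    (1.5 lattice units on a 10x10 grid) keeps trained maps smooth, which
    favors stable component planes over minimal quantization error."""

    epochs: int = 10
    lr_initial: float = 0.5
    lr_final: float = 0.05
    sigma_initial: float = 5.0   # lattice units
    sigma_final: float = 1.5
    seed: int = 0
    change_tol: float = 0.0      # early stop when mean |dW| per epoch < tol

    def __post_init__(self):
        if not (self.lr_initial >= self.lr_final > 0):
            raise ValueError("need lr_initial >= lr_final > 0")
        if not (self.sigma_initial >= self.sigma_final > 0):
            raise ValueError("need sigma_initial >= sigma_final > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SomModel:
    grid_rows: int
    grid_cols: int
    weights: np.ndarray                  # (rows*cols) x p
    column_names: list[str] | None = None
    trained_epochs: int = 0
    quantization_error_trace: list[float] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols

    def grid_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_neurons), self.grid_cols)
        return np.column_stack([r, c]).astype(float)

    def bmus(self, X: np.ndarray) -> np.ndarray:
        """Index of the best-matching unit for every row of X."""
        X = np.atleast_2d(X)
        # ||x-w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; the x term is constant per row
        d = (self.weights ** 2).sum(1)[None, :] - 2.0 * X @ self.weights.T
        return np.argmin(d, axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        """Mean Euclidean distance from samples to their BMU weights."""
        bmu = self.bmus(X)
        return float(np.linalg.norm(X - self.weights[bmu], axis=1).mean())


def train_som(X: np.ndarray, params: SomTrainParams,
              grid_rows: int = 10, grid_cols: int = 10,
              column_names: list[str] | None = None) -> SomModel:
    """Online SOM training on a (rows x cols) lattice.

    Weights start uniform random in [0, 1] per dimension (the inputs are
    peak-normalized), seeded.  Samples are revisited in a reshuffled
    order each epoch; lr and sigma decay exponentially from their initial
    to final values across epochs.  Training stops at ``epochs`` or when
    the mean absolute weight change in an epoch drops below
    ``change_tol``.

    Weight initialization and sample-order shuffling draw from two
    independent streams derived from the seed, so two runs with the same
    seed visit samples in identical orders even when their input
    dimensionalities differ — leave-one-feature-out retraining is then a
    matched-pairs comparison, not confounded by a diverged shuffle.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, p = X.shape
    ss_init, ss_perm = np.random.SeedSequence(params.seed).spawn(2)
    rng_init = np.random.default_rng(ss_init)
    rng = np.random.default_rng(ss_perm)
    model = SomModel(grid_rows, grid_cols,
                     weights=rng_init.uniform(size=(grid_rows * grid_cols, p)),
                     column_names=list(column_names) if column_names else None)
    coords = model.grid_coords()
    # squared lattice distances between all neuron pairs, precomputed
    gd2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    T = params.epochs
    model.quantization_error_trace.append(model.quantization_error(X))
    for t in range(T):
        frac = t / max(T - 1, 1)
        lr = params.lr_initial * (params.lr_final / params.lr_initial) ** frac
        sigma = params.sigma_initial * (params.sigma_final / params.sigma_initial) ** frac
        h_all = np.exp(-gd2 / (2.0 * sigma * sigma))  # neighborhood kernel rows
        W = model.weights
        total_change = 0.0
        for i in rng.permutation(n):
            x = X[i]
            bmu = np.argmin(((W - x) ** 2).sum(1))
            upd = (lr * h_all[bmu])[:, None] * (x - W)
            W += upd
            total_change += np.abs(upd).mean()
        model.trained_epochs = t + 1
        model.quantization_error_trace.append(model.quantization_error(X))
        if params.change_tol > 0 and total_change / n < params.change_tol:
            logger.debug("SOM converged after %d epochs", t + 1)
            break
    return model


def component_plane(model: SomModel, feature: str | int, X: np.ndarray,
                    feature_values: np.ndarray | None = None) -> np.ndarray:
    """Lattice grid of per-neuron means of one feature.

    Each cell holds the mean of the feature over the samples whose BMU is
    that neuron; neurons that win no sample fall back to their own weight
    coordinate for the feature (so the plane is defined everywhere).
    ``feature_values`` overrides the feature column of X, allowing planes
    of variables the map was not trained on.
    """
    if isinstance(feature, str):
        if model.column_names is None or feature not in model.column_names:
            raise KeyError(f"unknown feature {feature!r}")
        j = model.column_names.index(feature)
    else:
        j = int(feature)
        if not 0 <= j < model.weights.shape[1]:
            raise KeyError(f"feature index {j} out of range")
    vals = np.asarray(feature_values, float) if feature_values is not None else X[:, j]
    bmu = model.bmus(X)
    plane = model.weights[:, j].copy()
    sums = np.bincount(bmu, weights=vals, minlength=model.n_neurons)
    hits = np.bincount(bmu, minlength=model.n_neurons)
    occupied = hits > 0
    plane[occupied] = sums[occupied] / hits[occupied]
    return plane.reshape(model.grid_rows, model.grid_cols)


def clustering_tendency(plane: np.ndarray) -> float:
    """Moran's I of a lattice plane under rook adjacency, clipped to [-1, 1].

    Positive values mean neighboring cells hold similar values (spatially
    coherent clusters); a checkerboard is strongly negative; a constant
    plane carries no structure and scores 0 by convention.
    """
    z = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("plane contains non-finite values")
    if np.ptp(z) == 0.0:
        return 0.0
    z = z - z.mean()
    denom = (z ** 2).sum()
    if denom == 0.0:
        return 0.0
    num = 0.0
    w_total = 0
    # rook neighbors: horizontal and vertical adjacent pairs, each counted twice
    num += 2.0 * (z[:, :-1] * z[:, 1:]).sum()
    w_total += 2 * z[:, :-1].size
    num += 2.0 * (z[:-1, :] * z[1:, :]).sum()
    w_total += 2 * z[:-1, :].size
    moran = (z.size / w_total) * (num / denom)
    return float(np.clip(moran, -1.0, 1.0))


@dataclass
class SensitivityRanking:
    """Leave-one-feature-out importance ranking for one analysis subset."""

    subset_name: str
    ranked_groups: list[list[str]]   # descending importance; len>1 = tie
    scores: dict[str, float]         # structural-change score per feature

    def rank_of(self, feature: str) -> int:
        for rank, group in enumerate(self.ranked_groups, start=1):
            if feature in group:
                return rank
        raise KeyError(feature)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subset", "rank", "features", "score"])
            for rank, group in enumerate(self.ranked_groups, start=1):
                score = max(self.scores[f] for f in group)
                w.writerow([self.subset_name, rank, " + ".join(group), f"{score:.4f}"])


def _plane_values_at_bmus(model: SomModel, X: np.ndarray, target: np.ndarray) -> np.ndarray:
    plane = component_plane(model, 0, X, feature_values=target).ravel()
    return plane[model.bmus(X)]


def structure_change(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation of two BMU-aligned plane value series.

    Degenerate (constant) series carry no structure to compare; their
    correlation is taken as 0, i.e. maximal change.
    """
    if a.std() == 0.0 or b.std() == 0.0:
        return 1.0
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - np.clip(r, -1.0, 1.0)


def rank_features(subset: CompiledDataset, params: SomTrainParams,
                  n_restarts: int = 10, grid_rows: int = 10, grid_cols: int = 10,
                  target: str = "true_strain", tie_tol: float = 0.05) -> SensitivityRanking:
    """Rank a subset's input parameters by leave-one-feature-out SOM change.

    For each restart a reference SOM is trained on all columns and, per
    candidate input feature, a reduced SOM is trained (same seed) with
    that feature withheld.  The restart's change score for the feature is
    ``structure_change`` between the target (strain) plane values at each
    sample's BMU under the reference versus the reduced map.  Scores are
    averaged over restarts and ranked descending; features within
    ``tie_tol`` of the head of their group are reported as tied.
    """
    candidates = subset.input_names
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features to rank")
    X = subset.matrix
    names = subset.column_names
    t_idx = names.index(target)
    target_vals = X[:, t_idx]

    seeds = np.random.SeedSequence(params.seed).generate_state(n_restarts) % (2 ** 31)
    per_restart = {f: [] for f in candidates}
    for seed in seeds:
        p_r = SomTrainParams(epochs=params.epochs, lr_initial=params.lr_initial,
                             lr_final=params.lr_final, sigma_initial=params.sigma_initial,
                             sigma_final=params.sigma_final, seed=int(seed),
                             change_tol=params.change_tol)
        ref = train_som(X, p_r, grid_rows, grid_cols, column_names=names)
        a = _plane_values_at_bmus(ref, X, target_vals)
        for f in candidates:
            keep = [j for j, c in enumerate(names) if c != f]
            Xr = X[:, keep]
            red = train_som(Xr, p_r, grid_rows, grid_cols,
                            column_names=[names[j] for j in keep])
            b = _plane_values_at_bmus(red, Xr, target_vals)
            per_restart[f].append(structure_change(a, b))
    scores = {f: float(np.mean(v)) for f, v in per_restart.items()}

    order = sorted(candidates, key=lambda f: -scores[f])
    groups: list[list[str]] = []
    for f in order:
        if groups and scores[groups[-1][0]] - scores[f] < tie_tol:
            groups[-1].append(f)
        else:
            groups.append([f])
    return SensitivityRanking(subset_name=subset.subset_label,
                              ranked_groups=groups, scores=scores)


def save_plane_csv(plane: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, plane, delimiter=",", fmt="%.6g")


def save_plane_png(plane: np.ndarray, path: str | Path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(plane, cmap="viridis", origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
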