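"""Kohonen self-organizing map: training, mapping, stratified partitioning,
and the response-pattern applicability domain.

The map is a ``rows x cols`` grid of centroid vectors trained by online
competitive learning with a Gaussian neighborhood, linearly decaying
learning rate and radius.  Three downstream uses are provided:

* chemistry-aware train/test partitioning that draws test samples from
  occupied neurons, stratified by a category per sample;
* normalized response patterns (the vector of distances from a sample to
  every neuron centroid, min-max scaled to [0, 1]);
* the ASD applicability-domain statistic: the average distance between a
  query's response pattern and all training response patterns, rescaled
  by 1/sqrt(number of neurons) so it lies in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

#: Default applicability-domain cutoff (strict upper bound on the ASD).
#: Calibrated for one particular map/dataset; recalibrate for new data.
DEFAULT_ASD_THRESHOLD = 0.421


class SOMError(ValueError):
    pass


@dataclass(frozen=True)
class ADConfig:
    """Applicability-domain configuration: a query is in-domain iff its
    ASD is strictly below ``threshold``."""

    threshold: float = DEFAULT_ASD_THRESHOLD
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise SOMError(f"threshold must be in (0, 1), got {self.threshold}")


def default_grid_side(n_samples: int) -> int:
    """Heuristic side length: ceil(sqrt(5 * sqrt(n)))."""
    return max(2, int(np.ceil(np.sqrt(5.0 * np.sqrt(max(n_samples, 1))))))


@dataclass
class SOMModel:
    rows: int
    cols: int
    centroids: np.ndarray  # (rows*cols, n_features)
    topology: str = "toroidal"
    epochs: int = 0
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float | None = None
    seed: int | None = None
    trained: bool = False
    _grid: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.topology not in ("planar", "toroidal"):
            raise SOMError(f"unknown topology {self.topology!r}")
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.rows * self.cols:
            raise SOMError("centroid count does not match grid size")
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        self._grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]

    def grid_distances(self, winner: int) -> np.ndarray:
        """Squared grid distance from every neuron to ``winner``."""
        delta = np.abs(self._grid - self._grid[winner])
        if self.topology == "toroidal":
            delta[:, 0] = np.minimum(delta[:, 0], self.rows - delta[:, 0])
            delta[:, 1] = np.minimum(delta[:, 1], self.cols - delta[:, 1])
        return (delta**2).sum(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "topology": self.topology,
            "epochs": self.epochs,
            "lr_initial": self.lr_initial,
            "lr_final": self.lr_final,
            "radius_initial": self.radius_initial,
            "seed": self.seed,
            "trained": self.trained,
            "n_features": self.n_features,
            "centroids": self.centroids.ravel().tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        centroids = np.asarray(payload["centroids"]).reshape(
            payload["rows"] * payload["cols"], payload["n_features"]
        )
        return cls(
            rows=payload["rows"],
            cols=payload["cols"],
            centroids=centroids,
            topology=payload["topology"],
            epochs=payload["epochs"],
            lr_initial=payload["lr_initial"],
            lr_final=payload["lr_final"],
            radius_initial=payload["radius_initial"],
            seed=payload["seed"],
            trained=payload["trained"],
        )


def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise SOMError("X must be a non-empty 2-D array")
    if not np.isfinite(X).all():
        raise SOMError("X contains non-finite values")
    return X


def som_train(
    X,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 100,
    seed: int = 0,
    topology: str = "toroidal",
    lr_initial: float = 0.5,
    lr_final: float = 0.01,
    radius_initial: float | None = None,
) -> SOMModel:
    """Train a Kohonen map with standard online updates.

    Centroids are initialized uniformly within the per-feature data range.
    Each epoch presents every sample once in a reshuffled order; the winner
    and its Gaussian neighborhood move toward the sample.  Learning rate
    and neighborhood radius decay linearly over epochs.  Deterministic for
    a fixed seed.
    """
    X = _validate_X(X)
    n, p = X.shape
    if rows is None or cols is None:
        side = default_grid_side(n)
        rows = rows or side
        cols = cols or side
    if rows * cols < 2:
        raise SOMError("grid must have at least 2 neurons")
    if epochs < 1:
        raise SOMError("epochs must be >= 1")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    centroids = rng.uniform(size=(rows * cols, p)) * (hi - lo) + lo
    radius0 = radius_initial if radius_initial is not None else max(rows, cols) / 2.0
    radius0 = max(radius0, 1.0)

    model = SOMModel(
        rows=rows,
        cols=cols,
        centroids=centroids,
        topology=topology,
        epochs=epochs,
        lr_initial=lr_initial,
        lr_final=lr_final,
        radius_initial=radius0,
        seed=seed,
    )
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr_initial + (lr_final - lr_initial) * frac
        radius = radius0 + (1.0 - radius0) * frac
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            d2 = ((model.centroids - x) ** 2).sum(axis=1)
            winner = int(np.argmin(d2))
            g2 = model.grid_distances(winner)
            h = np.exp(-g2 / (2.0 * radius * radius))
            model.centroids += (lr * h)[:, None] * (x - model.centroids)
    model.trained = True
    return model


def som_map(model: SOMModel, x) -> int:
    """Index of the neuron whose centroid is nearest to ``x`` (Euclidean);
    ties break to the lowest neuron index."""
    if not model.trained:
        raise SOMError("model is not trained")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise SOMError(
            f"dimension mismatch: x has shape {x.shape}, expected ({model.n_features},)"
        )
    d2 = ((model.centroids - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first (lowest) index on ties


def som_map_all(model: SOMModel, X) -> np.ndarray:
    X = _validate_X(X)
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def quantization_error(model: SOMModel, X) -> float:
    """Mean Euclidean distance of samples to their winning centroids."""
    X = _validate_X(X)
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def som_partition(
    model: SOMModel,
    X,
    sample_ids,
    strata,
    test_fraction: float,
    seed: int = 0,
) -> tuple[list, list]:
    """Split samples into train/test ids, stratified by category, drawing
    test samples spread across the occupied neurons of each stratum.

    Within each stratum the test quota is ``round(test_fraction * n)``
    (so each stratum is within one sample of exact proportionality); test
    members are taken round-robin over that stratum's occupied neurons in
    a seeded random order.  The split is disjoint and exhaustive.
    """
    if not 0.0 < test_fraction < 1.0:
        raise SOMError(f"test_fraction must be in (0, 1), got {test_fraction}")
    X = _validate_X(X)
    sample_ids = list(sample_ids)
    strata = list(strata)
    if not len(sample_ids) == len(strata) == X.shape[0]:
        raise SOMError("sample_ids, strata and X must align")
    winners = som_map_all(model, X)
    rng = np.random.default_rng(seed)

    test_idx: list[int] = []
    for stratum in sorted(set(map(str, strata))):
        members = [i for i, s in enumerate(strata) if str(s) == stratum]
        quota = int(round(test_fraction * len(members)))
        quota = min(quota, len(members))
        by_neuron: dict[int, list[int]] = {}
        for i in members:
            by_neuron.setdefault(int(winners[i]), []).append(i)
        pools = [list(rng.permutation(v)) for _, v in sorted(by_neuron.items())]
        pools = [pools[j] for j in rng.permutation(len(pools))]
        taken = 0
        while taken < quota:
            progressed = False
            for pool in pools:
                if pool and taken < quota:
                    test_idx.append(int(pool.pop()))
                    taken += 1
                    progressed = True
            if not progressed:
                break
    test_set = set(test_idx)
    train_ids = [sample_ids[i] for i in range(len(sample_ids)) if i not in test_set]
    test_ids = [sample_ids[i] for i in sorted(test_set)]
    return train_ids, test_ids


def response_pattern(model: SOMModel, x) -> np.ndarray:
    """Distances from ``x`` to every neuron centroid, min-max scaled to [0, 1]."""
    if not model.trained:
        raise SOMError("model is not trained")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise SOMError(
            f"dimension mismatch: x has shape {x.shape}, expected ({model.n_features},)"
        )
    d = np.sqrt(((model.centroids - x) ** 2).sum(axis=1))
    span = d.max() - d.min()
    if span == 0:
        raise SOMError("degenerate model: all centroids equidistant from x")
    return (d - d.min()) / span


def response_patterns(model: SOMModel, X) -> np.ndarray:
    return np.vstack([response_pattern(model, x) for x in _validate_X(X)])


def asd(model: SOMModel, x, training_patterns) -> float:
    """Average SOM distance of ``x`` to a set of training response patterns.

    Mean Euclidean distance between the query's response pattern and each
    training pattern, divided by sqrt(number of neurons) so the result is
    in [0, 1] (patterns live in the unit hypercube).
    """
    training_patterns = np.asarray(training_patterns, dtype=float)
    if training_patterns.ndim != 2 or training_patterns.shape[0] < 1:
        raise SOMError("need at least one training response pattern")
    if training_patterns.shape[1] != model.n_neurons:
        raise SOMError("training patterns do not match the model's neuron count")
    r = response_pattern(model, x)
    d = np.sqrt(((training_patterns - r) ** 2).sum(axis=1))
    return float(d.mean() / np.sqrt(model.n_neurons))


def in_domain(asd_value: float, config: ADConfig | None = None) -> bool:
    """True iff the ASD is strictly below the configured threshold."""
    if asd_value < 0:
        raise SOMError(f"ASD must be non-negative, got {asd_value}")
    config = config or ADConfig()
    return asd_value < config.threshold


def cluster_ward(X, k: int) -> np.ndarray:
    """Ward agglomerative clustering into ``k`` clusters (labels 1..k)."""
    X = _validate_X(X)
    if k < 1:
        raise SOMError(f"k must be >= 1, got {k}")
    if k > X.shape[0]:
        raise SOMError(f"k={k} exceeds the number of samples ({X.shape[0]})")
    if X.shape[0] == 1:
        return np.array([1])
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")
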