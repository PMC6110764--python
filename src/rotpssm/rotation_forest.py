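"""From-scratch Rotation Forest ensemble classifier.

Rotation Forest grows each decision tree on a different linear view of the
training data. For tree *i* the feature set is randomly split into K
disjoint subsets; for every subset a random non-empty group of classes is
selected, their samples bootstrap-sampled, and PCA run on that sample
restricted to the subset's columns. The per-subset loading matrices are
assembled into a sparse block rotation matrix (exact zeros off-block) whose
rows and columns follow the original feature order, the tree is trained on
the rotated data X @ R_i, and class confidences are the plain average of
the trees' per-class probability estimates:

    lambda_j(x) = (1/L) * sum_i d_ij(x @ R_i)

with the predicted label the argmax of lambda (ties to the lowest class
index). All components are kept in every per-subset PCA, so each rotation
is square and information-preserving; the randomness of the partition and
of the class/bootstrap sampling is what diversifies the ensemble.

The base learner is an unpruned CART tree (Gini impurity); d_ij are
Laplace-smoothed (+1) leaf class frequencies, which keeps confidences off
the degenerate 0/1 extremes so ROC sweeps have usable resolution.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestConfig",
    "FeaturePartition",
    "RotationMatrix",
    "RotationForestModel",
    "make_partition",
    "build_rotation",
    "fit",
    "predict_confidence",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8
_CLASS_RETRY = 10

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyper-parameters.

    K : number of disjoint feature subsets per tree (default 20).
    L : number of trees (default 2). K=20, L=2 is the grid-searched
        optimum for the PSSM/2DPCA descriptor task.
    bootstrap_fraction : fraction of the selected classes' samples drawn
        for each per-subset PCA (default 0.75).
    class_subset_rule : "random" (each class kept with probability 1/2,
        resampled while empty) or "all" (every class, deterministic).
    with_replacement : bootstrap with replacement (default). Setting
        fraction=1.0 with replacement=False makes the PCA sample the full
        selected-class sample, with no duplication.
    """

    K: int = 20
    L: int = 2
    bootstrap_fraction: float = 0.75
    class_subset_rule: str = "random"
    with_replacement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError(
                f"bootstrap_fraction must be in (0, 1], got {self.bootstrap_fraction}"
            )
        if self.class_subset_rule not in ("random", "all"):
            raise ValueError(
                f"class_subset_rule must be 'random' or 'all', "
                f"got {self.class_subset_rule!r}"
            )


@dataclass
class FeaturePartition:
    """Disjoint covering split of feature indices {0..n-1} into K subsets."""

    subsets: list[np.ndarray]
    n_features: int

    def __post_init__(self) -> None:
        self.subsets = [np.asarray(s, dtype=int) for s in self.subsets]
        flat = np.concatenate(self.subsets) if self.subsets else np.array([], int)
        if len(flat) != self.n_features or len(set(flat.tolist())) != self.n_features:
            raise ValueError("subsets must disjointly cover all features")
        lo = self.n_features // len(self.subsets)
        if any(len(s) not in (lo, lo + 1) for s in self.subsets):
            raise ValueError("subset sizes must differ by at most one")


@dataclass
class RotationMatrix:
    """Sparse block rotation: per-subset PCA loadings in original feature order.

    ``matrix`` is n x n with exactly one nonzero block per feature subset
    (rows and columns at the subset's own indices); each block's columns
    are orthonormal PCA loadings fitted on a class-subset bootstrap sample.
    """

    matrix: np.ndarray
    blocks: list[np.ndarray]
    partition: FeaturePartition

    def __post_init__(self) -> None:
        n = self.partition.n_features
        if self.matrix.shape != (n, n):
            raise ValueError(f"rotation must be {n}x{n}, got {self.matrix.shape}")
        for s, block in zip(self.partition.subsets, self.blocks):
            gram = block.T @ block
            if np.max(np.abs(gram - np.eye(len(s)))) > _ORTHO_TOL:
                raise ValueError("rotation block columns are not orthonormal")
        mask = np.zeros((n, n), dtype=bool)
        for s in self.partition.subsets:
            mask[np.ix_(s, s)] = True
        if np.any(self.matrix[~mask] != 0.0):
            raise ValueError("rotation has nonzero entries outside its blocks")


@dataclass
class RotationForestModel:
    """L fitted (partition, rotation, tree) triples plus leaf statistics."""

    trees: list[DecisionTreeClassifier]
    rotations: list[RotationMatrix]
    partitions: list[FeaturePartition]
    classes: np.ndarray
    n_features: int
    config: ForestConfig
    leaf_counts: list[dict[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.trees) == len(self.rotations) == len(self.partitions)):
            raise ValueError("trees, rotations and partitions must align")
        if len(self.trees) < 1:
            raise ValueError("model must contain at least one tree")

    def predict_confidence(self, X: np.ndarray) -> np.ndarray:
        return predict_confidence(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def make_partition(n: int, K: int, rng: np.random.Generator) -> FeaturePartition:
    """Uniformly random disjoint covering partition of n features into K subsets.

    Sizes are as equal as possible: the n mod K remainder features are
    spread one per subset.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of features n={n}")
    perm = rng.permutation(n)
    base, extra = divmod(n, K)
    subsets, start = [], 0
    for j in range(K):
        size = base + (1 if j < extra else 0)
        subsets.append(np.sort(perm[start : start + size]))
        start += size
    return FeaturePartition(subsets, n_features=n)


def _pca_loadings(X: np.ndarray) -> np.ndarray:
    """All-component PCA loading matrix (columns = eigenvectors of the
    column-centered covariance, descending eigenvalue, first nonzero
    coordinate of each column positive)."""
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / max(len(X) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    loadings = eigvecs[:, order]
    for k in range(loadings.shape[1]):
        nz = np.nonzero(np.abs(loadings[:, k]) > 1e-12)[0]
        if nz.size and loadings[nz[0], k] < 0:
            loadings[:, k] = -loadings[:, k]
    return loadings


def build_rotation(
    X: np.ndarray,
    y: np.ndarray,
    partition: FeaturePartition,
    bootstrap_fraction: float,
    rng: np.random.Generator,
    class_subset_rule: str = "random",
    with_replacement: bool = True,
) -> RotationMatrix:
    """Build one sparse block rotation matrix from a training set.

    Per feature subset: select a random non-empty class subset, bootstrap a
    fraction of those classes' samples, run all-component PCA on the sample
    restricted to the subset's columns, and place the loading block at the
    subset's row/column indices. If a class selection yields fewer than two
    samples it is retried a bounded number of times, then falls back to the
    full training set (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 2:
        raise ValueError("need at least 2 samples to build a rotation")
    classes = np.unique(y)
    n = partition.n_features

    matrix = np.zeros((n, n))
    blocks: list[np.ndarray] = []
    for s in partition.subsets:
        pool = None
        if class_subset_rule == "all":
            pool = np.arange(len(X))
        else:
            for _ in range(_CLASS_RETRY):
                keep = classes[rng.random(len(classes)) < 0.5]
                if keep.size == 0:
                    continue
                cand = np.nonzero(np.isin(y, keep))[0]
                if len(cand) >= 2:
                    pool = cand
                    break
            if pool is None:
                logger.warning(
                    "class-subset sampling produced <2 samples after %d tries; "
                    "falling back to the full training set",
                    _CLASS_RETRY,
                )
                pool = np.arange(len(X))
        size = max(2, int(round(bootstrap_fraction * len(pool))))
        if with_replacement:
            take = rng.choice(pool, size=size, replace=True)
        else:
            size = min(size, len(pool))
            take = rng.choice(pool, size=size, replace=False)
        block = _pca_loadings(X[np.ix_(take, s)])
        matrix[np.ix_(s, s)] = block
        blocks.append(block)

    return RotationMatrix(matrix=matrix, blocks=blocks, partition=partition)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 20,
    L: int = 2,
    bootstrap_fraction: float = 0.75,
    seed: int = 0,
    class_subset_rule: str = "random",
    with_replacement: bool = True,
) -> RotationForestModel:
    """Fit a Rotation Forest: L independent (partition, rotation, tree) triples.

    Fully deterministic for a given seed. Requires both classes present and
    n >= K features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if len(X) < 4:
        raise ValueError(f"need at least 4 training samples, got {len(X)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    n = X.shape[1]
    if n < K:
        raise ValueError(
            f"K={K} exceeds n_features={n}; choose K <= {n}"
        )
    config = ForestConfig(
        K=K,
        L=L,
        bootstrap_fraction=bootstrap_fraction,
        class_subset_rule=class_subset_rule,
        with_replacement=with_replacement,
        seed=seed,
    )

    root = np.random.default_rng(seed)
    trees, rotations, partitions, leaf_counts = [], [], [], []
    for i in range(L):
        rng = np.random.default_rng(root.integers(2**31))
        partition = make_partition(n, K, rng)
        rotation = build_rotation(
            X,
            y,
            partition,
            bootstrap_fraction,
            rng,
            class_subset_rule=class_subset_rule,
            with_replacement=with_replacement,
        )
        Xr = X @ rotation.matrix
        tree = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(2**31))
        )
        tree.fit(Xr, y)
        # leaf -> per-class training counts, for Laplace-smoothed confidences
        leaves = tree.apply(Xr)
        counts: dict[int, np.ndarray] = {}
        for leaf, label in zip(leaves, y):
            if leaf not in counts:
                counts[leaf] = np.zeros(classes.size)
            counts[leaf][np.searchsorted(classes, label)] += 1
        trees.append(tree)
        rotations.append(rotation)
        partitions.append(partition)
        leaf_counts.append(counts)

    return RotationForestModel(
        trees=trees,
        rotations=rotations,
        partitions=partitions,
        classes=classes,
        n_features=n,
        config=config,
        leaf_counts=leaf_counts,
    )


def predict_confidence(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Average-combination class confidences, one row per sample.

    Each tree scores its own rotated input; per-tree class probabilities
    are Laplace-smoothed leaf frequencies, and the ensemble confidence is
    their unweighted mean (rows sum to 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, "
            f"got shape {X.shape}"
        )
    total = np.zeros((len(X), model.classes.size))
    for tree, rotation, counts in zip(
        model.trees, model.rotations, model.leaf_counts
    ):
        leaves = tree.apply(X @ rotation.matrix)
        probs = np.empty((len(X), model.classes.size))
        for row, leaf in enumerate(leaves):
            c = counts[leaf]
            probs[row] = (c + 1.0) / (c.sum() + model.classes.size)
        total += probs
    return total / len(model.trees)


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Labels by argmax of the confidence vector; ties go to the lowest
    class index."""
    lam = predict_confidence(model, X)
    return model.classes[np.argmax(lam, axis=1)]


def save_model(model: RotationForestModel, path: str | Path) -> None:
    """Serialize the fitted model to a single version-stamped archive."""
    payload = {
        "format_version": SERIALIZATION_VERSION,
        "n_features": model.n_features,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(
    path: str | Path, expected_n_features: int | None = None
) -> RotationForestModel:
    """Load a serialized model; rejects version or feature-count mismatches."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != SERIALIZATION_VERSION:
        raise ValueError(
            f"unsupported model archive version {payload.get('format_version')!r}"
        )
    if (
        expected_n_features is not None
        and payload["n_features"] != expected_n_features
    ):
        raise ValueError(
            f"model was fitted on {payload['n_features']} features, "
            f"expected {expected_n_features}"
        )
    return payload["model"]
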