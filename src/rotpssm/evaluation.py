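"""Metrics and cross-validation protocols for pair classification.

Implements the standard binary-classification metric suite over a
confusion table (accuracy, sensitivity, precision, Matthews correlation
coefficient), ROC curves with trapezoidal AUC, a stratified five-fold
cross-validation driver for the full PSSM -> 2DPCA -> Rotation Forest
pipeline, and a train-on-one-species / test-on-another protocol.

Within each CV fold the 2DPCA basis is fitted on the training-fold
proteins only; the test fold never influences the projection axes. This is
the leakage-free reading of the protocol — the alternative (fitting the
descriptor basis on all data) silently inflates test metrics.

Aggregates are reported as mean +/- sample (n-1) standard deviation over
folds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .pssm_io import PairDataset
from .twodpca import (
    TwoDPCAConfig,
    ProjectionBasis,
    fit_2dpca,
    pair_feature,
    project,
    pssm_to_fixed,
)
from . import rotation_forest as rf

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvaluationReport",
    "PipelineConfig",
    "confusion",
    "metrics",
    "roc_auc",
    "featurize",
    "fit_fold_basis",
    "five_fold_cv",
    "cross_species_eval",
]

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with positive class = interacting (label 1)."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class PipelineConfig:
    """End-to-end settings: descriptor extraction + ensemble + protocol."""

    twodpca: TwoDPCAConfig = field(default_factory=TwoDPCAConfig)
    K: int = 20
    L: int = 2
    bootstrap_fraction: float = 0.75
    class_subset_rule: str = "random"
    with_replacement: bool = True
    folds: int = 5
    pooled_roc: bool = False

    def forest_kwargs(self) -> dict:
        return dict(
            K=self.K,
            L=self.L,
            bootstrap_fraction=self.bootstrap_fraction,
            class_subset_rule=self.class_subset_rule,
            with_replacement=self.with_replacement,
        )


@dataclass
class FoldResult:
    """Metrics of one evaluated split.

    Metrics are stored as fractions (accuracy 0.974, not 97.4); the text
    report renders percentages. ``unavailable`` names metrics that cannot
    be computed on the split (e.g. precision/MCC/AUC when the test set is
    single-class) and are stored as NaN.
    """

    fold_index: int
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    precision: float
    mcc: float
    auc: float
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    unavailable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # consistency re-check only
            accu, sen, prec, mcc = metrics(self.counts)
        for name, stored, derived in (
            ("accuracy", self.accuracy, accu),
            ("sensitivity", self.sensitivity, sen),
            ("precision", self.precision, prec),
            ("mcc", self.mcc, mcc),
        ):
            if name in self.unavailable:
                continue
            if math.isnan(derived) and math.isnan(stored):
                continue
            if abs(stored - derived) > 1e-12:
                raise ValueError(
                    f"{name}={stored} inconsistent with confusion counts "
                    f"(derived {derived})"
                )

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class EvaluationReport:
    """Per-fold results plus mean +/- sample standard deviation."""

    folds: list[FoldResult]
    means: dict[str, float]
    stds: dict[str, float]
    config: PipelineConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": asdict(self.config),
            "folds": [
                {
                    "fold": f.fold_index,
                    "counts": asdict(f.counts),
                    **{m: f.metric(m) for m in METRIC_NAMES},
                    "unavailable": list(f.unavailable),
                }
                for f in self.folds
            ],
            "means": self.means,
            "stds": self.stds,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def to_text(self) -> str:
        """Aligned table: one row per test fold, then 'Average x +/- s'."""
        header = (
            f"{'Testing set':<12}"
            + "".join(f"{m:>12}" for m in ("Accu.(%)", "Sen.(%)", "Prec.(%)",
                                           "MCC(%)", "AUC(%)"))
        )
        lines = [header]
        for f in self.folds:
            cells = "".join(
                f"{100 * f.metric(m):>12.2f}" if not math.isnan(f.metric(m))
                else f"{'n/a':>12}"
                for m in METRIC_NAMES
            )
            lines.append(f"{f.fold_index:<12}{cells}")
        avg = "".join(
            f"{100 * self.means[m]:>6.2f}±{100 * self.stds[m]:<5.2f}"
            if not math.isnan(self.means[m]) else f"{'n/a':>12}"
            for m in METRIC_NAMES
        )
        lines.append(f"{'Average':<12}{avg}")
        return "\n".join(lines)


def confusion(predicted, actual) -> ConfusionCounts:
    """Count TP/FP/TN/FN with positive class 1."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {actual.shape}"
        )
    bad = set(np.unique(predicted)) | set(np.unique(actual))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(bad)}")
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1) & (actual == 1))),
        FP=int(np.sum((predicted == 1) & (actual == 0))),
        TN=int(np.sum((predicted == 0) & (actual == 0))),
        FN=int(np.sum((predicted == 0) & (actual == 1))),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, precision, MCC) from a confusion table.

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    sensitivity = TP / (TP+FN)
    precision   = TP / (TP+FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    Conventions: MCC is 0 when any denominator factor is zero (the
    standard limit); precision is NaN when no positive predictions exist
    (TP+FP = 0) and is excluded from aggregation with a warning; similarly
    sensitivity is NaN when the split has no positives.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / counts.total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn(
            "no positive predictions: precision undefined (NaN)", stacklevel=2
        )
        precision = float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return accuracy, sensitivity, precision, mcc


def roc_auc(scores, actual) -> tuple[float, np.ndarray]:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule.

    The sweep lowers the decision threshold through the unique scores,
    emitting one (FPR, TPR) point per threshold; tied scores move the
    curve diagonally, so the trapezoidal area equals the tie-corrected
    two-sample rank statistic P(score+ > score-) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if scores.shape != actual.shape:
        raise ValueError("scores and labels must have equal length")
    pos = int(np.sum(actual == 1))
    neg = int(np.sum(actual == 0))
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = actual[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]  # end of each tie group
    tpr = np.r_[0.0, tp[last] / pos]
    fpr = np.r_[0.0, fp[last] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def fit_fold_basis(
    dataset: PairDataset, config: TwoDPCAConfig
) -> ProjectionBasis:
    """Fit the 2DPCA basis from the proteins a dataset's pairs reference."""
    mats = [
        pssm_to_fixed(dataset.pssm_lookup[i], config)
        for i in dataset.protein_ids()
    ]
    return fit_2dpca(mats, d=config.d, config=config)


def featurize(dataset: PairDataset, basis: ProjectionBasis) -> np.ndarray:
    """Pair feature matrix: one row [f_A || f_B] per pair, in pair order."""
    cache = {
        i: project(pssm_to_fixed(dataset.pssm_lookup[i], basis.config), basis)
        for i in dataset.protein_ids()
    }
    return np.stack(
        [pair_feature(cache[a], cache[b]).values for a, b, _ in dataset.pairs]
    )


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded shuffle then per-label round-robin; fold sizes per class
    differ by at most one."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _evaluate_split(
    train: PairDataset,
    test: PairDataset,
    config: PipelineConfig,
    seed: int,
    fold_index: int,
) -> FoldResult:
    basis = fit_fold_basis(train, config.twodpca)
    X_train = featurize(train, basis)
    X_test = featurize(test, basis)
    model = rf.fit(X_train, train.labels, seed=seed, **config.forest_kwargs())
    lam = rf.predict_confidence(model, X_test)
    pos_col = int(np.searchsorted(model.classes, 1))
    scores = lam[:, pos_col]
    predicted = model.classes[np.argmax(lam, axis=1)]
    actual = test.labels

    counts = confusion(predicted, actual)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        accu, sen, prec, mcc = metrics(counts)
    unavailable: list[str] = []
    if len(np.unique(actual)) < 2:
        # single-class test set: only the correct-classification rate is
        # meaningful; on an all-positive set it coincides with sensitivity
        unavailable = ["precision", "mcc", "auc"]
        if np.all(actual == 1):
            prec = float("nan")
            mcc = float("nan")
        auc = float("nan")
        roc_points = np.empty((0, 2))
    else:
        auc, roc_points = roc_auc(scores, actual)
        if math.isnan(prec):
            unavailable = ["precision"]
    return FoldResult(
        fold_index=fold_index,
        counts=counts,
        accuracy=accu,
        sensitivity=sen,
        precision=prec,
        mcc=mcc,
        auc=auc,
        scores=scores,
        roc_points=roc_points,
        unavailable=tuple(unavailable),
    )


def _aggregate(
    folds: list[FoldResult], config: PipelineConfig, seed: int
) -> EvaluationReport:
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = np.array([f.metric(m) for f in folds], dtype=float)
        if np.any(np.isnan(vals)):
            warnings.warn(
                f"metric {m!r} undefined on {int(np.isnan(vals).sum())} "
                "fold(s); excluded from the average",
                stacklevel=3,
            )
        ok = vals[~np.isnan(vals)]
        means[m] = float(ok.mean()) if ok.size else float("nan")
        stds[m] = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return EvaluationReport(
        folds=folds, means=means, stds=stds, config=config, seed=seed
    )


def five_fold_cv(
    dataset: PairDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full pipeline (default k=5).

    Pairs are shuffled (seeded) and dealt round-robin per label so every
    fold holds interacting and non-interacting pairs in near-equal
    proportion. Each fold's 2DPCA basis and Rotation Forest are fitted on
    the other folds' pairs only.
    """
    config = config or PipelineConfig()
    labels = dataset.labels
    if len(dataset) < 10:
        raise ValueError(f"need at least 10 pairs, got {len(dataset)}")
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both labels")
    n_folds = config.folds
    min_class = min(np.sum(labels == 0), np.sum(labels == 1))
    if min_class < n_folds:
        raise ValueError(
            f"only {min_class} pairs in the rarer class; use at most "
            f"{min_class} folds (got {n_folds})"
        )
    rng = np.random.default_rng(seed)
    folds_idx = _stratified_folds(labels, n_folds, rng)
    all_idx = np.arange(len(dataset))
    results = []
    for f, test_idx in enumerate(folds_idx):
        train_idx = np.setdiff1d(all_idx, test_idx)
        results.append(
            _evaluate_split(
                dataset.subset(train_idx),
                dataset.subset(test_idx),
                config,
                seed=seed + 1000 * (f + 1),
                fold_index=f + 1,
            )
        )
    return _aggregate(results, config, seed)


def cross_species_eval(
    train: PairDataset,
    test: PairDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> FoldResult:
    """Train on one dataset, evaluate once on an independent one.

    Basis and model are fitted on ``train`` only; the protein universes
    may be disjoint. When the test set carries a single label (the usual
    shape of independent interaction sets, all-positive), only the
    correct-classification rate is reported and precision/MCC/AUC are
    flagged unavailable.
    """
    config = config or PipelineConfig()
    if len(test) == 0:
        raise ValueError("empty test dataset")
    return _evaluate_split(train, test, config, seed=seed, fold_index=1)
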