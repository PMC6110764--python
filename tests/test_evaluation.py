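"""Metrics, ROC/AUC, cross-validation and cross-species protocols."""

import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from rotpssm import (
    ConfusionCounts,
    PipelineConfig,
    SyntheticConfig,
    TwoDPCAConfig,
    confusion,
    cross_species_eval,
    five_fold_cv,
    generate_dataset,
    generate_pairs,
    generate_proteins,
    metrics,
    roc_auc,
)
from rotpssm.evaluation import _stratified_folds, fit_fold_basis

getcontext().prec = 60


def metrics_oracle(tp, fp, tn, fn):
    """Longhand metric formulas in exact rational / high-precision
    arithmetic, independent of the float implementation."""
    total = tp + fp + tn + fn
    accu = Fraction(tp + tn, total)
    sen = Fraction(tp, tp + fn) if tp + fn else None
    prec = Fraction(tp, tp + fp) if tp + fp else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den:
        mcc = Decimal(tp * tn - fp * fn) / Decimal(den).sqrt()
    else:
        mcc = Decimal(0)
    return accu, sen, prec, mcc


def auc_u_oracle(scores, labels):
    """Tie-corrected two-sample U statistic: concordant pairs + half
    ties over P*N, by explicit double loop."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = 0.0
    for p in pos:
        for n in neg:
            num += 1.0 if p > n else (0.5 if p == n else 0.0)
    return num / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_complement(self):
        c = confusion([0, 0, 1, 1], [1, 1, 0, 0])
        assert (c.TP, c.TN) == (0, 0)
        assert (c.FP, c.FN) == (2, 2)

    def test_matches_counting_loop_oracle(self, rng):
        pred = rng.integers(0, 2, 100)
        act = rng.integers(0, 2, 100)
        c = confusion(pred, act)
        tp = fp = tn = fn = 0
        for p, a in zip(pred, act):
            if p == 1 and a == 1:
                tp += 1
            elif p == 1 and a == 0:
                fp += 1
            elif p == 0 and a == 0:
                tn += 1
            else:
                fn += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
        assert c.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0, 1.0)

    def test_coin_flip_symmetry(self):
        accu, sen, prec, mcc = metrics(ConfusionCounts(25, 25, 25, 25))
        assert accu == 0.5
        assert mcc == 0.0

    def test_against_exact_arithmetic_oracle(self):
        accu, sen, prec, mcc = metrics(ConfusionCounts(94, 0, 100, 6))
        o_accu, o_sen, o_prec, o_mcc = metrics_oracle(94, 0, 100, 6)
        assert abs(accu - float(o_accu)) < 1e-12
        assert abs(sen - float(o_sen)) < 1e-12
        assert abs(prec - float(o_prec)) < 1e-12
        assert abs(mcc - float(o_mcc)) < 1e-12

    def test_random_tables_against_oracle(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(tp, fp, tn, fn)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    accu, sen, prec, mcc = metrics(c)
            o_accu, o_sen, o_prec, o_mcc = metrics_oracle(tp, fp, tn, fn)
            assert abs(accu - float(o_accu)) < 1e-12
            if o_sen is None:
                assert math.isnan(sen)
            else:
                assert abs(sen - float(o_sen)) < 1e-12
            if o_prec is None:
                assert math.isnan(prec)
            else:
                assert abs(prec - float(o_prec)) < 1e-12
            assert abs(mcc - float(o_mcc)) < 1e-12

    def test_zero_denominator_mcc_is_zero(self):
        _, _, _, mcc = metrics(ConfusionCounts(10, 0, 0, 5))
        assert mcc == 0.0

    def test_no_positive_predictions_warns_nan_precision(self):
        with pytest.warns(UserWarning, match="precision"):
            _, _, prec, _ = metrics(ConfusionCounts(0, 0, 5, 5))
        assert math.isnan(prec)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert abs(auc - 0.5) < 1e-12

    def test_matches_u_statistic_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=20)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert abs(auc - auc_u_oracle(scores, labels)) < 1e-10

    def test_matches_sklearn(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - roc_auc_score(labels, scores)) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 60))
    def test_u_statistic_equivalence_property(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1  # both classes present
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - auc_u_oracle(scores, labels)) < 1e-10


FAST = PipelineConfig(twodpca=TwoDPCAConfig(d=5), K=5, L=2)


class TestFiveFoldCV:
    def test_stratified_fold_sizes(self, rng):
        labels = np.r_[np.ones(23, int), np.zeros(19, int)]
        folds = _stratified_folds(labels, 5, rng)
        for label in (0, 1):
            sizes = [int(np.sum(labels[f] == label)) for f in folds]
            assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(42))

    def test_report_aggregation_identity(self, small_dataset):
        report = five_fold_cv(small_dataset, FAST, seed=3)
        assert len(report.folds) == 5
        for m in ("accuracy", "sensitivity", "precision", "mcc", "auc"):
            vals = [f.metric(m) for f in report.folds]
            assert abs(report.means[m] - np.mean(vals)) < 1e-12
            assert abs(report.stds[m] - np.std(vals, ddof=1)) < 1e-12

    def test_separable_dataset_high_accuracy(self, small_dataset):
        report = five_fold_cv(small_dataset, FAST, seed=3)
        assert report.means["accuracy"] >= 0.95

    def test_fold_metrics_consistent_with_counts(self, small_dataset):
        report = five_fold_cv(small_dataset, FAST, seed=5)
        for f in report.folds:
            accu, sen, prec, mcc = metrics(f.counts)
            assert f.accuracy == accu
            assert f.sensitivity == sen
            assert f.mcc == mcc

    def test_too_few_pairs_rejected(self, small_dataset):
        tiny = small_dataset.subset(range(8))
        with pytest.raises(ValueError, match="at least 10"):
            five_fold_cv(tiny, FAST, seed=0)

    def test_too_few_per_class_suggests_fewer_folds(self, small_dataset):
        # 40 pairs per class cannot be split into 50 stratified folds
        cfg = PipelineConfig(twodpca=TwoDPCAConfig(d=5), K=5, L=2, folds=50)
        with pytest.raises(ValueError, match="folds"):
            five_fold_cv(small_dataset, cfg, seed=0)

    def test_basis_independent_of_test_fold(self, small_dataset):
        """The training-fold basis is identical whether or not the test-fold
        proteins are present in the lookup at all (no leakage)."""
        labels = small_dataset.labels
        rng = np.random.default_rng(1)
        folds = _stratified_folds(labels, 5, rng)
        from rotpssm import PairDataset

        train_idx = np.setdiff1d(np.arange(len(small_dataset)), folds[0])
        # same training pairs, but the lookup still contains every protein
        # in the study including the held-out fold's
        train_full_lookup = PairDataset(
            [small_dataset.pairs[i] for i in train_idx],
            small_dataset.pssm_lookup,
        )
        basis_full_lookup = fit_fold_basis(train_full_lookup, TwoDPCAConfig(d=5))
        # versus a lookup stripped to the training pairs' own proteins
        stripped = small_dataset.subset(train_idx)
        basis_stripped = fit_fold_basis(stripped, TwoDPCAConfig(d=5))
        assert np.array_equal(basis_full_lookup.axes, basis_stripped.axes)
        assert np.array_equal(
            basis_full_lookup.mean_matrix, basis_stripped.mean_matrix
        )

    def test_label_permutation_null(self):
        """With labels shuffled the pipeline has no signal: mean CV accuracy
        over 10 seeds stays near chance."""
        accs = []
        for seed in range(10):
            config = SyntheticConfig(
                n_proteins=40,
                n_pairs_per_class=30,
                length_range=(30, 50),
                separation=3.0,
                seed=seed,
            )
            proteins = generate_proteins(config)
            ds = generate_pairs(proteins, config)
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation([l for _, _, l in ds.pairs])
            ds.pairs = [
                (a, b, int(l)) for (a, b, _), l in zip(ds.pairs, shuffled)
            ]
            report = five_fold_cv(ds, FAST, seed=seed)
            accs.append(report.means["accuracy"])
        assert 0.4 <= np.mean(accs) <= 0.6


class TestCrossSpecies:
    def test_resubstitution_sanity(self, small_dataset):
        res = cross_species_eval(small_dataset, small_dataset, FAST, seed=2)
        assert res.accuracy >= 0.95

    def test_all_positive_test_reports_accuracy_only(self, small_dataset):
        pos_idx = [
            i for i, (_, _, l) in enumerate(small_dataset.pairs) if l == 1
        ]
        test = small_dataset.subset(pos_idx)
        res = cross_species_eval(small_dataset, test, FAST, seed=2)
        assert set(res.unavailable) == {"precision", "mcc", "auc"}
        assert math.isnan(res.mcc) and math.isnan(res.auc)
        c = res.counts
        assert res.accuracy == c.TP / (c.TP + c.FN)
        assert res.accuracy == res.sensitivity

    def test_transfer_between_disjoint_species(self):
        """Two disjoint protein universes drawn from the same generative
        parameters: training on one transfers to the other well above
        chance."""
        accs = []
        for seed in range(10):
            base = dict(
                n_proteins=60,
                n_pairs_per_class=150,
                length_range=(30, 50),
                separation=3.0,
            )
            train = generate_dataset(
                SyntheticConfig(seed=seed, center_seed=seed, **base)
            )
            test = generate_dataset(
                SyntheticConfig(
                    seed=seed + 500, center_seed=seed, id_prefix="Q", **base
                )
            )
            res = cross_species_eval(train, test, FAST, seed=seed)
            accs.append(res.accuracy)
        assert np.mean(accs) >= 0.7

    def test_empty_test_rejected(self, small_dataset):
        empty = small_dataset.subset([])
        with pytest.raises(ValueError, match="empty|at least"):
            cross_species_eval(small_dataset, empty, FAST, seed=0)


class TestReportOutput:
    def test_json_round_trip(self, tmp_path, small_dataset):
        import json

        report = five_fold_cv(small_dataset, FAST, seed=3)
        path = tmp_path / "report.json"
        report.to_json(path)
        data = json.loads(path.read_text())
        assert len(data["folds"]) == 5
        assert data["means"]["accuracy"] == report.means["accuracy"]

    def test_text_table_shape(self, small_dataset):
        report = five_fold_cv(small_dataset, FAST, seed=3)
        text = report.to_text()
        lines = text.splitlines()
        assert len(lines) == 7  # header + 5 folds + average
        assert lines[-1].startswith("Average")
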