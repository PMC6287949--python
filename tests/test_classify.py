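"""Fold assignment, leakage-avoiding splits, undersampling, AUC, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosimpred.annotations import compute_ic, propagate_annotations
from gosimpred.classify import (
    ClassifierConfig,
    LabeledGeneSet,
    compute_auc,
    evaluate_cv,
    predict_candidates,
    split_matrix,
    stratified_folds,
    train_classifier,
    undersample,
)
from gosimpred.semsim import GeneSimilarityMatrix, build_matrix

from oracles import auc_by_concordance


def make_labels(n_pos, n_neg, n_ld=0):
    classes = {}
    for i in range(n_pos):
        classes[f"p{i:03d}"] = "LD" if i < n_ld else "HD"
    for i in range(n_neg):
        classes[f"n{i:03d}"] = "negative"
    return LabeledGeneSet(classes)


def toy_matrix(labels, seed=0, signal=1.0):
    """A block-structured similarity matrix with tunable class signal."""
    rng = np.random.default_rng(seed)
    genes = labels.genes
    y = labels.binary_array(genes)
    base = rng.uniform(0.05, 0.25, size=(len(genes), len(genes)))
    boost = signal * 0.5 * (y[:, None] == y[None, :])
    values = np.clip((base + base.T) / 2 + boost, 0, 1)
    np.fill_diagonal(values, 1.0)
    return GeneSimilarityMatrix(genes=genes, values=values,
                                measure="resnik", combine="max")


class TestStratifiedFolds:
    def test_exact_divisibility_gives_equal_fold_composition(self):
        labels = make_labels(10, 40)
        folds = stratified_folds(labels, k=5, seed=3)
        for fold in range(1, 6):
            test = folds.test_genes(fold)
            assert sum(labels.binary(g) == 1 for g in test) == 2
            assert sum(labels.binary(g) == -1 for g in test) == 8

    def test_same_seed_gives_identical_assignment(self):
        labels = make_labels(13, 37)
        a = stratified_folds(labels, k=5, seed=11)
        b = stratified_folds(labels, k=5, seed=11)
        assert a.fold_of == b.fold_of

    def test_remainder_spreads_by_at_most_one(self):
        labels = make_labels(11, 40)
        folds = stratified_folds(labels, k=5, seed=1)
        counts = [
            sum(labels.binary(g) == 1 for g in folds.test_genes(f))
            for f in range(1, 6)
        ]
        assert set(counts) <= {2, 3} and sum(counts) == 11

    def test_class_smaller_than_k_errors_naming_it(self):
        labels = make_labels(3, 40)
        with pytest.raises(ValueError, match="positive"):
            stratified_folds(labels, k=5, seed=0)


class TestSplitMatrix:
    def test_five_gene_worked_example(self):
        """Testing g4,g5 must reduce training to the 3x3 block over g1..g3."""
        labels = LabeledGeneSet({f"g{i}": "HD" if i < 3 else "negative"
                                 for i in range(1, 6)})
        genes = [f"g{i}" for i in range(1, 6)]
        values = np.arange(25, dtype=float).reshape(5, 5)
        values = (values + values.T) / 48  # symmetric, in [0, 1]
        matrix = GeneSimilarityMatrix(genes=genes, values=values,
                                      measure="resnik", combine="max")
        folds = type("F", (), {})()
        from gosimpred.classify import FoldAssignment
        folds = FoldAssignment(k=2, seed=0, fold_of={
            "g1": 1, "g2": 1, "g3": 1, "g4": 2, "g5": 2,
        })
        split = split_matrix(matrix, folds, test_fold=2)
        assert split.train_genes == ["g1", "g2", "g3"]
        assert split.test_genes == ["g4", "g5"]
        assert split.x_train.shape == (3, 3)
        assert split.x_test.shape == (2, 3)
        np.testing.assert_array_equal(split.x_train, values[:3, :3])
        np.testing.assert_array_equal(split.x_test, values[3:, :3])
        assert not set(split.test_genes) & set(split.train_genes)

    def test_every_split_has_train_count_features(self):
        labels = make_labels(10, 40)
        matrix = toy_matrix(labels)
        folds = stratified_folds(labels, k=5, seed=2)
        for fold in range(1, 6):
            split = split_matrix(matrix, folds, fold)
            assert split.x_train.shape == (40, 40)
            assert split.x_test.shape == (10, 40)
            assert not set(split.test_genes) & set(split.train_genes)

    def test_mismatched_gene_sets_error(self):
        labels = make_labels(5, 5)
        matrix = toy_matrix(labels)
        folds = stratified_folds(make_labels(5, 6), k=2, seed=0)
        with pytest.raises(ValueError, match="cover"):
            split_matrix(matrix, folds, 1)


class TestUndersample:
    def test_perc30_yields_thirty_percent_positives(self):
        labels = make_labels(120, 900)
        subset = undersample(labels.genes, labels, perc=30, seed=4)
        pos = sum(labels.binary(g) == 1 for g in subset)
        neg = sum(labels.binary(g) == -1 for g in subset)
        assert (pos, neg) == (120, 280)

    def test_insufficient_negatives_are_all_kept(self):
        labels = make_labels(50, 60)
        subset = undersample(labels.genes, labels, perc=30, seed=4)
        assert sum(labels.binary(g) == -1 for g in subset) == 60
        assert sum(labels.binary(g) == 1 for g in subset) == 50

    def test_deterministic_given_seed(self):
        labels = make_labels(20, 200)
        a = undersample(labels.genes, labels, perc=30, seed=9)
        b = undersample(labels.genes, labels, perc=30, seed=9)
        assert a == b

    def test_no_positives_errors(self):
        labels = make_labels(5, 20)
        negatives = labels.negatives
        with pytest.raises(ValueError, match="no positive"):
            undersample(negatives, labels, perc=30, seed=0)


class TestTrainClassifier:
    def test_rf_defaults_match_configuration(self):
        labels = make_labels(10, 10)
        matrix = toy_matrix(labels)
        fitted = train_classifier(
            ClassifierConfig(method="rf"), matrix.values,
            labels.binary_array(labels.genes), seed=0,
        )
        est = fitted.estimator
        assert est.n_estimators == 500
        assert est.max_features == "sqrt"
        assert est.bootstrap is True

    def test_separable_data_gives_training_auc_one(self):
        labels = make_labels(10, 10)
        y = labels.binary_array(labels.genes)
        x = np.column_stack([y * 0.4 + 0.5, np.linspace(0, 1, 20)])
        fitted = train_classifier(ClassifierConfig(method="rf"), x, y, seed=1)
        assert compute_auc(fitted.score_samples(x), y) == 1.0

    @pytest.mark.parametrize("method", ["nb", "svm_linear", "svm_radial"])
    def test_all_methods_score_higher_for_positives(self, method):
        labels = make_labels(15, 15)
        matrix = toy_matrix(labels, signal=1.0)
        y = labels.binary_array(labels.genes)
        fitted = train_classifier(ClassifierConfig(method=method),
                                  matrix.values, y, seed=2)
        scores = fitted.score_samples(matrix.values)
        assert compute_auc(scores, y) > 0.9

    def test_unknown_method_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="xgboost"):
            ClassifierConfig(method="xgboost")

    def test_single_class_training_errors(self):
        x = np.random.default_rng(0).uniform(size=(6, 6))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(ClassifierConfig(method="rf"), x, [1] * 6)


class TestComputeAuc:
    def test_forced_cases(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0
        assert compute_auc([0.5, 0.5, 0.5, 0.5], [1, 1, -1, -1]) == 0.5
        assert compute_auc([0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1]) == 0.75

    def test_one_class_missing_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_pairwise_concordance_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 13))
        labels = np.array([1, -1] + list(rng.choice([1, -1], size=n - 2)))
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        assert compute_auc(scores, labels) == pytest.approx(
            auc_by_concordance(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn_on_random_input(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        labels = np.array([1] * 20 + [-1] * 30)
        scores = np.round(rng.uniform(size=50), 2)
        assert compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        # a coarse score grid keeps distinct values distinct after transforms
        scores=st.lists(
            st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=4, max_size=20,
        ),
        scale=st.floats(0.1, 4.0),
        shift=st.floats(-3, 3),
    )
    def test_invariant_under_strictly_monotone_transforms(self, scores, scale, shift):
        n = len(scores)
        labels = np.array([1, 1, -1, -1] + [(-1) ** i for i in range(n - 4)])
        base = compute_auc(scores, labels)
        affine = compute_auc(np.array(scores) * scale + shift, labels)
        expo = compute_auc(np.exp(np.array(scores) * 0.5), labels)
        assert affine == pytest.approx(base, abs=1e-12)
        assert expo == pytest.approx(base, abs=1e-9)


class TestEvaluateCv:
    def test_twenty_repeats_five_folds_give_hundred_records(self):
        labels = make_labels(12, 48)
        matrix = toy_matrix(labels)
        result = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                             repeats=20, k=5, undersample_perc=30, seed=6)
        assert len(result.records) == 100
        assert result.mean_auc == pytest.approx(np.mean(result.aucs))

    def test_test_folds_identical_across_repeats(self):
        labels = make_labels(12, 48)
        matrix = toy_matrix(labels)
        result = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                             repeats=3, k=5, undersample_perc=30, seed=6)
        by_fold = {}
        for record in result.records:
            by_fold.setdefault(record.fold, set()).add(tuple(record.test_genes))
        assert all(len(variants) == 1 for variants in by_fold.values())

    def test_feature_columns_equal_training_genes_every_fold(self):
        labels = make_labels(12, 48)
        matrix = toy_matrix(labels)
        result = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                             repeats=2, k=5, seed=1)
        for record in result.records:
            assert set(record.feature_genes) == (
                set(matrix.genes) - set(record.test_genes)
            )

    def test_heldout_restricted_excludes_ld_from_the_metric(self):
        labels = make_labels(30, 30, n_ld=15)
        matrix = toy_matrix(labels)
        strat = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                            scheme="stratified", seed=2)
        heldout = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                              scheme="heldout_restricted", seed=2)
        n_ld_by_fold = {
            r.fold: sum(labels.class_of(g) == "LD" for g in r.test_genes)
            for r in strat.records
        }
        for s_rec, h_rec in zip(strat.records, heldout.records):
            assert h_rec.n_test_evaluable == (
                s_rec.n_test_evaluable - n_ld_by_fold[s_rec.fold]
            )

    def test_schemes_coincide_exactly_without_ld_genes(self):
        labels = make_labels(20, 40)
        matrix = toy_matrix(labels)
        a = evaluate_cv(matrix, labels, ClassifierConfig(method="rf"),
                        scheme="stratified", repeats=2, seed=9)
        b = evaluate_cv(matrix, labels, ClassifierConfig(method="rf"),
                        scheme="heldout_restricted", repeats=2, seed=9)
        assert [r.auc for r in a.records] == [r.auc for r in b.records]

    def test_fold_without_evaluable_class_is_invalid_and_warned(self):
        # one lone HD gene: most held-out folds have no evaluable positive
        labels = make_labels(25, 25, n_ld=24)
        matrix = toy_matrix(labels)
        with pytest.warns(UserWarning, match="lacks a class"):
            result = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                                 scheme="heldout_restricted", seed=3)
        invalid = [r for r in result.records if not r.valid]
        assert len(invalid) == 4  # the lone HD gene sits in exactly one fold
        assert all(r.auc is None for r in invalid)
        assert len(result.aucs) == 1

    def test_undersampling_affects_training_not_test(self):
        labels = make_labels(15, 60)
        matrix = toy_matrix(labels)
        plain = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                            seed=5)
        under = evaluate_cv(matrix, labels, ClassifierConfig(method="nb"),
                            undersample_perc=30, seed=5)
        for a, b in zip(plain.records, under.records):
            assert a.test_genes == b.test_genes


@pytest.fixture(scope="module")
def trained_context(clean_dataset):
    ds = clean_dataset
    graph = ds.ontology.graph
    propagate_annotations(ds.corpus, graph)
    ic = compute_ic(ds.corpus, graph)
    matrix = build_matrix(ds.labels.genes, ds.corpus, graph,
                          measure="resnik", ic=ic)
    fitted = train_classifier(
        ClassifierConfig(method="rf"), matrix.values,
        ds.labels.subset(matrix.genes).binary_array(matrix.genes),
        seed=1, feature_genes=matrix.genes,
    )
    return ds, graph, ic, matrix, fitted


class TestPredictCandidates:
    def test_training_overlap_and_missing_are_excluded_with_reasons(
        self, trained_context
    ):
        ds, graph, ic, matrix, fitted = trained_context
        ds.corpus.register("GHOST")
        candidates = [matrix.genes[0], "GHOST"] + ds.candidates[:4]
        preds, excl = predict_candidates(
            fitted, matrix.genes, candidates, ds.corpus, graph,
            measure="resnik", ic=ic,
        )
        reasons = dict(zip(excl["gene_id"], excl["reason"]))
        assert reasons[matrix.genes[0]] == "overlaps training set"
        assert reasons["GHOST"] == "missing annotations"
        assert len(preds) == 4

    def test_signature_branch_candidates_outrank_the_rest(self, trained_context):
        ds, graph, ic, matrix, fitted = trained_context
        preds, _ = predict_candidates(
            fitted, matrix.genes, ds.candidates, ds.corpus, graph,
            measure="resnik", ic=ic,
        )
        scores = dict(zip(preds["gene_id"], preds["score"]))
        branch_a = [c for c in ds.candidates if ds.candidate_branch[c] == 0]
        branch_b = [c for c in ds.candidates if ds.candidate_branch[c] != 0]
        assert min(scores[c] for c in branch_a) > max(scores[c] for c in branch_b)

    def test_ranking_is_sorted_descending(self, trained_context):
        ds, graph, ic, matrix, fitted = trained_context
        preds, _ = predict_candidates(
            fitted, matrix.genes, ds.candidates, ds.corpus, graph,
            measure="resnik", ic=ic,
        )
        assert list(preds["score"]) == sorted(preds["score"], reverse=True)
        assert list(preds["rank"]) == list(range(1, len(preds) + 1))

    def test_zero_scoreable_candidates_errors(self, trained_context):
        ds, graph, ic, matrix, fitted = trained_context
        with pytest.raises(ValueError, match="no scoreable"):
            predict_candidates(
                fitted, matrix.genes, [matrix.genes[0]], ds.corpus, graph,
                measure="resnik", ic=ic,
            )
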