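"""Monte-Carlo augmentation: apportionment, moments, fidelity, error."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from editsig import (
    RFConfig,
    TREATMENT_CLASSES,
    estimate_prediction_error,
    fit_generator,
    largest_remainder,
    sample_synthetic,
    train_rf,
    validate_synthetic,
)


def _cohort_and_matrix(n_per_class=40, n_features=5, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    classes = ["CTRL", "BD", "SZ", "SA"]
    labels = np.repeat(classes, n_per_class)
    ids = [f"s{i}" for i in range(len(labels))]
    base = rng.normal(-1.5, 0.4, size=(len(labels), n_features))
    if shift:
        for i, cls in enumerate(classes[1:]):
            base[labels == cls, i % n_features] += shift
    matrix = pd.DataFrame(
        1 / (1 + np.exp(-base)), index=ids, columns=[f"b{i}" for i in range(n_features)]
    )
    cohort = pd.DataFrame(
        {
            "diagnosis": labels,
            "sex": np.where(rng.random(len(labels)) < 0.5, "M", "F"),
            "age": 40.0,
        },
        index=ids,
    )
    for t in TREATMENT_CLASSES:
        cohort[t] = rng.integers(0, 2, len(labels))
    return matrix, cohort


class TestLargestRemainder:
    def test_study_weights_hand_oracle(self):
        counts = largest_remainder(np.array([85, 39, 31, 14]) / 169, 500)
        np.testing.assert_array_equal(counts, [252, 115, 92, 41])

    def test_equal_weights_n4(self):
        np.testing.assert_array_equal(largest_remainder([0.25] * 4, 4), [1, 1, 1, 1])

    def test_conserves_n_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.dirichlet(np.ones(5))
            n = int(rng.integers(5, 1000))
            assert largest_remainder(w, n).sum() == n


class TestFitGenerator:
    def test_shrinkage_conditions_singular_covariance(self):
        from editsig.augment import MAX_COND, _shrink

        S = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank-1, infinite condition
        Sg, gamma = _shrink(S)
        w = np.linalg.eigvalsh(Sg)
        assert w.min() > 0 and w.max() / w.min() <= MAX_COND
        # full shrinkage (gamma = 1) is exactly the diagonal
        np.testing.assert_array_equal((1 - 1.0) * S + 1.0 * np.diag(np.diag(S)), np.eye(2))

    def test_seeded_determinism(self):
        matrix, cohort = _cohort_and_matrix(seed=3)
        g1 = fit_generator(matrix, cohort, seed=5)
        g2 = fit_generator(matrix, cohort, seed=5)
        for cls in g1.classes:
            np.testing.assert_array_equal(g1.means[cls], g2.means[cls])
            np.testing.assert_array_equal(g1.covs[cls], g2.covs[cls])

    def test_small_class_rejected(self):
        matrix, cohort = _cohort_and_matrix(seed=4)
        keep = ~((cohort["diagnosis"] == "SA") & (np.arange(len(cohort)) % 40 > 2))
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_generator(matrix[keep], cohort[keep])

    def test_refit_self_consistency(self):
        # refitting on a large synthetic draw recovers class means closely
        matrix, cohort = _cohort_and_matrix(n_per_class=50, seed=5)
        gen = fit_generator(matrix, cohort)
        syn_m, syn_c = sample_synthetic(gen, 5000 * 4, seed=6)
        refit = fit_generator(syn_m, syn_c)
        for cls in gen.classes:
            assert np.abs(refit.means[cls] - gen.means[cls]).max() < 0.05


class TestSampleSynthetic:
    def test_values_in_unit_interval(self):
        matrix, cohort = _cohort_and_matrix(seed=7)
        gen = fit_generator(matrix, cohort)
        syn_m, _ = sample_synthetic(gen, 500, seed=8)
        assert ((syn_m > 0) & (syn_m < 1)).all().all()

    def test_class_counts_follow_weights(self):
        matrix, cohort = _cohort_and_matrix(seed=9)
        # imbalance the cohort to the study's class weights
        gen = fit_generator(matrix, cohort)
        gen.class_weights = pd.Series(
            [85 / 169, 39 / 169, 31 / 169, 14 / 169], index=gen.classes
        )
        _, syn_c = sample_synthetic(gen, 500, seed=10)
        counts = syn_c["diagnosis"].value_counts()
        assert counts[gen.classes[0]] == 252 and counts[gen.classes[3]] == 41

    def test_n_below_classes_rejected(self):
        matrix, cohort = _cohort_and_matrix(seed=11)
        gen = fit_generator(matrix, cohort)
        with pytest.raises(ValueError, match="at least"):
            sample_synthetic(gen, 3, seed=12)


class TestValidateSynthetic:
    def test_identical_tables_zero_deltas(self):
        matrix, cohort = _cohort_and_matrix(seed=13)
        rep = validate_synthetic(
            matrix, cohort["diagnosis"], matrix, cohort["diagnosis"]
        )
        assert (rep["mean_shift"] == 0).all()
        assert (rep["sd_ratio"] == 1).all()
        assert rep["pass"].all()

    def test_generator_samples_pass_at_large_n(self):
        matrix, cohort = _cohort_and_matrix(n_per_class=60, seed=14)
        gen = fit_generator(matrix, cohort)
        syn_m, syn_c = sample_synthetic(gen, 5000, seed=15)
        rep = validate_synthetic(matrix, cohort["diagnosis"], syn_m, syn_c["diagnosis"])
        assert rep["pass"].mean() > 0.95

    def test_planted_mean_shift_fails_exactly_that_cell(self):
        matrix, cohort = _cohort_and_matrix(n_per_class=60, seed=16)
        gen = fit_generator(matrix, cohort)
        syn_m, syn_c = sample_synthetic(gen, 4000, seed=17)
        cls, feat = "BD", "b2"
        mask = (syn_c["diagnosis"] == cls).to_numpy()
        shifted = syn_m.copy()
        shifted.loc[mask, feat] += 2 * matrix.loc[cohort["diagnosis"] == cls, feat].std()
        rep = validate_synthetic(matrix, cohort["diagnosis"], shifted, syn_c["diagnosis"])
        failed = rep[~rep["mean_pass"]]
        assert list(failed["class"]) == [cls] and list(failed["feature"]) == [feat]

    def test_schema_mismatch_rejected(self):
        matrix, cohort = _cohort_and_matrix(seed=18)
        with pytest.raises(ValueError, match="schema"):
            validate_synthetic(
                matrix,
                cohort["diagnosis"],
                matrix.rename(columns={"b0": "x0"}),
                cohort["diagnosis"],
            )


class TestEstimatePredictionError:
    def _model_and_generator(self, shift, seed):
        from editsig import encode_covariates

        matrix, cohort = _cohort_and_matrix(n_per_class=50, shift=shift, seed=seed)
        features = matrix.join(encode_covariates(cohort))
        model = train_rf(
            features, cohort["diagnosis"], RFConfig(ntree=100, mtry_grid=(2,), seed=seed)
        )
        gen = fit_generator(matrix, cohort, seed=seed)
        return model, gen

    def test_report_shape_one_plus_classes(self):
        model, gen = self._model_and_generator(shift=2.0, seed=20)
        syn_m, syn_c = sample_synthetic(gen, 400, seed=21)
        err = estimate_prediction_error(model, syn_m, syn_c)
        assert len(err) == 1 + len(gen.classes)
        assert err.index[0] == "overall"
        assert ((err["ci_low"] <= err["error"]) & (err["error"] <= err["ci_high"])).all()

    def test_noise_generator_error_near_chance(self):
        # a generator whose classes share one law carries no class signal,
        # so the error approaches 1 - max class weight
        model, gen = self._model_and_generator(shift=0.0, seed=22)
        pooled_mean = np.mean([gen.means[c] for c in gen.classes], axis=0)
        pooled_cov = np.mean([gen.covs[c] for c in gen.classes], axis=0)
        for cls in gen.classes:
            gen.means[cls] = pooled_mean
            gen.covs[cls] = pooled_cov
            gen.sex_prevalence[cls] = 0.5
            gen.treatment_prevalence[cls] = dict.fromkeys(
                gen.treatment_prevalence[cls], 0.5
            )
        syn_m, syn_c = sample_synthetic(gen, 800, seed=23)
        err = estimate_prediction_error(model, syn_m, syn_c)
        chance = 1 - gen.class_weights.max()
        assert abs(err.loc["overall", "error"] - chance) < 0.1

    def test_matched_generator_error_tracks_heldout_error(self):
        # synthetic-data error approximates held-out error on matched data
        from editsig import encode_covariates, evaluate_multiclass, predict_votes
        from editsig.rf import predicted_classes, stratified_split

        matrix, cohort = _cohort_and_matrix(n_per_class=80, shift=1.2, seed=24)
        features = matrix.join(encode_covariates(cohort))
        y = cohort["diagnosis"]
        train, test = stratified_split(y, 0.7, seed=24)
        model = train_rf(
            features.loc[train], y.loc[train], RFConfig(ntree=200, mtry_grid=(3,), seed=24)
        )
        votes = predict_votes(model, features.loc[test])
        _, acc, _ = evaluate_multiclass(predicted_classes(votes), y.loc[test])
        gen = fit_generator(matrix.loc[train], cohort.loc[train], seed=24)
        syn_m, syn_c = sample_synthetic(gen, 1000, seed=25)
        err = estimate_prediction_error(model, syn_m, syn_c)
        assert abs(err.loc["overall", "error"] - (1 - acc)) < 0.1
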