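"""PLS models, nested cross-validation, ROC and bootstrap inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import KFold

from neoconn.panel import FeaturePanel, combine_feature_spaces
from neoconn.pls import (PlsModel, PlsNestedCV, binarize_ga, bootstrap_beta_z,
                         equalized_subgroup_comparison, fisher_z_compare,
                         nested_cv, pls_fit, roc_analysis,
                         shuffled_label_control)


def make_panel(x, ga, name="custom"):
    return FeaturePanel.from_array(
        x, ga, [f"s{i}" for i in range(len(ga))],
        [f"{name}:{j}" for j in range(x.shape[1])], name)


def auc_pair_counting(scores, labels):
    """Exhaustive concordant-pair oracle: (concordant + ties/2) / (n1*n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = 0.0
    for p, n in itertools.product(pos, neg):
        num += 1.0 if p > n else (0.5 if p == n else 0.0)
    return num / (len(pos) * len(neg))


class TestPlsModel:
    def test_full_rank_equals_ols(self, rng):
        x = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        m = pls_fit(x, y, k=4)
        xi = np.column_stack([np.ones(12), x])
        beta = np.linalg.lstsq(xi, y, rcond=None)[0]
        assert np.max(np.abs(m.predict(x) - xi @ beta)) < 1e-8

    def test_first_component_direction(self, rng):
        x = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        m = pls_fit(x, y, k=1)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        c = xs.T @ (y - y.mean())
        w = m._pls.x_weights_[:, 0]
        cosine = abs(c @ w) / (np.linalg.norm(c) * np.linalg.norm(w))
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pls_fit(rng.normal(size=(10, 3)), np.ones(10), k=1)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            pls_fit(rng.normal(size=(10, 3)), rng.normal(size=10), k=5)

    def test_component_path_matches_fresh_fits(self, rng):
        x = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        full = pls_fit(x, y, k=5)
        for k in range(1, 6):
            fresh = pls_fit(x, y, k=k)
            assert np.allclose(full.coef_at(k), fresh.beta_per_sd_, atol=1e-10)

    def test_scaling_learned_from_training_only(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = pls_fit(x, y, k=2)
        x_test = rng.normal(size=(5, 5))
        x_test_mod = x_test.copy()
        x_test_mod[0] += 1e6  # extreme artifact in one test row
        p1 = m.predict(x_test)[1:]
        p2 = m.predict(x_test_mod)[1:]
        assert np.array_equal(p1, p2)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.z > 0

    def test_all_equal_scores(self):
        res = roc_analysis([1.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(0.5)

    def test_toy_with_ties_matches_pair_counting(self):
        scores = [1, 2, 3, 2.5]
        labels = [0, 0, 1, 1]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(auc_pair_counting(scores, labels))
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_curve_monotone(self, rng):
        res = roc_analysis(rng.normal(size=40), np.array([0, 1] * 20))
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    scores = rng.integers(0, 5, size=n).astype(float)  # force ties
    res = roc_analysis(scores, labels)
    assert res.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)


class TestBinarize:
    def test_threshold_convention(self):
        assert binarize_ga([31.9, 32.0, 40.0]).tolist() == [0, 1, 1]


class TestNestedCV:
    def make_signal_panel(self, rng, n=40, p=12, noise=1.0):
        ga = rng.uniform(25, 40, size=n)
        w = rng.normal(size=p)
        x = np.outer(ga - ga.mean(), w) + noise * rng.normal(size=(n, p))
        return make_panel(x, ga)

    def test_every_subject_predicted_once_and_k_in_range(self, rng):
        panel = self.make_signal_panel(rng)
        res = nested_cv(panel, k_max=5, seed=0)
        assert np.isfinite(res.oof_predictions).all()
        assert len(res.oof_predictions) == panel.n_subjects
        assert all(1 <= k <= 20 for k in res.per_fold_optimal_k)
        assert len(res.per_fold_optimal_k) == 10
        assert res.performance["df"] == panel.n_subjects - 2
        assert res.r > 0.8  # strong implanted linear signal

    def test_final_k_is_rounded_mean(self, rng):
        panel = self.make_signal_panel(rng)
        res = nested_cv(panel, k_max=4, seed=1)
        expected = int(np.floor(np.mean(res.per_fold_optimal_k) + 0.5))
        assert res.final_k == expected

    def test_too_few_subjects_rejected(self, rng):
        panel = self.make_signal_panel(rng, n=15)
        with pytest.raises(ValueError, match="at least 20"):
            nested_cv(panel)

    def test_classification_mode_outputs_roc(self, rng):
        panel = self.make_signal_panel(rng, n=44)
        res = nested_cv(panel, mode="classification", k_max=3, seed=0)
        assert res.roc is not None
        assert 0 <= res.auc <= 1
        assert res.auc > 0.8

    def test_seeded_determinism(self, rng):
        panel = self.make_signal_panel(rng)
        r1 = nested_cv(panel, k_max=3, seed=5)
        r2 = nested_cv(panel, k_max=3, seed=5)
        assert np.array_equal(r1.oof_predictions, r2.oof_predictions)
        assert r1.per_fold_optimal_k == r2.per_fold_optimal_k

    def test_no_leakage_from_held_out_fold(self, rng):
        # corrupting one held-out subject must not move predictions of the
        # other subjects in its fold (their model never saw the artifact,
        # and scaling comes from training data only)
        panel = self.make_signal_panel(rng, n=30)
        res1 = nested_cv(panel, k_max=3, seed=2)
        folds = list(KFold(10, shuffle=True, random_state=2).split(panel.values))
        target_fold = next(test for _, test in folds if len(test) > 1)
        victim, *others = list(target_fold)
        x2 = panel.x.copy()
        x2.iloc[victim] = 1e6
        panel2 = FeaturePanel(x=x2, ga=panel.ga, metric_name="mod")
        res2 = nested_cv(panel2, k_max=3, seed=2)
        assert np.array_equal(res1.oof_predictions[others],
                              res2.oof_predictions[others])

    def test_estimator_api(self, rng):
        panel = self.make_signal_panel(rng)
        est = PlsNestedCV(k_max=3, random_state=0)
        est.fit(panel.values, panel.ga_values)
        assert est.final_k_ >= 1
        assert est.beta_per_sd_.shape == (panel.n_features,)
        preds = est.predict(panel.values)
        assert preds.shape == (panel.n_subjects,)
        params = est.get_params()
        assert params["outer_folds"] == 10 and params["mode"] == "regression"


class TestBootstrapBetaZ:
    def test_strongest_feature_has_largest_z(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ga = rng.uniform(25, 40, size=40)
            x = np.column_stack([ga + 0.05 * rng.normal(size=40),
                                 *[rng.normal(size=40) for _ in range(9)]])
            z = bootstrap_beta_z(x, ga, k=2, n_boot=500, seed=seed)
            if np.argmax(np.abs(z)) == 0:
                hits += 1
        assert hits == 20

    def test_seeded_repeatability(self, rng):
        x = rng.normal(size=(30, 6))
        ga = rng.uniform(25, 40, size=30)
        z1 = bootstrap_beta_z(x, ga, k=2, n_boot=200, seed=3)
        z2 = bootstrap_beta_z(x, ga, k=2, n_boot=200, seed=3)
        assert np.array_equal(z1, z2)


class TestFisherZCompare:
    def test_equal_correlations(self):
        z, p = fisher_z_compare(0.3, 50, 0.3, 50)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_closed_form_value(self):
        z, _ = fisher_z_compare(0.441, 88, 0.111, 88)
        assert z == pytest.approx(2.361, abs=1e-3)

    def test_antisymmetry(self):
        z1, _ = fisher_z_compare(0.5, 40, 0.2, 60)
        z2, _ = fisher_z_compare(0.2, 60, 0.5, 40)
        assert z1 == pytest.approx(-z2)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.2, 50)


class TestCombineFeatureSpaces:
    def test_default_sizes_concatenate(self, rng):
        ga = rng.uniform(25, 40, size=20)
        a = make_panel(rng.normal(size=(20, 4005)), ga, "rsfc")
        b = make_panel(rng.normal(size=(20, 90)), ga, "falff")
        c = make_panel(rng.normal(size=(20, 90)), ga, "vol")
        combined = combine_feature_spaces(a, b, c)
        assert combined.n_features == 4185

    def test_self_combination_rejected(self, rng):
        ga = rng.uniform(25, 40, size=10)
        a = make_panel(rng.normal(size=(10, 5)), ga, "m")
        with pytest.raises(ValueError, match="duplicated"):
            combine_feature_spaces(a, a)

    def test_single_panel_identity(self, rng):
        ga = rng.uniform(25, 40, size=10)
        a = make_panel(rng.normal(size=(10, 5)), ga, "m")
        assert combine_feature_spaces(a) is a


class TestEqualizedSubgroup:
    def test_equal_sizes_skip_subsampling(self, rng):
        ga = rng.uniform(25, 40, size=30)
        x = np.outer(ga - ga.mean(), rng.normal(size=10)) + rng.normal(size=(30, 10))
        panel = make_panel(x, ga)
        masks = {"a": np.arange(10) < 5, "b": np.arange(10) >= 5}
        cmp = equalized_subgroup_comparison(panel, masks, n_repeats=50, seed=0,
                                            k_max=2)
        assert cmp.n_repeats_used == 1

    def test_signal_group_outperforms_noise_group(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ga = rng.uniform(25, 40, size=30)
            signal = np.outer(ga - ga.mean(), rng.normal(size=5)) + rng.normal(size=(30, 5))
            noise = rng.normal(size=(30, 15))
            panel = make_panel(np.hstack([signal, noise]), ga)
            masks = {"signal": np.arange(20) < 5, "noise": np.arange(20) >= 5}
            cmp = equalized_subgroup_comparison(panel, masks, n_repeats=3,
                                                seed=seed, k_max=2)
            small_perf = (cmp.perf_small if cmp.group_small == "signal"
                          else cmp.perf_large_avg)
            other = (cmp.perf_large_avg if cmp.group_small == "signal"
                     else cmp.perf_small)
            if small_perf > other:
                wins += 1
        assert wins >= 9


def test_shuffled_labels_give_chance_performance(rng):
    # cohort-sized panel: cross-validated null predictions carry a small
    # anti-correlation bias that shrinks with n, so chance level is
    # asserted at the study's sample size
    ga = rng.uniform(25, 40, size=88)
    x = np.outer(ga - ga.mean(), rng.normal(size=8)) + rng.normal(size=(88, 8))
    panel = make_panel(x, ga)
    null_auc = shuffled_label_control(panel, mode="classification",
                                      n_shuffles=20, seed=0, k_max=2)
    assert abs(null_auc.mean() - 0.5) < 0.05
    null_r = shuffled_label_control(panel, mode="regression",
                                    n_shuffles=20, seed=0, k_max=2)
    assert abs(null_r.mean()) < 0.15
    # empirical permutation p-value is computable from the null distribution
    observed = nested_cv(panel, mode="classification", k_max=2, seed=0).auc
    p_emp = (1 + (null_auc >= observed).sum()) / (len(null_auc) + 1)
    assert p_emp < 0.1
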