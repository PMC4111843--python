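import numpy as np
import pandas as pd
import pytest

from mhcbench.features import FEATURE_NAMES
from mhcbench.reliability import (
    BLIND_PAIR,
    TRAIN_PAIR,
    combine_max,
    fit_logistic,
    loocv_combined,
    loocv_evaluate,
    loocv_probabilities,
    pairwise_feature_search,
    reporting_split,
)


def _labels(y):
    return ["large" if v else "small" for v in y]


def simulate_logistic(rng, n=200, beta=(1.5, -2.0), intercept=-0.3):
    x = rng.normal(size=(n, 2))
    logit = intercept + x @ np.array(beta)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return x, _labels(y)


class TestFitLogistic:
    def test_matches_statsmodels_mle(self, rng):
        # independent oracle: unpenalized ML fit on the same standardized
        # design (ridge 1e-6 is numerically negligible off separation)
        import statsmodels.api as sm

        x, labels = simulate_logistic(rng)
        model = fit_logistic(x, labels, ("f1", "f2"))
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        sm_fit = sm.Logit(
            [1 if l == "large" else 0 for l in labels], sm.add_constant(z)
        ).fit(disp=False)
        assert model.intercept == pytest.approx(sm_fit.params[0], abs=1e-3)
        np.testing.assert_allclose(model.coefficients, sm_fit.params[1:], atol=1e-3)

    def test_penalized_score_equations_hold(self, rng):
        x, labels = simulate_logistic(rng, n=150)
        ridge = 1e-3
        model = fit_logistic(x, labels, ("f1", "f2"), ridge=ridge)
        z = (x - model.means) / model.scales
        y = np.array([1 if l == "large" else 0 for l in labels])
        p = model.predict_proba(x)
        grad_intercept = np.sum(y - p)
        grad_coef = z.T @ (y - p) - ridge * model.coefficients
        assert abs(grad_intercept) < 1e-2
        np.testing.assert_allclose(grad_coef, 0.0, atol=1e-2)

    def test_separated_data_saturates_under_small_ridge(self):
        x = np.column_stack([np.r_[np.zeros(10), np.ones(10) * 4], np.zeros(20)])
        labels = _labels(np.r_[np.zeros(10), np.ones(10)].astype(bool))
        model = fit_logistic(x, labels, ("f1", "f2"), ridge=1e-6)
        p = model.predict_proba(x)
        assert np.all(p[:10] <= 0.01) and np.all(p[10:] >= 0.99)

    def test_null_labels_give_near_zero_coefficients(self, rng):
        x = rng.normal(size=(400, 2))
        y = rng.random(400) < 0.3  # independent of x
        model = fit_logistic(x, _labels(y), ("f1", "f2"))
        assert np.abs(model.coefficients).max() < 0.25
        p = model.predict_proba(x)
        assert abs(p.mean() - y.mean()) < 0.05

    def test_duplicated_rows_leave_model_unchanged(self, rng):
        x, labels = simulate_logistic(rng, n=80)
        m1 = fit_logistic(x, labels, ("f1", "f2"))
        m2 = fit_logistic(np.vstack([x, x]), labels + labels, ("f1", "f2"))
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-4)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-4)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_logistic(x, ["small"] * 10, ("f1", "f2"))

    def test_coefficient_recovery_over_seeds(self):
        # planted 2-feature model, n=200: signs recovered every time and
        # average relative error under 25%
        beta = np.array([1.5, -2.0])
        rel_errors, signs_ok = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, labels = simulate_logistic(rng, n=200, beta=tuple(beta))
            model = fit_logistic(x, labels, ("f1", "f2"))
            # coefficients are on standardized scale; x is standard normal
            # so scales ~ 1 and comparison is direct after rescaling
            est = model.coefficients / model.scales
            signs_ok.append(np.all(np.sign(est) == np.sign(beta)))
            rel_errors.append(np.abs((est - beta) / beta).mean())
        assert all(signs_ok)
        assert np.mean(rel_errors) < 0.25


class TestLoocv:
    def test_minimal_n_three_contract(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        probs = loocv_probabilities(x, ["small", "large", "small"], ("f1", "f2"))
        assert probs.shape == (3,)
        assert np.all((probs > 0) & (probs < 1))

    def test_separable_feature_reaches_high_aroc(self, rng):
        x = np.column_stack([np.r_[rng.normal(0, 0.3, 30), rng.normal(4, 0.3, 30)],
                             rng.normal(size=60)])
        labels = _labels(np.r_[np.zeros(30), np.ones(30)].astype(bool))
        _, auc = loocv_evaluate(x, labels, ("f1", "f2"))
        assert auc > 0.95

    def test_permuted_labels_show_no_optimism(self, rng):
        # under label permutation LOOCV must not look better than chance;
        # note the estimator is in fact pessimistic under the null (each
        # held-out example's own class is underrepresented in training),
        # so the null mean sits below 0.5 rather than at it
        x = rng.normal(size=(40, 2))
        aucs = []
        for _ in range(100):
            y = np.zeros(40, dtype=bool)
            y[rng.choice(40, 15, replace=False)] = True
            _, auc = loocv_evaluate(x, _labels(y), ("f1", "f2"))
            aucs.append(auc)
        assert np.mean(aucs) < 0.55
        assert np.quantile(aucs, 0.9) < 0.75

    def test_probabilities_invariant_to_example_order(self, rng):
        x, labels = simulate_logistic(rng, n=30)
        probs = loocv_probabilities(x, labels, ("f1", "f2"))
        perm = rng.permutation(30)
        probs_perm = loocv_probabilities(
            x[perm], [labels[i] for i in perm], ("f1", "f2")
        )
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-6)


class TestPairwiseSearch:
    def _table(self, rng, n=60):
        return pd.DataFrame(rng.normal(size=(n, 10)), columns=FEATURE_NAMES)

    def test_all_45_pairs_evaluated(self, rng):
        tab = self._table(rng)
        y = rng.random(60) < 0.4
        out = pairwise_feature_search(tab, _labels(y))
        assert len(out) == 45

    def test_planted_pair_ranks_first(self, rng):
        tab = self._table(rng, n=80)
        logit = 2.5 * tab["log_size_cv"] - 2.5 * tab["ent_meas_cv"]
        y = rng.random(80) < 1 / (1 + np.exp(-logit))
        out = pairwise_feature_search(tab, _labels(y))
        top = {out.iloc[0]["feature_a"], out.iloc[0]["feature_b"]}
        assert top == {"log_size_cv", "ent_meas_cv"}

    def test_restriction_limits_candidates(self, rng):
        from mhcbench.features import BLIND_FEATURES

        tab = self._table(rng)
        y = rng.random(60) < 0.4
        out = pairwise_feature_search(tab, _labels(y), restrict_to=BLIND_FEATURES)
        assert len(out) == 6  # C(4,2)
        used = set(out["feature_a"]) | set(out["feature_b"])
        assert used <= set(BLIND_FEATURES)

    def test_ranking_deterministic(self, rng):
        tab = self._table(rng)
        y = rng.random(60) < 0.4
        a = pairwise_feature_search(tab, _labels(y))
        b = pairwise_feature_search(tab, _labels(y))
        pd.testing.assert_frame_equal(a, b)


class TestCombineAndReport:
    def test_elementwise_maximum(self):
        np.testing.assert_allclose(
            combine_max([0.3, 0.1], [0.7, 0.05]), [0.7, 0.1]
        )

    def test_identical_inputs_identity(self):
        p = np.array([0.2, 0.4, 0.9])
        np.testing.assert_allclose(combine_max(p, p), p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_max([0.1], [0.1, 0.2])

    def test_complementary_models_combine_well(self, rng):
        # two disjoint failure modes, each visible to one feature only:
        # the max-combined model must not be worse than the weaker single
        n = 120
        mode = rng.integers(0, 3, n)  # 0: fine, 1: mode A fails, 2: mode B fails
        f_a = np.where(mode == 1, 3.0, 0.0) + rng.normal(0, 0.4, n)
        f_b = np.where(mode == 2, 3.0, 0.0) + rng.normal(0, 0.4, n)
        tab = pd.DataFrame(
            {name: rng.normal(size=n) for name in FEATURE_NAMES}
        )
        tab["log_size_cv"], tab["ent_meas_cv"] = f_a, rng.normal(size=n)
        tab["entss_bl"], tab["ent_pred_bl"] = f_b, rng.normal(size=n)
        labels = _labels(mode > 0)
        _, auc_a = loocv_evaluate(tab, labels, TRAIN_PAIR)
        _, auc_b = loocv_evaluate(tab, labels, BLIND_PAIR)
        _, auc_c = loocv_combined(tab, labels)
        assert auc_c >= min(auc_a, auc_b)
        assert auc_c > 0.8

    def test_reporting_split_boundaries(self):
        groups = reporting_split([0.1, 0.19, 0.21, 0.9], cutoff=0.2)
        assert list(groups) == ["good", "good", "bad", "bad"]

    def test_cutoff_zero_flags_everything(self):
        assert list(reporting_split([0.05, 0.5], cutoff=0.0)) == ["bad", "bad"]
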