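import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesioncast.region_models import (
    COEF_CAP,
    FitConfig,
    aic,
    fit_all_regions,
    fit_logistic,
    nested_cv_fit,
    normalize_features,
    predict_region,
    select_best_model,
    select_features_kendall,
)
from lesioncast.region_models import RegionModel


def kendall_tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else np.nan


class TestKendallScreen:
    def test_perfect_concordance_selected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        df = pd.DataFrame({"same": y.astype(float), "noise": rng.normal(size=40)})
        assert "same" in select_features_kendall(df, y)

    def test_constant_feature_excluded(self):
        y = np.array([0, 1] * 10)
        df = pd.DataFrame({"const": np.ones(20)})
        assert select_features_kendall(df, y) == []

    def test_tau_b_matches_pair_counting_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 9.0])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 1])
        tau, _ = stats.kendalltau(x, y, variant="b")
        assert tau == pytest.approx(kendall_tau_b_oracle(x, y))

    def test_oracle_agreement_on_random_tied_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 2, n)
            expected = kendall_tau_b_oracle(x, y)
            tau, _ = stats.kendalltau(x, y, variant="b")
            if np.isnan(expected):
                assert np.isnan(tau)
            else:
                assert tau == pytest.approx(expected)

    def test_single_class_outcome_raises(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            select_features_kendall(df, np.zeros(10, int))


class TestNormalizeFeatures:
    def test_scaling_and_idempotence(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [0.0, 0.5, 1.0]})
        scaled, params = normalize_features(df)
        assert scaled["a"].tolist() == [0.0, 0.5, 1.0]
        assert scaled["b"].tolist() == [0.0, 0.5, 1.0]
        assert params.constant == ()

    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 2.0]})
        _, params = normalize_features(df)
        assert params.constant == ("a",)

    def test_new_data_may_fall_outside_unit_interval(self):
        train = pd.DataFrame({"a": [2.0, 4.0]})
        _, params = normalize_features(train)
        out = params.transform(pd.DataFrame({"a": [6.0, 0.0]}))
        assert out["a"].tolist() == [2.0, -1.0]  # passed through, not clipped


class TestFitLogistic:
    def test_probability_formula(self):
        # a=[1], b=0, x=1 -> P = 1/(1+e^-1)
        model = RegionModel(
            region_id=1, method="none", feature_names=("x",),
            coef=np.array([1.0]), intercept=0.0, log_likelihood=0.0,
            n_params=2, aic=4.0,
        )
        probs, pred = predict_region(model, pd.DataFrame({"x": [1.0, 0.0]}))
        assert probs[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)
        assert probs[1] == pytest.approx(0.5)
        assert pred.tolist() == [1, 1]  # P >= 0.5 is presence, boundary included

    def test_logistic_symmetry(self):
        model = RegionModel(
            region_id=1, method="none", feature_names=("x",),
            coef=np.array([2.0]), intercept=0.0, log_likelihood=0.0,
            n_params=2, aic=4.0,
        )
        probs, _ = predict_region(model, pd.DataFrame({"x": [1.5, -1.5]}))
        assert probs[0] + probs[1] == pytest.approx(1.0)

    def test_large_l1_penalty_shrinks_all_slopes_to_zero(self, logistic_cohort):
        x, y, _ = logistic_cohort
        coef, b, ll, k, sep = fit_logistic(x.to_numpy(), y, "l1", lam=1e6)
        assert np.all(coef == 0)
        assert k == 1

    def test_l1_shrinkage_monotone_in_lambda(self, logistic_cohort):
        x, y, _ = logistic_cohort
        nonzeros = []
        for lam in (1e-4, 1e-2, 1e-1, 1.0, 10.0):
            coef, *_ = fit_logistic(x.to_numpy(), y, "l1", lam=lam)
            nonzeros.append(int(np.sum(np.abs(coef) > 1e-8)))
        assert nonzeros == sorted(nonzeros, reverse=True)

    def test_perfect_separation_capped_and_flagged(self):
        x = np.array([[-2.0], [-1.0], [1.0], [2.0]] * 5)
        y = (x[:, 0] > 0).astype(int)
        coef, b, ll, k, sep = fit_logistic(x, y, "none")
        assert sep
        assert np.all(np.abs(coef) <= COEF_CAP)

    def test_unpenalized_matches_statsmodels(self, logistic_cohort):
        import statsmodels.api as sm

        x, y, _ = logistic_cohort
        xs = x.to_numpy()[:, :3]
        coef, b, ll, k, sep = fit_logistic(xs, y, "none")
        ref = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
        assert b == pytest.approx(ref.params[0], abs=1e-4)
        assert np.allclose(coef, ref.params[1:], atol=1e-4)
        assert ll == pytest.approx(ref.llf, abs=1e-6)


class TestAIC:
    @pytest.mark.parametrize("ll,k,expected", [(0.0, 2, 4.0), (-10.0, 3, 26.0)])
    def test_formula(self, ll, k, expected):
        assert aic(ll, k) == expected

    def test_useless_parameter_costs_two(self):
        assert aic(-5.0, 4) - aic(-5.0, 3) == 2.0


class TestNestedCV:
    def test_candidate_count_with_sufficient_presence(self, logistic_cohort):
        x, y, _ = logistic_cohort
        cfg = FitConfig(method="none", resamples=5, seed=0)
        cands = nested_cv_fit(x, y, cfg)
        assert len(cands) == cfg.outer_folds * cfg.resamples

    def test_low_presence_single_model_path(self, logistic_cohort):
        x, _, _ = logistic_cohort
        y = np.zeros(len(x), dtype=int)
        y[:3] = 1
        cands = nested_cv_fit(x, y, FitConfig(method="none", seed=0))
        assert len(cands) == 1
        assert cands[0].provenance["path"] == "single"

    def test_same_seed_identical_candidates(self, logistic_cohort):
        x, y, _ = logistic_cohort
        cfg = FitConfig(method="none", resamples=3, seed=7)
        a = nested_cv_fit(x, y, cfg)
        b = nested_cv_fit(x, y, cfg)
        assert [m.aic for m in a] == [m.aic for m in b]
        assert [m.feature_names for m in a] == [m.feature_names for m in b]

    def test_regularized_candidates_carry_lambda_and_scaler(self, logistic_cohort):
        x, y, _ = logistic_cohort
        cfg = FitConfig(method="l2", resamples=1, lambda_grid=(1e-3, 1e-1, 10.0), seed=0)
        cands = nested_cv_fit(x, y, cfg)
        assert len(cands) == 4
        assert all(m.lam in cfg.lambda_grid for m in cands)
        assert all(m.scaler is not None for m in cands)


class TestModelSelection:
    def _model(self, aic_val, k, sens):
        return RegionModel(
            region_id=1, method="none", feature_names=(), coef=np.zeros(0),
            intercept=0.0, log_likelihood=0.0, n_params=k, aic=aic_val,
            provenance={"validation_sensitivity": sens},
        )

    def test_argmin_aic(self):
        models = [self._model(a, 2, 0.5) for a in (10.2, 9.8, 11.0)]
        assert select_best_model(models) is models[1]

    def test_tie_breaks(self):
        tie_params = [self._model(10.0, 3, 0.5), self._model(10.0, 2, 0.5)]
        assert select_best_model(tie_params).n_params == 2
        tie_sens = [self._model(10.0, 2, 0.4), self._model(10.0, 2, 0.9)]
        assert select_best_model(tie_sens).validation_sensitivity == 0.9

    def test_single_and_empty(self):
        m = self._model(5.0, 2, 0.5)
        assert select_best_model([m]) is m
        with pytest.raises(ValueError):
            select_best_model([])


class TestParameterRecovery:
    def _simulate(self, n, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
        beta = np.array([1.5, -1.5, 0.0, 0.0, 0.0])
        lin = x.to_numpy() @ beta + 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        return x, y, beta

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (100, 1000):
            est = []
            for seed in range(5):
                x, y, beta = self._simulate(n, seed)
                coef, *_ = fit_logistic(x.to_numpy(), y, "none")
                est.append(coef)
            errs.append(np.abs(np.mean(est, axis=0) - beta).mean())
        assert errs[1] < errs[0]

    def test_sign_recovery_of_strong_effects(self):
        x, y, beta = self._simulate(300, seed=3)
        cfg = FitConfig(method="none", resamples=2, seed=1)
        best = select_best_model(nested_cv_fit(x, y, cfg))
        strong = {"f0": 1, "f1": -1}
        for name, sign in strong.items():
            if name in best.feature_names:
                i = best.feature_names.index(name)
                assert np.sign(best.coef[i]) == sign


class TestFitAllRegions:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        lesion = pd.DataFrame(
            0.0, index=[f"s{i}" for i in range(n)], columns=[1, 2, 3]
        )
        feats = pd.DataFrame(
            rng.normal(size=(n, 4)),
            index=lesion.index,
            columns=[f"v{i}" for i in range(4)],
        )
        # region 1: presence driven by v0; region 2: all absent; region 3: sparse
        present = feats["v0"] > 0
        lesion.loc[present, 1] = 20.0
        lesion.loc[lesion.index[:2], 3] = 5.0
        return lesion, feats

    def test_totality_and_unmodellable_handling(self):
        lesion, feats = self._cohort()
        cfg = FitConfig(method="none", resamples=2, seed=0)
        result = fit_all_regions(lesion, feats, cfg)
        assert set(result.models) == {1, 3}
        assert result.unmodellable == {2: "no presence"}
        assert result.candidate_counts[1] == 8
        assert result.candidate_counts[3] == 1  # only 2 presences

    def test_selected_features_passed_kendall_screen(self):
        lesion, feats = self._cohort()
        cfg = FitConfig(method="none", resamples=2, seed=0)
        result = fit_all_regions(lesion, feats, cfg)
        model = result.models[1]
        y = (lesion[1] > 0).astype(int).to_numpy()
        # the winning feature set was screened within its training fold; on
        # this strong-signal region the driver feature must be present
        assert "v0" in model.feature_names

    def test_predictions_matrix_shape_and_threshold(self):
        lesion, feats = self._cohort()
        cfg = FitConfig(method="none", resamples=2, seed=0)
        result = fit_all_regions(lesion, feats, cfg)
        pred = result.predictions(feats)
        assert pred.shape == (60, 2)
        probs, cls = predict_region(result.models[1], feats)
        assert np.all((probs >= 0.5) == (cls == 1))
        assert np.all((probs > 0) & (probs < 1))
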