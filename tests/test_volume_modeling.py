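"""Train/test split, stepwise-AIC selection (against an R step() oracle),
validation statistics, and prediction with the bundled reference models."""

import numpy as np
import pandas as pd
import pytest

from canopyscale.volume_modeling import (
    REFERENCE_MODEL_005HA,
    REFERENCE_MODEL_1HA,
    VolumeModel,
    evaluate,
    fit_stepwise,
    predict,
    split_train_test,
)


class TestSplit:
    @pytest.mark.parametrize("n,n_train", [(50, 35), (1100, 770), (10, 7)])
    def test_sizes(self, n, n_train):
        tr, te = split_train_test(range(n), 0.7, seed=1)
        assert len(tr) == n_train and len(te) == n - n_train
        assert set(tr).isdisjoint(te) and set(tr) | set(te) == set(range(n))

    def test_deterministic(self):
        assert split_train_test(range(40), seed=9) == split_train_test(range(40), seed=9)
        assert split_train_test(range(40), seed=9) != split_train_test(range(40), seed=10)

    def test_too_few_plots(self):
        with pytest.raises(ValueError):
            split_train_test(range(9))


class TestStepwise:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(5)
        mt = pd.DataFrame(
            {"MCH": rng.uniform(10, 30, 50), "CV": rng.uniform(0.1, 0.6, 50),
             "var": rng.uniform(5, 40, 50)}
        )
        vols = pd.Series(10 + 2 * mt["MCH"], index=mt.index)
        m = fit_stepwise(mt, vols, ["MCH", "CV", "var"])
        assert set(m.coefficients) == {"MCH"}
        assert m.intercept == pytest.approx(10.0, abs=1e-6)
        assert m.coefficients["MCH"] == pytest.approx(2.0, abs=1e-6)

    def test_matches_r_step_oracle_on_signal_data(self):
        # identical data fed to R: step(lm(y~1), scope=y~x1+...+x6, 'both')
        # selects {x1, x4} with the coefficients below (frozen R output)
        rng = np.random.default_rng(123)
        mt = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"x{i}" for i in range(1, 7)])
        y = pd.Series(5 + 2 * mt["x1"] - 3 * mt["x4"] + rng.normal(scale=1.0, size=40))
        m = fit_stepwise(mt, y, list(mt.columns))
        assert set(m.coefficients) == {"x1", "x4"}
        assert m.intercept == pytest.approx(5.014662, abs=1e-5)
        assert m.coefficients["x1"] == pytest.approx(1.889378, abs=1e-5)
        assert m.coefficients["x4"] == pytest.approx(-2.891638, abs=1e-5)

    def test_matches_r_step_oracle_on_pure_noise(self):
        # same draw fed to R step(): selects exactly {m9, m20, m23}
        rng = np.random.default_rng(1007)
        mt = pd.DataFrame(rng.normal(size=(1000, 30)), columns=[f"m{i}" for i in range(30)])
        y = pd.Series(rng.normal(size=1000))
        m = fit_stepwise(mt, y, list(mt.columns))
        assert set(m.coefficients) == {"m9", "m20", "m23"}

    def test_consistency_on_noisy_linear_model(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(77)
        n = 500
        mt = pd.DataFrame(
            {"MCH": rng.uniform(10, 30, n), "CV": rng.uniform(0.1, 0.6, n),
             "q90": rng.uniform(15, 35, n), "kurt": rng.uniform(2, 4, n)}
        )
        vols = pd.Series(
            -100 + 20 * mt["MCH"] + 80 * mt["CV"] + rng.normal(0, 30, n), index=mt.index
        )
        m = fit_stepwise(mt, vols, list(mt.columns))
        assert {"MCH", "CV"} <= set(m.coefficients)
        X = sm.add_constant(mt[["MCH", "CV"]])
        ref = sm.OLS(vols, X).fit()
        assert abs(m.coefficients["MCH"] - 20) < 3 * ref.bse["MCH"]
        assert abs(m.coefficients["CV"] - 80) < 3 * ref.bse["CV"]

    def test_pure_noise_selection_stays_moderate(self):
        sizes = []
        for s in range(30):
            rng = np.random.default_rng(2000 + s)
            mt = pd.DataFrame(rng.normal(size=(400, 30)), columns=[f"m{i}" for i in range(30)])
            y = pd.Series(rng.normal(size=400))
            sizes.append(len(fit_stepwise(mt, y, list(mt.columns)).coefficients))
        sizes = np.asarray(sizes)
        # AIC admits a handful of spurious terms out of 30, never many
        assert (sizes <= 9).mean() >= 0.9
        assert sizes.mean() <= 6

    def test_collinear_candidate_never_entered(self):
        rng = np.random.default_rng(3)
        mt = pd.DataFrame({"a": rng.normal(size=60)})
        mt["b"] = 2.0 * mt["a"]  # exact copy of a, rescaled
        y = pd.Series(3 + 4 * mt["a"] + rng.normal(0, 0.1, 60), index=mt.index)
        m = fit_stepwise(mt, y, ["a", "b"])
        assert len(m.coefficients) == 1

    def test_stepwise_aic_not_worse_than_intercept_only(self):
        rng = np.random.default_rng(8)
        mt = pd.DataFrame({"MCH": rng.uniform(10, 30, 80)})
        y = pd.Series(5 + 3 * mt["MCH"] + rng.normal(0, 5, 80), index=mt.index)
        m = fit_stepwise(mt, y, ["MCH"])
        r2_train, _ = evaluate(m, mt, y)
        assert r2_train >= 0.0  # never beneath the intercept-only fit


class TestEvaluate:
    def test_perfect_and_mean_predictions(self):
        mt = pd.DataFrame({"MCH": [1.0, 2.0, 3.0]})
        y = pd.Series([10.0, 20.0, 30.0])
        perfect = VolumeModel(intercept=0.0, coefficients={"MCH": 10.0})
        r2, rmse = evaluate(perfect, mt, y)
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(0.0)
        flat = VolumeModel(intercept=20.0, coefficients={})
        r2, rmse = evaluate(flat, mt, y)
        assert r2 == pytest.approx(0.0)

    def test_hand_triple(self):
        mt = pd.DataFrame({"x": [110.0, 190.0, 310.0]})
        y = pd.Series([100.0, 200.0, 300.0])
        ident = VolumeModel(intercept=0.0, coefficients={"x": 1.0})
        r2, rmse = evaluate(ident, mt, y)
        assert rmse == pytest.approx(10.0)
        assert r2 == pytest.approx(1 - 300.0 / 20000.0)  # 0.985

    def test_zero_variance_gives_nan(self):
        mt = pd.DataFrame({"x": [1.0, 2.0]})
        y = pd.Series([5.0, 5.0])
        r2, _ = evaluate(VolumeModel(0.0, {"x": 1.0}), mt, y)
        assert np.isnan(r2)


class TestPredict:
    def test_reference_005ha_hand_value(self):
        v = predict(REFERENCE_MODEL_005HA, {"MCH": 20.0, "CV": 0.3})
        assert v == pytest.approx(393.24, abs=0.01)

    def test_reference_1ha_hand_value(self):
        v = predict(
            REFERENCE_MODEL_1HA, {"var": 2.0, "q20": 15.0, "q40": 18.0, "q70": 22.0, "kurt": 3.0}
        )
        assert v == pytest.approx(530.91, abs=0.01)

    def test_negative_prediction_floored(self):
        zeros = {"MCH": 0.0, "CV": 0.0}
        assert predict(REFERENCE_MODEL_005HA, zeros) == 0.0
        assert predict(REFERENCE_MODEL_005HA, zeros, clip_negative=False) == pytest.approx(-144.85)

    def test_missing_metric_raises_with_name(self):
        with pytest.raises(KeyError, match="CV"):
            predict(REFERENCE_MODEL_005HA, {"MCH": 20.0})


def test_model_json_roundtrip(tmp_path):
    m = VolumeModel(1.5, {"MCH": 2.0}, plot_scale="1ha", fit_stats={"r2": 0.9})
    p = tmp_path / "m.json"
    m.to_json(p)
    back = VolumeModel.from_json(p)
    assert back.intercept == m.intercept and back.coefficients == m.coefficients
    assert back.plot_scale == "1ha" and back.fit_stats["r2"] == 0.9
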