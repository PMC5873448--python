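import numpy as np
import pandas as pd
import pytest

from cpmagg import (
    CovariateError,
    IPDataset,
    PublishedCPM,
    coefficient_difference_summary,
    collapse,
    linear_predictor,
)

# Printed per-covariate coefficient spread across the four TAVI models
# (max minus min, a model omitting the covariate contributing zero).
TAVI_RANGES = {
    "age_66_70": 0.461, "age_71_75": 0.909, "age_76_80": 1.292,
    "age_81_85": 1.782, "age_gt_85": 2.351, "age_ge_90": 0.420,
    "age_per_5": 0.122, "female": 0.357, "bmi_lt_22": 0.359,
    "bmi_lt_18_5": 0.820, "bmi_18_5_29_9": 0.410, "bmi_gt_35": 0.393,
    "nyha_iv": 0.377, "mi_3wk": 0.825, "critical_preop": 0.870,
    "pulm_hypertension": 0.600, "no_sinus_rhythm": 0.343,
    "lvef_30_50": 0.283, "lvef_lt_30": 0.570, "lvef_lt_40": 0.450,
    "prior_cardiac_surgery": 0.307, "arterial_vessel_disease": 0.359,
    "copd": 0.511, "dialysis": 1.179, "emergency": 1.057,
    "non_tf_access": 0.673, "ta_access": 0.700, "other_access": 0.780,
    "egfr_lt_45": 0.900, "egfr_per_5": 0.069, "diabetes": 0.600,
    "prior_bav": 0.450, "acuity_2": 0.451, "acuity_3": 0.993,
    "acuity_4": 1.207,
}


def _df(**cols):
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})


class TestLinearPredictor:
    def test_worked_example(self):
        cpm = PublishedCPM("german_av_sub", -4.0, {"nyha_iv": 0.532, "dialysis": 1.164})
        lp = linear_predictor(cpm, _df(nyha_iv=[1.0], dialysis=[0.0]))
        assert lp == pytest.approx([-3.468], abs=1e-12)

    def test_all_zero_covariates_give_intercept(self, small_cpm):
        lp = linear_predictor(small_cpm, _df(a=[0, 0], b=[0, 0], c=[0, 0]))
        assert np.allclose(lp, small_cpm.intercept)

    def test_cancellation(self):
        cpm = PublishedCPM("m", 0.0, {"a": 0.5, "b": -0.25})
        lp = linear_predictor(cpm, _df(a=[2, 0], b=[4, 0]))
        assert np.allclose(lp, [0.0, 0.0])

    def test_missing_covariate_names_model_and_column(self, small_cpm):
        with pytest.raises(CovariateError, match=r"toy.*'b'"):
            linear_predictor(small_cpm, _df(a=[1.0], c=[1.0]))

    def test_linearity(self, small_cpm, rng):
        cols = ["a", "b", "c"]
        X1 = pd.DataFrame(rng.standard_normal((20, 3)), columns=cols)
        X2 = pd.DataFrame(rng.standard_normal((20, 3)), columns=cols)
        zero = pd.DataFrame(np.zeros((20, 3)), columns=cols)
        f = lambda X: linear_predictor(small_cpm, X)  # noqa: E731
        lhs = f(X1 + X2) - f(zero)
        rhs = (f(X1) - f(zero)) + (f(X2) - f(zero))
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestCollapse:
    def test_identity_stacking(self, small_cpm):
        m = collapse("stacked", {"gamma0": 0.0, "gammas": [1.0]}, [small_cpm])
        assert m.intercept == pytest.approx(small_cpm.intercept)
        assert m.coefficients == pytest.approx(small_cpm.coefficients)

    def test_fully_shrunk_hybrid_is_intercept_only(self, small_cpm):
        m = collapse(
            "hybrid",
            {"beta0": -1.2, "gammas": [0.0], "adjustments": {"a": 0.0}},
            [small_cpm],
        )
        assert m.intercept == pytest.approx(-1.2)
        assert all(v == 0 for v in m.coefficients.values())

    def test_two_model_hand_example(self):
        c1 = PublishedCPM("c1", 0.5, {"a": 1.0})
        c2 = PublishedCPM("c2", -0.5, {"a": 0.2, "b": 1.0})
        m = collapse("stacked", {"gamma0": 0.1, "gammas": [0.5, 2.0]}, [c1, c2])
        assert m.intercept == pytest.approx(0.1 + 0.25 - 1.0)
        assert m.coefficients["a"] == pytest.approx(0.9)
        assert m.coefficients["b"] == pytest.approx(2.0)

    def test_unknown_method_tag(self, small_cpm):
        with pytest.raises(ValueError, match="unknown method"):
            collapse("nonsense", {}, [small_cpm])

    @pytest.mark.parametrize("method", ["recalibration", "revision", "stacked", "hybrid"])
    def test_component_and_collapsed_risks_agree(self, method, rng):
        """Evaluating via the structural components and via the collapsed
        coefficient map must give identical risks (to 1e-10)."""
        from scipy.special import expit

        names = [f"v{i}" for i in range(6)]
        for _ in range(25):
            cpms = [
                PublishedCPM(
                    f"m{j}",
                    rng.normal(),
                    {n: rng.normal() for n in rng.choice(names, 4, replace=False)},
                )
                for j in range(2)
            ]
            X = pd.DataFrame(rng.standard_normal((15, len(names))), columns=names)
            lps = np.column_stack([linear_predictor(c, X) for c in cpms])
            if method == "recalibration":
                comp = {"alpha0": rng.normal(), "alpha1": rng.normal()}
                eta = comp["alpha0"] + comp["alpha1"] * lps[:, 0]
                model = collapse(method, comp, [cpms[0]])
            elif method == "revision":
                delta = {n: rng.normal() for n in list(cpms[0].coefficients)[:2]}
                comp = {"alpha0": rng.normal(), "alpha1": rng.normal(), "delta": delta}
                eta = comp["alpha0"] + comp["alpha1"] * lps[:, 0]
                for n, d in delta.items():
                    eta = eta + d * X[n].to_numpy()
                model = collapse(method, comp, [cpms[0]])
            elif method == "stacked":
                comp = {"gamma0": rng.normal(), "gammas": rng.normal(size=2)}
                eta = comp["gamma0"] + lps @ comp["gammas"]
                model = collapse(method, comp, cpms)
            else:
                adj = {n: rng.normal() for n in names[:3]}
                comp = {"beta0": rng.normal(), "gammas": rng.normal(size=2),
                        "adjustments": adj}
                eta = comp["beta0"] + lps @ comp["gammas"]
                for n, d in adj.items():
                    eta = eta + d * X[n].to_numpy()
                model = collapse(method, comp, cpms)
            assert np.allclose(model.predict_risk(X), expit(eta), atol=1e-10)


class TestCoefficientSpread:
    def test_reproduces_every_printed_range(self, tavi_cpms):
        s = coefficient_difference_summary(tavi_cpms)
        assert len(s.ranges) == 35
        for name, printed in TAVI_RANGES.items():
            assert s.ranges[name] == pytest.approx(printed, abs=1e-12), name

    def test_summary_statistics(self, tavi_cpms):
        s = coefficient_difference_summary(tavi_cpms)
        assert round(s.mean, 3) == 0.692
        assert s.lower_quartile == pytest.approx(0.385, abs=5e-4)
        assert s.upper_quartile == pytest.approx(0.885, abs=5e-4)

    def test_single_model_covariate_range_is_its_coefficient(self, tavi_cpms):
        s = coefficient_difference_summary(tavi_cpms)
        assert s.ranges["female"] == pytest.approx(0.357)
        # negative single-model coefficient: range is its magnitude
        assert s.ranges["egfr_per_5"] == pytest.approx(0.069)

    def test_identical_models_have_zero_spread(self, small_cpm):
        twin = PublishedCPM("twin", small_cpm.intercept, dict(small_cpm.coefficients))
        s = coefficient_difference_summary([small_cpm, twin])
        assert (s.ranges == 0).all() and s.mean == 0

    def test_errors(self, small_cpm):
        with pytest.raises(ValueError):
            coefficient_difference_summary([small_cpm])
        with pytest.raises(ValueError, match="empty"):
            coefficient_difference_summary(
                [small_cpm, small_cpm], covariate_union=[]
            )


class TestIPDataset:
    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            IPDataset(_df(a=[1.0, np.nan]), np.array([0, 1]))

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError, match="binary"):
            IPDataset(_df(a=[1.0, 2.0]), np.array([0, 2]))

    def test_rejects_duplicate_names(self):
        X = pd.DataFrame(np.ones((2, 2)), columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            IPDataset(X, np.array([0, 1]))

    def test_single_class_blocks_fitting(self):
        d = IPDataset(_df(a=[1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError, match="both"):
            d.require_both_classes()

    def test_nonfinite_cpm_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PublishedCPM("bad", np.inf, {"a": 1.0})
        with pytest.raises(ValueError, match="finite"):
            PublishedCPM("bad", 0.0, {"a": np.nan})
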