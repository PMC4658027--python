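"""Adjustment equations, stepwise selection, leptin statistics."""

import numpy as np
import pandas as pd
import pytest

import feedcast as fc
from feedcast.genomic_adjustment import (
    DEFAULT_EXCLUSIONS,
    apply_eq9,
    apply_eq10,
    apply_eq11,
    apply_eq12,
    best_subset_ols,
    compute_deltas,
    expand_candidates,
    group_effects,
    leptin_allele_stats,
    stepwise_ols,
    variance_explained,
)


class TestPublishedEquations:
    def test_eq9_steer_worked_value(self):
        assert apply_eq9(0, 503.99, -0.42) == pytest.approx(564.0, abs=0.1)

    def test_eq9_mbv_rea_slope(self):
        base = apply_eq9(1, 480.0, 0.0)
        assert apply_eq9(1, 480.0, 1.0) - base == pytest.approx(44.5, abs=1e-12)

    def test_eq10_steer_worked_value(self):
        assert apply_eq10(0, 120, 314, 52.3, -0.42) == pytest.approx(589.4, abs=0.1)

    def test_eq10_marbling_panel_span(self):
        # a 100-point spread in the Angus marbling MBV moves AFSBW ~25 kg
        lo = apply_eq10(0, 120, 314, 0.0, 0.0)
        hi = apply_eq10(0, 120, 314, 100.0, 0.0)
        assert hi - lo == pytest.approx(-25.7, abs=1e-9)

    def test_eq11_worked_value_and_slope(self):
        assert apply_eq11(0, 9.0, -0.42) == pytest.approx(10.16, abs=0.01)
        assert apply_eq11(0, 9.0, 1.0) - apply_eq11(0, 9.0, 0.0) == pytest.approx(-0.606)

    def test_eq12_slope(self):
        assert apply_eq12(1, 10.0, 1.0) - apply_eq12(1, 10.0, 0.0) == pytest.approx(-0.45)

    def test_published_application_is_bit_stable(self):
        a = np.zeros(5)
        x = np.full(5, 503.99)
        m = np.full(5, -0.42)
        assert np.array_equal(apply_eq9(a, x, m), apply_eq9(a, x, m))


class TestComputeDeltas:
    def test_exact_subtractions(self):
        df = pd.DataFrame(
            {
                "afsbw_ct_kg": [566.2],
                "afsbw_hh_kg": [504.0],
                "adg_kg_d": [1.57],
                "padg_hh_kg_d": [1.50],
                "padg_ct_kg_d": [1.60],
                "edof_d": [154.4],
                "dof_hh_d": [140.0],
                "dof_ct_d": [154.4],
                "dmr_kg_d": [8.4],
                "pdmi_hh_kg_d": [8.0],
            }
        )
        out = compute_deltas(df)
        assert out.loc[0, "d_afsbw_kg"] == pytest.approx(62.2)
        assert out.loc[0, "d_dof_ct_d"] == 0.0
        assert out.loc[0, "d_dmi_kg_d"] == pytest.approx(0.4)

    def test_missingness_propagates_not_zero(self):
        df = pd.DataFrame({"afsbw_ct_kg": [566.2], "adg_kg_d": [1.5]})
        out = compute_deltas(df)
        assert np.isnan(out.loc[0, "d_afsbw_kg"])
        assert np.isnan(out.loc[0, "d_dmi_kg_d"])

    def test_identical_predictions_zero_deltas(self):
        df = pd.DataFrame(
            {
                "afsbw_ct_kg": [500.0],
                "afsbw_hh_kg": [500.0],
                "adg_kg_d": [1.5],
                "padg_hh_kg_d": [1.5],
                "padg_ct_kg_d": [1.5],
                "edof_d": [150.0],
                "dof_hh_d": [150.0],
                "dof_ct_d": [150.0],
                "dmr_kg_d": [8.0],
                "pdmi_hh_kg_d": [8.0],
            }
        )
        out = compute_deltas(df)
        for c in ("d_afsbw_kg", "d_adg_hh_kg_d", "d_dof_hh_d", "d_dmi_kg_d"):
            assert out.loc[0, c] == 0.0


class TestFitForms:
    def test_eq9_noiseless_truth_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 400
        df = pd.DataFrame(
            {
                "sex": rng.choice(["steer", "heifer"], n),
                "afsbw_hh_kg": rng.normal(480, 30, n),
                "mbv_rea": rng.normal(-0.4, 0.47, n),
            }
        )
        a = (df["sex"] == "heifer").to_numpy(float)
        df["afsbw_ct_kg"] = apply_eq9(a, df["afsbw_hh_kg"], df["mbv_rea"])
        fit = fc.fit_eq9_form(df)
        assert fit.terms.loc["mbv_rea", "coef"] == pytest.approx(44.5, abs=1e-8)
        assert fit.terms.loc["a", "coef"] == pytest.approx(-175.9, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        # OLS identity: residual mean zero on training data
        resid = df["afsbw_ct_kg"] - fit.predict(df)
        assert abs(resid.mean()) < 1e-8

    def test_eq9_single_sex_drops_interaction(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "sex": ["steer"] * 60,
                "afsbw_hh_kg": rng.normal(500, 25, 60),
                "mbv_rea": rng.normal(-0.4, 0.5, 60),
            }
        )
        df["afsbw_ct_kg"] = apply_eq9(0, df["afsbw_hh_kg"], df["mbv_rea"])
        with pytest.warns(UserWarning, match="single-sex"):
            fit = fc.fit_eq9_form(df)
        assert "a" not in fit.terms.index

    def test_eq10_rank_deficiency_names_term(self):
        rng = np.random.default_rng(2)
        n = 80
        df = pd.DataFrame(
            {
                "sex": rng.choice(["steer", "heifer"], n),
                "hip_height_cm": np.full(n, 120.0),  # constant HH: collinear terms
                "isbw_kg": rng.normal(310, 40, n),
                "mbv_cab_mrb": rng.normal(50, 17, n),
                "mbv_rea": rng.normal(-0.4, 0.47, n),
                "afsbw_ct_kg": rng.normal(550, 50, n),
            }
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fc.fit_eq10_form(df)

    def test_eq11_noiseless_truth_recovered(self):
        rng = np.random.default_rng(3)
        n = 300
        df = pd.DataFrame(
            {
                "sex": rng.choice(["steer", "heifer"], n),
                "pdmi_hh_kg_d": rng.normal(9.0, 0.8, n),
                "mbv_rea": rng.normal(-0.4, 0.47, n),
            }
        )
        a = (df["sex"] == "heifer").to_numpy(float)
        df["dmr_kg_d"] = apply_eq11(a, df["pdmi_hh_kg_d"], df["mbv_rea"])
        fit = fc.fit_eq11_form(df)
        assert fit.terms.loc["mbv_rea", "coef"] == pytest.approx(-0.606, abs=1e-9)


class TestStepwise:
    @staticmethod
    def _noise_frame(rng, n, k, prefix="z"):
        return pd.DataFrame(
            rng.standard_normal((n, k)), columns=[f"{prefix}{i}" for i in range(k)]
        )

    def test_single_strong_predictor_selected_exactly(self, rng):
        n = 500
        df = self._noise_frame(rng, n, 5)
        df["x"] = rng.standard_normal(n)
        df["y"] = 5.0 * df["x"] + rng.standard_normal(n)
        cands = ["x"] + [f"z{i}" for i in range(5)]
        fit = stepwise_ols(df, "y", cands)
        selected = [t for t in fit.terms.index if t != "const"]
        assert selected == ["x"]
        # independent oracle: exhaustive best-subset search agrees
        best = best_subset_ols(df, "y", cands)
        assert [t for t in best.terms.index if t != "const"] == ["x"]

    def test_false_entry_rate_controlled(self):
        # all-noise candidates: mean selected size bounded by 2 * k * entry_p
        k, sizes = 6, []
        for s in range(500):
            r = np.random.default_rng(s)
            df = self._noise_frame(r, 100, k)
            df["y"] = r.standard_normal(100)
            fit = stepwise_ols(df, "y", [f"z{i}" for i in range(k)], entry_p=0.15)
            sizes.append(len(fit.terms) - 1)
        assert np.mean(sizes) <= k * 0.15 * 2

    def test_exact_candidate_enters_with_r2_one(self, rng):
        df = self._noise_frame(rng, 100, 3)
        df["y"] = df["z1"]
        fit = stepwise_ols(df, "y", ["z0", "z1", "z2"])
        assert "z1" in fit.terms.index
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_mutual_exclusion_enforced(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "leptin_class": rng.standard_normal(n),  # numeric stand-in score
            }
        )
        df["mbv_rea"] = df["leptin_class"] * 0.95 + 0.3 * rng.standard_normal(n)
        df["y"] = 2.0 * df["mbv_rea"] + 0.5 * rng.standard_normal(n)
        fit = stepwise_ols(df, "y", ["mbv_rea", "leptin_class"], exclusions=DEFAULT_EXCLUSIONS)
        selected = set(fit.terms.index) - {"const"}
        assert len(selected & {"mbv_rea", "leptin_class"}) == 1

    def test_candidate_order_only_breaks_ties(self, rng):
        n = 400
        df = self._noise_frame(rng, n, 4)
        df["x"] = rng.standard_normal(n)
        df["y"] = 3.0 * df["x"] + rng.standard_normal(n)
        cands = ["x"] + [f"z{i}" for i in range(4)]
        a = stepwise_ols(df, "y", cands)
        b = stepwise_ols(df, "y", cands[::-1])
        assert set(a.terms.index) == set(b.terms.index)

    def test_too_few_rows_rejected(self, rng):
        df = self._noise_frame(rng, 8, 5)
        df["y"] = rng.standard_normal(8)
        with pytest.raises(ValueError):
            stepwise_ols(df, "y", [f"z{i}" for i in range(5)])

    def test_expand_candidates_builds_interactions_and_quadratics(self, small_cohort):
        out, cands = expand_candidates(small_cohort, ["mbv_rea", "mbv_cab_mrb"])
        assert "a_x_mbv_rea" in cands and "mbv_rea_sq" in cands
        np.testing.assert_allclose(out["mbv_rea_sq"], out["mbv_rea"] ** 2)


class TestLeptinStats:
    def test_printed_count_ratios(self):
        assert leptin_allele_stats(254, 416, 164)["ct_ratio"] == pytest.approx(1.24, abs=0.005)
        assert leptin_allele_stats(406, 349, 61)["ct_ratio"] == pytest.approx(2.46, abs=0.005)

    def test_chi_square_against_hw_style_expectation(self):
        st = leptin_allele_stats(313, 282, 70)
        # hand-computed Pearson chi-square oracle against 25:50:25
        n = 313 + 282 + 70
        exp = np.array([0.25, 0.5, 0.25]) * n
        chi2 = (((np.array([313, 282, 70]) - exp) ** 2) / exp).sum()
        assert st["chi2"] == pytest.approx(chi2, abs=1e-9)
        assert st["chi2"] == pytest.approx(192.9, abs=0.05)
        assert st["p"] < 1e-4

    def test_allele_bookkeeping(self):
        st = leptin_allele_stats(10, 20, 5)
        assert st["c_alleles"] == 40 and st["t_alleles"] == 30

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            leptin_allele_stats(0, 0, 0)


class TestVarianceExplained:
    def test_orthogonal_addition_contributes_nothing(self, rng):
        n = 200
        df = pd.DataFrame({"b": rng.standard_normal(n)})
        df["y"] = 2.0 * df["b"] + 0.1 * rng.standard_normal(n)
        # construct an added predictor orthogonal to y and b
        z = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), df["b"], df["y"]])
        df["z"] = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        out = variance_explained(df, "y", ["b"], ["z"])
        assert out["increment_pct"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_decomposition_sums_to_100(self, rng):
        n = 150
        df = pd.DataFrame({"b": rng.standard_normal(n), "z": rng.standard_normal(n)})
        df["y"] = df["b"] + 2.0 * df["z"]
        out = variance_explained(df, "y", ["b"], ["z"])
        assert 100.0 * out["r2_base"] + out["increment_pct"] == pytest.approx(100.0, abs=1e-8)


class TestGroupEffects:
    def test_identical_groups_near_zero_spread(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "sex": rng.choice(["steer", "heifer"], n),
                "leptin_class": rng.choice(["CCCC", "CTCT", "TTTT"], n),
                "y": rng.standard_normal(n),
            }
        )
        out = group_effects(df, "y")
        sex_means = out[out["factor"] == "sex"]["lsmean"]
        assert sex_means.max() - sex_means.min() < 0.5

    def test_recovers_constructed_sex_offset(self, rng):
        n = 2000
        sex = rng.choice(["steer", "heifer"], n)
        d = 0.06  # heifer - steer offset on the REA MBV
        y = np.where(sex == "heifer", -0.434, -0.494) + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame({"sex": sex, "leptin_class": rng.choice(["CCCC", "CTCT"], n), "y": y})
        out = group_effects(df, "y")
        sexed = out[out["factor"] == "sex"].set_index("level")["lsmean"]
        assert sexed["heifer"] - sexed["steer"] == pytest.approx(d, abs=0.02)

    def test_two_level_factor_reduces_to_t_test(self, rng):
        import statsmodels.api as sm
        from scipy import stats as sps

        n = 120
        g = rng.choice(["a", "b"], n)
        y = np.where(g == "b", 0.8, 0.0) + rng.standard_normal(n)
        df = pd.DataFrame({"sex": g, "y": y})
        out = group_effects(df, "y", factors=("sex",))
        res = out.attrs["model"]
        t = sps.ttest_ind(y[g == "a"], y[g == "b"], equal_var=True).statistic
        assert res.fvalue == pytest.approx(t**2, rel=1e-9)
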