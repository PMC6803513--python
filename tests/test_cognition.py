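import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmdisp.battery import default_battery
from wmdisp.cognition import (
    age_detrend_standardize,
    compute_composites,
    compute_dispersion,
    correlation_table,
    residualize_on_age,
)


def _ols_oracle(age, y):
    """Normal-equations quadratic fit: beta = (X'X)^-1 X'y."""
    ac = age - age.mean()
    X = np.column_stack([np.ones_like(ac), ac, ac**2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta, y - X @ beta


def _frame(age, cols):
    df = pd.DataFrame(cols)
    df.insert(0, "age", age)
    df.insert(0, "participant_id", [f"p{i}" for i in range(len(age))])
    return df


class TestAgeDetrendStandardize:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(59, 89, 20)
        cols = {f"t{i}": rng.normal(10, 3, 20) for i in range(3)}
        bat = None
        model, t = age_detrend_standardize(_frame(age, cols), bat)
        for name, y in cols.items():
            beta, resid = _ols_oracle(age, y)
            fit = model.tests[name]
            got = np.array([fit.intercept, fit.beta_age, fit.beta_age2])
            np.testing.assert_allclose(got, beta, atol=1e-10)
            # T-scores are an affine map of the oracle residuals
            expect = 50 + 10 * (resid - resid.mean()) / resid.std(ddof=1)
            np.testing.assert_allclose(t[name].to_numpy(), expect, atol=1e-9)

    def test_t_columns_mean_50_sd_10(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(59, 89, 40)
        cols = {f"t{i}": rng.normal(0, 2, 40) for i in range(5)}
        _, t = age_detrend_standardize(_frame(age, cols))
        np.testing.assert_allclose(t.mean().to_numpy(), 50.0, atol=1e-9)
        np.testing.assert_allclose(t.std(ddof=1).to_numpy(), 10.0, atol=1e-9)

    def test_residuals_uncorrelated_with_age_terms(self):
        rng = np.random.default_rng(7)
        age = rng.uniform(59, 89, 40)
        _, t = age_detrend_standardize(_frame(age, {"y": rng.normal(size=40)}))
        ac = age - age.mean()
        resid = t["y"].to_numpy() - 50.0
        for term in (ac, ac**2):
            r = np.corrcoef(resid, term)[0, 1]
            assert abs(r) < 1e-10

    def test_constant_column_gives_all_50(self):
        age = np.linspace(60, 88, 10)
        _, t = age_detrend_standardize(_frame(age, {"c": np.full(10, 7.0)}))
        np.testing.assert_array_equal(t["c"].to_numpy(), 50.0)

    def test_noise_free_age_polynomial_is_degenerate(self):
        age = np.linspace(60, 88, 12)
        y = 3.0 + 0.5 * age - 0.01 * age**2
        with pytest.raises(ValueError, match="degenerate|zero residual"):
            age_detrend_standardize(_frame(age, {"y": y}))

    def test_sparse_column_left_missing_with_warning(self):
        age = np.linspace(60, 88, 10)
        y = np.full(10, np.nan)
        y[:3] = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning, match="usable rows"):
            model, t = age_detrend_standardize(_frame(age, {"y": y}))
        assert not model.tests["y"].available
        assert t["y"].isna().all()

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(8)
        age = rng.uniform(59, 89, 20)
        y = rng.normal(size=20)
        y[[3, 11]] = np.nan
        _, t = age_detrend_standardize(_frame(age, {"y": y}))
        assert t["y"].isna().to_numpy().tolist() == np.isnan(y).tolist()


class TestResidualizeOnAge:
    def test_matches_oracle(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(59, 89, 30)
        y = rng.normal(size=30)
        _, expect = _ols_oracle(age, y)
        np.testing.assert_allclose(residualize_on_age(y, age), expect, atol=1e-10)

    def test_perfectly_explained_score_has_zero_residuals(self):
        age = np.linspace(60, 88, 15)
        y = 2.0 + 0.3 * age
        np.testing.assert_allclose(residualize_on_age(y, age), 0.0, atol=1e-9)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError, match="pairs"):
            residualize_on_age(np.array([1.0, 2, 3]), np.array([60.0, 70, 80]))


class TestComputeDispersion:
    def test_hand_computed_sample_sd(self, battery):
        # sqrt((100 + 0 + 100) / 2) = 10 across three memory T-scores
        t = pd.DataFrame(
            [[40.0, 50.0, 60.0]], columns=["adas_cog", "lm_i", "lm_ii"]
        )
        disp = compute_dispersion(t, battery, min_fraction=0.1)
        assert disp["isd_bp"].iloc[0] == pytest.approx(10.0)
        assert disp["isd_mem"].iloc[0] == pytest.approx(10.0)

    def test_equal_scores_give_zero_and_single_score_missing(self, battery):
        t = pd.DataFrame(
            [[50.0, 50.0, 50.0, 55.0]],
            columns=["adas_cog", "lm_i", "lm_ii", "tmt_a"],
        )
        disp = compute_dispersion(t, battery, min_fraction=0.1)
        assert disp["isd_mem"].iloc[0] == 0.0
        assert np.isnan(disp["isd_ef"].iloc[0])  # only one executive score

    def test_five_of_fifteen_excluded(self, battery):
        rng = np.random.default_rng(10)
        vals = rng.normal(50, 10, (8, 15))
        t = pd.DataFrame(vals, columns=battery.names)
        t.iloc[0, 5:] = np.nan  # participant completes only 5 tests
        disp = compute_dispersion(t, battery, min_fraction=0.5)
        assert disp["excluded"].iloc[0]
        assert disp["exclusion_reason"].iloc[0] == "insufficient_tests"
        assert not disp["excluded"].iloc[1:].any()

    def test_three_sd_outlier_excluded(self, battery):
        rng = np.random.default_rng(11)
        vals = 50 + rng.normal(0, 1, (30, 15))
        vals[0] = 50 + np.array([300.0, -300] * 7 + [300])  # huge scatter
        t = pd.DataFrame(vals, columns=battery.names)
        disp = compute_dispersion(t, battery)
        assert disp["exclusion_reason"].iloc[0] == "isd_bp_outlier"

    def test_matches_rowwise_oracle_with_missingness(self, battery):
        rng = np.random.default_rng(12)
        for _ in range(50):
            vals = rng.normal(50, 10, (10, 15))
            vals[rng.random(vals.shape) < rng.uniform(0, 0.4)] = np.nan
            t = pd.DataFrame(vals, columns=battery.names)
            disp = compute_dispersion(t, battery)
            for i in range(10):
                row = vals[i][np.isfinite(vals[i])]
                expect = row.std(ddof=1) if row.size >= 2 else np.nan
                got = disp["isd_bp"].iloc[i]
                assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(
                    expect, rel=1e-12
                )

    @given(
        shift=st.floats(-30, 30, allow_nan=False),
        scale=st.floats(0.1, 5, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        battery = default_battery()
        rng = np.random.default_rng(13)
        vals = rng.normal(50, 10, (6, 15))
        t = pd.DataFrame(vals, columns=battery.names)
        base = compute_dispersion(t, battery)["isd_bp"].to_numpy()
        shifted = compute_dispersion(t + shift, battery)["isd_bp"].to_numpy()
        scaled = compute_dispersion(t * scale, battery)["isd_bp"].to_numpy()
        np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-9)


class TestComputeComposites:
    def test_matches_row_mean_then_z_oracle(self, battery):
        rng = np.random.default_rng(14)
        vals = rng.normal(50, 10, (20, 15))
        t = pd.DataFrame(vals, columns=battery.names)
        comp = compute_composites(t, battery)
        mem = t[battery.memory_tests].to_numpy().mean(axis=1)
        expect = (mem - mem.mean()) / mem.std(ddof=1)
        np.testing.assert_allclose(comp["com_mem"].to_numpy(), expect, atol=1e-12)

    def test_antisymmetric_for_two_opposite_rows(self, battery):
        rows = np.tile([40.0, 60.0], (15, 1)).T
        t = pd.DataFrame(rows, columns=battery.names)
        comp = compute_composites(t, battery)
        z = comp["com_mem"].to_numpy()
        assert z[0] == pytest.approx(-z[1])
        assert z.sum() == pytest.approx(0.0, abs=1e-12)

    def test_identical_cohort_is_degenerate(self, battery):
        t = pd.DataFrame(np.full((5, 15), 50.0), columns=battery.names)
        with pytest.raises(ValueError, match="zero variance"):
            compute_composites(t, battery)

    def test_sparse_domain_rows_missing(self, battery):
        rng = np.random.default_rng(15)
        t = pd.DataFrame(rng.normal(50, 10, (6, 15)), columns=battery.names)
        t.loc[0, battery.memory_tests[1:]] = np.nan  # one memory score left
        comp = compute_composites(t, battery)
        assert np.isnan(comp["com_mem"].iloc[0])


class TestCorrelationTable:
    def test_self_and_negated_self(self):
        x = np.array([1.0, 2, 3, 4, 5])
        out = correlation_table({"x": x, "y": x, "z": -x})
        r = {(a, b): v for a, b, v in zip(out.var1, out.var2, out.r)}
        assert r[("x", "y")] == pytest.approx(1.0)
        assert r[("x", "z")] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # cov = 8/4 = 2, sd_x = sd_y = sqrt(10/4): r = 8/sqrt(10*10) = 0.8
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        out = correlation_table({"x": x, "y": y})
        assert out.r.iloc[0] == pytest.approx(0.8)
        assert out.n.iloc[0] == 5

    def test_one_tailed_halves_p_in_hypothesized_direction(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=30)
        y = -x + rng.normal(scale=2, size=30)
        two = correlation_table({"x": x, "y": y})
        one = correlation_table({"x": x, "y": y}, {("x", "y"): "one-negative"})
        assert one.p.iloc[0] == pytest.approx(two.p.iloc[0] / 2)
        wrong = correlation_table({"x": x, "y": y}, {("x", "y"): "one-positive"})
        assert wrong.p.iloc[0] == pytest.approx(1 - two.p.iloc[0] / 2)

    def test_pairwise_complete_n_and_sparse_pair_warning(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([2.0, 1, 4, np.nan, 5])
        z = np.array([np.nan, np.nan, np.nan, 1.0, 2.0])
        with pytest.warns(UserWarning, match="complete"):
            out = correlation_table({"x": x, "y": y, "z": z})
        row_xy = out[(out.var1 == "x") & (out.var2 == "y")].iloc[0]
        assert row_xy.n == 3
        row_xz = out[(out.var1 == "x") & (out.var2 == "z")].iloc[0]
        assert np.isnan(row_xz.r)
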