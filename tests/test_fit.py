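import numpy as np
import pytest

from lineup_mpt import (
    FitError,
    ModelParameters,
    RestrictionSet,
    ValidationError,
    base_restrictions,
    cohens_w,
    compare_nested,
    expected_counts,
    fit_model,
    load_fixture,
    sensitivity_w,
)
from lineup_mpt.model import ConditionSpec, ResponseTable

from _oracles import brute_force_g_squared, min_detectable_w_bisect


def rounded_table(label, params, n_cp, n_ca, fmt="simultaneous"):
    """Counts placed exactly at expected values (requires integer expectations)."""
    cond = ConditionSpec(label, fmt, "morphed", n_cp, n_ca)
    exp = expected_counts(params, cond)
    counts = [round(v, 6) for v in exp]
    assert all(abs(c - round(c)) < 1e-9 for c in counts), "choose n giving integer cells"
    return ResponseTable(cond, *(int(round(c)) for c in counts))


class TestFitModel:
    def test_saturated_single_condition(self, make_response_table):
        # counts on the model manifold (generated at dP=0.4, b=0.2, g=0.5, dA=0.1)
        t = make_response_table("a", (56, 20, 24), (24, 30, 46))
        fit = fit_model([t], RestrictionSet.free(("a",)), seed=0, n_restarts=3)
        assert fit.df == 0
        assert fit.g_squared == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value == 1.0

    def test_counts_at_expected_values_recover_theta(self):
        # dP=0.4, b=0.2, g=0.5, dA=0.1 at k=6 with n chosen so expectations
        # land on integers: probabilities are multiples of 1/120
        params = ModelParameters(0.4, 0.2, 0.5, 0.1, 6)
        t = rounded_table("a", params, 1200, 1200)
        fit = fit_model([t], RestrictionSet.free(("a",)), seed=0, n_restarts=3)
        assert fit.g_squared == pytest.approx(0.0, abs=1e-6)
        for p in ("dP", "b", "g", "dA"):
            assert fit.estimate(p, "a") == pytest.approx(getattr(params, p), abs=1e-4)

    def test_exp2_base_model(self, exp2_tables, base_rs):
        fit = fit_model(exp2_tables, base_rs, seed=0, n_restarts=3)
        assert fit.df == 7
        assert fit.g_squared == pytest.approx(2.55, abs=0.02)
        assert fit.converged
        assert fit.n_total == 3132

    def test_expected_count_conservation(self, exp2_tables, base_rs):
        fit = fit_model(exp2_tables, base_rs, seed=0, n_restarts=2, compute_se=False)
        for table in exp2_tables:
            e = fit.expected[table.condition.label]
            assert e[:3].sum() == pytest.approx(table.condition.n_culprit_present, abs=1e-6)
            assert e[3:].sum() == pytest.approx(table.condition.n_culprit_absent, abs=1e-6)

    def test_restart_seed_reproducible(self, exp2_tables, base_rs):
        f1 = fit_model(exp2_tables, base_rs, seed=7, n_restarts=3)
        f2 = fit_model(exp2_tables, base_rs, seed=7, n_restarts=3)
        assert f1.estimates == f2.estimates
        assert f1.g_squared == f2.g_squared

    def test_restriction_mismatch_raises(self, exp2_tables):
        rs = RestrictionSet.free(("x", "y", "z", "w"))
        with pytest.raises(ValidationError, match="restrictions cover"):
            fit_model(exp2_tables, rs)

    def test_empty_tables_raises(self, base_rs):
        with pytest.raises(ValidationError):
            fit_model([], base_rs)

    def test_boundary_estimate_flagged(self, make_response_table):
        # dA is not identifiable away from 1 when everyone rejects
        t = make_response_table("a", (100, 0, 0), (0, 0, 100))
        with pytest.warns(UserWarning):
            fit = fit_model([t], RestrictionSet.free(("a",)), seed=0, n_restarts=2)
        assert fit.boundary
        for g in fit.boundary:
            assert np.isnan(fit.standard_errors[g])


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_g_squared_matches_grid_polish(self, seed):
        # two conditions, <= 200 observations, all four parameters shared
        rng = np.random.default_rng(seed)
        # interior generating values keep the MLE off the [0, 1] boundary,
        # where logit-scale and clipped-simplex optimisers converge differently
        from lineup_mpt import predict_category_probabilities
        gen = predict_category_probabilities(ModelParameters(0.35, 0.2, 0.55, 0.2, 6))
        counts = np.vstack([
            np.concatenate([rng.multinomial(50, gen.cp()),
                            rng.multinomial(50, gen.ca())])
            for _ in range(2)
        ])
        tables = []
        for i, row in enumerate(counts):
            cond = ConditionSpec(f"c{i}", "simultaneous", "morphed", 50, 50)
            tables.append(ResponseTable(cond, *(int(v) for v in row)))
        rs = (RestrictionSet.free(("c0", "c1"))
              .share("dP", "all").share("b", "all").share("g", "all").share("dA", "all"))
        fit = fit_model(tables, rs, seed=0, n_restarts=5, compute_se=False)

        def slot_map(theta):
            return [tuple(theta)] * 2

        oracle = brute_force_g_squared(counts.astype(float), slot_map, n_free=4)
        assert fit.g_squared == pytest.approx(oracle, abs=1e-4)


class TestCompareNested:
    def test_exp2_published_values(self, exp2_tables, base_rs):
        base = fit_model(exp2_tables, base_rs, seed=0, n_restarts=3, compute_se=False)
        r1 = fit_model(exp2_tables, base_rs.share("b", ["sim_morphed", "sim_nonmorphed"]),
                       seed=0, n_restarts=3, compute_se=False)
        t1 = compare_nested(base, r1)
        assert t1.delta_g_squared == pytest.approx(5.31, abs=0.05)
        assert round(t1.w, 2) == 0.04
        r2 = fit_model(exp2_tables, base_rs.share("b", ["sim_morphed", "seq_morphed"]),
                       seed=0, n_restarts=3, compute_se=False)
        t2 = compare_nested(base, r2)
        assert t2.delta_g_squared == pytest.approx(21.89, abs=0.05)
        assert round(t2.w, 2) == 0.08

    def test_self_comparison_raises(self, exp2_tables, base_rs):
        fit = fit_model(exp2_tables, base_rs, seed=0, n_restarts=2, compute_se=False)
        with pytest.raises(FitError, match="identical"):
            compare_nested(fit, fit)

    def test_non_nested_raises(self, exp2_tables, base_rs):
        base = fit_model(exp2_tables, base_rs, seed=0, n_restarts=2, compute_se=False)
        other_rs = RestrictionSet.free(base_rs.labels).share("b", "all")
        other = fit_model(exp2_tables, other_rs, seed=0, n_restarts=2, compute_se=False)
        with pytest.raises(FitError, match="not nested|identical"):
            compare_nested(base, other)

    def test_additivity_along_restriction_chain(self, exp2_tables, base_rs):
        chain = [
            base_rs,
            base_rs.share("b", ["sim_morphed", "sim_nonmorphed"]),
            base_rs.share("b", ["sim_morphed", "sim_nonmorphed"]).share("b", "all"),
        ]
        fits = [fit_model(exp2_tables, rs, seed=0, n_restarts=3, compute_se=False)
                for rs in chain]
        ab = compare_nested(fits[0], fits[1]).delta_g_squared
        bc = compare_nested(fits[1], fits[2]).delta_g_squared
        ac = compare_nested(fits[0], fits[2]).delta_g_squared
        assert ac == pytest.approx(ab + bc, abs=1e-4)


class TestCohensW:
    def test_published_rounding(self):
        assert round(cohens_w(21.89, 3132), 2) == 0.08
        assert round(cohens_w(12.53, 3040), 2) == 0.06

    def test_zero(self):
        assert cohens_w(0.0, 100) == 0.0

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert cohens_w(-1e-9, 100) == 0.0

    def test_bad_n(self):
        with pytest.raises(ValidationError):
            cohens_w(1.0, 0)


class TestSensitivityW:
    def test_published_sensitivity_values(self):
        assert sensitivity_w(0.05, 0.95, 3132, 1) == pytest.approx(0.064, abs=1e-3)
        assert sensitivity_w(0.05, 0.95, 3040, 1) == pytest.approx(0.065, abs=1e-3)

    @pytest.mark.parametrize("alpha,power,n,df", [
        (0.05, 0.95, 3132, 1), (0.05, 0.8, 500, 1), (0.01, 0.9, 2000, 3),
    ])
    def test_matches_bisection_oracle(self, alpha, power, n, df):
        oracle = min_detectable_w_bisect(alpha, power, n, df)
        assert sensitivity_w(alpha, power, n, df) == pytest.approx(oracle, abs=1e-6)

    def test_power_at_alpha_gives_zero(self):
        assert sensitivity_w(0.05, 0.05, 1000, 1) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            sensitivity_w(0.0, 0.9, 100, 1)
        with pytest.raises(ValidationError):
            sensitivity_w(0.05, 0.9, 0, 1)
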