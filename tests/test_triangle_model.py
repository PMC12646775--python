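"""Any-of-m likelihood identities, triangle designs and stratified MLEs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from contact_triad.triangle_model import (
    _make_logp_grad,
    build_triangle_design,
    connection_probability,
    fit_triangle_model,
    odds_ratios,
    stratified_probability,
    triangle_observation_loglik,
)
from contact_triad.inference_report import PosteriorFit


class TestLink:
    def test_symmetry_at_zero(self):
        assert connection_probability(0.0) == 0.5

    def test_stable_at_large_eta(self):
        p = connection_probability(30.0)
        assert 0 < 1 - p < 1e-12
        # far beyond double resolution: saturates without overflow
        assert connection_probability(700.0) == 1.0
        assert connection_probability(-700.0) == pytest.approx(0.0)

    @given(st.floats(-600, 600))
    @settings(deadline=None)
    def test_antisymmetry(self, eta):
        assert connection_probability(-eta) == pytest.approx(
            1 - connection_probability(eta), abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            connection_probability(float("nan"))


class TestAnyOfMLikelihood:
    @pytest.mark.parametrize("p,m,y,expected", [
        (0.5, 1, True, math.log(0.5)),
        (0.5, 2, True, math.log(0.75)),
        (0.5, 1, False, math.log(0.5)),
        (0.3, 4, True, math.log(1 - 0.7 ** 4)),
        (0.3, 4, False, 4 * math.log(0.7)),
    ])
    def test_closed_forms(self, p, m, y, expected):
        assert triangle_observation_loglik(p, m, y) == pytest.approx(expected)

    def test_monte_carlo_oracle(self):
        """Brute force over Bernoulli draws: P(any of 4 at p=0.3)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        frac = (rng.random((n, 4)) < 0.3).any(axis=1).mean()
        model = math.exp(triangle_observation_loglik(0.3, 4, True))
        se = math.sqrt(model * (1 - model) / n)
        assert abs(frac - model) < 3 * se

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("m", [1, 2, 10])
    def test_monte_carlo_grid(self, p, m):
        rng = np.random.default_rng(7 + m)
        n = 100_000
        frac = (rng.random((n, m)) < p).any(axis=1).mean()
        model = math.exp(triangle_observation_loglik(p, m, True))
        se = math.sqrt(max(model * (1 - model), 1e-12) / n)
        assert abs(frac - model) < max(3 * se, 1e-4)

    def test_probabilities_sum_to_one(self):
        ps = np.array([1e-9, 1e-4, 0.01, 0.3, 0.7, 0.999, 1 - 1e-9])
        for m in (1, 2, 17, 10_000):
            tot = (np.exp(triangle_observation_loglik(ps, m, np.ones_like(ps, bool)))
                   + np.exp(triangle_observation_loglik(ps, m, np.zeros_like(ps, bool))))
            np.testing.assert_allclose(tot, 1.0, atol=1e-12)

    @given(st.floats(1e-6, 1 - 1e-6))
    @settings(deadline=None)
    def test_reduces_to_bernoulli_at_m1(self, p):
        assert triangle_observation_loglik(p, 1, True) == pytest.approx(
            math.log(p), rel=1e-9)
        assert triangle_observation_loglik(p, 1, False) == pytest.approx(
            math.log1p(-p), rel=1e-9)

    def test_monotone_in_p_and_m(self):
        ps = np.linspace(0.01, 0.99, 30)
        pc = np.exp(triangle_observation_loglik(ps, 3, np.ones(30, bool)))
        assert np.all(np.diff(pc) > 0)
        ms = np.arange(1, 40)
        pc = np.exp(triangle_observation_loglik(0.1, ms, np.ones(39, bool)))
        assert np.all(np.diff(pc) > 0)

    def test_finite_at_extreme_p_and_m(self):
        assert np.isfinite(triangle_observation_loglik(1 - 1e-12, 10_000, True))
        assert np.isfinite(triangle_observation_loglik(1 - 1e-12, 10_000, False))
        assert np.isfinite(triangle_observation_loglik(1e-12, 10_000, True))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            triangle_observation_loglik(1.2, 1, True)
        with pytest.raises(ValueError):
            triangle_observation_loglik(0.5, 0, True)


def _mini_triangle_table(settings_pair=("work", "work"), sizes=(1, 1)):
    return pd.DataFrame({
        "participant_id": ["p1"], "visit": [2],
        "primary_event_id": ["a"], "secondary_event_id": ["b"],
        "certainty": ["yes"], "g_primary": [sizes[0]], "g_secondary": [sizes[1]],
        "setting_primary": [settings_pair[0]], "setting_secondary": [settings_pair[1]],
        "touch_primary": ["no"], "touch_secondary": ["no"],
        "frequency_primary": ["4+/wk"], "frequency_secondary": ["<1/wk"],
        "duration_primary": ["60+min"], "duration_secondary": ["60+min"],
        "m": [sizes[0] * sizes[1]], "y": [True]})


def _mini_participants():
    participants = pd.DataFrame({
        "participant_id": ["p1"], "household_id": ["h1"], "visit": [2],
        "age_years": [40], "sex": ["male"], "occupation_raw": ["employed"]})
    households = pd.DataFrame({
        "household_id": ["h1"], "location_id": ["L1"], "household_size": [4],
        "density_at_first_visit": [800.0]})
    return participants, households


class TestDesign:
    def test_participant_only_has_no_contact_columns(self):
        participants, households = _mini_participants()
        d = build_triangle_design(_mini_triangle_table(), participants,
                                  households, "participant_only")
        assert not any(c.startswith(("n_", "same_", "group_", "log_m", "both_"))
                       for c in d.columns)

    def test_same_setting_indicator(self):
        participants, households = _mini_participants()
        d = build_triangle_design(_mini_triangle_table(("work", "work")),
                                  participants, households, "shared_contact")
        i = d.columns.index("same_setting")
        assert d.X[0, i] == 1.0
        d2 = build_triangle_design(_mini_triangle_table(("work", "home")),
                                   participants, households, "shared_contact")
        assert d2.X[0, d2.columns.index("same_setting")] == 0.0

    def test_individual_contacts_group_covariates(self):
        participants, households = _mini_participants()
        d = build_triangle_design(_mini_triangle_table(sizes=(1, 1)),
                                  participants, households, "individual_contact")
        assert d.X[0, d.columns.index("group_contact")] == 0.0
        assert d.X[0, d.columns.index("log_m")] == 0.0
        d2 = build_triangle_design(_mini_triangle_table(sizes=(10, 10)),
                                   participants, households, "individual_contact")
        assert d2.X[0, d2.columns.index("group_contact")] == 1.0
        assert d2.X[0, d2.columns.index("log_m")] == pytest.approx(math.log(100))

    def test_setting_counts_symmetric(self):
        participants, households = _mini_participants()
        d = build_triangle_design(_mini_triangle_table(("work", "home")),
                                  participants, households, "individual_contact")
        assert d.X[0, d.columns.index("n_setting[work]")] == 1.0
        assert d.X[0, d.columns.index("n_setting[home]")] == 1.0

    def test_unknown_spec(self):
        participants, households = _mini_participants()
        with pytest.raises(ValueError):
            build_triangle_design(_mini_triangle_table(), participants,
                                  households, "everything")

    def test_nested_column_sets(self, small_survey, small_triangles):
        _, tables, _ = small_survey
        cols = {}
        for spec in ("participant_only", "individual_contact", "shared_contact"):
            d = build_triangle_design(small_triangles, tables["participant"],
                                      tables["household"], spec)
            cols[spec] = set(d.columns)
        assert cols["participant_only"] < cols["individual_contact"]
        assert cols["individual_contact"] < cols["shared_contact"]


class TestGradient:
    def test_matches_finite_differences(self, small_survey, small_triangles):
        _, tables, _ = small_survey
        d = build_triangle_design(small_triangles.head(300),
                                  tables["participant"], tables["household"],
                                  "shared_contact")
        logp_grad, dim, _ = _make_logp_grad(d)
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.2, dim)
        _, grad = logp_grad(theta)
        eps = 1e-6
        for i in rng.choice(dim, size=12, replace=False):
            e = np.zeros(dim)
            e[i] = eps
            num = (logp_grad(theta + e)[0] - logp_grad(theta - e)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestFit:
    def test_seeded_rerun_identical(self, small_survey, small_triangles, tiny_mcmc):
        _, tables, _ = small_survey
        d = build_triangle_design(small_triangles.head(300),
                                  tables["participant"], tables["household"],
                                  "participant_only")
        f1 = fit_triangle_model(d, tiny_mcmc)
        f2 = fit_triangle_model(d, tiny_mcmc)
        np.testing.assert_array_equal(f1.draws, f2.draws)


class TestStratifiedProbability:
    def _table(self, y, m, stratum):
        return pd.DataFrame({"y": y, "m": m, "stratum": stratum})

    def test_m1_reduces_to_proportion(self):
        y = [True] * 30 + [False] * 70
        df = self._table(y, [1] * 100, ["a"] * 100)
        out = stratified_probability(df, "stratum")
        assert out["p_hat"].iloc[0] == pytest.approx(0.3, abs=1e-6)

    def test_m2_closed_form_inversion(self):
        """With constant m = 2, p̂ = 1 − sqrt(1 − k/n)."""
        y = [True] * 36 + [False] * 64
        df = self._table(y, [2] * 100, ["a"] * 100)
        out = stratified_probability(df, "stratum")
        assert out["p_hat"].iloc[0] == pytest.approx(1 - math.sqrt(0.64),
                                                     abs=1e-6)

    def test_recovered_ordering(self):
        rng = np.random.default_rng(11)
        rows = []
        for stratum, p in (("lo", 0.10), ("hi", 0.20)):
            m = rng.integers(1, 5, size=3000)
            y = rng.random(3000) < -np.expm1(m * np.log1p(-p))
            rows.append(pd.DataFrame({"y": y, "m": m, "stratum": stratum}))
        out = stratified_probability(pd.concat(rows), "stratum").set_index("stratum")
        assert out.loc["lo", "p_hat"] < out.loc["hi", "p_hat"]
        assert out.loc["lo", "p_hat"] == pytest.approx(0.10, abs=0.03)
        assert out.loc["hi", "p_hat"] == pytest.approx(0.20, abs=0.03)

    def test_missing_variable(self):
        with pytest.raises(KeyError):
            stratified_probability(self._table([True], [1], ["a"]), "nope")


class TestOddsRatios:
    def _fit_with_draws(self, values):
        draws = np.tile(np.asarray(values, float), (2, 4, 1))
        return PosteriorFit(model="t", names=["x"], draws=draws,
                            log_likelihood=np.zeros((2, 4, 1)), seed=0, n_obs=1)

    def test_zero_draws(self):
        est, _ = odds_ratios(self._fit_with_draws([0.0]), "x")
        assert est == 1.0

    def test_constant_half(self):
        est, _ = odds_ratios(self._fit_with_draws([math.log(0.5)]), "x")
        assert est == pytest.approx(0.5)
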