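"""Count-model design construction, likelihood and small-scale fits."""

import math

import numpy as np
import pandas as pd
import pytest

from contact_triad.count_model import (
    CountModelParams,
    _make_logp_grad,
    build_count_design,
    count_log_likelihood,
    fit_count_model,
    relative_rates,
)
from contact_triad.inference_report import McmcConfig, PosteriorFit
from contact_triad.synthetic_data import SyntheticConfig, generate_population, generate_contact_diaries
from tests.test_synthetic_data import _interceptonly_count_truth


def _toy_tables():
    households = pd.DataFrame({
        "household_id": ["h1"], "location_id": ["L1"],
        "household_size": [3], "density_at_first_visit": [500.0]})
    participants = pd.DataFrame({
        "participant_id": ["p1", "p2"], "household_id": ["h1", "h1"],
        "visit": [2, 2], "age_years": [30, 40], "sex": ["male", "female"],
        "occupation_raw": ["employed", None]})
    diaries = pd.DataFrame({
        "event_id": ["e1", "e2", "e3"],
        "participant_id": ["p1", "p1", "p2"], "visit": [2, 2, 2],
        "group_size": [3, 5, 2],
        "contact_age_category": ["20-39"] * 3, "age_guess": [pd.NA] * 3,
        "setting": ["home", "work", "home"], "touch": ["no"] * 3,
        "frequency": ["4+/wk"] * 3, "duration": ["60+min"] * 3,
        "repeat_flag": [False] * 3})
    return participants, households, diaries


class TestDesign:
    def test_outcomes_all_vs_extra_household(self):
        participants, households, diaries = _toy_tables()
        all_d = build_count_design(participants, households, diaries, "all")
        extra = build_count_design(participants, households, diaries,
                                   "extra-household")
        # p2 is dropped (missing occupation); p1 has home 3 + work 5
        assert all_d.y.tolist() == [8]
        assert extra.y.tolist() == [5]

    def test_incomplete_covariates_excluded(self):
        participants, households, diaries = _toy_tables()
        d = build_count_design(participants, households, diaries)
        assert d.frame["participant_id"].tolist() == ["p1"]

    def test_unadjusted_single_block(self):
        participants, households, diaries = _toy_tables()
        participants["occupation_raw"] = "employed"
        d = build_count_design(participants, households, diaries,
                               covariates=["age"])
        assert all(c == "intercept" or c.startswith(("age[", "visit["))
                   for c in d.columns)

    def test_unknown_outcome(self):
        participants, households, diaries = _toy_tables()
        with pytest.raises(ValueError):
            build_count_design(participants, households, diaries, "weekend")


class TestLikelihood:
    def test_poisson_closed_forms(self):
        participants, households, diaries = _toy_tables()
        participants = participants.iloc[:1]
        d = build_count_design(participants, households, diaries)
        params = CountModelParams(
            beta=np.zeros(len(d.columns)), u_loc=np.zeros(1),
            u_hh=np.zeros(1), u_part=np.zeros(1), e_obs=np.zeros(1))
        d.y = np.array([0])
        assert count_log_likelihood(params, d)[0] == pytest.approx(-1.0)
        d.y = np.array([2])
        params.beta[0] = math.log(2.0)
        expected = 2 * math.log(2) - 2 - math.log(2)
        assert count_log_likelihood(params, d)[0] == pytest.approx(expected)

    def test_matches_hand_coded_pmf(self, small_survey):
        """Pointwise log-likelihood equals y log μ − μ − log y! to 1e-10."""
        _, tables, _ = small_survey
        d = build_count_design(tables["participant"], tables["household"],
                               tables["contact"])
        rng = np.random.default_rng(0)
        for _ in range(100):
            params = CountModelParams(
                beta=rng.normal(0, 0.3, len(d.columns)),
                u_loc=rng.normal(0, 0.3, d.n_loc),
                u_hh=rng.normal(0, 0.3, d.n_hh),
                u_part=rng.normal(0, 0.3, d.n_part),
                e_obs=rng.normal(0, 0.3, d.n))
            ll = count_log_likelihood(params, d)
            eta = (d.X @ params.beta + params.u_loc[d.loc_idx]
                   + params.u_hh[d.hh_idx] + params.u_part[d.part_idx]
                   + params.e_obs)
            mu = np.exp(eta)
            hand = (d.y * eta - mu
                    - np.array([math.lgamma(v + 1) for v in d.y]))
            np.testing.assert_allclose(ll, hand, rtol=1e-10)

    def test_nonfinite_predictor_rejected(self):
        participants, households, diaries = _toy_tables()
        d = build_count_design(participants, households, diaries)
        params = CountModelParams(
            beta=np.full(len(d.columns), np.nan), u_loc=np.zeros(1),
            u_hh=np.zeros(1), u_part=np.zeros(1), e_obs=np.zeros(d.n))
        with pytest.raises(ValueError):
            count_log_likelihood(params, d)

    def test_gradient_matches_finite_differences(self, small_survey):
        _, tables, _ = small_survey
        d = build_count_design(tables["participant"].head(40),
                               tables["household"], tables["contact"])
        logp_grad, dim, _ = _make_logp_grad(d)
        rng = np.random.default_rng(1)
        theta = rng.normal(0, 0.2, dim)
        _, grad = logp_grad(theta)
        eps = 1e-6
        for i in rng.choice(dim, size=12, replace=False):
            e = np.zeros(dim)
            e[i] = eps
            num = (logp_grad(theta + e)[0] - logp_grad(theta - e)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


def _fit_dataset(seed, sigma_obs=0.5):
    cfg = SyntheticConfig(
        n_locations=3, households_per_location=5, visits=(2,),
        participation_rate=1.0, repeat_rate=0.0, seed=seed,
        count_truth=_interceptonly_count_truth(math.log(8.0),
                                               sigma_obs=sigma_obs))
    pop = generate_population(cfg)
    diaries = generate_contact_diaries(pop, cfg)
    return pop, diaries


class TestFit:
    def test_interceptonly_moment_identity(self):
        """Posterior mean of exp(β0 + σ_obs²/2) tracks the sample mean."""
        pop, diaries = _fit_dataset(21)
        d = build_count_design(pop.participants, pop.households, diaries,
                               covariates=[])
        fit = fit_count_model(d, McmcConfig(chains=2, iterations=400,
                                            warmup=200, seed=3,
                                            max_treedepth=8))
        b0 = fit.draws_for("intercept")
        so = fit.draws_for("sigma_obs")
        implied = float(np.exp(b0 + 0.5 * so ** 2).mean())
        assert implied == pytest.approx(d.y.mean(), rel=0.15)

    def test_seeded_fit_is_deterministic(self, tiny_mcmc):
        pop, diaries = _fit_dataset(22)
        d = build_count_design(pop.participants, pop.households, diaries,
                               covariates=[])
        f1 = fit_count_model(d, tiny_mcmc)
        f2 = fit_count_model(d, tiny_mcmc)
        np.testing.assert_array_equal(f1.draws, f2.draws)
        np.testing.assert_array_equal(f1.log_likelihood, f2.log_likelihood)

    def test_overdispersion_detected(self):
        """σ_obs posterior concentrates away from 0 when truth has
        overdispersion and near 0 when it does not."""
        fits = {}
        for name, so in (("od", 1.0), ("eq", 0.0)):
            cfg = SyntheticConfig(
                n_locations=3, households_per_location=8, visits=(2, 3),
                participation_rate=1.0, repeat_rate=0.0, seed=23,
                count_truth=_interceptonly_count_truth(math.log(8.0),
                                                       sigma_obs=so))
            pop = generate_population(cfg)
            diaries = generate_contact_diaries(pop, cfg)
            d = build_count_design(pop.participants, pop.households, diaries,
                                   covariates=[])
            fit = fit_count_model(d, McmcConfig(chains=2, iterations=400,
                                                warmup=200, seed=4,
                                                max_treedepth=8))
            fits[name] = float(fit.draws_for("sigma_obs").mean())
        assert fits["od"] > 0.5
        assert fits["eq"] < fits["od"] / 2


class TestRelativeRates:
    def _fit_with_draws(self, values):
        draws = np.tile(np.asarray(values, float), (2, 4, 1))
        return PosteriorFit(model="t", names=["x"], draws=draws,
                            log_likelihood=np.zeros((2, 4, 1)), seed=0, n_obs=1)

    def test_zero_draws_give_unit_rate(self):
        est, (lo, hi) = relative_rates(self._fit_with_draws([0.0]), "x")
        assert est == lo == hi == 1.0

    def test_constant_log2(self):
        est, _ = relative_rates(self._fit_with_draws([math.log(2)]), "x")
        assert est == pytest.approx(2.0)

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            relative_rates(self._fit_with_draws([0.0]), "y")
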