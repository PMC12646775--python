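"""Posterior containers, convergence diagnostics, WAIC, descriptive tables.

The two regression modules return a :class:`PosteriorFit`; this module owns
everything computed *from* a fit — rank-normalized split R-hat, bulk/tail
effective sample sizes, WAIC and model ranking — plus the descriptive
survey summaries (stratified contact characteristics, daily-contact
distributions, and the contact decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .survey_data import (
    DEFAULT_MIDPOINTS,
    MidpointConfig,
    derive_occupation_class,
    derive_participant_age_group,
    weekly_contact_minutes,
)

__all__ = [
    "McmcConfig",
    "PosteriorFit",
    "ConvergenceError",
    "gelman_rubin",
    "effective_sample_size",
    "waic",
    "WaicResult",
    "compare_models",
    "descriptive_report",
    "percentage",
    "pooled_total",
    "count_weighted_percentage",
]

#: minimum bulk/tail effective sample size regarded as adequate
ESS_THRESHOLD = 200.0


class ConvergenceError(RuntimeError):
    """Raised when a fit fails its R-hat / ESS checks."""


@dataclass
class McmcConfig:
    """Chains and iteration counts for the NUTS runs.

    Defaults are four chains of 2000 iterations with the first 1000
    discarded as warm-up.  ``test_preset`` is a reduced configuration for
    small synthetic fits.
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")

    @classmethod
    def test_preset(cls, seed: int = 0, chains: int = 2) -> "McmcConfig":
        """Reduced preset for small synthetic fits (shallower trees, fewer
        iterations); the full default remains 4 × 2000/1000."""
        return cls(chains=chains, iterations=500, warmup=250, seed=seed,
                   max_treedepth=8)


class WaicResult(NamedTuple):
    lppd: float
    p_waic: float
    waic: float


def _as_chain_draws(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws of shape (chains, draws)")
    return x


def gelman_rubin(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for one parameter.

    ``draws`` has shape (chains, draws).  Degenerate chains (zero variance
    everywhere) have no defined scale-reduction factor and are reported as
    1.0 by convention; a single chain is an error.
    """
    x = _as_chain_draws(draws)
    if x.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    if np.ptp(x) == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(az.rhat(x))
    return 1.0 if np.isnan(r) else r


class EssResult(NamedTuple):
    bulk: float
    tail: float
    adequate: bool


def effective_sample_size(
    draws: np.ndarray, threshold: float = ESS_THRESHOLD
) -> EssResult:
    """Bulk and tail effective sample size with an adequacy flag.

    Autocorrelation-based (rank-normalized) ESS.  A degenerate constant
    chain carries no information beyond one value per chain and is reported
    as ESS = number of chains (flagged inadequate under any sensible
    threshold).
    """
    x = _as_chain_draws(draws)
    chains = float(x.shape[0])
    if np.ptp(x) == 0.0:
        return EssResult(chains, chains, chains >= threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bulk = float(az.ess(x, method="bulk"))
        tail = float(az.ess(x, method="tail"))
    if np.isnan(bulk):
        bulk = chains
    if np.isnan(tail):
        tail = chains
    return EssResult(bulk, tail, bulk >= threshold and tail >= threshold)


def waic(log_likelihood: np.ndarray) -> WaicResult:
    """Watanabe-Akaike information criterion from pointwise log-likelihoods.

    ``log_likelihood`` is (chains, draws, n_obs) or (draws, n_obs).  Uses
    lppd_i = log mean_s exp(ll_is) via log-sum-exp, p_waic_i = var_s(ll_is)
    (sample variance), and waic = -2 (lppd - p_waic), so lower is better.
    """
    ll = np.asarray(log_likelihood, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, n_obs) matrix with at least 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WaicResult(lppd, p_waic, -2.0 * (lppd - p_waic))


@dataclass
class PosteriorFit:
    """Posterior draws of the reported parameters plus pointwise likelihood.

    ``draws`` holds the retained (post-warmup) draws of the *reported*
    parameters — fixed effects, visit effects and random-effect SDs — with
    shape (chains, kept, len(names)); latent per-unit effects are used for
    the pointwise log-likelihood and then dropped.
    """

    model: str
    names: list[str]
    draws: np.ndarray
    log_likelihood: np.ndarray
    seed: int
    n_obs: int
    meta: dict = field(default_factory=dict)

    def draws_for(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise KeyError(f"unknown parameter {name!r}; have {self.names}")
        return self.draws[:, :, self.names.index(name)]

    def diagnostics(self) -> pd.DataFrame:
        """Per-parameter R-hat, bulk/tail ESS and flags."""
        rows = []
        for i, name in enumerate(self.names):
            x = self.draws[:, :, i]
            degenerate = np.ptp(x) == 0.0
            ess = effective_sample_size(x)
            rows.append({
                "parameter": name,
                "rhat": gelman_rubin(x) if x.shape[0] >= 2 else np.nan,
                "ess_bulk": ess.bulk,
                "ess_tail": ess.tail,
                "ess_adequate": ess.adequate,
                "degenerate": degenerate,
            })
        return pd.DataFrame(rows).set_index("parameter")

    def waic(self) -> WaicResult:
        return waic(self.log_likelihood)

    def check_convergence(self, rhat_max: float = 1.05,
                          ess_min: float = ESS_THRESHOLD) -> None:
        diag = self.diagnostics()
        bad = diag[(diag["rhat"] > rhat_max)
                   | (diag["ess_bulk"] < ess_min)
                   | (diag["ess_tail"] < ess_min)]
        if not bad.empty:
            raise ConvergenceError(
                f"{self.model}: convergence checks failed\n{bad.to_string()}")

    def exp_summary(self, term: str) -> tuple[float, tuple[float, float]]:
        """Posterior mean and central 95% interval of exp(coefficient)."""
        x = np.exp(self.draws_for(term).ravel())
        return float(x.mean()), (float(np.quantile(x, 0.025)),
                                 float(np.quantile(x, 0.975)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            x = self.draws_for(name).ravel()
            rows.append({
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
            })
        return pd.DataFrame(rows).set_index("parameter")


def compare_models(fits: Mapping[str, PosteriorFit]) -> pd.DataFrame:
    """Rank fits by WAIC (ascending); ties broken by name for stability.

    All fits must score the same observation set.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {name: f.n_obs for name, f in fits.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"fits score different observation sets: {n_obs}")
    rows = []
    for name, f in fits.items():
        w = f.waic()
        rows.append({"model": name, "lppd": w.lppd, "p_waic": w.p_waic,
                     "waic": w.waic})
    out = pd.DataFrame(rows).sort_values(["waic", "model"]).reset_index(drop=True)
    out["d_waic"] = out["waic"] - out["waic"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# Descriptive reporting (survey-table summaries)
# ---------------------------------------------------------------------------

def percentage(part: float, whole: float) -> float:
    """Percentage of ``whole`` represented by ``part``."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def pooled_total(counts) -> int:
    """Total across strata (e.g. per-visit counts pooled over visits)."""
    return int(np.sum(np.asarray(list(counts), dtype=np.int64)))


def count_weighted_percentage(counts, percentages) -> float:
    """Pool per-stratum percentages weighting by stratum size."""
    c = np.asarray(list(counts), dtype=float)
    p = np.asarray(list(percentages), dtype=float)
    if c.shape != p.shape or c.sum() <= 0:
        raise ValueError("counts and percentages must align, counts positive")
    return float(np.sum(c * p) / c.sum())


GROUP_SIZE_BANDS = ((1, 1, "1"), (2, 5, "2-5"), (6, 10, "6-10"),
                    (11, 20, "11-20"), (21, np.inf, "21+"))
WEEKLY_TIME_BANDS = ((0, 30, "<30 min/wk"), (30, 150, "30-149 min/wk"),
                     (150, np.inf, "150+ min/wk"))
CONTACT_AGE_BANDS = ("2-4", "5-19", "20-39", "40-64", "65+", "unknown")


def _band(values, bands):
    out = np.empty(len(values), dtype=object)
    v = np.asarray(values, dtype=float)
    for lo, hi, label in bands:
        out[(v >= lo) & (v <= hi)] = label
    return out


def descriptive_report(
    tables: Mapping[str, pd.DataFrame],
    midpoints: MidpointConfig = DEFAULT_MIDPOINTS,
) -> dict[str, pd.DataFrame]:
    """Stratified descriptive summaries of a survey-table bundle.

    Returns three tables:

    * ``contact_characteristics`` — total reported contacts (events weighted
      by group size, repeats excluded) broken down by group-size band,
      setting, touch, frequency and duration, with column percentages within
      each participant age group plus a pooled "total" column;
    * ``daily_contacts`` — median / IQR / mean daily reported contacts per
      participant-visit, stratified by age group, sex, occupation class and
      household size;
    * ``decomposition`` — within-age-group percentage composition of
      contacts by setting, group-size band and weekly contact minutes.
    """
    participants = tables["participant"].copy()
    contacts = tables["contact"]
    participants["age_group"] = participants["age_years"].map(
        derive_participant_age_group)

    ev = contacts[~contacts["repeat_flag"]].merge(
        participants[["participant_id", "visit", "age_group"]],
        on=["participant_id", "visit"], how="left")
    ev = ev.copy()
    ev["n_contacts"] = ev["group_size"].astype(int)
    ev["group_size_band"] = _band(ev["group_size"], GROUP_SIZE_BANDS)
    known = ev["frequency"].notna() & ev["duration"].notna()
    minutes = np.full(len(ev), np.nan)
    minutes[np.asarray(known)] = [
        weekly_contact_minutes(f, d, midpoints)
        for f, d in zip(ev.loc[known, "frequency"], ev.loc[known, "duration"])]
    ev["weekly_minutes_band"] = _band(np.nan_to_num(minutes, nan=-1.0),
                                      WEEKLY_TIME_BANDS)

    char_rows = []
    for characteristic in ("group_size_band", "setting", "touch",
                           "frequency", "duration"):
        for age_group, sub in [("total", ev)] + list(ev.groupby("age_group")):
            total = sub["n_contacts"].sum()
            counts = sub.groupby(characteristic)["n_contacts"].sum()
            for level, count in counts.items():
                char_rows.append({
                    "characteristic": characteristic,
                    "level": level,
                    "age_group": age_group,
                    "contacts": int(count),
                    "percent": percentage(count, total) if total else np.nan,
                })
    contact_characteristics = pd.DataFrame(char_rows)

    totals = (ev.groupby(["participant_id", "visit"])["n_contacts"].sum()
              .rename("daily_contacts").reset_index())
    pv = participants.merge(totals, on=["participant_id", "visit"], how="left")
    pv["daily_contacts"] = pv["daily_contacts"].fillna(0).astype(int)
    pv = pv.merge(tables["household"][["household_id", "household_size"]],
                  on="household_id", how="left")
    pv["occupation"] = pv["occupation_raw"].map(derive_occupation_class)

    daily_rows = []
    for stratum in ("age_group", "sex", "occupation", "household_size"):
        for level, sub in pv.groupby(stratum):
            x = sub["daily_contacts"]
            daily_rows.append({
                "stratum": stratum, "level": level, "n": len(sub),
                "median": float(x.median()),
                "q25": float(x.quantile(0.25)),
                "q75": float(x.quantile(0.75)),
                "mean": float(x.mean()),
            })
    daily_contacts = pd.DataFrame(daily_rows)

    decomp_rows = []
    for characteristic in ("setting", "group_size_band", "weekly_minutes_band"):
        for age_group, sub in ev.groupby("age_group"):
            total = sub["n_contacts"].sum()
            counts = sub.groupby(characteristic)["n_contacts"].sum()
            for level, count in counts.items():
                decomp_rows.append({
                    "age_group": age_group,
                    "characteristic": characteristic,
                    "level": level,
                    "percent": percentage(count, total) if total else np.nan,
                })
    decomposition = pd.DataFrame(decomp_rows)

    return {
        "contact_characteristics": contact_characteristics,
        "daily_contacts": daily_contacts,
        "decomposition": decomposition,
    }
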