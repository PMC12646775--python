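"""Hierarchical overdispersed-Poisson regression of daily contact counts.

The outcome is each participant-visit's total reported contacts (or the
total excluding home-setting events).  Counts are modelled as Poisson with

    log mean = x'β + γ_visit + u_location + u_household + u_participant + e_obs

where the four normal random effects act at location, household, participant
and observation level; the observation-level effect makes the marginal
distribution lognormal-Poisson and captures the overdispersion of daily
contact counts (the "quasi-Poisson" of the survey literature, realized as a
fully generative model).  Fitting is Bayesian via NUTS with non-centred
random effects, weakly-informative priors (Normal(0, 5) intercept,
Normal(0, 2.5) slopes, half-Normal(0, 1) SDs), and effects are reported as
relative rates exp(β) with central 95% credible intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson

from . import _design
from ._nuts import sample_nuts
from .inference_report import McmcConfig, PosteriorFit

__all__ = [
    "CountDesign",
    "CountModelParams",
    "build_count_design",
    "count_log_likelihood",
    "fit_count_model",
    "relative_rates",
]

log = logging.getLogger(__name__)

_SIGMA_NAMES = ("sigma_loc", "sigma_hh", "sigma_part", "sigma_obs")


@dataclass
class CountDesign:
    """Encoded observations for the contact-count model."""

    y: np.ndarray                 # (n,) nonnegative counts
    X: np.ndarray                 # (n, p) fixed effects incl. intercept
    columns: list[str]
    loc_idx: np.ndarray
    hh_idx: np.ndarray
    part_idx: np.ndarray
    n_loc: int
    n_hh: int
    n_part: int
    outcome: str
    centers: dict[str, float] = field(default_factory=dict)
    frame: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class CountModelParams:
    """One parameter configuration (e.g. a posterior draw or truth)."""

    beta: np.ndarray              # aligned with CountDesign.columns
    u_loc: np.ndarray
    u_hh: np.ndarray
    u_part: np.ndarray
    e_obs: np.ndarray
    sigma_loc: float = 0.0
    sigma_hh: float = 0.0
    sigma_part: float = 0.0
    sigma_obs: float = 0.0


def build_count_design(
    participants: pd.DataFrame,
    households: pd.DataFrame,
    diaries: pd.DataFrame,
    outcome: str = "all",
    covariates="all",
) -> CountDesign:
    """Assemble the count-model design from validated survey tables.

    ``outcome="all"`` sums group sizes over all non-repeat events of the
    participant-visit; ``"extra-household"`` excludes home-setting events
    (transport/shopping and other non-home settings count).  Rows with
    incomplete covariates are dropped (complete-case).  ``covariates``
    selects adjustment blocks ("all", or e.g. ``["age"]`` for an unadjusted
    age-only model); visit fixed effects are always included.
    """
    if outcome not in ("all", "extra-household"):
        raise ValueError(f"unknown outcome {outcome!r}")
    ev = diaries[~diaries["repeat_flag"]]
    if outcome == "extra-household":
        ev = ev[ev["setting"] != "home"]
    totals = (ev.groupby(["participant_id", "visit"])["group_size"].sum()
              .rename("y").reset_index())

    pv, complete = _design.participant_frame(participants, households)
    pv = pv.merge(totals, on=["participant_id", "visit"], how="left")
    pv["y"] = pv["y"].fillna(0).astype(int)
    pv = pv[np.asarray(complete)].reset_index(drop=True)
    if pv.empty:
        raise ValueError("no complete-case observations in the design")

    X, names, centers = _design.encode_fixed_effects(pv, covariates)
    idx = _design.group_indices(pv)
    return CountDesign(
        y=pv["y"].to_numpy(np.int64), X=X, columns=names,
        loc_idx=idx["loc_idx"], hh_idx=idx["hh_idx"], part_idx=idx["part_idx"],
        n_loc=idx["n_loc"], n_hh=idx["n_hh"], n_part=idx["n_part"],
        outcome=outcome, centers=centers, frame=pv,
    )


def count_log_likelihood(params: CountModelParams, design: CountDesign) -> np.ndarray:
    """Pointwise Poisson log-pmf at the mean implied by ``params``."""
    eta = (
        design.X @ params.beta
        + params.u_loc[design.loc_idx]
        + params.u_hh[design.hh_idx]
        + params.u_part[design.part_idx]
        + params.e_obs
    )
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return poisson.logpmf(design.y, np.exp(eta))


def _make_logp_grad(design: CountDesign):
    X, y = design.X, design.y.astype(float)
    n, p = X.shape
    nl, nh, npart = design.n_loc, design.n_hh, design.n_part
    li, hi_, pi = design.loc_idx, design.hh_idx, design.part_idx
    prior_var = np.full(p, 2.5 ** 2)
    prior_var[design.columns.index("intercept")] = 5.0 ** 2

    s_beta = slice(0, p)
    s_zl = slice(p, p + nl)
    s_zh = slice(p + nl, p + nl + nh)
    s_zp = slice(p + nl + nh, p + nl + nh + npart)
    s_zo = slice(p + nl + nh + npart, p + nl + nh + npart + n)
    s_tau = slice(p + nl + nh + npart + n, p + nl + nh + npart + n + 4)
    dim = s_tau.stop

    def logp_grad(theta: np.ndarray):
        beta = theta[s_beta]
        zl, zh, zp, zo = theta[s_zl], theta[s_zh], theta[s_zp], theta[s_zo]
        tau = np.clip(theta[s_tau], -15.0, 10.0)
        sig = np.exp(tau)
        eta = (X @ beta + sig[0] * zl[li] + sig[1] * zh[hi_]
               + sig[2] * zp[pi] + sig[3] * zo)
        mu = np.exp(np.minimum(eta, 80.0))  # cap keeps gradients finite
        logp = (
            float(y @ eta - mu.sum())
            - 0.5 * float(beta @ (beta / prior_var))
            - 0.5 * float(zl @ zl + zh @ zh + zp @ zp + zo @ zo)
            - 0.5 * float(sig @ sig) + float(tau.sum())
        )
        resid = y - mu
        g = np.empty(dim)
        g[s_beta] = X.T @ resid - beta / prior_var
        bl = np.bincount(li, weights=resid, minlength=nl)
        bh = np.bincount(hi_, weights=resid, minlength=nh)
        bp = np.bincount(pi, weights=resid, minlength=npart)
        g[s_zl] = sig[0] * bl - zl
        g[s_zh] = sig[1] * bh - zh
        g[s_zp] = sig[2] * bp - zp
        g[s_zo] = sig[3] * resid - zo
        g[s_tau] = np.array([
            sig[0] * (zl @ bl), sig[1] * (zh @ bh),
            sig[2] * (zp @ bp), sig[3] * (zo @ resid),
        ]) - sig * sig + 1.0
        return logp, g

    slices = {"beta": s_beta, "z_loc": s_zl, "z_hh": s_zh, "z_part": s_zp,
              "z_obs": s_zo, "tau": s_tau}
    return logp_grad, dim, slices


def fit_count_model(design: CountDesign, config: McmcConfig) -> PosteriorFit:
    """Sample the posterior of the contact-count model with NUTS.

    Returns a :class:`PosteriorFit` reporting the fixed effects (including
    visit effects) and the four random-effect SDs, with the pointwise
    Poisson log-likelihood retained for WAIC.
    """
    logp_grad, dim, slices = _make_logp_grad(design)
    init = np.zeros(dim)
    init[0] = float(np.log(design.y.mean() + 0.5))
    init[slices["tau"]] = np.log(0.5)

    draws, stats = sample_nuts(
        logp_grad, init, chains=config.chains, iterations=config.iterations,
        warmup=config.warmup, seed=config.seed,
        max_treedepth=config.max_treedepth, target_accept=config.target_accept)
    chains, kept, _ = draws.shape
    if stats.divergences.sum() > 0:
        log.warning("count model: %d divergent transitions post-warmup",
                    int(stats.divergences.sum()))

    # pointwise log-likelihood (chains, kept, n) for WAIC
    flat = draws.reshape(chains * kept, dim)
    X, y = design.X, design.y.astype(float)
    lgamma = gammaln(y + 1.0)
    ll = np.empty((chains * kept, design.n))
    for start in range(0, flat.shape[0], 256):
        th = flat[start:start + 256]
        sig = np.exp(th[:, slices["tau"]])
        eta = (
            th[:, slices["beta"]] @ X.T
            + sig[:, [0]] * th[:, slices["z_loc"]][:, design.loc_idx]
            + sig[:, [1]] * th[:, slices["z_hh"]][:, design.hh_idx]
            + sig[:, [2]] * th[:, slices["z_part"]][:, design.part_idx]
            + sig[:, [3]] * th[:, slices["z_obs"]]
        )
        ll[start:start + 256] = y * eta - np.exp(eta) - lgamma

    p = len(design.columns)
    reported = np.concatenate([
        draws[:, :, :p],
        np.exp(draws[:, :, slices["tau"]]),
    ], axis=2)
    names = list(design.columns) + list(_SIGMA_NAMES)
    return PosteriorFit(
        model=f"counts[{design.outcome}]",
        names=names,
        draws=reported,
        log_likelihood=ll.reshape(chains, kept, design.n),
        seed=config.seed,
        n_obs=design.n,
        meta={
            "outcome": design.outcome,
            "centers": design.centers,
            "divergences": int(stats.divergences.sum()),
            "step_size": stats.step_size.tolist(),
        },
    )


def relative_rates(fit: PosteriorFit, term: str) -> tuple[float, tuple[float, float]]:
    """Relative rate exp(β) for a term: posterior mean and 95% interval."""
    return fit.exp_summary(term)
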