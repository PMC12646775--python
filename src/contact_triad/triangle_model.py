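"""Hierarchical logistic models of triangle connectedness with the
group-aware "any-of-m" likelihood.

A potential contact triangle whose primary and secondary events have group
sizes g₁ and g₂ stands for m = g₁·g₂ underlying person-level triangles.
Each underlying triangle is connected independently with probability
p = logit⁻¹(η); the survey only observes whether *any* of them is, so the
observation-level likelihood is

    y = 1 (connected):      P = 1 − (1 − p)^m
    y = 0 (not connected):  P = (1 − p)^m

which reduces to ordinary Bernoulli-logistic at m = 1.  η carries fixed
effects for one of three strictly nested covariate sets —

* ``participant_only``: participant and household characteristics (age
  group, sex, log household size, occupation, log10 density) plus visit;
* ``individual_contact``: + characteristics of the two contact events
  (symmetric per-pair counts of setting / frequency / duration / touch
  levels), an any-group indicator and log m;
* ``shared_contact``: + indicators for shared attributes of the pair (same
  setting, same frequency, same duration, both involve touch)

— and normal random effects at location, household and participant level.
Priors and sampling match the count model (NUTS, non-centred effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_expit

from . import _design
from ._nuts import sample_nuts
from .inference_report import McmcConfig, PosteriorFit

__all__ = [
    "MODEL_SPECIFICATIONS",
    "TriangleDesign",
    "connection_probability",
    "triangle_observation_loglik",
    "build_triangle_design",
    "fit_triangle_model",
    "odds_ratios",
    "stratified_probability",
]

log = logging.getLogger(__name__)

#: the three nested specifications, smallest first
MODEL_SPECIFICATIONS = ("participant_only", "individual_contact", "shared_contact")

_P_FLOOR = 1e-12  # clamp for p inside the likelihood, guards log1p at the edges

_SIGMA_NAMES = ("sigma_loc", "sigma_hh", "sigma_part")


def connection_probability(linear_predictor) -> np.ndarray:
    """Inverse-logit link, numerically stable for |η| up to ~700."""
    eta = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return expit(eta)


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log σ(x) = min(x, 0) − log1p(e^−|x|); same values as log_expit but
    built from SIMD-friendly primitives (hot path of the sampler)."""
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x < 0, stable near both 0 and -inf."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < -np.log(2.0)
    out[small] = np.log1p(-np.exp(x[small]))
    out[~small] = np.log(-np.expm1(x[~small]))
    return out


def triangle_observation_loglik(p, m, y) -> np.ndarray:
    """Log-likelihood of one (or many) potential-triangle observations.

    ``p`` is the per-underlying-triangle connection probability in (0, 1)
    (clamped to [1e-12, 1-1e-12]), ``m`` the underlying-triangle count and
    ``y`` the observed connectedness.  Vectorized over all arguments.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p must lie in [0, 1]")
    if np.any(m < 1):
        raise ValueError("m must be >= 1")
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    log_none = m * np.log1p(-p)          # log (1-p)^m
    out = np.where(y, _log1mexp(log_none), log_none)
    return out if out.ndim else float(out)


def build_triangle_design(
    triangles: pd.DataFrame,
    participants: pd.DataFrame,
    households: pd.DataFrame,
    spec: str = "shared_contact",
):
    """Design matrix for one nested specification on a trimmed triangle table.

    Contact-level attributes enter symmetrically in the unordered pair: for
    each categorical attribute the design counts how many of the two events
    carry each non-reference level (references: social setting, <1/wk
    frequency, <10 min duration).  Rows with incomplete participant
    covariates are dropped (complete-case).
    """
    if spec not in MODEL_SPECIFICATIONS:
        raise ValueError(f"unknown specification {spec!r}; "
                         f"choose from {MODEL_SPECIFICATIONS}")
    pv, complete = _design.participant_frame(participants, households)
    pv = pv[np.asarray(complete)]
    tri = triangles.merge(pv, on=["participant_id", "visit"], how="inner")
    if tri.empty:
        raise ValueError("no complete-case triangles in the design")
    tri = tri.reset_index(drop=True)

    X, names, centers = _design.encode_fixed_effects(tri, "all")

    extra_cols: list[np.ndarray] = []
    extra_names: list[str] = []
    if spec in ("individual_contact", "shared_contact"):
        pair = lambda attr, level: (
            (tri[f"{attr}_primary"] == level).to_numpy(float)
            + (tri[f"{attr}_secondary"] == level).to_numpy(float))
        for level in ("home", "work", "school", "other"):  # ref: social
            extra_cols.append(pair("setting", level))
            extra_names.append(f"n_setting[{level}]")
        for level in ("1-3/wk", "4+/wk"):                  # ref: <1/wk
            extra_cols.append(pair("frequency", level))
            extra_names.append(f"n_frequency[{level}]")
        for level in ("10-59min", "60+min"):               # ref: <10min
            extra_cols.append(pair("duration", level))
            extra_names.append(f"n_duration[{level}]")
        extra_cols.append(pair("touch", "yes"))
        extra_names.append("n_touch")
        m = tri["m"].to_numpy(float)
        extra_cols.append(((tri["g_primary"] > 1) | (tri["g_secondary"] > 1))
                          .to_numpy(float))
        extra_names.append("group_contact")
        extra_cols.append(np.log(m))
        extra_names.append("log_m")
    if spec == "shared_contact":
        same = lambda attr: (tri[f"{attr}_primary"] == tri[f"{attr}_secondary"]
                             ).to_numpy(float)
        extra_cols.append(same("setting"))
        extra_names.append("same_setting")
        extra_cols.append(same("frequency"))
        extra_names.append("same_frequency")
        extra_cols.append(same("duration"))
        extra_names.append("same_duration")
        extra_cols.append(((tri["touch_primary"] == "yes")
                           & (tri["touch_secondary"] == "yes")).to_numpy(float))
        extra_names.append("both_touch")
    if extra_cols:
        X = np.column_stack([X] + extra_cols)
        names = names + extra_names

    idx = _design.group_indices(tri)
    return TriangleDesign(
        y=tri["y"].to_numpy(bool), m=tri["m"].to_numpy(np.int64),
        X=X, columns=names,
        loc_idx=idx["loc_idx"], hh_idx=idx["hh_idx"], part_idx=idx["part_idx"],
        n_loc=idx["n_loc"], n_hh=idx["n_hh"], n_part=idx["n_part"],
        spec=spec, centers=centers, frame=tri,
    )


@dataclass
class TriangleDesign:
    """Encoded potential triangles for one nested specification."""

    y: np.ndarray
    m: np.ndarray
    X: np.ndarray
    columns: list[str]
    loc_idx: np.ndarray
    hh_idx: np.ndarray
    part_idx: np.ndarray
    n_loc: int
    n_hh: int
    n_part: int
    spec: str
    centers: dict[str, float] = field(default_factory=dict)
    frame: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.y.shape[0]


def _pointwise_ll_and_grad(eta: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Any-of-m log-likelihood and its derivative w.r.t. η, vectorized."""
    p = expit(eta)
    log_none = m * log_expit(-eta)       # m log(1-p), always <= 0
    ll = np.where(y, _log1mexp(np.minimum(log_none, -1e-300)), log_none)
    # d/dη: y=0 -> -m p ;  y=1 -> m p (1-P)/P with P = 1 - (1-p)^m,
    # evaluated in log space so the η -> -inf limit (slope 1) stays finite
    log_dll_y1 = np.log(m) + log_expit(eta) + log_none - np.where(y, ll, 0.0)
    dll = np.where(y, np.exp(log_dll_y1), -m * p)
    return ll, dll


def _make_logp_grad(design: TriangleDesign):
    X, y, m = design.X, design.y, design.m.astype(float)
    n, p_dim = X.shape
    nl, nh, npart = design.n_loc, design.n_hh, design.n_part
    li, hi_, pi = design.loc_idx, design.hh_idx, design.part_idx
    prior_var = np.full(p_dim, 2.5 ** 2)
    prior_var[design.columns.index("intercept")] = 5.0 ** 2

    # split rows by outcome once: the two likelihood branches never mix
    i1 = np.flatnonzero(y)
    i0 = np.flatnonzero(~y)
    m1, m0 = m[i1], m[i0]
    log_m1 = np.log(m1)

    s_beta = slice(0, p_dim)
    s_zl = slice(p_dim, p_dim + nl)
    s_zh = slice(p_dim + nl, p_dim + nl + nh)
    s_zp = slice(p_dim + nl + nh, p_dim + nl + nh + npart)
    s_tau = slice(p_dim + nl + nh + npart, p_dim + nl + nh + npart + 3)
    dim = s_tau.stop

    def logp_grad(theta: np.ndarray):
        beta = theta[s_beta]
        zl, zh, zp = theta[s_zl], theta[s_zh], theta[s_zp]
        tau = np.clip(theta[s_tau], -15.0, 10.0)
        sig = np.exp(tau)
        eta = X @ beta + sig[0] * zl[li] + sig[1] * zh[hi_] + sig[2] * zp[pi]
        le_neg = _log_sigmoid(-eta)      # log(1-p)
        le_pos = eta + le_neg            # log p
        # y = 0: ll = m log(1-p), d/dη = -m p
        log_none0 = m0 * le_neg[i0]
        dll0 = -m0 * np.exp(le_pos[i0])
        # y = 1: ll = log(1 - (1-p)^m), d/dη in log space (finite at η→-∞)
        log_none1 = np.minimum(m1 * le_neg[i1], -1e-300)
        ll1 = _log1mexp(log_none1)
        dll1 = np.exp(log_m1 + le_pos[i1] + log_none1 - ll1)
        dll = np.empty(n)
        dll[i1], dll[i0] = dll1, dll0
        logp = (
            float(log_none0.sum()) + float(ll1.sum())
            - 0.5 * float(beta @ (beta / prior_var))
            - 0.5 * float(zl @ zl + zh @ zh + zp @ zp)
            - 0.5 * float(sig @ sig) + float(tau.sum())
        )
        g = np.empty(dim)
        g[s_beta] = X.T @ dll - beta / prior_var
        bl = np.bincount(li, weights=dll, minlength=nl)
        bh = np.bincount(hi_, weights=dll, minlength=nh)
        bp = np.bincount(pi, weights=dll, minlength=npart)
        g[s_zl] = sig[0] * bl - zl
        g[s_zh] = sig[1] * bh - zh
        g[s_zp] = sig[2] * bp - zp
        g[s_tau] = np.array([
            sig[0] * (zl @ bl), sig[1] * (zh @ bh), sig[2] * (zp @ bp),
        ]) - sig * sig + 1.0
        return logp, g

    slices = {"beta": s_beta, "z_loc": s_zl, "z_hh": s_zh, "z_part": s_zp,
              "tau": s_tau}
    return logp_grad, dim, slices


def fit_triangle_model(design: TriangleDesign, config: McmcConfig) -> PosteriorFit:
    """Sample the posterior of one nested triangle specification with NUTS."""
    logp_grad, dim, slices = _make_logp_grad(design)
    init = np.zeros(dim)
    init[slices["tau"]] = np.log(0.5)

    draws, stats = sample_nuts(
        logp_grad, init, chains=config.chains, iterations=config.iterations,
        warmup=config.warmup, seed=config.seed,
        max_treedepth=config.max_treedepth, target_accept=config.target_accept)
    chains, kept, _ = draws.shape
    if stats.divergences.sum() > 0:
        log.warning("triangle model %s: %d divergent transitions post-warmup",
                    design.spec, int(stats.divergences.sum()))

    flat = draws.reshape(chains * kept, dim)
    X = design.X
    mf = design.m.astype(float)
    ll = np.empty((chains * kept, design.n))
    for start in range(0, flat.shape[0], 256):
        th = flat[start:start + 256]
        sig = np.exp(th[:, slices["tau"]])
        eta = (
            th[:, slices["beta"]] @ X.T
            + sig[:, [0]] * th[:, slices["z_loc"]][:, design.loc_idx]
            + sig[:, [1]] * th[:, slices["z_hh"]][:, design.hh_idx]
            + sig[:, [2]] * th[:, slices["z_part"]][:, design.part_idx]
        )
        ll[start:start + 256], _ = _pointwise_ll_and_grad(eta, mf, design.y)

    p_dim = len(design.columns)
    reported = np.concatenate([
        draws[:, :, :p_dim],
        np.exp(draws[:, :, slices["tau"]]),
    ], axis=2)
    names = list(design.columns) + list(_SIGMA_NAMES)
    return PosteriorFit(
        model=f"triangles[{design.spec}]",
        names=names,
        draws=reported,
        log_likelihood=ll.reshape(chains, kept, design.n),
        seed=config.seed,
        n_obs=design.n,
        meta={
            "spec": design.spec,
            "centers": design.centers,
            "divergences": int(stats.divergences.sum()),
            "step_size": stats.step_size.tolist(),
        },
    )


def odds_ratios(fit: PosteriorFit, term: str) -> tuple[float, tuple[float, float]]:
    """Odds ratio exp(β) for a term: posterior mean and 95% interval."""
    return fit.exp_summary(term)


def stratified_probability(
    triangles: pd.DataFrame, stratum_variable: str
) -> pd.DataFrame:
    """Per-stratum connection probability from unadjusted any-of-m fits.

    For each level of ``stratum_variable`` the per-underlying-triangle
    probability p̂ is the maximum-likelihood estimate under the any-of-m
    likelihood with a stratum intercept only (no hierarchy) — the
    group-size-aware analogue of a stratified proportion.  Empty strata are
    excluded with a warning.
    """
    if stratum_variable not in triangles.columns:
        raise KeyError(f"stratum variable {stratum_variable!r} not in table")
    rows = []
    for level, sub in triangles.groupby(stratum_variable, dropna=True):
        y = sub["y"].to_numpy(bool)
        m = sub["m"].to_numpy(float)
        if len(sub) == 0:
            log.warning("stratum %r is empty; excluded", level)
            continue

        def nll(eta: float) -> float:
            return -float(np.sum(triangle_observation_loglik(expit(eta), m, y)))

        if y.all():
            p_hat = 1.0
        elif not y.any():
            p_hat = 0.0
        else:
            res = minimize_scalar(nll, bounds=(-30.0, 30.0), method="bounded",
                                  options={"xatol": 1e-10})
            p_hat = float(expit(res.x))
        rows.append({stratum_variable: level, "n": len(sub),
                     "connected": int(y.sum()), "p_hat": p_hat})
    return pd.DataFrame(rows)
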