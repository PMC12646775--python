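"""Shared covariate encoding for the two hierarchical regression models.

Both models adjust for the same participant- and household-level covariates
(age group, sex, log household size, occupation class, log10 population
density) plus visit fixed effects, with reference levels age 36-45, male and
employed.  Continuous covariates are centred at the sample mean of the
design rows; effects on density are therefore per 10-fold increase.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .survey_data import (
    PARTICIPANT_AGE_GROUPS,
    derive_occupation_class,
    derive_participant_age_group,
)

AGE_REFERENCE = "36-45"
OCCUPATION_REFERENCE = "employed"

log = logging.getLogger(__name__)


def participant_frame(participants: pd.DataFrame,
                      households: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Participant-visit rows with derived covariates and a complete-case mask."""
    pv = participants.merge(households, on="household_id", how="left")
    pv["age_group"] = pv["age_years"].map(derive_participant_age_group)
    pv["occupation"] = pv["occupation_raw"].map(derive_occupation_class)
    complete = (
        (pv["age_group"] != "unknown")
        & pv["sex"].isin(["male", "female"])
        & (pv["occupation"] != "unknown")
        & pv["density_at_first_visit"].notna()
        & (pv["density_at_first_visit"] > 0)
        & pv["household_size"].notna()
    )
    dropped = int((~complete).sum())
    if dropped:
        log.info("complete-case filter removed %d of %d participant-visit rows",
                 dropped, len(pv))
    return pv, complete


_BLOCKS = ("age", "sex", "household_size", "occupation", "density")


def encode_fixed_effects(
    pv: pd.DataFrame,
    covariates="all",
    include_intercept: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Fixed-effect design block: intercept, covariates, visit dummies.

    ``covariates`` is "all" or a subset of
    {"age", "sex", "household_size", "occupation", "density"} (an
    unadjusted model uses a single block).  Returns (X, column names,
    centring constants).
    """
    blocks = _BLOCKS if covariates == "all" else tuple(covariates)
    unknown = set(blocks) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown covariate blocks {sorted(unknown)}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    centers: dict[str, float] = {}
    n = len(pv)
    if include_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    if "age" in blocks:
        for g in PARTICIPANT_AGE_GROUPS:
            if g == AGE_REFERENCE:
                continue
            cols.append((pv["age_group"] == g).to_numpy(float))
            names.append(f"age[{g}]")
    if "sex" in blocks:
        cols.append((pv["sex"] == "female").to_numpy(float))
        names.append("sex[female]")
    if "household_size" in blocks:
        x = np.log(pv["household_size"].to_numpy(float))
        centers["log_household_size"] = float(x.mean())
        cols.append(x - x.mean())
        names.append("log_household_size")
    if "occupation" in blocks:
        for occ in ("student", "other"):
            cols.append((pv["occupation"] == occ).to_numpy(float))
            names.append(f"occupation[{occ}]")
    if "density" in blocks:
        x = np.log10(pv["density_at_first_visit"].to_numpy(float))
        centers["log10_density"] = float(x.mean())
        cols.append(x - x.mean())
        names.append("log10_density")
    visits = sorted(pv["visit"].unique())
    for v in visits[1:]:  # first present visit is the reference
        cols.append((pv["visit"] == v).to_numpy(float))
        names.append(f"visit[{v}]")
    return np.column_stack(cols), names, centers


def group_indices(pv: pd.DataFrame) -> dict[str, np.ndarray]:
    """Integer location/household/participant indices for random effects."""
    out = {}
    for key, col in (("loc", "location_id"), ("hh", "household_id"),
                     ("part", "participant_id")):
        codes, uniques = pd.factorize(pv[col], sort=True)
        out[f"{key}_idx"] = codes.astype(np.int64)
        out[f"n_{key}"] = len(uniques)
        out[f"{key}_levels"] = list(uniques)
    return out
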