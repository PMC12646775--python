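"""Potential contact triangles: construction, underlying counts, trimming.

A *potential contact triangle* is a (participant, primary contact event,
secondary contact event) triple about which the survey asked whether the two
contacts interacted in the prior week.  When either event is a group the
triple stands for m = g_primary × g_secondary *underlying* person-level
triangles; m drives both the any-of-m likelihood and the trimming rule that
drops the most extreme 0.5% of observations by m.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .survey_data import dichotomize_certainty

__all__ = [
    "underlying_triangle_count",
    "select_random_primaries",
    "enumerate_potential_triangles",
    "trim_by_underlying_count",
]

log = logging.getLogger(__name__)


def underlying_triangle_count(g_primary: int, g_secondary: int) -> int:
    """Number of person-level triangles implied by a pair of contact events.

    Each member of the primary event paired with each member of the
    secondary event forms one underlying triangle with the participant, so
    the count is the product of the two group sizes (two groups of 10 imply
    100 underlying triangles).
    """
    g1, g2 = int(g_primary), int(g_secondary)
    if g1 < 1 or g2 < 1:
        raise ValueError(f"group sizes must be >= 1, got ({g_primary}, {g_secondary})")
    return g1 * g2


def select_random_primaries(event_ids, seed) -> list:
    """Draw the two primary contact events uniformly without replacement.

    Mirrors the survey instrument for synthetic or re-sampled data; when a
    recorded triangle table is available its primaries are used instead.
    Fewer than two events yields an empty selection (logged, not an error).
    """
    ids = list(event_ids)
    if len(ids) < 2:
        log.info("fewer than two contact events; no primaries selected")
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=2, replace=False)
    return [ids[i] for i in sorted(picked)]


def enumerate_potential_triangles(
    diaries: pd.DataFrame,
    responses: pd.DataFrame,
    cutoff: str = "probably-yes",
) -> pd.DataFrame:
    """Build the potential-triangle table from diaries and certainty responses.

    One row per unordered (primary, secondary) pair: the connectivity
    question asked about the two primaries from both sides is collapsed to a
    single triangle keyed on the lower event id.  ``y`` is the certainty
    response dichotomized at ``cutoff``; ``m`` is the product of the two
    group sizes.  Event-level attributes of both contacts are carried along
    for downstream design matrices.  Repeat-flagged events are excluded: a
    repeat re-lists a person whose dyads are already represented.
    """
    ev_cols = ["event_id", "participant_id", "visit", "group_size", "setting",
               "touch", "frequency", "duration", "repeat_flag"]
    events = diaries[ev_cols].set_index("event_id")

    for col in ("primary_event_id", "secondary_event_id"):
        unknown = ~responses[col].isin(events.index)
        if unknown.any():
            rows = list(np.flatnonzero(np.asarray(unknown)))[:20]
            raise ValueError(
                f"triangle responses reference unknown {col} at rows {rows}")

    resp = responses.copy()
    prim = events.loc[resp["primary_event_id"]].reset_index(drop=True)
    seco = events.loc[resp["secondary_event_id"]].reset_index(drop=True)
    mism = (
        (prim["participant_id"].to_numpy() != resp["participant_id"].to_numpy())
        | (seco["participant_id"].to_numpy() != resp["participant_id"].to_numpy())
        | (prim["visit"].to_numpy() != resp["visit"].to_numpy())
        | (seco["visit"].to_numpy() != resp["visit"].to_numpy())
    )
    if mism.any():
        rows = list(np.flatnonzero(mism))[:20]
        raise ValueError(
            f"triangle responses cross participant-visit boundaries at rows {rows}")

    keep = ~(prim["repeat_flag"].to_numpy() | seco["repeat_flag"].to_numpy())
    resp = resp[keep].reset_index(drop=True)
    prim = prim[keep].reset_index(drop=True)
    seco = seco[keep].reset_index(drop=True)

    out = pd.DataFrame({
        "participant_id": resp["participant_id"].to_numpy(),
        "visit": resp["visit"].to_numpy(),
        "primary_event_id": resp["primary_event_id"].to_numpy(),
        "secondary_event_id": resp["secondary_event_id"].to_numpy(),
        "certainty": resp["certainty"].to_numpy(),
        "g_primary": prim["group_size"].to_numpy(int),
        "g_secondary": seco["group_size"].to_numpy(int),
    })
    for name, side in (("primary", prim), ("secondary", seco)):
        for attr in ("setting", "touch", "frequency", "duration"):
            out[f"{attr}_{name}"] = side[attr].to_numpy()

    # collapse the doubly-asked primary-primary dyad (and any other duplicate
    # unordered pair) to one row keyed on the lower event id
    lo = np.minimum(out["primary_event_id"], out["secondary_event_id"])
    hi = np.maximum(out["primary_event_id"], out["secondary_event_id"])
    out["_pair_lo"], out["_pair_hi"] = lo, hi
    out = (
        out.sort_values(["participant_id", "visit", "_pair_lo", "_pair_hi",
                         "primary_event_id"])
        .drop_duplicates(subset=["participant_id", "visit", "_pair_lo", "_pair_hi"],
                         keep="first")
        .drop(columns=["_pair_lo", "_pair_hi"])
        .reset_index(drop=True)
    )
    out["m"] = out["g_primary"].to_numpy() * out["g_secondary"].to_numpy()
    out["y"] = out["certainty"].map(lambda c: dichotomize_certainty(c, cutoff))
    return out


def trim_by_underlying_count(
    triangles: pd.DataFrame,
    quantile: float = 0.995,
    per_visit: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop potential triangles in the top tail of the underlying count m.

    Rows with m *strictly above* the empirical ``quantile`` (linear-
    interpolation order statistic) are removed, so ties at the threshold are
    retained and the retained fraction is at least the quantile up to ties.
    Returns ``(retained, trimmed)``.  ``per_visit`` computes the threshold
    within each visit instead of pooled.
    """
    if triangles.empty:
        raise ValueError("cannot trim an empty triangle table")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")

    def _mask(df: pd.DataFrame) -> np.ndarray:
        thr = np.quantile(df["m"].to_numpy(float), quantile, method="linear")
        return df["m"].to_numpy(float) > thr

    if per_visit:
        drop = np.zeros(len(triangles), dtype=bool)
        for _, idx in triangles.groupby("visit").indices.items():
            sub = triangles.iloc[idx]
            drop[idx] = _mask(sub)
    else:
        drop = _mask(triangles)
    retained = triangles[~drop].reset_index(drop=True)
    trimmed = triangles[drop].reset_index(drop=True)
    return retained, trimmed
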