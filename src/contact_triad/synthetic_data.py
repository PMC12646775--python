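"""Synthetic contact-survey generator with known ground truth.

Emits the four survey tables of :mod:`contact_triad.survey_data` from a
generative model that mirrors the models fitted downstream, so that every
stage of the pipeline can be exercised against known truth:

* a **population** of locations on a density transect, households within
  locations and participants within households, with age, sex and occupation
  structure loosely matching a semi-urban southern-China cohort;
* **contact diaries**: per participant-visit, a total contact count drawn
  from a Poisson whose log-mean is a linear predictor plus normal random
  effects at location / household / participant / observation level (the
  lognormal-Poisson that the count model fits), partitioned into contact
  events with a zero-truncated, heavy-tailed group-size distribution;
* **triangle responses**: two primary events chosen at random per
  participant-visit; for every (primary, secondary) pair each of the
  m = g_primary × g_secondary underlying person-level triangles is
  independently connected with probability p, logit p being a linear
  predictor with location / household / participant random effects.  The
  latent "any underlying triangle connected" indicator is mapped onto the
  four-level certainty scale with configurable softening so the certainty
  cutoffs can be exercised.

All randomness flows from ``SyntheticConfig.seed`` through three fixed
sub-streams (population / diaries / triangles), so each table can be
regenerated independently and reruns are bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .survey_data import (
    CONTACT_AGE_CATEGORIES,
    derive_occupation_class,
    derive_participant_age_group,
)

__all__ = [
    "CountTruth",
    "TriangleTruth",
    "SyntheticConfig",
    "SyntheticTruth",
    "Population",
    "generate_population",
    "generate_contact_diaries",
    "generate_triangle_responses",
    "generate_survey",
]


# ---------------------------------------------------------------------------
# Truth parameter blocks
# ---------------------------------------------------------------------------

def _default_count_age() -> dict[str, float]:
    # log relative rates vs the 36-45 reference; flat through middle age,
    # dip for young adults, decline in the elderly.
    return {
        "2-15": math.log(1.06),
        "16-25": math.log(0.84),
        "26-35": math.log(0.98),
        "36-45": 0.0,
        "46-55": -0.02,
        "56-65": math.log(0.86),
        "66-75": math.log(0.76),
        "76+": math.log(0.60),
    }


@dataclass
class CountTruth:
    """Generating parameters for daily contact counts (log-link scale)."""

    intercept: float = math.log(10.0)
    age: dict[str, float] = field(default_factory=_default_count_age)
    sex_female: float = 0.0
    log_household_size: float = 0.15
    occupation: dict[str, float] = field(
        default_factory=lambda: {"student": -0.15, "other": -0.45}
    )
    log10_density: float = math.log(1.10)  # per 10-fold density increase
    visit: dict[int, float] = field(
        default_factory=lambda: {2: 0.0, 3: -0.05, 4: 0.0, 5: 0.05}
    )
    sigma_loc: float = 0.20
    sigma_hh: float = 0.25
    sigma_part: float = 0.35
    sigma_obs: float = 0.30


def _default_triangle_age() -> dict[str, float]:
    # U-shaped log odds of connection vs 36-45: children and the elderly
    # have more locally clustered contacts.
    return {
        "2-15": math.log(1.38),
        "16-25": 0.15,
        "26-35": 0.05,
        "36-45": 0.0,
        "46-55": 0.02,
        "56-65": 0.30,
        "66-75": 0.60,
        "76+": math.log(2.67),
    }


@dataclass
class TriangleTruth:
    """Generating parameters for per-underlying-triangle connection (logit).

    Contact-level terms use the symmetric pair encoding of the triangle
    design matrix: per-attribute counts over the two contact events
    (reference levels: social setting, <1/wk frequency, <10 min duration),
    a pair-level any-group indicator and log of the underlying-triangle
    count, and shared-attribute indicators.  Zeroing blocks with
    :meth:`participant_only` / :meth:`individual_contact` makes the
    corresponding nested specification the generating model.
    """

    intercept: float = -1.5
    age: dict[str, float] = field(default_factory=_default_triangle_age)
    sex_female: float = 0.20
    log_household_size: float = 0.30
    occupation: dict[str, float] = field(
        default_factory=lambda: {"student": 0.30, "other": 0.25}
    )
    log10_density: float = math.log(0.57)
    visit: dict[int, float] = field(
        default_factory=lambda: {2: 0.0, 3: 0.0, 4: 0.05, 5: 0.20}
    )
    # per-contact counts (0/1/2 over the pair)
    setting: dict[str, float] = field(
        default_factory=lambda: {
            "home": 0.10,
            "work": math.log(0.30),
            "school": math.log(0.23),
            "other": -0.30,
        }
    )
    frequency: dict[str, float] = field(
        default_factory=lambda: {"1-3/wk": 0.30, "4+/wk": 0.60}
    )
    duration: dict[str, float] = field(
        default_factory=lambda: {"10-59min": 0.30, "60+min": 0.70}
    )
    touch: float = 0.40
    group_indicator: float = math.log(0.26)
    log_m: float = math.log(0.37)
    # shared-attribute indicators
    same_setting: float = math.log(7.37)
    same_frequency: float = 0.50
    same_duration: float = 0.40
    both_touch: float = 0.50
    sigma_loc: float = 0.30
    sigma_hh: float = 0.30
    sigma_part: float = 0.50

    def participant_only(self) -> "TriangleTruth":
        """Copy with all contact-level and shared-attribute effects zeroed."""
        t = self.individual_contact()
        t.setting = {k: 0.0 for k in t.setting}
        t.frequency = {k: 0.0 for k in t.frequency}
        t.duration = {k: 0.0 for k in t.duration}
        t.touch = 0.0
        t.group_indicator = 0.0
        t.log_m = 0.0
        return t

    def individual_contact(self) -> "TriangleTruth":
        """Copy with shared-attribute effects zeroed (contact-level kept)."""
        t = TriangleTruth(**{k: (dict(v) if isinstance(v, dict) else v)
                             for k, v in asdict(self).items()})
        t.same_setting = 0.0
        t.same_frequency = 0.0
        t.same_duration = 0.0
        t.both_touch = 0.0
        return t


# ---------------------------------------------------------------------------
# Survey-shape configuration
# ---------------------------------------------------------------------------

_AGE_BAND_WEIGHTS = {
    (2, 15): 0.12, (16, 25): 0.13, (26, 35): 0.13, (36, 45): 0.17,
    (46, 55): 0.18, (56, 65): 0.15, (66, 75): 0.08, (76, 90): 0.04,
}

_SETTING_PROBS = {
    # event setting conditional on participant occupation class
    "employed": {"home": 0.25, "work": 0.45, "school": 0.01, "social": 0.16, "other": 0.13},
    "student": {"home": 0.25, "work": 0.02, "school": 0.48, "social": 0.15, "other": 0.10},
    "other": {"home": 0.45, "work": 0.04, "school": 0.01, "social": 0.30, "other": 0.20},
    "unknown": {"home": 0.40, "work": 0.15, "school": 0.05, "social": 0.25, "other": 0.15},
}

_FREQUENCY_PROBS = {
    # conditional on setting; household and school contacts are near-daily
    "home": {"<1/wk": 0.01, "1-3/wk": 0.04, "4+/wk": 0.95},
    "work": {"<1/wk": 0.20, "1-3/wk": 0.12, "4+/wk": 0.68},
    "school": {"<1/wk": 0.03, "1-3/wk": 0.05, "4+/wk": 0.92},
    "social": {"<1/wk": 0.18, "1-3/wk": 0.17, "4+/wk": 0.65},
    "other": {"<1/wk": 0.35, "1-3/wk": 0.20, "4+/wk": 0.45},
}

_DURATION_PROBS = {
    "home": {"<10min": 0.10, "10-59min": 0.15, "60+min": 0.75},
    "work": {"<10min": 0.42, "10-59min": 0.15, "60+min": 0.43},
    "school": {"<10min": 0.10, "10-59min": 0.15, "60+min": 0.75},
    "social": {"<10min": 0.30, "10-59min": 0.20, "60+min": 0.50},
    "other": {"<10min": 0.55, "10-59min": 0.25, "60+min": 0.20},
}

_TOUCH_PROBS = {
    "home": 0.45, "work": 0.08, "school": 0.45, "social": 0.18, "other": 0.08,
}

_CONTACT_AGE_MARGINAL = {"0-4": 0.04, "5-19": 0.20, "20-39": 0.30, "40-64": 0.36, "65+": 0.10}


@dataclass
class SyntheticConfig:
    """Scale, marginal and truth configuration for the generator.

    The defaults emulate the structure of the study the pipeline targets —
    communities sampled along a density transect with ~20 households each,
    four analysed visits, a median of ~10 daily contacts, a third of contact
    events reported as groups with a heavy-tailed size distribution — at a
    scale set by ``n_locations`` and ``households_per_location``.
    """

    n_locations: int = 40
    households_per_location: int = 20
    visits: tuple[int, ...] = (2, 3, 4, 5)
    # monotone density transect (people/km²); sign of `density_gradient`
    # sets whether density rises or falls with location index
    density_range: tuple[float, float] = (100.0, 10_000.0)
    density_gradient: int = 1
    density_jitter_sd: float = 0.10  # lognormal sd of household-level jitter
    mean_household_size: float = 4.0
    enrolment_prob: float = 0.65    # per-resident enrolment within household
    participation_rate: float = 0.85  # per-visit attendance
    unknown_rate: float = 0.004     # missing sex/occupation/age rate
    # group-size distribution: P(group) mass on sizes >= 2, with the excess
    # over 2 negative-binomial (heavy tail)
    p_group: float = 0.33
    group_nb_r: float = 0.4
    group_nb_mean: float = 7.0
    repeat_rate: float = 0.05       # per participant-visit repeat-event rate
    category_missing_rate: float = 0.05  # contact age: category absent, guess given
    age_unknown_rate: float = 0.01       # contact age: both absent
    multiple_age_prob: float = 0.6  # P(group event spans multiple age bands)
    # certainty softening: a true yes reported as "probably yes" (resp. a
    # true no as "probably no") with these probabilities
    soften_yes: float = 0.10
    soften_no: float = 0.10
    count_truth: CountTruth = field(default_factory=CountTruth)
    triangle_truth: TriangleTruth = field(default_factory=TriangleTruth)
    seed: int = 0

    def validate(self) -> None:
        if self.n_locations < 1 or self.households_per_location < 1:
            raise ValueError("need at least one location and household per location")
        if not set(self.visits) <= {2, 3, 4, 5} or not self.visits:
            raise ValueError("visits must be a nonempty subset of {2,3,4,5}")
        for name in ("sigma_loc", "sigma_hh", "sigma_part"):
            if getattr(self.count_truth, name) < 0 or getattr(self.triangle_truth, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count_truth.sigma_obs < 0:
            raise ValueError("sigma_obs must be >= 0")
        for p in (self.p_group, self.repeat_rate, self.soften_yes, self.soften_no,
                  self.enrolment_prob, self.participation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.density_range) <= 0:
            raise ValueError("density range must be positive")


@dataclass
class SyntheticTruth:
    """Realized random effects and generating parameters."""

    config: SyntheticConfig
    location_ids: list[str]
    household_ids: list[str]
    participant_ids: list[str]
    count_u_loc: np.ndarray
    count_u_hh: np.ndarray
    count_u_part: np.ndarray
    triangle_u_loc: np.ndarray
    triangle_u_hh: np.ndarray
    triangle_u_part: np.ndarray
    # filled by generate_contact_diaries: per participant-visit e_obs
    observation_effects: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "config": _jsonable(asdict(self.config)),
            "location_ids": self.location_ids,
            "household_ids": self.household_ids,
            "participant_ids": self.participant_ids,
            "count_u_loc": self.count_u_loc.tolist(),
            "count_u_hh": self.count_u_hh.tolist(),
            "count_u_part": self.count_u_part.tolist(),
            "triangle_u_loc": self.triangle_u_loc.tolist(),
            "triangle_u_hh": self.triangle_u_hh.tolist(),
            "triangle_u_part": self.triangle_u_part.tolist(),
            "observation_effects": (
                None if self.observation_effects is None
                else self.observation_effects.to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class Population:
    locations: pd.DataFrame
    households: pd.DataFrame
    participants: pd.DataFrame
    truth: SyntheticTruth


def _stream(config: SyntheticConfig, key: int, seed=None) -> np.random.Generator:
    # counter-based sub-streams: one per generator stage
    entropy = config.seed if seed is None else seed
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=entropy, spawn_key=(key,))
    ))


# ---------------------------------------------------------------------------
# Stage 1: population
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator) -> int:
    bands = list(_AGE_BAND_WEIGHTS)
    w = np.array(list(_AGE_BAND_WEIGHTS.values()))
    lo, hi = bands[rng.choice(len(bands), p=w / w.sum())]
    return int(rng.integers(lo, hi + 1))


def _draw_occupation_raw(age: int, rng: np.random.Generator) -> str:
    if age < 5:
        return "child not in school"
    if age <= 22:
        if rng.random() < 0.85:
            return "student"
        return "employed" if age >= 16 and rng.random() < 0.6 else "unemployed"
    if age <= 60:
        r = rng.random()
        if r < 0.75:
            return "employed"
        return "homemaker" if r < 0.88 else "unemployed"
    return "retired" if rng.random() < 0.85 else "employed"


def generate_population(config: SyntheticConfig, seed: int | None = None) -> Population:
    """Locations on a monotone density transect, households, participants.

    Deterministic given the seed.  Ages span 2-90 with occupation
    conditional on age (students concentrated at school ages, employment in
    working ages).  Location densities are exactly monotone in location
    index; household densities add small lognormal jitter.
    """
    config.validate()
    rng = _stream(config, 0, seed)
    nloc = config.n_locations
    lo, hi = min(config.density_range), max(config.density_range)
    dens = np.geomspace(lo, hi, nloc) if nloc > 1 else np.array([math.sqrt(lo * hi)])
    if config.density_gradient < 0:
        dens = dens[::-1]
    loc_ids = [f"L{i + 1:03d}" for i in range(nloc)]
    locations = pd.DataFrame({"location_id": loc_ids, "population_density": dens})

    hh_rows, part_rows = [], []
    for li, loc in enumerate(loc_ids):
        for h in range(config.households_per_location):
            hid = f"{loc}H{h + 1:03d}"
            size = 1 + int(rng.poisson(config.mean_household_size - 1))
            hh_dens = dens[li] * math.exp(rng.normal(0.0, config.density_jitter_sd))
            hh_rows.append((hid, loc, size, hh_dens))
            n_enrolled = max(1, int(rng.binomial(size, config.enrolment_prob)))
            for k in range(n_enrolled):
                pid = f"{hid}P{k + 1:02d}"
                age = _draw_age(rng)
                sex = "unknown" if rng.random() < config.unknown_rate else (
                    "female" if rng.random() < 0.5 else "male")
                occ = ("unclassified" if rng.random() < config.unknown_rate
                       else _draw_occupation_raw(age, rng))
                age_out = pd.NA if rng.random() < config.unknown_rate else age
                attended = [v for v in config.visits
                            if rng.random() < config.participation_rate]
                if not attended:
                    attended = [config.visits[int(rng.integers(len(config.visits)))]]
                for v in attended:
                    part_rows.append((pid, hid, v, age_out, sex, occ))

    households = pd.DataFrame(
        hh_rows, columns=["household_id", "location_id", "household_size",
                          "density_at_first_visit"])
    participants = pd.DataFrame(
        part_rows, columns=["participant_id", "household_id", "visit",
                            "age_years", "sex", "occupation_raw"])
    participants["age_years"] = pd.array(participants["age_years"], dtype="Int64")

    hh_ids = households["household_id"].tolist()
    pids = sorted(participants["participant_id"].unique())
    ct, tt = config.count_truth, config.triangle_truth
    truth = SyntheticTruth(
        config=config,
        location_ids=loc_ids,
        household_ids=hh_ids,
        participant_ids=pids,
        count_u_loc=rng.normal(0.0, 1.0, nloc) * ct.sigma_loc,
        count_u_hh=rng.normal(0.0, 1.0, len(hh_ids)) * ct.sigma_hh,
        count_u_part=rng.normal(0.0, 1.0, len(pids)) * ct.sigma_part,
        triangle_u_loc=rng.normal(0.0, 1.0, nloc) * tt.sigma_loc,
        triangle_u_hh=rng.normal(0.0, 1.0, len(hh_ids)) * tt.sigma_hh,
        triangle_u_part=rng.normal(0.0, 1.0, len(pids)) * tt.sigma_part,
    )
    return Population(locations, households, participants, truth)


# ---------------------------------------------------------------------------
# Stage 2: contact diaries
# ---------------------------------------------------------------------------

def _participant_frame(pop: Population) -> pd.DataFrame:
    """Participant-visit rows joined with household covariates and indices."""
    df = pop.participants.merge(pop.households, on="household_id", how="left")
    df["age_group"] = df["age_years"].map(derive_participant_age_group)
    df["occupation"] = df["occupation_raw"].map(derive_occupation_class)
    loc_index = {l: i for i, l in enumerate(pop.truth.location_ids)}
    hh_index = {h: i for i, h in enumerate(pop.truth.household_ids)}
    part_index = {p: i for i, p in enumerate(pop.truth.participant_ids)}
    df["loc_i"] = df["location_id"].map(loc_index)
    df["hh_i"] = df["household_id"].map(hh_index)
    df["part_i"] = df["participant_id"].map(part_index)
    return df


def _count_linear_predictor(row, truth: CountTruth) -> float:
    eta = truth.intercept
    eta += truth.age.get(row.age_group, 0.0)
    if row.sex == "female":
        eta += truth.sex_female
    eta += truth.log_household_size * math.log(row.household_size)
    eta += truth.occupation.get(row.occupation, 0.0)
    eta += truth.log10_density * math.log10(row.density_at_first_visit)
    eta += truth.visit.get(int(row.visit), 0.0)
    return eta


def _draw_group_size(config: SyntheticConfig, rng) -> int:
    if rng.random() >= config.p_group:
        return 1
    r, mu = config.group_nb_r, config.group_nb_mean
    return 2 + int(rng.negative_binomial(r, r / (r + mu)))


def _draw_cat(probs: dict[str, float], rng) -> str:
    keys = list(probs)
    w = np.array(list(probs.values()), dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def generate_contact_diaries(
    pop: Population, config: SyntheticConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Contact-event table whose totals follow the generating count model.

    Per participant-visit the total contact count is Poisson with log-mean
    Xβ + visit effect + u_loc + u_hh + u_part + e_obs; the total is then
    partitioned into events by drawing group sizes until it is exhausted.
    Repeat-flagged events (re-listings of already-counted people) are added
    on top and never change the total.  The realized observation-level
    effects e_obs are recorded on ``pop.truth.observation_effects``.
    """
    config = config or pop.truth.config
    rng = _stream(config, 1, seed)
    truth = config.count_truth
    pv = _participant_frame(pop)

    rows, obs_rows = [], []
    for row in pv.itertuples(index=False):
        e_obs = rng.normal(0.0, truth.sigma_obs) if truth.sigma_obs > 0 else 0.0
        eta = (
            _count_linear_predictor(row, truth)
            + pop.truth.count_u_loc[row.loc_i]
            + pop.truth.count_u_hh[row.hh_i]
            + pop.truth.count_u_part[row.part_i]
            + e_obs
        )
        obs_rows.append((row.participant_id, row.visit, e_obs))
        total = int(rng.poisson(math.exp(eta)))
        remaining, k = total, 0
        sizes = []
        while remaining > 0:
            s = min(_draw_group_size(config, rng), remaining)
            sizes.append(s)
            remaining -= s
        if sizes and rng.random() < config.repeat_rate:
            sizes.append(-int(rng.choice(np.abs(sizes))))  # negative marks repeat
        for s in sizes:
            repeat = s < 0
            size = abs(int(s))
            k += 1
            setting = _draw_cat(_SETTING_PROBS[row.occupation], rng)
            freq = _draw_cat(_FREQUENCY_PROBS[setting], rng)
            dur = _draw_cat(_DURATION_PROBS[setting], rng)
            touch = "yes" if rng.random() < _TOUCH_PROBS[setting] else "no"
            if size > 1 and rng.random() < config.multiple_age_prob:
                cat, guess = "multiple", pd.NA
            else:
                band = _draw_cat(_CONTACT_AGE_MARGINAL, rng)
                u = rng.random()
                if u < config.age_unknown_rate:
                    cat, guess = pd.NA, pd.NA
                elif u < config.age_unknown_rate + config.category_missing_rate:
                    lo, hi = {"0-4": (0, 4), "5-19": (5, 19), "20-39": (20, 39),
                              "40-64": (40, 64), "65+": (65, 90)}[band]
                    cat, guess = pd.NA, int(rng.integers(lo, hi + 1))
                else:
                    cat, guess = band, pd.NA
            rows.append((
                f"{row.participant_id}v{row.visit}e{k}", row.participant_id,
                row.visit, size, cat, guess, setting, touch, freq, dur, repeat,
            ))

    pop.truth.observation_effects = pd.DataFrame(
        obs_rows, columns=["participant_id", "visit", "e_obs"])
    diaries = pd.DataFrame(rows, columns=[
        "event_id", "participant_id", "visit", "group_size",
        "contact_age_category", "age_guess", "setting", "touch",
        "frequency", "duration", "repeat_flag"])
    diaries["age_guess"] = pd.array(diaries["age_guess"], dtype="Int64")
    diaries["contact_age_category"] = diaries["contact_age_category"].astype("string")
    return diaries


# ---------------------------------------------------------------------------
# Stage 3: triangle responses
# ---------------------------------------------------------------------------

def _triangle_linear_predictor(row, ev1, ev2, truth: TriangleTruth) -> float:
    """Logit of the per-underlying-triangle connection probability.

    ``ev1``/``ev2`` are contact-event namedtuples; the pair encoding is
    symmetric (counts and indicators over the unordered pair), matching the
    triangle design matrix.
    """
    eta = truth.intercept
    eta += truth.age.get(row.age_group, 0.0)
    if row.sex == "female":
        eta += truth.sex_female
    eta += truth.log_household_size * math.log(row.household_size)
    eta += truth.occupation.get(row.occupation, 0.0)
    eta += truth.log10_density * math.log10(row.density_at_first_visit)
    eta += truth.visit.get(int(row.visit), 0.0)
    for ev in (ev1, ev2):
        eta += truth.setting.get(ev.setting, 0.0)
        eta += truth.frequency.get(ev.frequency, 0.0)
        eta += truth.duration.get(ev.duration, 0.0)
        if ev.touch == "yes":
            eta += truth.touch
    m = int(ev1.group_size) * int(ev2.group_size)
    if ev1.group_size > 1 or ev2.group_size > 1:
        eta += truth.group_indicator
    eta += truth.log_m * math.log(m)
    if ev1.setting == ev2.setting:
        eta += truth.same_setting
    if ev1.frequency == ev2.frequency:
        eta += truth.same_frequency
    if ev1.duration == ev2.duration:
        eta += truth.same_duration
    if ev1.touch == "yes" and ev2.touch == "yes":
        eta += truth.both_touch
    return eta


def generate_triangle_responses(
    diaries: pd.DataFrame,
    pop: Population,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triangle-certainty table from the any-of-m connection mechanism.

    Two primary events are drawn uniformly without replacement per
    participant-visit (repeat-flagged events are ineligible); every
    (primary, other event) pair is asked about.  The latent indicator is
    connected with probability 1 − (1−p)^m and then softened onto the
    four-level scale.  The primary-primary dyad is asked from both sides
    with a consistent answer.  Participant-visits with fewer than two
    eligible events yield no rows.
    """
    config = config or pop.truth.config
    rng = _stream(config, 2, seed)
    truth = config.triangle_truth
    pv = _participant_frame(pop)
    pv_lookup = {(r.participant_id, r.visit): r for r in pv.itertuples(index=False)}

    rows = []
    eligible = diaries[~diaries["repeat_flag"]]
    for (pid, visit), group in eligible.groupby(["participant_id", "visit"], sort=True):
        events = list(group.itertuples(index=False))
        if len(events) < 2:
            continue
        row = pv_lookup[(pid, visit)]
        u = (pop.truth.triangle_u_loc[row.loc_i]
             + pop.truth.triangle_u_hh[row.hh_i]
             + pop.truth.triangle_u_part[row.part_i])
        prim_idx = rng.choice(len(events), size=2, replace=False)
        primaries = [events[i] for i in sorted(prim_idx)]
        # one latent outcome per unordered pair, reused for both askings
        latent: dict[frozenset, str] = {}
        for primary in primaries:
            for other in events:
                if other.event_id == primary.event_id:
                    continue
                key = frozenset((primary.event_id, other.event_id))
                if key not in latent:
                    eta = _triangle_linear_predictor(row, primary, other, truth) + u
                    p = 1.0 / (1.0 + math.exp(-eta))
                    m = int(primary.group_size) * int(other.group_size)
                    p_any = -math.expm1(m * math.log1p(-p)) if p < 1.0 else 1.0
                    connected = rng.random() < p_any
                    if connected:
                        cert = "probably yes" if rng.random() < config.soften_yes else "yes"
                    else:
                        cert = "probably no" if rng.random() < config.soften_no else "no"
                    latent[key] = cert
                rows.append((pid, visit, primary.event_id, other.event_id, latent[key]))

    return pd.DataFrame(rows, columns=[
        "participant_id", "visit", "primary_event_id", "secondary_event_id",
        "certainty"])


def generate_survey(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate all four survey tables plus ground truth in one call."""
    if seed is not None:
        config.seed = seed
    pop = generate_population(config)
    diaries = generate_contact_diaries(pop, config)
    responses = generate_triangle_responses(diaries, pop, config)
    tables = {
        "location": pop.locations,
        "household": pop.households,
        "participant": pop.participants,
        "contact": diaries,
        "triangle": responses,
    }
    return tables, pop.truth
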