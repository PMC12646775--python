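"""Survey tables, validation, and covariate derivation for contact-diary data.

The analysis consumes four linked tables describing an egocentric contact
survey in which cohort participants, nested in households which are nested in
sampled locations (villages / neighbourhoods), report every face-to-face
interaction from the prior day:

* ``location`` — sampled community with a population density (people/km²).
* ``household`` — household, its location, size, and the density recorded at
  the first analysed visit (used as a fixed household-level covariate).
* ``participant`` — one row per participant per study visit with age, sex and
  raw occupation.
* ``contact`` — one row per *contact event*: a diary entry describing either a
  single person or a group met at once, with a reported group size, setting,
  touch, frequency and duration categories, and an optional repeat flag
  marking people already listed in another event.
* ``triangle`` — one row per connectivity question: for a randomly selected
  *primary* contact event and another (*secondary*) event of the same
  participant-visit, how certain the participant is that the two interacted in
  the prior week ("yes" / "probably yes" / "probably no" / "no").

Tables are plain :class:`pandas.DataFrame` objects; :func:`read_table` /
:func:`write_table` handle CSV I/O with schema and invariant validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "MidpointConfig",
    "DEFAULT_MIDPOINTS",
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "validate_table",
    "check_referential_integrity",
    "derive_participant_age_group",
    "derive_contact_age_category",
    "derive_occupation_class",
    "total_reported_contacts",
    "weekly_contact_minutes",
    "dichotomize_certainty",
    "log10_density",
]

# ---------------------------------------------------------------------------
# Category vocabularies
# ---------------------------------------------------------------------------

#: Participant age groups: children pooled (few under-5s), 10-year bands for
#: ages 16-75, open-ended top band.
PARTICIPANT_AGE_GROUPS = (
    "2-15", "16-25", "26-35", "36-45", "46-55", "56-65", "66-75", "76+",
)

#: Age bands offered for reported contacts; groups spanning bands are
#: recorded as "multiple".
CONTACT_AGE_CATEGORIES = ("0-4", "5-19", "20-39", "40-64", "65+")
CONTACT_AGE_LEVELS = CONTACT_AGE_CATEGORIES + ("multiple", "unknown")

SETTINGS = ("home", "work", "school", "social", "other")
TOUCH_LEVELS = ("yes", "no", "unknown")
FREQUENCY_LEVELS = ("<1/wk", "1-3/wk", "4+/wk")
DURATION_LEVELS = ("<10min", "10-59min", "60+min")
SEX_LEVELS = ("male", "female", "unknown")
OCCUPATION_CLASSES = ("employed", "student", "other", "unknown")
CERTAINTY_LEVELS = ("yes", "probably yes", "probably no", "no")
#: Certainty cutoffs for calling a triangle connected, from strictest to most
#: lenient.  "probably-yes" (yes + probably yes affirmative) is the main
#: analysis; the other two are sensitivity analyses.
CERTAINTY_CUTOFFS = ("yes-only", "probably-yes", "probably-no")
VISITS = (2, 3, 4, 5)


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(ValueError):
    """Rows violate a type invariant; message lists offending row numbers."""


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

# column -> (dtype kind, nullable); kind in {"id", "int", "float", "bool", "str"}
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "location": {
        "location_id": ("id", False),
        "population_density": ("float", False),
    },
    "household": {
        "household_id": ("id", False),
        "location_id": ("id", False),
        "household_size": ("int", False),
        "density_at_first_visit": ("float", False),
    },
    "participant": {
        "participant_id": ("id", False),
        "household_id": ("id", False),
        "visit": ("int", False),
        "age_years": ("int", True),
        "sex": ("str", False),
        "occupation_raw": ("str", True),
    },
    "contact": {
        "event_id": ("id", False),
        "participant_id": ("id", False),
        "visit": ("int", False),
        "group_size": ("int", False),
        "contact_age_category": ("str", True),
        "age_guess": ("int", True),
        "setting": ("str", False),
        "touch": ("str", False),
        "frequency": ("str", False),
        "duration": ("str", False),
        "repeat_flag": ("bool", False),
    },
    "triangle": {
        "participant_id": ("id", False),
        "visit": ("int", False),
        "primary_event_id": ("id", False),
        "secondary_event_id": ("id", False),
        "certainty": ("str", False),
    },
}

_CATEGORY_COLUMNS: dict[tuple[str, str], tuple[str, ...]] = {
    ("participant", "sex"): SEX_LEVELS,
    ("contact", "contact_age_category"): CONTACT_AGE_LEVELS,
    ("contact", "setting"): SETTINGS,
    ("contact", "touch"): TOUCH_LEVELS,
    ("contact", "frequency"): FREQUENCY_LEVELS,
    ("contact", "duration"): DURATION_LEVELS,
    ("triangle", "certainty"): CERTAINTY_LEVELS,
}


def _coerce(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[kind]
    out = df.copy()
    for col, (ckind, nullable) in schema.items():
        if ckind == "int":
            out[col] = pd.array(pd.to_numeric(out[col]), dtype="Int64")
        elif ckind == "float":
            out[col] = pd.to_numeric(out[col]).astype(float)
        elif ckind == "bool":
            out[col] = out[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, 1: True, 0: False,
                 "1": True, "0": False}
            ).astype(bool)
        else:  # id / str
            out[col] = out[col].astype("string")
    return out[list(schema)]


def validate_table(df: pd.DataFrame, kind: str) -> list[str]:
    """Return a list of human-readable violations (empty if the table is valid).

    Row numbers in messages are 0-based positions within the table.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing required columns: {missing}")

    errors: list[str] = []

    def _rows(mask: pd.Series) -> str:
        idx = [int(i) for i in np.flatnonzero(np.asarray(mask))]
        return f"rows {idx[:20]}" + (" ..." if len(idx) > 20 else "")

    for col, (ckind, nullable) in schema.items():
        if not nullable:
            isna = df[col].isna()
            if isna.any():
                errors.append(f"{kind}.{col}: missing values at {_rows(isna)}")
    for (tkind, col), levels in _CATEGORY_COLUMNS.items():
        if tkind != kind:
            continue
        bad = df[col].notna() & ~df[col].isin(levels)
        if bad.any():
            offending = sorted(df.loc[bad, col].unique())
            errors.append(
                f"{kind}.{col}: values {offending} outside levels {list(levels)}"
                f" at {_rows(bad)}"
            )

    if kind == "location":
        bad = df["population_density"] <= 0
        if bad.any():
            errors.append(f"location.population_density must be > 0 at {_rows(bad)}")
        dup = df["location_id"].duplicated()
        if dup.any():
            errors.append(f"location.location_id duplicated at {_rows(dup)}")
    elif kind == "household":
        bad = df["household_size"] < 1
        if bad.any():
            errors.append(f"household.household_size must be >= 1 at {_rows(bad)}")
        bad = df["density_at_first_visit"] <= 0
        if bad.any():
            errors.append(f"household.density_at_first_visit must be > 0 at {_rows(bad)}")
    elif kind == "participant":
        bad = df["age_years"].notna() & (df["age_years"] < 2)
        if bad.any():
            errors.append(f"participant.age_years must be >= 2 at {_rows(bad)}")
        bad = ~df["visit"].isin(VISITS)
        if bad.any():
            errors.append(f"participant.visit must be in {VISITS} at {_rows(bad)}")
        dup = df.duplicated(subset=["participant_id", "visit"])
        if dup.any():
            errors.append(f"participant: duplicate (participant_id, visit) at {_rows(dup)}")
    elif kind == "contact":
        bad = df["group_size"] < 1
        if bad.any():
            errors.append(f"contact.group_size must be >= 1 at {_rows(bad)}")
        bad = df["age_guess"].notna() & (df["age_guess"] < 0)
        if bad.any():
            errors.append(f"contact.age_guess must be >= 0 at {_rows(bad)}")
        dup = df["event_id"].duplicated()
        if dup.any():
            errors.append(f"contact.event_id duplicated at {_rows(dup)}")
    elif kind == "triangle":
        bad = df["primary_event_id"] == df["secondary_event_id"]
        if bad.any():
            errors.append(
                f"triangle: primary_event_id equals secondary_event_id at {_rows(bad)}"
            )
    return errors


def check_referential_integrity(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Cross-table foreign-key checks on a dict of validated tables."""
    errors: list[str] = []

    def _fk(child: str, col: str, parent: str, pcol: str) -> None:
        if child not in tables or parent not in tables:
            return
        valid = set(tables[parent][pcol].dropna())
        bad = ~tables[child][col].isin(valid)
        if bad.any():
            rows = list(np.flatnonzero(np.asarray(bad)))[:20]
            errors.append(
                f"{child}.{col}: unknown {parent}.{pcol} at rows {rows}"
            )

    _fk("household", "location_id", "location", "location_id")
    _fk("participant", "household_id", "household", "household_id")
    _fk("contact", "participant_id", "participant", "participant_id")
    _fk("triangle", "primary_event_id", "contact", "event_id")
    _fk("triangle", "secondary_event_id", "contact", "event_id")
    if "triangle" in tables and "contact" in tables:
        ev = tables["contact"].set_index("event_id")[["participant_id", "visit"]]
        tri = tables["triangle"]
        for col in ("primary_event_id", "secondary_event_id"):
            known = tri[col].isin(ev.index)
            sub = tri[known]
            mism = (
                (ev.loc[sub[col], "participant_id"].to_numpy() != sub["participant_id"].to_numpy())
                | (ev.loc[sub[col], "visit"].to_numpy() != sub["visit"].to_numpy())
            )
            if mism.any():
                rows = list(np.asarray(sub.index)[mism])[:20]
                errors.append(
                    f"triangle.{col}: event belongs to a different participant-visit"
                    f" at rows {rows}"
                )
    return errors


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the survey CSV tables.

    Empty strings are treated as missing.  Raises :class:`SchemaError` if
    columns are missing and :class:`ValidationError` listing offending rows if
    any invariant is violated.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace("", pd.NA)
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in raw.columns]
    if missing:
        raise SchemaError(f"{kind} table at {path} missing columns: {missing}")
    df = _coerce(raw, kind)
    errors = validate_table(df, kind)
    if errors:
        raise ValidationError(f"{kind} table at {path} invalid:\n" + "\n".join(errors))
    return df


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a table as CSV ("" = missing) in documented column order."""
    cols = list(TABLE_SCHEMAS[kind])
    df[cols].to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Covariate derivations
# ---------------------------------------------------------------------------

_AGE_GROUP_EDGES = (15, 25, 35, 45, 55, 65, 75)


def derive_participant_age_group(age_years) -> str:
    """Map an age in years to the participant age-group label.

    Children aged 2-15 share one band; ages 16-75 fall in 10-year bands; 76+
    is open-ended.  Missing ages map to ``"unknown"``; ages below 2 are
    outside the cohort and raise ``ValueError``.
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)) or age_years is pd.NA:
        return "unknown"
    age = int(age_years)
    if age < 2:
        raise ValueError(f"participant age {age} below cohort minimum of 2")
    for edge, label in zip(_AGE_GROUP_EDGES, PARTICIPANT_AGE_GROUPS):
        if age <= edge:
            return label
    return "76+"


def derive_contact_age_category(category=None, age_guess=None) -> str:
    """Resolve the contact age band, preferring the reported category.

    The respondent's category response wins when present; otherwise a numeric
    age guess is binned into the five bands; with neither, ``"unknown"``.
    """
    if category is not None and category is not pd.NA and not (
        isinstance(category, float) and math.isnan(category)
    ):
        if category not in CONTACT_AGE_LEVELS:
            raise ValueError(f"unknown contact age category {category!r}")
        return str(category)
    if age_guess is None or age_guess is pd.NA or (
        isinstance(age_guess, float) and math.isnan(age_guess)
    ):
        return "unknown"
    guess = int(age_guess)
    if guess < 0:
        raise ValueError(f"negative age guess {guess}")
    if guess <= 4:
        return "0-4"
    if guess <= 19:
        return "5-19"
    if guess <= 39:
        return "20-39"
    if guess <= 64:
        return "40-64"
    return "65+"


_OCCUPATION_MAP = {
    "employed": "employed",
    "worker": "employed",
    "farmer": "employed",
    "self-employed": "employed",
    "student": "student",
    "pupil": "student",
    "retired": "other",
    "unemployed": "other",
    "homemaker": "other",
    "child not in school": "other",
    "preschool": "other",
    "other": "other",
}


def derive_occupation_class(occupation_raw) -> str:
    """Collapse free-text occupation to employed / student / other / unknown.

    "other" covers children not in school and participants reporting being
    unemployed, retired or homemakers; unmapped or missing input is
    ``"unknown"``.
    """
    if occupation_raw is None or occupation_raw is pd.NA or (
        isinstance(occupation_raw, float) and math.isnan(occupation_raw)
    ):
        return "unknown"
    return _OCCUPATION_MAP.get(str(occupation_raw).strip().lower(), "unknown")


def total_reported_contacts(events) -> int:
    """Total contacts for one participant-visit: the sum of event group sizes.

    Events flagged as repeats re-list people already counted in another event
    and contribute zero to the total.  Accepts a contact-table slice or any
    iterable of (group_size, repeat_flag) records.
    """
    if isinstance(events, pd.DataFrame):
        sizes = events["group_size"].to_numpy(dtype=float)
        repeats = events["repeat_flag"].to_numpy(dtype=bool)
    else:
        rows = list(events)
        if not rows:
            return 0
        sizes = np.array([r[0] for r in rows], dtype=float)
        repeats = np.array([bool(r[1]) for r in rows])
    if sizes.size == 0:
        return 0
    return int(sizes[~repeats].sum())


@dataclass(frozen=True)
class MidpointConfig:
    """Category midpoints used to score contact intimacy (time/week).

    Frequency midpoints are contacts per week, duration midpoints minutes per
    contact.  Open-ended bins have no defined midpoint, so their values close
    the bin at a plausible cap: <1/wk at 0.5, 4+/wk at 5 (daily-ish), 60+ min
    at 90.  The ordering of intimacy scores is insensitive to these caps.
    """

    frequency: dict[str, float] = field(
        default_factory=lambda: {"<1/wk": 0.5, "1-3/wk": 2.0, "4+/wk": 5.0}
    )
    duration: dict[str, float] = field(
        default_factory=lambda: {"<10min": 5.0, "10-59min": 34.5, "60+min": 90.0}
    )


DEFAULT_MIDPOINTS = MidpointConfig()


def weekly_contact_minutes(
    frequency: str, duration: str, midpoints: MidpointConfig = DEFAULT_MIDPOINTS
) -> float:
    """Weekly minutes spent with a contact: frequency × duration midpoints."""
    try:
        f = midpoints.frequency[frequency]
        d = midpoints.duration[duration]
    except KeyError as exc:
        raise ValueError(f"unknown frequency/duration level: {exc}") from exc
    return f * d


_AFFIRMATIVE: dict[str, frozenset] = {
    "yes-only": frozenset({"yes"}),
    "probably-yes": frozenset({"yes", "probably yes"}),
    "probably-no": frozenset({"yes", "probably yes", "probably no"}),
}


def dichotomize_certainty(certainty: str, cutoff: str = "probably-yes") -> bool:
    """Collapse the four-level certainty response to connected / not.

    The main analysis treats "yes" and "probably yes" as affirmative
    (``cutoff="probably-yes"``); the stricter ``"yes-only"`` and more lenient
    ``"probably-no"`` cutoffs drive the sensitivity analyses.
    """
    if certainty not in CERTAINTY_LEVELS:
        raise ValueError(f"unknown certainty level {certainty!r}")
    if cutoff not in _AFFIRMATIVE:
        raise ValueError(f"unknown cutoff {cutoff!r}")
    return certainty in _AFFIRMATIVE[cutoff]


def log10_density(density: float) -> float:
    """Base-10 log of population density; effects are per 10-fold increase."""
    density = float(density)
    if not density > 0:
        raise ValueError(f"population density must be positive, got {density}")
    return math.log10(density)
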