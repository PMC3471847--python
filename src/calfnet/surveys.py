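"""Survey and life-history data model: IO, validation, filtering, sampling periods.

The raw material of fission-fusion social analysis is a long table of survey
observations (one row per individual per survey; the survey *is* the group,
membership having been resolved in the field by a chain rule) plus a
life-history table for each individual (sex, birth date, weaning date, mother
identity, last sighting).  This module reads and validates both tables,
removes unidentified animals, collapses surveys into day-level sampling
periods, applies the long-gap mortality rule, and selects analysable calf
subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("calfnet")

#: Sentinel token for an unidentified or uncertain individual.
UNKNOWN_ID = "UNKNOWN"

#: Days per (Julian) year used for all age arithmetic.
DAYS_PER_YEAR = 365.25

#: Years of non-sighting after weaning beyond which an animal is presumed dead.
MORTALITY_GAP_YEARS = 4.0

#: Minimum distinct pre-weaning sighting days for a calf to enter the analysis.
MIN_SIGHTING_DAYS = 15

SURVEY_COLUMNS = ("survey_id", "date", "individual_id")
INDIVIDUAL_COLUMNS = (
    "individual_id",
    "sex",
    "birth_date",
    "weaning_date",
    "mother_id",
    "last_sighting_date",
)

_DATE_COLS = ("birth_date", "weaning_date", "last_sighting_date")


@dataclass(frozen=True)
class SamplingPeriod:
    """One calendar day of surveys: the unit over which co-occurrence is tallied.

    ``groups`` holds one frozenset of individual ids per survey conducted that
    day; an individual may appear in several same-day groups.
    """

    date: pd.Timestamp
    groups: tuple = field(default_factory=tuple)

    def observed(self) -> frozenset:
        """All individuals sighted at least once this day."""
        out: set = set()
        for g in self.groups:
            out |= g
        return frozenset(out)


def _parse_dates(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        if col not in df.columns:
            continue
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: unparseable {col} {df[col].iloc[row]!r} at data row {row + 1}"
            )
        df[col] = parsed
    return df


def read_surveys(path) -> pd.DataFrame:
    """Read a survey table (survey_id, date, individual_id) from CSV.

    Duplicate (survey_id, individual_id) rows are dropped with a warning
    (group membership is a set).  A survey id appearing under two dates is a
    hard error.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = _parse_dates(df, ["date"], path)
    blank = df["survey_id"].isna() | df["individual_id"].isna()
    if blank.any():
        row = int(np.flatnonzero(blank.to_numpy())[0])
        raise ValueError(f"{path}: blank survey_id/individual_id at data row {row + 1}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["survey_id", "individual_id"], keep="first")
    if len(df) < n0:
        logger.warning("read_surveys: dropped %d duplicate membership rows", n0 - len(df))
    dates_per_survey = df.groupby("survey_id")["date"].nunique()
    if (dates_per_survey > 1).any():
        bad_id = dates_per_survey[dates_per_survey > 1].index[0]
        raise ValueError(f"{path}: survey_id {bad_id!r} maps to more than one date")
    logger.info("read_surveys: %d rows, %d surveys, %d individuals",
                len(df), df["survey_id"].nunique(), df["individual_id"].nunique())
    return df.reset_index(drop=True)[list(SURVEY_COLUMNS)]


def write_surveys(surveys: pd.DataFrame, path) -> None:
    out = surveys.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_individuals(path) -> pd.DataFrame:
    """Read the individual metadata table from CSV, indexed by individual_id.

    ``survived_to_10`` is an optional boolean override column.  The ordering
    birth < weaning <= last sighting is enforced where all three are present.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = _parse_dates(df, _DATE_COLS, path)
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"{path}: duplicate individual_id {dup!r}")
    if "survived_to_10" in df.columns:
        df["survived_to_10"] = df["survived_to_10"].map(
            {"True": True, "true": True, "1": True, "1.0": True,
             "False": False, "false": False, "0": False, "0.0": False}
        )
    else:
        df["survived_to_10"] = pd.NA
    df["sex"] = df["sex"].fillna("unknown")
    df = df.set_index("individual_id")
    have = df["birth_date"].notna() & df["weaning_date"].notna()
    bad = have & (df["birth_date"] >= df["weaning_date"])
    if bad.any():
        raise ValueError(
            f"{path}: date ordering violated (need birth < weaning) "
            f"for {list(df.index[bad])[:5]}"
        )
    early = (have & df["last_sighting_date"].notna()
             & (df["weaning_date"] > df["last_sighting_date"]))
    if early.any():
        # possible for rarely-sighted calves; relevant to the mortality rule
        logger.warning("read_individuals: %d individuals last sighted before "
                       "weaning (e.g. %s)", int(early.sum()),
                       list(df.index[early])[:3])
    logger.info("read_individuals: %d individuals", len(df))
    return df


def write_individuals(individuals: pd.DataFrame, path) -> None:
    out = individuals.reset_index()
    for col in _DATE_COLS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def filter_unknown_ids(surveys: pd.DataFrame) -> pd.DataFrame:
    """Drop survey rows whose individual is the UNKNOWN sentinel."""
    keep = surveys["individual_id"] != UNKNOWN_ID
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_unknown_ids: removed %d of %d rows (%.1f%%)",
                    n_removed, len(surveys), 100 * n_removed / len(surveys))
    return surveys[keep].reset_index(drop=True)


def build_sampling_periods(surveys: pd.DataFrame, window=None) -> list:
    """Collapse surveys into day-level sampling periods.

    ``window`` is an optional half-open ``[start, end)`` pair of dates; a
    survey dated exactly on ``end`` is excluded.  Each survey becomes one
    group set; one period is emitted per day with at least one survey.
    """
    df = surveys
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        if start >= end:
            raise ValueError(f"window start {start} must precede end {end}")
        df = df[(df["date"] >= start) & (df["date"] < end)]
    periods = []
    for date, day_df in df.groupby("date", sort=True):
        groups = tuple(
            frozenset(members["individual_id"])
            for _, members in day_df.groupby("survey_id", sort=True)
        )
        periods.append(SamplingPeriod(date=date, groups=groups))
    return periods


def infer_mortality(individual: pd.Series, as_of_date) -> str:
    """Apply the long-gap mortality rule to one individual.

    An animal unsighted for more than :data:`MORTALITY_GAP_YEARS` years after
    weaning is presumed dead.  The gap is measured from the later of the last
    sighting and the weaning date, since the rule concerns post-weaning
    non-sighting.  A ``survived_to_10`` override, when present, wins.

    Returns ``"alive"`` or ``"presumed_dead"``.
    """
    override = individual.get("survived_to_10")
    if override is True:
        return "alive"
    if override is False:
        return "presumed_dead"
    if pd.isna(individual.get("weaning_date")):
        raise ValueError("infer_mortality requires a weaning date")
    if pd.isna(individual.get("last_sighting_date")):
        raise ValueError("infer_mortality requires a last sighting date")
    ref = max(individual["last_sighting_date"], individual["weaning_date"])
    gap_years = (pd.Timestamp(as_of_date) - ref).days / DAYS_PER_YEAR
    return "presumed_dead" if gap_years > MORTALITY_GAP_YEARS else "alive"


def preweaning_sighting_days(individuals: pd.DataFrame, surveys: pd.DataFrame) -> pd.Series:
    """Distinct sighting days inside each individual's [birth, weaning) window."""
    counts = {}
    by_id = surveys.groupby("individual_id")["date"]
    for ind_id, row in individuals.iterrows():
        birth, wean = row["birth_date"], row["weaning_date"]
        if pd.isna(birth) or pd.isna(wean) or ind_id not in by_id.groups:
            counts[ind_id] = 0
            continue
        dates = by_id.get_group(ind_id)
        counts[ind_id] = int(dates[(dates >= birth) & (dates < wean)].nunique())
    return pd.Series(counts, name="preweaning_days")


def select_subjects(
    individuals: pd.DataFrame,
    surveys: pd.DataFrame,
    min_days: int = MIN_SIGHTING_DAYS,
    as_of_date=None,
) -> pd.DataFrame:
    """Select calf subjects with a resolvable weaning-to-age-10 survival outcome.

    A subject must have known birth and weaning dates, at least ``min_days``
    distinct pre-weaning sighting days, and a resolved outcome: survival is
    established by a ``survived_to_10`` override or a sighting at or beyond
    age 10; death by the override or the long-gap rule with the last sighting
    falling before age 10.  Animals still within the 4-year grace window are
    unresolved and excluded.

    Returns a frame indexed by subject id with columns ``survived`` (bool),
    ``sex``, ``preweaning_days``, ``mother_id``, ``weaning_age_years``.
    """
    if as_of_date is None:
        as_of_date = surveys["date"].max()
    as_of_date = pd.Timestamp(as_of_date)
    days = preweaning_sighting_days(individuals, surveys)

    rows = {}
    n_candidates = 0
    for ind_id, row in individuals.iterrows():
        if pd.isna(row["birth_date"]) or pd.isna(row["weaning_date"]):
            continue
        n_candidates += 1
        if days.get(ind_id, 0) < min_days:
            continue
        survived = _resolve_outcome(row, as_of_date)
        if survived is None:
            continue
        wean_age = (row["weaning_date"] - row["birth_date"]).days / DAYS_PER_YEAR
        rows[ind_id] = {
            "survived": survived,
            "sex": row["sex"],
            "preweaning_days": int(days[ind_id]),
            "mother_id": row.get("mother_id"),
            "weaning_age_years": wean_age,
        }
    subjects = pd.DataFrame.from_dict(rows, orient="index")
    subjects.index.name = "subject_id"
    logger.info("select_subjects: %d candidates -> %d subjects (min %d days, as of %s)",
                n_candidates, len(subjects), min_days, as_of_date.date())
    return subjects


def _resolve_outcome(row: pd.Series, as_of_date) -> bool | None:
    override = row.get("survived_to_10")
    if override is True or override is False:
        return bool(override)
    last = row.get("last_sighting_date")
    if pd.isna(last):
        return None
    age10 = row["birth_date"] + pd.Timedelta(days=round(10 * DAYS_PER_YEAR))
    if last >= age10:
        return True
    if infer_mortality(row, as_of_date) == "presumed_dead":
        return False
    return None
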