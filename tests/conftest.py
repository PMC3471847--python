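import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import calfnet as cn

logging.getLogger("calfnet").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A compact population: enough calves to analyse, fast to simulate."""
    return cn.PopulationConfig(seed=42, years=12.0, n_individuals=30,
                               birth_rate=0.3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return cn.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_subjects(small_dataset):
    surveys = cn.filter_unknown_ids(small_dataset.surveys)
    return cn.select_subjects(small_dataset.individuals, surveys)


def make_periods(day_groups):
    """Build sampling periods from {date: [group-iterables]}."""
    return [
        cn.SamplingPeriod(date=pd.Timestamp(d),
                          groups=tuple(frozenset(g) for g in groups))
        for d, groups in sorted(day_groups.items())
    ]


def random_survey_table(rng, n_individuals=8, n_days=40, surveys_per_day=2.0,
                        group_geom_p=0.45, start="2001-01-01"):
    """Small random survey table for oracle comparisons."""
    ids = [f"X{i}" for i in range(n_individuals)]
    rows = []
    sid = 0
    start = pd.Timestamp(start)
    for day in range(n_days):
        for _ in range(rng.poisson(surveys_per_day)):
            size = min(1 + rng.geometric(group_geom_p), n_individuals)
            members = rng.choice(ids, size=size, replace=False)
            for m in members:
                rows.append({"survey_id": f"S{sid:05d}",
                             "date": start + pd.Timedelta(days=day),
                             "individual_id": m})
            sid += 1
    if not rows:  # guarantee at least one survey
        rows.append({"survey_id": "S00000", "date": start, "individual_id": ids[0]})
    return pd.DataFrame(rows)


def surveys_to_day_groups(surveys):
    """List (per day) of group membership sets, straight off the raw rows."""
    return [
        [set(g["individual_id"]) for _, g in day_df.groupby("survey_id")]
        for _, day_df in surveys.groupby("date")
    ]


def brute_force_dyad_counts(surveys, id_a, id_b, day_groups=None):
    """Day-by-day dyad tally straight off the raw survey rows."""
    if day_groups is None:
        day_groups = surveys_to_day_groups(surveys)
    x = ya = yb = yab = 0
    for groups in day_groups:
        together = any(id_a in g and id_b in g for g in groups)
        a_seen = any(id_a in g for g in groups)
        b_seen = any(id_b in g for g in groups)
        if together:
            x += 1
        elif a_seen and b_seen:
            yab += 1
        elif a_seen:
            ya += 1
        elif b_seen:
            yb += 1
    return x, ya, yb, yab
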