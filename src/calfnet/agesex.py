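"""Age-sex class assignment and survivor/non-survivor tie-strength comparisons.

Every member of a calf's infancy network is assigned to one of six age-sex
classes (calf, juvenile, adult x female, male) by classifying each of its
in-window sighting days by age on that day — calf [0, 4), juvenile [4, 10),
adult [10, inf) years — and taking the majority class; an exact tie goes to
the older class.  Per subject, the number of associates and the summed HWI
tie strength in each class are tabulated, and survivors are compared with
non-survivors per sex and class by two-sample permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .inference import PermutationResult, permutation_test_two_sample
from .surveys import DAYS_PER_YEAR

logger = logging.getLogger("calfnet")

AGE_BOUNDS_YEARS = (4.0, 10.0)
AGE_CLASSES = ("calf", "juvenile", "adult")
AGE_SEX_CLASSES = ("calf_F", "calf_M", "juvenile_F", "juvenile_M",
                   "adult_F", "adult_M")


def age_class_at(age_years: float) -> str:
    """Age class for an exact age: [0,4) calf, [4,10) juvenile, >=10 adult."""
    if age_years < AGE_BOUNDS_YEARS[0]:
        return "calf"
    if age_years < AGE_BOUNDS_YEARS[1]:
        return "juvenile"
    return "adult"


def assign_age_class(birth_date, observation_dates, tie_break: str = "older") -> str:
    """Majority-rule age class over a member's in-window sighting days.

    Each sighting day is classified by the member's age that day; the class
    with the most days wins.  ``tie_break`` resolves exact ties toward the
    ``"older"`` (default) or ``"younger"`` class.
    """
    dates = np.asarray(observation_dates)
    if not np.issubdtype(dates.dtype, np.datetime64):
        dates = pd.to_datetime(pd.Index(observation_dates)).values
    dates = dates.astype("datetime64[D]")
    if dates.size == 0:
        raise ValueError("member has no in-window observations")
    if pd.isna(birth_date):
        raise ValueError("member birth date unknown")
    birth = np.datetime64(pd.Timestamp(birth_date), "D")
    ages = (dates - birth).astype(int) / DAYS_PER_YEAR
    counts = [int((ages < AGE_BOUNDS_YEARS[0]).sum()),
              int(((ages >= AGE_BOUNDS_YEARS[0])
                   & (ages < AGE_BOUNDS_YEARS[1])).sum()),
              int((ages >= AGE_BOUNDS_YEARS[1]).sum())]
    tallies = dict(zip(AGE_CLASSES, counts))
    best = max(tallies.values())
    winners = [c for c in AGE_CLASSES if tallies[c] == best]
    if tie_break == "older":
        return winners[-1]
    if tie_break == "younger":
        return winners[0]
    raise ValueError("tie_break must be 'older' or 'younger'")


def assign_network_classes(G: nx.Graph, surveys: pd.DataFrame,
                           individuals: pd.DataFrame, window,
                           tie_break: str = "older", assoc=None) -> dict:
    """Age-sex class per network member, e.g. ``"juvenile_M"``.

    Unknown-sex members get suffix ``_U`` and are tracked separately
    downstream.  Observation dates are each member's distinct in-window
    sighting days.  Passing a precomputed
    :class:`~calfnet.association.AssociationData` routes the day
    classification through its event arrays, which is much faster when many
    subject networks share one survey table.
    """
    if assoc is not None and individuals["birth_date"].notna().all():
        return _assign_classes_from_events(G, individuals, window, tie_break,
                                           assoc)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = surveys[(surveys["date"] >= start) & (surveys["date"] < end)]
    dates_by_id = sub.groupby("individual_id")["date"].unique()
    births = individuals["birth_date"].to_dict()
    sexes = individuals["sex"].to_dict()
    classes = {}
    for node in G.nodes:
        sex = sexes.get(node, G.nodes[node].get("sex", "unknown"))
        birth = births.get(node, pd.NaT)
        obs = dates_by_id.get(node, [])
        ac = assign_age_class(birth, obs, tie_break=tie_break)
        suffix = {"F": "F", "M": "M"}.get(str(sex), "U")
        classes[node] = f"{ac}_{suffix}"
    return classes


def _assign_classes_from_events(G, individuals, window, tie_break, assoc):
    """Vectorized majority-rule class assignment off precomputed day events."""
    d0, d1 = assoc._day_range(window)
    mask = (assoc.obs_day >= d0) & (assoc.obs_day < d1)
    days, inds = assoc.obs_day[mask], assoc.obs_ind[mask]
    epoch = assoc._epoch
    birth_day = np.array([
        (individuals.loc[i, "birth_date"] - epoch).days
        if i in individuals.index else np.iinfo(np.int32).min
        for i in assoc.ids])
    ages = (days - birth_day[inds]) / DAYS_PER_YEAR
    cls_idx = np.digitize(ages, AGE_BOUNDS_YEARS)
    tally = np.zeros((len(assoc.ids), 3), dtype=int)
    np.add.at(tally, (inds, cls_idx), 1)
    sexes = individuals["sex"].to_dict()
    idx = {i: k for k, i in enumerate(assoc.ids)}
    classes = {}
    for node in G.nodes:
        t = tally[idx[node]]
        if t.sum() == 0:
            raise ValueError(f"member {node!r} has no in-window observations")
        best = t.max()
        winners = [k for k in range(3) if t[k] == best]
        k = winners[-1] if tie_break == "older" else winners[0]
        suffix = {"F": "F", "M": "M"}.get(str(sexes.get(node, "unknown")), "U")
        classes[node] = f"{AGE_CLASSES[k]}_{suffix}"
    return classes


@dataclass
class AgeSexProfile:
    """Per-subject associate counts and summed tie strengths by age-sex class."""

    subject_id: str
    counts: dict = field(default_factory=dict)
    strengths: dict = field(default_factory=dict)
    unknown_count: int = 0
    unknown_strength: float = 0.0


def compute_profile(G: nx.Graph, subject, classes: dict,
                    exclude_mother: str | None = None) -> AgeSexProfile:
    """Tally the subject's direct ties by age-sex class.

    Counts sum to the subject's binary degree and strengths to its raw
    strength (sexed classes plus the unknown-sex bucket).  Pass the mother id
    via ``exclude_mother`` to drop the maternal tie from the adult-female
    sums (sensitivity variant); by default she is included.
    """
    prof = AgeSexProfile(subject_id=subject,
                         counts={c: 0 for c in AGE_SEX_CLASSES},
                         strengths={c: 0.0 for c in AGE_SEX_CLASSES})
    for nbr in G.neighbors(subject):
        if exclude_mother is not None and nbr == exclude_mother:
            continue
        w = G.edges[subject, nbr]["weight"]
        cls = classes[nbr]
        if cls in prof.counts:
            prof.counts[cls] += 1
            prof.strengths[cls] += w
        else:
            prof.unknown_count += 1
            prof.unknown_strength += w
    return prof


def profiles_table(profiles) -> pd.DataFrame:
    """Long-format table (subject_id, class, count, strength) over all profiles."""
    rows = []
    for p in profiles:
        for cls in AGE_SEX_CLASSES:
            rows.append({"subject_id": p.subject_id, "class": cls,
                         "count": p.counts[cls], "strength": p.strengths[cls]})
        if p.unknown_count:
            rows.append({"subject_id": p.subject_id, "class": "unknown_sex",
                         "count": p.unknown_count, "strength": p.unknown_strength})
    return pd.DataFrame(rows, columns=["subject_id", "class", "count", "strength"])


def compare_by_survival(profiles: pd.DataFrame, subjects: pd.DataFrame,
                        sex: str, cls: str, measure: str = "strength",
                        n_perm: int = 10000, seed=None):
    """Permutation test of one class measure between survivors and non-survivors.

    ``profiles`` is the long table from :func:`profiles_table`; ``subjects``
    supplies per-subject sex and survival.  Returns a
    :class:`PermutationResult`, or a string reason when one survival group is
    empty and the test must be skipped.
    """
    if measure not in ("strength", "count"):
        raise ValueError("measure must be 'strength' or 'count'")
    sel = subjects[subjects["sex"] == sex]
    wide = profiles[profiles["class"] == cls].set_index("subject_id")[measure]
    vals = wide.reindex(sel.index).fillna(0.0)
    surv = vals[sel["survived"].astype(bool)].to_numpy(float)
    died = vals[~sel["survived"].astype(bool)].to_numpy(float)
    if len(surv) == 0 or len(died) == 0:
        reason = (f"skipped {sex}/{cls}/{measure}: "
                  f"{len(surv)} survivors vs {len(died)} non-survivors")
        logger.warning(reason)
        return reason
    return permutation_test_two_sample(died, surv, n_perm=n_perm, seed=seed)


def survival_comparison_grid(profiles: pd.DataFrame, subjects: pd.DataFrame,
                             n_perm: int = 10000, seed=None) -> pd.DataFrame:
    """Full 2 sexes x 6 classes x {count, strength} comparison grid.

    Emits one row per test with group means +/- SEM, the observed difference
    (non-survivors minus survivors), and the permutation p-value; skipped
    tests carry the reason instead.  Sub-seeds are drawn deterministically
    from ``seed`` so the grid is reproducible as a whole.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("F", "M"):
        for cls in AGE_SEX_CLASSES:
            for measure in ("count", "strength"):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                sel = subjects[subjects["sex"] == sex]
                vals = (profiles[profiles["class"] == cls]
                        .set_index("subject_id")[measure]
                        .reindex(sel.index).fillna(0.0))
                surv = vals[sel["survived"].astype(bool)]
                died = vals[~sel["survived"].astype(bool)]
                row = {"sex": sex, "class": cls, "measure": measure,
                       "n_survived": len(surv), "n_died": len(died),
                       "mean_survived": surv.mean() if len(surv) else np.nan,
                       "sem_survived": surv.sem() if len(surv) > 1 else np.nan,
                       "mean_died": died.mean() if len(died) else np.nan,
                       "sem_died": died.sem() if len(died) > 1 else np.nan}
                res = compare_by_survival(profiles, subjects, sex, cls, measure,
                                          n_perm=n_perm, seed=sub_seed)
                if isinstance(res, PermutationResult):
                    row.update({"observed_difference": died.mean() - surv.mean(),
                                "p_value": res.p_value,
                                "n_permutations": res.n_permutations,
                                "exact": res.exact, "skipped": ""})
                else:
                    row.update({"observed_difference": np.nan, "p_value": np.nan,
                                "n_permutations": 0, "exact": False,
                                "skipped": res})
                rows.append(row)
    return pd.DataFrame(rows)
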