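"""Dyadic association: half-weight index and per-subject infancy networks.

Association between two animals A and B is tallied per sampling period (one
calendar day).  Each day is classified once per dyad: a day on which A and B
share at least one survey group counts toward X; a day on which both are
sighted but never together counts toward Yab; days on which only one is
sighted count toward Ya or Yb.  The half-weight index

    HWI = X / (X + 0.5 * (Ya + Yb) + Yab)

corrects for unequal sighting effort and lies in [0, 1].

A calf's infancy network is built from *all* surveys during its birth-to-
weaning window — whether or not the calf itself was present — over every
individual sighted at least ``min_sightings`` days in that window, so the
network captures indirect as well as direct connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("calfnet")


@dataclass(frozen=True)
class DyadCounts:
    """Sampling-period tallies for one dyad (A, B).

    x: days together in the same group; ya: days A sighted without B;
    yb: days B sighted without A; yab: days both sighted, never together.
    """

    x: int
    ya: int
    yb: int
    yab: int

    def __post_init__(self):
        if min(self.x, self.ya, self.yb, self.yab) < 0:
            raise ValueError("dyad counts must be nonnegative")

    @property
    def denominator(self) -> float:
        return self.x + 0.5 * (self.ya + self.yb) + self.yab


class NeverObservedError(ValueError):
    """Raised when an HWI is requested for a dyad with no sightings at all."""


def half_weight_index(counts: DyadCounts) -> float:
    """Half-weight association index X / (X + 0.5(Ya+Yb) + Yab)."""
    denom = counts.denominator
    if denom == 0:
        raise NeverObservedError("dyad never observed: HWI undefined")
    return counts.x / denom


def compute_dyad_counts(periods, id_a: str, id_b: str) -> DyadCounts:
    """Classify each sampling period for one dyad (reference implementation).

    Together takes precedence over apart when A and B co-occur in one survey
    but not another on the same day.
    """
    if id_a == id_b:
        raise ValueError("dyad requires two distinct individuals")
    x = ya = yb = yab = 0
    for period in periods:
        together = any(id_a in g and id_b in g for g in period.groups)
        if together:
            x += 1
            continue
        obs = period.observed()
        a_seen, b_seen = id_a in obs, id_b in obs
        if a_seen and b_seen:
            yab += 1
        elif a_seen:
            ya += 1
        elif b_seen:
            yb += 1
    return DyadCounts(x, ya, yb, yab)


class AssociationData:
    """Day-level co-membership events precomputed once for fast window queries.

    Builds, from a survey table, (day, individual) observation events and
    deduplicated (day, i, j) together-pair events so that dyad counts over any
    date window reduce to array masking plus one small matrix product.  Share
    one instance across all subjects of a dataset.
    """

    def __init__(self, surveys: pd.DataFrame):
        df = surveys
        self.ids = np.array(sorted(df["individual_id"].unique()))
        self._idx = {i: k for k, i in enumerate(self.ids)}
        n = len(self.ids)
        dates = pd.to_datetime(df["date"])
        self._epoch = dates.min() if len(df) else pd.Timestamp("2000-01-01")
        day = ((dates - self._epoch).dt.days).to_numpy()
        ind = df["individual_id"].map(self._idx).to_numpy()

        obs = np.unique(np.stack([day, ind], axis=1), axis=0) if len(df) else np.empty((0, 2), int)
        self.obs_day, self.obs_ind = obs[:, 0], obs[:, 1]

        tg_day, tg_i, tg_j = [], [], []
        if len(df):
            by_day = pd.DataFrame({"day": day, "survey_id": df["survey_id"].to_numpy(),
                                   "ind": ind})
            for d, day_df in by_day.groupby("day", sort=True):
                pairs = set()
                for _, g in day_df.groupby("survey_id", sort=False):
                    members = np.unique(g["ind"].to_numpy())
                    for a, b in combinations(members.tolist(), 2):
                        pairs.add((a, b))
                for a, b in pairs:
                    tg_day.append(d)
                    tg_i.append(a)
                    tg_j.append(b)
        self.tg_day = np.array(tg_day, dtype=int)
        self.tg_i = np.array(tg_i, dtype=int)
        self.tg_j = np.array(tg_j, dtype=int)
        self.n = n

    def _day_range(self, window) -> tuple[int, int]:
        start = (pd.Timestamp(window[0]) - self._epoch).days
        end = (pd.Timestamp(window[1]) - self._epoch).days
        return start, end

    def sighting_days(self, window) -> pd.Series:
        """Distinct sighting days per individual inside the half-open window."""
        d0, d1 = self._day_range(window)
        mask = (self.obs_day >= d0) & (self.obs_day < d1)
        counts = np.bincount(self.obs_ind[mask], minlength=self.n)
        return pd.Series(counts, index=self.ids, name="sighting_days")

    def dyad_counts_matrix(self, window, node_ids) -> dict:
        """X / Ya / Yb / Yab matrices over ``node_ids`` for the window.

        Returns dict with keys ``ids`` (array), ``x``, ``both``, ``obs_days``;
        derived counts: yab = both - x, ya = obs_days[i] - both.
        """
        d0, d1 = self._day_range(window)
        sub = np.array([self._idx[i] for i in node_ids])
        m = len(sub)
        inv = -np.ones(self.n, dtype=int)
        inv[sub] = np.arange(m)

        omask = (self.obs_day >= d0) & (self.obs_day < d1) & (inv[self.obs_ind] >= 0)
        days = self.obs_day[omask] - d0
        n_days = max(d1 - d0, 1)
        B = np.zeros((m, n_days), dtype=np.float64)
        B[inv[self.obs_ind[omask]], days] = 1.0
        both = (B @ B.T).astype(int)
        obs_days = B.sum(axis=1).astype(int)

        x = np.zeros((m, m), dtype=int)
        if len(self.tg_day):
            tmask = ((self.tg_day >= d0) & (self.tg_day < d1)
                     & (inv[self.tg_i] >= 0) & (inv[self.tg_j] >= 0))
            ii = inv[self.tg_i[tmask]]
            jj = inv[self.tg_j[tmask]]
            np.add.at(x, (ii, jj), 1)
            x = x + x.T
        return {"ids": np.asarray(node_ids), "x": x, "both": both, "obs_days": obs_days}


def build_infancy_network(
    subject_id: str,
    surveys: pd.DataFrame,
    individuals: pd.DataFrame,
    min_sightings: int = 15,
    assoc: AssociationData | None = None,
    count_unit: str = "days",
) -> nx.Graph:
    """Weighted association network for one calf's birth-to-weaning window.

    Nodes are all individuals sighted at least ``min_sightings`` distinct days
    (or survey rows, with ``count_unit="rows"``) inside the subject's infancy
    window; every pair ever seen together in-window is connected with its HWI
    as the edge weight (no threshold).  The network may be disconnected.

    Raises ``ValueError`` if the subject itself fails the sighting threshold.
    """
    if subject_id not in individuals.index:
        raise ValueError(f"unknown subject {subject_id!r}")
    row = individuals.loc[subject_id]
    if pd.isna(row["birth_date"]) or pd.isna(row["weaning_date"]):
        raise ValueError(f"subject {subject_id!r} lacks birth/weaning dates")
    window = (row["birth_date"], row["weaning_date"])
    if assoc is None:
        assoc = AssociationData(surveys)

    if count_unit == "days":
        counts = assoc.sighting_days(window)
    elif count_unit == "rows":
        d = surveys[(surveys["date"] >= window[0]) & (surveys["date"] < window[1])]
        counts = d["individual_id"].value_counts().reindex(assoc.ids, fill_value=0)
    else:
        raise ValueError("count_unit must be 'days' or 'rows'")
    nodes = list(counts.index[counts >= min_sightings])
    if subject_id not in nodes:
        raise ValueError(
            f"subject {subject_id!r} not eligible: "
            f"{int(counts.get(subject_id, 0))} < {min_sightings} in-window sightings"
        )
    sight_days = assoc.sighting_days(window)

    mats = assoc.dyad_counts_matrix(window, nodes)
    x, both, obs = mats["x"], mats["both"], mats["obs_days"]

    G = nx.Graph(subject_id=subject_id,
                 window_start=str(window[0].date()), window_end=str(window[1].date()),
                 min_sightings=min_sightings)
    sexes = individuals["sex"].to_dict()
    for node in nodes:
        G.add_node(node, sex=sexes.get(node, "unknown"),
                   sighting_days=int(sight_days[node]))
    ai, bi = np.nonzero(np.triu(x, k=1))
    xs = x[ai, bi]
    boths = both[ai, bi]
    yabs = boths - xs
    yas = obs[ai] - boths
    ybs = obs[bi] - boths
    hwis = xs / (xs + 0.5 * (yas + ybs) + yabs)
    G.add_edges_from(
        (nodes[a], nodes[b],
         {"weight": float(h), "x": int(xv), "ya": int(yav),
          "yb": int(ybv), "yab": int(yabv)})
        for a, b, h, xv, yav, ybv, yabv
        in zip(ai, bi, hwis, xs, yas, ybs, yabs))
    logger.info("infancy network %s: %d nodes, %d edges",
                subject_id, G.number_of_nodes(), G.number_of_edges())
    return G


def network_to_edgelist(G: nx.Graph) -> pd.DataFrame:
    """Weighted edge list (id_a, id_b, hwi, x, ya, yb, yab) for export."""
    rows = [
        {"id_a": a, "id_b": b, "hwi": d["weight"],
         "x": d["x"], "ya": d["ya"], "yb": d["yb"], "yab": d["yab"]}
        for a, b, d in sorted(G.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "hwi", "x", "ya", "yb", "yab"])


def write_network(G: nx.Graph, edgelist_path=None, graphml_path=None) -> None:
    if edgelist_path is not None:
        network_to_edgelist(G).to_csv(edgelist_path, index=False)
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
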