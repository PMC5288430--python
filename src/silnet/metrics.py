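"""Per-student network quantities on school friendship-nomination networks.

Three families of measures are computed on each school's directed
nomination network (the network boundary is one school's two surveyed
grades; measures never cross schools):

* **Peer exposure** (Valente): the percentage of regular smokers in the
  ego's first, second and third out-degree separation sets, where the
  degree-k separation set holds the alters at directed geodesic distance
  exactly k (read off the non-zero pattern of row *ego* of the adjacency
  power X^k after removing the ego and members of lower sets).
* **Relative distance to smokers**: the ego's mean geodesic distance to
  smoking alters divided by its mean distance to all alters, as a
  percentage; unreachable alters enter at the maximum finite geodesic
  observed in that school's network.
* **Individual Coleman homophily index**: the ego's excess of same-group
  out-ties over the random-mixing expectation, scaled to [-1, 1].

Missing-value convention: quantities that are undefined for an ego (empty
separation set, no smokers in the school, zero out-degree) are returned as
``None`` (``NaN`` in table output); such students are excluded from the
regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .types import NominationEdge, StudentRecord

MAX_SEPARATION = 3


@dataclass
class SchoolNetwork:
    """Roster-aligned adjacency and node labels for one school.

    ``adjacency[i, j] == 1`` iff student ``roster[i]`` nominated
    ``roster[j]``.  The diagonal is zero and row sums are at most five.
    """

    school_id: str
    roster: list
    adjacency: np.ndarray            # dense 0/1, square
    smoking: np.ndarray              # 0/1 per node (regular smoker)
    groups: np.ndarray               # parental-education group label per node

    def __post_init__(self):
        n = len(self.roster)
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match roster")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency has a non-zero diagonal")
        self.smoking = np.asarray(self.smoking, dtype=np.int8)
        self.groups = np.asarray(self.groups)
        self._index = {s: i for i, s in enumerate(self.roster)}
        self._dist = None

    @property
    def n(self) -> int:
        return len(self.roster)

    def index_of(self, student_id) -> int:
        return self._index[student_id]

    def distance_matrix(self) -> np.ndarray:
        """Directed geodesic distances (np.inf where unreachable)."""
        if self._dist is None:
            self._dist = shortest_path(
                csr_matrix(self.adjacency), method="D", unweighted=True,
                directed=True,
            )
        return self._dist

    def max_finite_distance(self) -> Optional[float]:
        """Largest finite off-diagonal geodesic in this school, if any."""
        d = self.distance_matrix()
        finite = d[np.isfinite(d) & (d > 0)]
        return float(finite.max()) if finite.size else None


@dataclass
class ExposureProfile:
    """Per-student exposure and homophily measures (percent scales)."""

    student_id: str
    out_degree: int
    exp_deg1: Optional[float]
    exp_deg2: Optional[float]
    exp_deg3: Optional[float]
    rel_dist_smokers: Optional[float]
    dist_all_alters: Optional[float]
    dist_smoking_alters: Optional[float]
    coleman_parental_edu: Optional[float]


def build_school_networks(
    records: Sequence[StudentRecord],
    edges: Sequence[NominationEdge],
    group_field: str = "father_edu",
) -> dict:
    """Assemble one :class:`SchoolNetwork` per school from a cohort.

    ``group_field`` selects the attribute used as the homophily grouping
    (father's education by default; "unknown" is a group of its own).
    """
    by_school: dict[str, list[StudentRecord]] = {}
    for r in records:
        by_school.setdefault(r.school_id, []).append(r)
    nets = {}
    rec_by_id = {r.student_id: r for r in records}
    edges_by_school: dict[str, list[NominationEdge]] = {}
    for e in edges:
        if e.ego_id not in rec_by_id or e.alter_id not in rec_by_id:
            missing = e.ego_id if e.ego_id not in rec_by_id else e.alter_id
            raise ValueError(f"edge endpoint {missing!r} not in roster")
        edges_by_school.setdefault(rec_by_id[e.ego_id].school_id, []).append(e)
    for school_id, recs in by_school.items():
        roster = [r.student_id for r in recs]
        idx = {s: i for i, s in enumerate(roster)}
        n = len(roster)
        adj = np.zeros((n, n), dtype=np.int8)
        for e in edges_by_school.get(school_id, []):
            adj[idx[e.ego_id], idx[e.alter_id]] = 1
        groups = np.array([getattr(r, group_field) for r in recs], dtype=object)
        if any(g is None for g in groups):
            raise ValueError(
                f"school {school_id}: unlabeled {group_field} (impute first)"
            )
        nets[school_id] = SchoolNetwork(
            school_id=school_id,
            roster=roster,
            adjacency=adj,
            smoking=np.array([int(r.regular_smoker) for r in recs]),
            groups=groups,
        )
    return nets


def separation_sets(net: SchoolNetwork, ego, variant: str = "exact"):
    """First/second/third out-degree separation sets of an ego.

    With ``variant="exact"`` (default) set_k holds the alters at directed
    geodesic distance exactly k: the non-zero pattern of row ego of X^k
    with the ego and members of lower-degree sets removed.  With
    ``variant="walk"`` set_k is the raw non-zero pattern of X^k (alters
    reachable by some length-k walk, ego excluded) — kept as a switch for
    the cruder adjacency-power reading.
    """
    if variant not in ("exact", "walk"):
        raise ValueError(f"unknown variant {variant!r}")
    i = net.index_of(ego)
    row = np.zeros(net.n, dtype=np.int64)
    row[i] = 1
    sets = []
    claimed = {i}
    adj = net.adjacency.astype(np.int64)
    for _k in range(MAX_SEPARATION):
        row = row @ adj
        reached = set(np.nonzero(row)[0]) - {i}
        if variant == "exact":
            reached -= claimed
            claimed |= reached
        sets.append(frozenset(net.roster[j] for j in reached))
    return tuple(sets)


def exposure_at_degree(net: SchoolNetwork, ego, k: int,
                       variant: str = "exact") -> Optional[float]:
    """Percent of regular smokers in the ego's degree-k separation set.

    Returns ``None`` when the set is empty (exposure undefined).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"separation degree must be 1, 2 or 3, got {k}")
    members = separation_sets(net, ego, variant=variant)[k - 1]
    if not members:
        return None
    smokers = sum(net.smoking[net.index_of(s)] for s in members)
    return 100.0 * smokers / len(members)


def _ego_distances(net: SchoolNetwork, i: int, mode: str) -> np.ndarray:
    if mode == "directed":
        d = net.distance_matrix()[i].copy()
    elif mode == "symmetrized":
        sym = np.minimum(net.distance_matrix(), net.distance_matrix().T)
        d = sym[i].copy()
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return d


def relative_distance_to_smokers(net: SchoolNetwork, ego,
                                 mode: str = "directed") -> Optional[float]:
    """Relative distance to smokers as a percent: 100 x (mean distance to
    smoking alters) / (mean distance to all alters).

    Alters are every other node in the school network.  Unreachable alters
    enter at the maximum finite geodesic observed in the school.  ``None``
    when no alter smokes (s = 0) or when no finite distance exists at all.
    Exactly 100 when every alter smokes.
    """
    parts = _relative_distance_parts(net, ego, mode)
    return None if parts is None else parts[0]


def _relative_distance_parts(net: SchoolNetwork, ego, mode: str = "directed"):
    """(relative %, mean distance to all, mean distance to smokers)."""
    i = net.index_of(ego)
    if net.n < 2:
        return None
    d = _ego_distances(net, i, mode)
    d = np.delete(d, i)
    y = np.delete(net.smoking, i)
    maxfin = net.max_finite_distance()
    if maxfin is None:
        return None  # edgeless school: every distance undefined
    d[~np.isfinite(d)] = maxfin
    g = d.size
    s = int(y.sum())
    mean_all = float(d.sum() / g)
    if s == 0 or mean_all == 0:
        return None
    mean_smokers = float((d * y).sum() / s)
    if s == g:
        # every alter smokes: the two means coincide by construction
        return 100.0, mean_all, mean_all
    return 100.0 * mean_smokers / mean_all, mean_all, mean_smokers


def coleman_index(net: SchoolNetwork, ego, grouping: Optional[str] = None) -> Optional[float]:
    """Individual Coleman homophily index of an ego in [-1, 1].

    With out-degree d, m same-group out-ties, and same-group availability
    p = (n_g - 1)/(n - 1) (n_g the size of the ego's group in the school):

        index = (m/d - p) / (1 - p)   if m/d >= p
        index = (m/d - p) / p         otherwise

    so all-internal ties give 1, all-external give -1 and random mixing
    gives 0.  ``None`` when d = 0 or when p is 0 or 1 (the ego's group is
    a singleton or the whole school).  ``grouping`` may supply an
    alternative per-node label array aligned with the roster.
    """
    i = net.index_of(ego)
    groups = net.groups if grouping is None else np.asarray(grouping)
    if any(g is None for g in groups):
        raise ValueError("unlabeled alters: every node needs a group label")
    out = np.nonzero(net.adjacency[i])[0]
    d = out.size
    if d == 0:
        return None
    n_g = int(np.sum(groups == groups[i]))
    p = (n_g - 1) / (net.n - 1)
    if p <= 0.0 or p >= 1.0:
        return None
    m = int(np.sum(groups[out] == groups[i]))
    ratio = m / d
    if ratio >= p:
        return (ratio - p) / (1.0 - p)
    return (ratio - p) / p


def coleman_index_network(net: SchoolNetwork, group=None) -> Optional[float]:
    """Group- or network-level Coleman homophily index.

    For one group g the counts are pooled over its members: with M the
    number of g-to-g out-ties, D all out-ties of g members and
    p = (n_g - 1)/(n - 1), the index is (M/D - p)/(1 - p) when M/D >= p
    and (M/D - p)/p otherwise.  With ``group=None`` returns the out-tie
    weighted mean over all groups — approximately 0 under random mixing
    (unlike the mean of the individual index, whose two-branch scaling
    makes it negatively biased at small out-degree).
    """
    if group is None:
        labels = [g for g in dict.fromkeys(net.groups)]
        vals, weights = [], []
        for g in labels:
            members = np.flatnonzero(net.groups == g)
            d = int(net.adjacency[members].sum())
            v = coleman_index_network(net, g)
            if v is not None and d > 0:
                vals.append(v)
                weights.append(d)
        if not vals:
            return None
        return float(np.average(vals, weights=weights))
    members = np.flatnonzero(net.groups == group)
    n_g = members.size
    if n_g == 0:
        raise ValueError(f"no members in group {group!r}")
    p = (n_g - 1) / (net.n - 1)
    if p <= 0.0 or p >= 1.0:
        return None
    sub = net.adjacency[members]
    D = int(sub.sum())
    if D == 0:
        return None
    M = int(sub[:, members].sum())
    ratio = M / D
    if ratio >= p:
        return (ratio - p) / (1.0 - p)
    return (ratio - p) / p


def household_exposure(record: StudentRecord) -> int:
    """Number of smoking household members (validated pass-through)."""
    h = record.household_smokers
    if h is None:
        raise ValueError(f"{record.student_id}: household smoker count missing")
    if h < 0:
        raise ValueError(f"{record.student_id}: negative household smokers")
    return int(h)


def exposure_profile(net: SchoolNetwork, ego, variant: str = "exact",
                     distance_mode: str = "directed") -> ExposureProfile:
    """All network measures for one ego."""
    i = net.index_of(ego)
    parts = _relative_distance_parts(net, ego, distance_mode)
    return ExposureProfile(
        student_id=ego,
        out_degree=int(net.adjacency[i].sum()),
        exp_deg1=exposure_at_degree(net, ego, 1, variant),
        exp_deg2=exposure_at_degree(net, ego, 2, variant),
        exp_deg3=exposure_at_degree(net, ego, 3, variant),
        rel_dist_smokers=None if parts is None else parts[0],
        dist_all_alters=None if parts is None else parts[1],
        dist_smoking_alters=None if parts is None else parts[2],
        coleman_parental_edu=coleman_index(net, ego),
    )


def age_band(age: int) -> str:
    if age < 14:
        return "<14"
    if age <= 15:
        return "14-15"
    return "16+"


def compute_metrics_table(
    records: Sequence[StudentRecord],
    edges: Sequence[NominationEdge],
    composites=None,
    variant: str = "exact",
    distance_mode: str = "directed",
    group_field: str = "father_edu",
) -> pd.DataFrame:
    """One row per respondent: attributes, SES composite, network measures.

    ``composites`` (from :func:`silnet.ses.score_cohort`) is joined in when
    given.  Undefined network measures appear as ``NaN``.
    """
    nets = build_school_networks(records, edges, group_field=group_field)
    comp_by_id = {c.student_id: c for c in (composites or [])}
    rows = []
    for r in records:
        prof = exposure_profile(nets[r.school_id], r.student_id,
                                variant=variant, distance_mode=distance_mode)
        row = {
            "student_id": r.student_id,
            "school_id": r.school_id,
            "country": r.country,
            "grade": r.grade,
            "sex": r.sex,
            "age": r.age,
            "age_band": age_band(r.age),
            "tried_smoking": int(r.tried_smoking),
            "regular_smoker": int(r.regular_smoker),
            "dependence_score": r.dependence_score,
            "household_smokers": household_exposure(r),
            "out_degree": prof.out_degree,
            "exp_deg1": prof.exp_deg1,
            "exp_deg2": prof.exp_deg2,
            "exp_deg3": prof.exp_deg3,
            "rel_dist_smokers": prof.rel_dist_smokers,
            "dist_all_alters": prof.dist_all_alters,
            "dist_smoking_alters": prof.dist_smoking_alters,
            "coleman_parental_edu": prof.coleman_parental_edu,
        }
        c = comp_by_id.get(r.student_id)
        if c is not None:
            row["lowest_count"] = c.lowest_count
            row["ses_band"] = c.lowest_count_banded
            row["fas_band"] = c.fas_band
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.astype({c: float for c in
                      ("exp_deg1", "exp_deg2", "exp_deg3", "rel_dist_smokers",
                       "dist_all_alters", "dist_smoking_alters",
                       "coleman_parental_edu")})
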