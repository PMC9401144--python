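"""Episode-of-care construction from claims and the duration of stay D^in.

Claims of one patient are linked into per-fracture episodes with two
thresholds: an inpatient admission within ``tau1`` days of a previous
discharge is a hospital transfer belonging to the same fracture, and an
outpatient visit within ``tau2`` days of an admission, discharge, or
already-linked visit date is continuing care for the same fracture.  Both
rules are applied transitively (closure).  D^in of an episode runs from the
first admission to the last discharge across transfers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageParams",
    "Episode",
    "link_records",
    "duration_of_stay",
    "filter_cases",
    "interval_distributions",
    "case_summary",
]


@dataclass(frozen=True)
class LinkageParams:
    """Linkage thresholds: tau1 = transfer gap (days), tau2 = care-continuity
    gap (days).  Defaults are the 10/35-day working points chosen from the
    inpatient/outpatient interval distributions."""

    tau1: float = 10.0
    tau2: float = 35.0
    #: if False, outpatient visits anchor only on admission/discharge dates
    #: (no visit-to-visit chaining); the transitive reading is the default
    transitive_visits: bool = True

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("tau1 and tau2 must be non-negative")


@dataclass
class Episode:
    """A linked series of claims attributed to one fracture."""

    patient_id: str
    records: pd.DataFrame  # time-ordered claim rows
    H: frozenset[str] = field(default_factory=frozenset)  # hospitalized providers
    D_in: float = float("nan")
    has_surgery: bool = False
    n_hospital_providers: int = 0
    age_at_admission: float = float("nan")
    sex: str = ""


_NA_DAY = -(10**9)


def _days(s: pd.Series) -> np.ndarray:
    """ISO date strings -> integer days since epoch; blanks -> sentinel."""
    dt = pd.to_datetime(s.replace("", pd.NA), errors="coerce", format="%Y-%m-%d")
    out = dt.values.astype("datetime64[D]").astype("int64")
    out[dt.isna().to_numpy()] = _NA_DAY
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _link_group(
    is_in: np.ndarray, adm: np.ndarray, dis: np.ndarray, day: np.ndarray,
    params: LinkageParams, pid: str,
) -> list[list[int]]:
    """Union the records of one patient under the tau rules; returns index
    groups (positions into the group's arrays)."""
    n = len(is_in)
    uf = _UnionFind(n)

    # inpatient transfer chains: a sweep over admissions, linking a stay to
    # the open chain while its admission is within tau1 of the running
    # furthest discharge (overlapping stays merge, with a warning)
    inp = np.where(is_in)[0]
    if len(inp) > 1:
        order = inp[np.argsort(adm[inp], kind="stable")]
        reach = -np.inf
        max_dis = -np.inf
        prev = -1
        for k in order:
            if prev >= 0 and adm[k] <= reach:
                if adm[k] < max_dis:
                    logger.warning(
                        "overlapping inpatient stays for patient %s merged", pid
                    )
                uf.union(prev, k)
                reach = max(reach, dis[k] + params.tau1)
                max_dis = max(max_dis, dis[k])
            else:
                reach = dis[k] + params.tau1
                max_dis = dis[k]
            prev = k

    # tau2 anchors: outpatient visits initiate links to every anchor point
    # within tau2 days (inpatient stays expose admission and discharge)
    pts_day: list[int] = []
    pts_rec: list[int] = []
    pts_out: list[bool] = []
    for k in inp:
        pts_day += [int(adm[k]), int(dis[k])]
        pts_rec += [int(k), int(k)]
        pts_out += [False, False]
    out = np.where(~is_in)[0]
    for k in out:
        pts_day.append(int(day[k]))
        pts_rec.append(int(k))
        pts_out.append(True)
    if out.size:
        order2 = np.lexsort((pts_rec, pts_day))
        pts_day = [pts_day[i] for i in order2]
        pts_rec = [pts_rec[i] for i in order2]
        pts_out = [pts_out[i] for i in order2]
        m = len(pts_day)
        for i in range(m):
            if not pts_out[i]:
                continue
            d0, r0 = pts_day[i], pts_rec[i]
            j = i - 1
            while j >= 0 and d0 - pts_day[j] <= params.tau2:
                if params.transitive_visits or not pts_out[j]:
                    uf.union(r0, pts_rec[j])
                j -= 1
            j = i + 1
            while j < m and pts_day[j] - d0 <= params.tau2:
                if params.transitive_visits or not pts_out[j]:
                    uf.union(r0, pts_rec[j])
                j += 1

    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(uf.find(k), []).append(k)
    return list(groups.values())


def link_records(claims: pd.DataFrame, params: LinkageParams | None = None) -> list[Episode]:
    """Link claims into episodes (transitive closure of the tau rules)."""
    params = params or LinkageParams()
    df = claims.reset_index(drop=True)
    is_in = (df["record_type"].to_numpy() == "inpatient")
    adm = _days(df["admission_date"])
    dis = _days(df["discharge_date"])
    vis = _days(df["visit_date"])
    day = np.where(is_in, adm, vis)
    surg = (df["surgery_date"].astype(str).to_numpy() != "")
    ages = df["age"].to_numpy()
    pids = df["patient_id"].astype(str).to_numpy()
    prov = df["provider_id"].astype(str).to_numpy()
    sexes = df["sex"].astype(str).to_numpy()

    order = np.lexsort((prov, day, pids))
    episodes: list[Episode] = []
    first_days: list[int] = []
    i = 0
    n = len(df)
    while i < n:
        j = i
        pid = pids[order[i]]
        while j < n and pids[order[j]] == pid:
            j += 1
        g = order[i:j]
        for members in _link_group(is_in[g], adm[g], dis[g], day[g], params, pid):
            rows = g[np.sort(np.asarray(members))]
            inp_rows = rows[is_in[rows]]
            H = frozenset(prov[inp_rows]) if inp_rows.size else frozenset()
            ep = Episode(
                patient_id=pid,
                records=df.iloc[rows].reset_index(drop=True),
                H=H,
                has_surgery=bool(surg[inp_rows].any()) if inp_rows.size else False,
                n_hospital_providers=len(H),
                sex=str(sexes[rows[0]]),
            )
            if inp_rows.size:
                ep.D_in = float(dis[inp_rows].max() - adm[inp_rows].min())
                ep.age_at_admission = float(ages[inp_rows[np.argmin(adm[inp_rows])]])
            episodes.append(ep)
            first_days.append(int(day[rows].min()))
        i = j
    keys = sorted(range(len(episodes)),
                  key=lambda k: (episodes[k].patient_id, first_days[k]))
    return [episodes[k] for k in keys]


class OutpatientOnlyEpisode(ValueError):
    """Duration of stay is undefined for an episode without inpatient records."""


def duration_of_stay(episode: Episode) -> float:
    """D^in in whole days: last discharge minus first admission."""
    if not episode.H:
        raise OutpatientOnlyEpisode(
            f"episode of patient {episode.patient_id} has no inpatient records"
        )
    return episode.D_in


def filter_cases(
    episodes: list[Episode],
    giant_component_nodes: set[str] | frozenset[str],
    max_days: float = 400.0,
) -> pd.DataFrame:
    """Case table restricted to the analyzable surgical cases.

    Keeps an episode iff it contains surgery, every hospital used lies in the
    network's giant component, and D^in does not exceed ``max_days``
    (inclusive boundary: only stays *exceeding* the cap are dropped).
    """
    nodes = set(giant_component_nodes)
    rows = []
    for i, ep in enumerate(episodes):
        if not ep.H or not ep.has_surgery:
            continue
        if not ep.H <= nodes:
            continue
        if ep.D_in > max_days:
            continue
        rows.append(
            {
                "case_id": f"c{i:06d}",
                "patient_id": ep.patient_id,
                "D_in": ep.D_in,
                "H": ";".join(sorted(ep.H)),
                "age": ep.age_at_admission,
                "sex": ep.sex,
                "n_hospital_providers": ep.n_hospital_providers,
            }
        )
    if not rows:
        logger.warning("filter_cases produced an empty case table")
        return pd.DataFrame(
            columns=["case_id", "patient_id", "D_in", "H", "age", "sex",
                     "n_hospital_providers"]
        )
    return pd.DataFrame(rows)


def interval_distributions(claims: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Empirical CDFs of inpatient (discharge -> next admission) and
    outpatient (visit -> next visit) gaps per patient, pooled over patients."""
    df = claims.reset_index(drop=True)
    is_in = df["record_type"].to_numpy() == "inpatient"
    pids = df["patient_id"].astype(str).to_numpy()
    adm = _days(df["admission_date"])
    dis = _days(df["discharge_date"])
    vis = _days(df["visit_date"])

    in_gaps: list[int] = []
    out_gaps: list[int] = []
    # inpatient gaps: per patient, sort stays by admission
    sel = np.where(is_in)[0]
    order = sel[np.lexsort((adm[sel], pids[sel]))]
    for k in range(1, len(order)):
        a, b = order[k - 1], order[k]
        if pids[a] == pids[b]:
            in_gaps.append(int(adm[b] - dis[a]))
    sel = np.where(~is_in)[0]
    order = sel[np.lexsort((vis[sel], pids[sel]))]
    for k in range(1, len(order)):
        a, b = order[k - 1], order[k]
        if pids[a] == pids[b]:
            out_gaps.append(int(vis[b] - vis[a]))

    def table(gaps: list[int]) -> pd.DataFrame:
        if not gaps:
            return pd.DataFrame(columns=["value", "cdf"])
        vals, counts = np.unique(np.asarray(gaps), return_counts=True)
        return pd.DataFrame({"value": vals, "cdf": np.cumsum(counts) / len(gaps)})

    return {"inpatient": table(in_gaps), "outpatient": table(out_gaps)}


def case_summary(cases: pd.DataFrame) -> dict:
    """Cohort summary: n, mean age, mean D^in, sex shares, transfer shares."""
    if len(cases) == 0:
        raise ValueError("case table is empty")
    nh = cases["n_hospital_providers"]
    sex = cases["sex"].value_counts(normalize=True)
    return {
        "n_cases": int(len(cases)),
        "mean_age": float(cases["age"].mean()),
        "mean_D_in": float(cases["D_in"].mean()),
        "share_female": float(sex.get("female", 0.0)),
        "share_male": float(sex.get("male", 0.0)),
        "share_1_provider": float((nh == 1).mean()),
        "share_2_providers": float((nh == 2).mean()),
        "share_3plus_providers": float((nh >= 3).mean()),
    }
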