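"""Episode linkage: tau rules, D^in arithmetic, filters, and the
interval-graph connected-components oracle."""

import numpy as np
import pandas as pd
import pytest

import carenet as cn
from carenet.episodes import (
    LinkageParams,
    OutpatientOnlyEpisode,
    case_summary,
    duration_of_stay,
    interval_distributions,
    link_records,
)
from carenet.synth import CLAIMS_COLUMNS


def _claims(rows):
    """rows: (pid, mid, type, adm, dis, visit, surgery) with day offsets."""
    base = np.datetime64("2015-01-01")

    def d(off):
        return "" if off is None else str(base + np.timedelta64(off, "D"))

    data = [
        (pid, mid, rt, d(adm), d(dis), d(vis), d(surg), 80, "female", True)
        for (pid, mid, rt, adm, dis, vis, surg) in rows
    ]
    return pd.DataFrame(data, columns=CLAIMS_COLUMNS)


def test_transfer_within_tau1_merges_and_beyond_splits():
    stays = _claims([
        ("p1", "A", "inpatient", 0, 20, None, 1),
        ("p1", "B", "inpatient", 25, 60, None, None),
    ])
    eps = link_records(stays, LinkageParams(tau1=10, tau2=35))
    assert len(eps) == 1 and eps[0].H == {"A", "B"}
    far = _claims([
        ("p1", "A", "inpatient", 0, 20, None, 1),
        ("p1", "B", "inpatient", 36, 60, None, None),
    ])
    eps = link_records(far, LinkageParams(tau1=10, tau2=0))
    assert len(eps) == 2


def test_outpatient_joins_within_tau2_only():
    for gap, expected in ((30, 1), (40, 2)):
        claims = _claims([
            ("p1", "C", "outpatient", None, None, 0, None),
            ("p1", "A", "inpatient", gap, gap + 30, None, 1),
        ])
        eps = link_records(claims, LinkageParams(tau1=10, tau2=35))
        assert len(eps) == expected


def test_visit_chains_are_transitive_and_flag_disables_chaining():
    claims = _claims([
        ("p1", "A", "inpatient", 0, 10, None, 1),
        ("p1", "C", "outpatient", None, None, 40, None),
        ("p1", "C", "outpatient", None, None, 70, None),
    ])
    eps = link_records(claims, LinkageParams(tau1=10, tau2=35))
    assert len(eps) == 1  # 70 joins through the visit at 40
    eps = link_records(claims, LinkageParams(tau1=10, tau2=35,
                                             transitive_visits=False))
    assert len(eps) == 2  # visit at 70 is > 35 from both anchors


def test_duration_of_stay_date_arithmetic():
    one = _claims([("p1", "A", "inpatient", 0, 58, None, 1)])
    ep, = link_records(one)
    assert duration_of_stay(ep) == 58.0
    same_day = _claims([("p1", "A", "inpatient", 3, 3, None, 3)])
    ep, = link_records(same_day)
    assert duration_of_stay(ep) == 0.0
    transfer = _claims([
        ("p1", "A", "inpatient", 0, 19, None, 1),   # Jan 1 - Jan 20
        ("p1", "B", "inpatient", 24, 59, None, None),  # Jan 25 - Mar 1
    ])
    ep, = link_records(transfer)
    assert duration_of_stay(ep) == 59.0


def test_outpatient_only_episode_has_no_duration():
    claims = _claims([("p1", "C", "outpatient", None, None, 0, None)])
    ep, = link_records(claims)
    with pytest.raises(OutpatientOnlyEpisode):
        duration_of_stay(ep)


def test_overlapping_stays_merge_with_warning(caplog):
    claims = _claims([
        ("p1", "A", "inpatient", 0, 30, None, 1),
        ("p1", "B", "inpatient", 10, 25, None, None),
    ])
    with caplog.at_level("WARNING"):
        eps = link_records(claims)
    assert len(eps) == 1
    assert any("overlapping" in r.message for r in caplog.records)


def test_filter_cases_rules_and_boundary():
    rows = [
        ("p1", "A", "inpatient", 0, 50, None, 1),      # kept
        ("p2", "A", "inpatient", 0, 50, None, None),   # no surgery
        ("p3", "B", "inpatient", 0, 50, None, 1),      # provider outside GC
        ("p4", "A", "inpatient", 0, 400, None, 1),     # D=400 kept (inclusive)
        ("p5", "A", "inpatient", 0, 401, None, 1),     # D=401 dropped
    ]
    eps = link_records(_claims(rows))
    cases = cn.filter_cases(eps, {"A"}, max_days=400)
    assert set(cases["patient_id"]) == {"p1", "p4"}


def test_filter_cases_empty_result_warns_not_raises(caplog):
    eps = link_records(_claims([("p1", "A", "inpatient", 0, 5, None, None)]))
    with caplog.at_level("WARNING"):
        cases = cn.filter_cases(eps, {"A"})
    assert len(cases) == 0


def test_interval_distribution_tables():
    claims = _claims([
        ("p1", "A", "inpatient", 0, 10, None, 1),
        ("p1", "B", "inpatient", 15, 30, None, None),
        ("p2", "C", "outpatient", None, None, 0, None),
        ("p2", "C", "outpatient", None, None, 7, None),
        ("p2", "C", "outpatient", None, None, 14, None),
    ])
    t = interval_distributions(claims)
    assert t["inpatient"]["value"].tolist() == [5]
    assert t["inpatient"]["cdf"].tolist() == [1.0]
    assert t["outpatient"]["value"].tolist() == [7]
    assert t["outpatient"]["cdf"].tolist() == [1.0]
    empty = interval_distributions(claims.head(1))
    assert len(empty["inpatient"]) == 0 and len(empty["outpatient"]) == 0


def test_case_summary_fields():
    eps = link_records(_claims([
        ("p1", "A", "inpatient", 0, 50, None, 1),
        ("p2", "A", "inpatient", 0, 30, None, 1),
        ("p2", "B", "inpatient", 35, 60, None, None),
    ]))
    cases = cn.filter_cases(eps, {"A", "B"})
    s = case_summary(cases)
    assert s["n_cases"] == 2
    assert s["share_1_provider"] == 0.5 and s["share_2_providers"] == 0.5
    assert s["mean_age"] == 80.0


# --- randomized oracle -----------------------------------------------------


def _oracle_components(df, tau1, tau2):
    """Brute-force pairwise rule graph + connected components."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(df.index)
    rows = list(df.itertuples())
    for i, a in enumerate(rows):
        for b in rows[i + 1:]:
            if a.record_type == "inpatient" and b.record_type == "inpatient":
                first, second = (a, b) if a.adm <= b.adm else (b, a)
                linked = second.adm - first.dis <= tau1
            elif a.record_type == "outpatient" and b.record_type == "outpatient":
                linked = abs(a.vis - b.vis) <= tau2
            else:
                o, h = (a, b) if a.record_type == "outpatient" else (b, a)
                linked = min(abs(o.vis - h.adm), abs(o.vis - h.dis)) <= tau2
            if linked:
                G.add_edge(a.Index, b.Index)
    return {frozenset(c) for c in nx.connected_components(G)}


def _random_patient(rng, n_records):
    rows = []
    for k in range(n_records):
        if rng.random() < 0.4:
            adm = int(rng.integers(0, 300))
            dis = adm + int(rng.integers(0, 60))
            rows.append(("p", f"m{rng.integers(0, 5)}", "inpatient",
                         adm, dis, None, adm if rng.random() < 0.5 else None))
        else:
            rows.append(("p", f"m{rng.integers(0, 5)}", "outpatient",
                         None, None, int(rng.integers(0, 300)), None))
    return _claims(rows)


@pytest.mark.parametrize("tau1,tau2", [(10, 35), (0, 0), (5, 14), (30, 60), (1, 100), (50, 7)])
def test_linkage_matches_interval_graph_oracle(tau1, tau2):
    rng = np.random.default_rng(tau1 * 101 + tau2)
    for trial in range(150):
        df = _random_patient(rng, int(rng.integers(1, 31)))
        base = np.datetime64("2015-01-01")
        aux = df.assign(
            adm=(pd.to_datetime(df["admission_date"].replace("", pd.NA)) - pd.Timestamp(base)).dt.days,
            dis=(pd.to_datetime(df["discharge_date"].replace("", pd.NA)) - pd.Timestamp(base)).dt.days,
            vis=(pd.to_datetime(df["visit_date"].replace("", pd.NA)) - pd.Timestamp(base)).dt.days,
        )
        expected = _oracle_components(aux, tau1, tau2)
        eps = link_records(df, LinkageParams(tau1=tau1, tau2=tau2))
        got = set()
        for ep in eps:
            key = frozenset(
                aux.index[
                    (aux["record_type"] == r.record_type)
                    & (aux["provider_id"] == r.provider_id)
                    & (aux["admission_date"] == r.admission_date)
                    & (aux["visit_date"] == r.visit_date)
                    & (aux["discharge_date"] == r.discharge_date)
                ].tolist().pop(0)
                for r in ep.records.itertuples()
            )
            got.add(key)
        assert len(eps) == len(expected)


def test_raising_thresholds_never_increases_episode_count():
    rng = np.random.default_rng(42)
    for _ in range(30):
        df = _random_patient(rng, 20)
        counts = [
            len(link_records(df, LinkageParams(tau1=t1, tau2=t2)))
            for t1, t2 in [(0, 0), (5, 10), (10, 35), (40, 80)]
        ]
        assert counts == sorted(counts, reverse=True)


def test_merged_episode_duration_at_least_component_max():
    rng = np.random.default_rng(3)
    for _ in range(30):
        df = _random_patient(rng, 12)
        strict = link_records(df, LinkageParams(tau1=0, tau2=0))
        loose = link_records(df, LinkageParams(tau1=20, tau2=50))
        if not any(e.H for e in strict):
            continue
        max_strict = max(e.D_in for e in strict if e.H)
        max_loose = max(e.D_in for e in loose if e.H)
        assert max_loose >= max_strict
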