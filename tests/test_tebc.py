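"""Targeted edge betweenness centrality: nuclei extraction, destination
buffering, path scoring against an exhaustive-enumeration oracle, the
normal-vs-flood classification, and dispersion summaries."""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

import floodaccess as fa
from floodaccess.network import Edge, Facility, FacilitySet, SpeedProfile, TravelGraph
from floodaccess.tebc import (
    BACKUP_INCREASED,
    FLOODED,
    LOST,
    UNCHANGED,
    Origin,
    OriginSet,
    gini,
    population_nuclei,
    select_destinations,
    tebc_delta,
    tebc_dispersion,
    tebc_scores,
)


def graph_from_weights(coords, weighted_edges):
    """TravelGraph built directly from (a, b, minutes) triples."""
    g = nx.Graph()
    for n, (x, y) in coords.items():
        g.add_node(n, x=x, y=y)
    for eid, (a, b, w) in enumerate(weighted_edges):
        g.add_edge(a, b, weight=w, length_m=w, road_class="trunk", edge_id=eid)
    return TravelGraph(g, SpeedProfile.driving())


def origin_at(coords, node, pop=10.0):
    return Origin(coords[node][0], coords[node][1], pop)


def facility_at(coords, node, fid=0):
    return Facility(fid, coords[node][0], coords[node][1])


# --- population nuclei -----------------------------------------------------


def test_single_block_nucleus_at_block_center():
    frame = fa.GridFrame(0.0, 1000.0, 100.0, 10, 10)
    pop = fa.PopulationGrid(frame, np.full((10, 10), 5.0))
    origins = population_nuclei(pop, 1000.0)
    assert len(origins) == 1
    o = origins.origins[0]
    assert (o.x, o.y, o.population) == (500.0, 500.0, 500.0)


def test_all_zero_grid_gives_no_nuclei():
    frame = fa.GridFrame(0.0, 2000.0, 100.0, 20, 20)
    pop = fa.PopulationGrid(frame, np.zeros((20, 20)))
    assert len(population_nuclei(pop)) == 0


def test_nuclei_match_direct_blocking_oracle():
    rng = np.random.default_rng(3)
    frame = fa.GridFrame(0.0, 3000.0, 100.0, 30, 30)
    vals = np.where(rng.random((30, 30)) < 0.1, rng.uniform(1, 50, (30, 30)), 0.0)
    pop = fa.PopulationGrid(frame, vals)
    origins = population_nuclei(pop, 1000.0)
    blocks = vals.reshape(3, 10, 3, 10).sum(axis=(1, 3))
    assert len(origins) == int((blocks > 0).sum())
    got = {(o.x, o.y): o.population for o in origins}
    for r, c in zip(*np.nonzero(blocks > 0)):
        key = (c * 1000.0 + 500.0, 3000.0 - (r * 1000.0 + 500.0))
        assert got[key] == pytest.approx(blocks[r, c])


def test_non_integer_aggregation_ratio_rejected():
    frame = fa.GridFrame(0.0, 1000.0, 300.0, 3, 3)
    pop = fa.PopulationGrid(frame, np.ones((3, 3)))
    with pytest.raises(ValueError):
        population_nuclei(pop, 1000.0)


# --- destination selection -------------------------------------------------


def test_buffer_is_inclusive_at_range():
    facs = FacilitySet(
        [Facility(0, 19900.0, 0.0), Facility(1, 20000.0, 0.0), Facility(2, 20001.0, 0.0)]
    )
    sel, n = select_destinations(Origin(0.0, 0.0, 1.0), facs, 20000.0)
    assert sel == [0, 1] and n == 2


def test_no_facility_in_range_gives_zero_n():
    facs = FacilitySet([Facility(0, 50000.0, 0.0)])
    sel, n = select_destinations(Origin(0.0, 0.0, 1.0), facs, 20000.0)
    assert sel == [] and n == 0


# --- direct applications of the score definition ---------------------------


def test_path_graph_accumulates_per_origin():
    """A-B-C with the facility at C: the closer edge carries both origins."""
    coords = {0: (0.0, 0.0), 1: (1000.0, 0.0), 2: (2000.0, 0.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0), (1, 2, 1.0)])
    origins = OriginSet([origin_at(coords, 0), origin_at(coords, 1)])
    facs = FacilitySet([facility_at(coords, 2)])
    fld = tebc_scores(g, origins, facs, range_m=50000.0)
    assert fld.exact[1] == 2  # edge B-C
    assert fld.exact[0] == 1  # edge A-B


def test_two_facilities_split_one_origin_in_halves():
    coords = {0: (0.0, 0.0), 1: (-1000.0, 0.0), 2: (1000.0, 0.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0), (0, 2, 1.0)])
    origins = OriginSet([origin_at(coords, 0)])
    facs = FacilitySet([facility_at(coords, 1, 0), facility_at(coords, 2, 1)])
    fld = tebc_scores(g, origins, facs, range_m=50000.0)
    assert fld.exact[0] == Fraction(1, 2)
    assert fld.exact[1] == Fraction(1, 2)


def test_n_counts_in_range_destinations_even_if_unreachable():
    """N is the buffer count, not the reachable count: an in-range but
    disconnected facility still dilutes the origin's weight."""
    coords = {0: (0.0, 0.0), 1: (1000.0, 0.0), 2: (0.0, 1000.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0)])  # node 2 isolated
    origins = OriginSet([origin_at(coords, 0)])
    facs = FacilitySet([facility_at(coords, 1, 0), facility_at(coords, 2, 1)])
    fld = tebc_scores(g, origins, facs, range_m=50000.0)
    assert fld.exact[0] == Fraction(1, 2)


def test_tie_break_prefers_lexicographically_smallest_route():
    """Two equal-cost routes 0-1-3 and 0-2-3: the node-id order picks 0-1-3."""
    coords = {0: (0.0, 0.0), 1: (0.0, 1000.0), 2: (0.0, -1000.0), 3: (2000.0, 0.0)}
    g = graph_from_weights(
        coords, [(0, 1, 1.0), (1, 3, 1.0), (0, 2, 1.0), (2, 3, 1.0)]
    )
    origins = OriginSet([origin_at(coords, 0)])
    facs = FacilitySet([facility_at(coords, 3)])
    fld = tebc_scores(g, origins, facs, range_m=50000.0)
    assert fld.exact.get(0) == 1 and fld.exact.get(1) == 1
    assert 2 not in fld.exact and 3 not in fld.exact


def test_empty_graph_scores_zero():
    g = TravelGraph(nx.Graph(), SpeedProfile.driving())
    origins = OriginSet([Origin(0.0, 0.0, 1.0)])
    facs = FacilitySet([Facility(0, 10.0, 0.0)])
    fld = tebc_scores(g, origins, facs, range_m=50000.0)
    assert fld.exact == {}


# --- exhaustive oracle -----------------------------------------------------


def brute_force_tebc(graph, origins, facilities, range_m):
    """Exhaustive enumeration of ALL simple paths per (origin, facility)
    pair with exact rational costs; among minimum-cost paths the
    lexicographically smallest node sequence wins; every edge on it gets
    1/N with N the in-range facility count."""
    g = graph.g
    coords = {n: (d["x"], d["y"]) for n, d in g.nodes(data=True)}
    scores: dict[int, Fraction] = {}
    for o in origins:
        onode = min(
            coords,
            key=lambda n: (math.hypot(coords[n][0] - o.x, coords[n][1] - o.y), n),
        )
        in_range = [
            f
            for f in facilities
            if math.hypot(f.x - o.x, f.y - o.y) <= range_m
        ]
        n = len(in_range)
        if n == 0:
            continue
        for f in in_range:
            fnode = min(
                coords,
                key=lambda nd: (math.hypot(coords[nd][0] - f.x, coords[nd][1] - f.y), nd),
            )
            if onode == fnode:
                continue
            best_cost, best_path = None, None
            for path in nx.all_simple_paths(g, onode, fnode):
                cost = sum(
                    Fraction(g[a][b]["weight"]).limit_denominator(1 << 20)
                    for a, b in zip(path[:-1], path[1:])
                )
                if best_cost is None or cost < best_cost or (
                    cost == best_cost and path < best_path
                ):
                    best_cost, best_path = cost, path
            if best_path is None:
                continue
            for a, b in zip(best_path[:-1], best_path[1:]):
                eid = g[a][b]["edge_id"]
                scores[eid] = scores.get(eid, Fraction(0)) + Fraction(1, n)
    return scores


def random_case(seed):
    """Sparse random graph with dyadic weights (multiples of 0.25) so that
    equal-cost ties are exact in floating point."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 15))
    g = nx.gnm_random_graph(n, n + int(rng.integers(0, 6)), seed=int(rng.integers(1 << 30)))
    coords = {i: (float(rng.uniform(0, 10000)), float(rng.uniform(0, 10000))) for i in g.nodes}
    weighted = [
        (a, b, float(rng.integers(1, 16)) * 0.25) for a, b in g.edges
    ]
    tg = graph_from_weights(coords, weighted)
    k_o = int(rng.integers(1, 6))
    k_f = int(rng.integers(1, 4))
    o_nodes = rng.choice(n, size=min(k_o, n), replace=False)
    f_nodes = rng.choice(n, size=min(k_f, n), replace=False)
    origins = OriginSet([origin_at(coords, int(i)) for i in o_nodes])
    facs = FacilitySet([facility_at(coords, int(i), k) for k, i in enumerate(f_nodes)])
    range_m = float(rng.uniform(4000, 15000))
    return tg, origins, facs, range_m


@pytest.mark.parametrize("seed", range(60))
def test_scores_match_exhaustive_oracle(seed):
    tg, origins, facs, range_m = random_case(seed)
    got = tebc_scores(tg, origins, facs, range_m).exact
    expected = brute_force_tebc(tg, origins, facs, range_m)
    assert got == expected


@pytest.mark.parametrize("seed", range(20))
def test_mass_conservation_identity(seed):
    """Sum of scores equals sum over origins of path-edge-count / N."""
    tg, origins, facs, range_m = random_case(seed)
    fld = tebc_scores(tg, origins, facs, range_m)
    assert fld.total_mass() == fld.expected_mass()


# --- delta classification --------------------------------------------------


def test_bridge_fixture_classification(bridge):
    from floodaccess.synthetic import (
        BRIDGE_DETOUR_EDGE_IDS,
        BRIDGE_EDGE_ID,
    )

    res = fa.run_pipeline(bridge, fa.PipelineConfig(profile="driving"))
    classes = res.tebc_deltas.classes()
    assert classes[BRIDGE_EDGE_ID] == FLOODED
    for eid in BRIDGE_DETOUR_EDGE_IDS:
        assert classes[eid] == BACKUP_INCREASED
    # the bridge carries every origin: its normal score is the origin count
    n_origins = sum(
        1 for rec in res.tebc_normal.origin_records if rec["n_destinations"] > 0
    )
    assert res.tebc_normal.score(BRIDGE_EDGE_ID) == n_origins
    assert res.tebc_normal.score(BRIDGE_EDGE_ID) == max(res.tebc_normal.scores.values())


def test_identical_fields_all_unchanged():
    coords = {0: (0.0, 0.0), 1: (1000.0, 0.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0)])
    origins = OriginSet([origin_at(coords, 0)])
    facs = FacilitySet([facility_at(coords, 1)])
    fld = tebc_scores(g, origins, facs, 50000.0)
    delta = tebc_delta(fld, fld, g.edge_ids(), g.edge_ids())
    assert set(delta.classes().values()) == {UNCHANGED}


def test_intact_edge_losing_all_score_is_lost():
    coords = {0: (0.0, 0.0), 1: (1000.0, 0.0), 2: (2000.0, 0.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0), (1, 2, 1.0)])
    origins = OriginSet([origin_at(coords, 0)])
    fld_normal = tebc_scores(g, origins, FacilitySet([facility_at(coords, 2)]), 50000.0)
    empty = tebc_scores(g, OriginSet([]), FacilitySet([facility_at(coords, 2)]), 50000.0)
    delta = tebc_delta(fld_normal, empty, g.edge_ids(), g.edge_ids())
    assert set(delta.classes().values()) == {LOST}


def test_unexpected_extra_edges_rejected():
    coords = {0: (0.0, 0.0), 1: (1000.0, 0.0)}
    g = graph_from_weights(coords, [(0, 1, 1.0)])
    fld = tebc_scores(g, OriginSet([]), FacilitySet([facility_at(coords, 1)]), 50000.0)
    with pytest.raises(ValueError):
        tebc_delta(fld, fld, {0}, {0, 99})


# --- dispersion ------------------------------------------------------------


def test_gini_zero_for_equal_scores():
    assert gini(np.full(10, 3.0)) == pytest.approx(0.0)


def test_gini_near_one_for_single_dominant_edge():
    v = np.array([1000.0] + [1e-9] * 99)
    assert gini(v) > 0.98


def test_gini_matches_textbook_double_sum():
    rng = np.random.default_rng(8)
    v = rng.uniform(0, 5, 40)
    num = sum(abs(a - b) for a, b in itertools.product(v, v))
    expected = num / (2 * len(v) ** 2 * v.mean())
    assert gini(v) == pytest.approx(expected, rel=1e-12)


def test_all_zero_field_reports_degenerate():
    fld = fa.TEBCField({}, 20000.0, "driving")
    out = tebc_dispersion(fld)
    assert out == {"max": 0.0, "gini": 0.0, "n_positive": 0, "degenerate": True}
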