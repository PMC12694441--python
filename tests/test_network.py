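"""Discretization and the two-level compatibility graph construction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from osteokap.network import (
    DiscreteProfile, DiscretizationError, FEATURE_CLASSES, ClassRule,
    default_class_rules, discretize_profile, class_match, are_compatible,
    build_graph, write_edge_list, write_graphml, age_bin,
)
from tests.conftest import make_record, random_profile


def test_age_bins_are_ten_year_intervals():
    assert age_bin(47) == "40-49"
    assert age_bin(40) == "40-49"
    assert age_bin(89) == "80-89"
    for bad in (39, 90, 120):
        with pytest.raises(DiscretizationError):
            age_bin(bad)


def test_discretization_binarization_rules():
    p = discretize_profile(make_record(age_years=47, alcohol="occasional",
                                       activity="lt30", education="college",
                                       dxa_count=2))
    assert p.anthropometric[0] == "40-49"
    assert p.demographic == ("high", "urban")
    alcohol_any = p.lifestyle[2]
    physically_active = p.lifestyle[5]
    assert alcohol_any is True          # occasional counts as consumption
    assert physically_active is False   # lt30 is below the activity threshold
    assert p.clinical[3] is True        # dxa_ever = any scan
    q = discretize_profile(make_record(education="high_school", activity="m30to60"))
    assert q.demographic[0] == "low"
    assert q.lifestyle[5] is True


def test_class_sizes_match_the_four_class_layout():
    p = discretize_profile(make_record())
    assert len(p.anthropometric) == 3 and len(p.demographic) == 2
    assert len(p.lifestyle) == 6 and len(p.clinical) == 5
    assert [len(v) for v in FEATURE_CLASSES.values()] == [3, 2, 6, 5]


def test_class_match_counts_and_thresholds(rng):
    rules = default_class_rules()
    a = random_profile(rng, "a")
    assert class_match(a, a, rules["anthropometric"]) == (3, True)
    b = DiscreteProfile("b", (a.anthropometric[0], "normal" if a.anthropometric[1] != "normal" else "obese",
                             a.anthropometric[2]), a.demographic, a.lifestyle, a.clinical)
    assert class_match(a, b, rules["anthropometric"]) == (2, True)
    c = DiscreteProfile("c", a.anthropometric,
                        (a.demographic[0], "rural" if a.demographic[1] != "rural" else "urban"),
                        a.lifestyle, a.clinical)
    assert class_match(a, c, rules["demographic"]) == (1, False)


def test_class_rule_bounds():
    with pytest.raises(ValueError):
        ClassRule("demographic", ("education_bin", "environment"), 3)
    with pytest.raises(KeyError):
        class_match(DiscreteProfile("x", (), (), (), ()),
                    DiscreteProfile("y", (), (), (), ()),
                    ClassRule("bogus", ("f",), 1))


def test_compatibility_needs_three_of_four_classes(rng):
    a = random_profile(rng, "a")
    assert are_compatible(a, a)  # identical: 4 classes pass
    # flip the whole lifestyle and one clinical pair -> lifestyle 0/6 fails,
    # clinical 3/5 fails: only anthropometric+demographic pass
    b = DiscreteProfile("b", a.anthropometric, a.demographic,
                        tuple(not v for v in a.lifestyle),
                        tuple(not v for v in a.clinical[:2]) + a.clinical[2:])
    assert not are_compatible(a, b)
    # restore clinical: anthropometric+demographic+clinical pass -> edge
    c = DiscreteProfile("c", a.anthropometric, a.demographic,
                        tuple(not v for v in a.lifestyle), a.clinical)
    assert are_compatible(a, c)


def test_identical_profiles_build_a_complete_graph(rng):
    base = random_profile(rng, "x")
    profiles = [DiscreteProfile(f"n{i}", base.anthropometric, base.demographic,
                                base.lifestyle, base.clinical) for i in range(6)]
    G = build_graph(profiles)
    assert G.number_of_edges() == 6 * 5 // 2


def test_two_matching_classes_yield_no_edge(rng):
    a = random_profile(rng, "a")
    b = DiscreteProfile("b", a.anthropometric, a.demographic,
                        tuple(not v for v in a.lifestyle),
                        tuple(not v for v in a.clinical[:2]) + a.clinical[2:])
    G = build_graph([a, b])
    assert G.number_of_edges() == 0
    assert set(G.nodes) == {"a", "b"}  # isolates stay in the graph object


def test_duplicate_ids_rejected(rng):
    a = random_profile(rng, "a")
    with pytest.raises(ValueError, match="duplicate"):
        build_graph([a, a])


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_vectorized_graph_equals_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    profiles = [random_profile(rng, f"p{i}") for i in range(50)]
    G = build_graph(profiles)
    oracle_edges = {
        frozenset((a.id, b.id))
        for a, b in itertools.combinations(profiles, 2)
        if are_compatible(a, b)
    }
    assert {frozenset(e) for e in G.edges()} == oracle_edges
    assert not any(G.has_edge(n, n) for n in G.nodes)


def test_relaxing_thresholds_never_removes_edges(rng):
    profiles = [random_profile(rng, f"p{i}") for i in range(40)]
    strict = default_class_rules()
    edges_strict = {frozenset(e) for e in build_graph(profiles, strict).edges()}
    for cname in FEATURE_CLASSES:
        relaxed = dict(strict)
        rule = relaxed[cname]
        relaxed[cname] = ClassRule(cname, rule.feature_names,
                                   max(1, rule.min_matches - 1))
        edges_relaxed = {frozenset(e)
                         for e in build_graph(profiles, relaxed).edges()}
        assert edges_strict <= edges_relaxed


def test_graph_exports(tmp_path, rng):
    profiles = [random_profile(rng, f"p{i}") for i in range(20)]
    G = build_graph(profiles)
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(G, edge_path)
    lines = edge_path.read_text().strip().splitlines()
    assert len(lines) == G.number_of_edges()
    assert all(len(line.split("\t")) == 2 for line in lines)
    gml = tmp_path / "g.graphml"
    write_graphml(G, gml)
    back = nx.read_graphml(gml)
    assert back.number_of_edges() == G.number_of_edges()
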