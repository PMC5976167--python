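"""Triad census engine: classification, census, deltas, three-arc trails."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from triadnet import (
    MAN_LABELS,
    DyadState,
    Network,
    census_delta,
    classify_triad,
    count_three_paths,
    triad_census,
)
from triadnet.netcore import TRIAD_TABLE, _code_to_arcs, census_array

from conftest import random_network


def _nx_label(arcs):
    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    g.add_edges_from(arcs)
    counts = nx.triadic_census(g)
    (label,) = [lab for lab, c in counts.items() if c == 1]
    return label


def test_classification_table_matches_networkx_for_all_64_codes():
    for code in range(64):
        assert MAN_LABELS[TRIAD_TABLE[code]] == _nx_label(_code_to_arcs(code))


@pytest.mark.parametrize(
    "states, expected",
    [
        ((DyadState.NULL, DyadState.NULL, DyadState.NULL), "003"),
        ((DyadState.MUTUAL, DyadState.MUTUAL, DyadState.MUTUAL), "300"),
        # a->b, b->c, a->c: transitive triple
        ((DyadState.ASYM_OUT, DyadState.ASYM_OUT, DyadState.ASYM_OUT), "030T"),
        # a->b, b->c, c->a: 3-cycle
        ((DyadState.ASYM_OUT, DyadState.ASYM_IN, DyadState.ASYM_OUT), "030C"),
        ((DyadState.ASYM_OUT, DyadState.NULL, DyadState.NULL), "012"),
        ((DyadState.MUTUAL, DyadState.NULL, DyadState.NULL), "102"),
    ],
)
def test_classify_triad_examples(states, expected):
    assert classify_triad(*states) == expected


def test_classify_triad_is_isomorphism_invariant():
    """Every permutation of the three units yields the same label."""
    for code in range(64):
        arcs = _code_to_arcs(code)
        labels = set()
        for perm in itertools.permutations(range(3)):
            mapped = {(perm[a], perm[b]) for a, b in arcs}
            net = Network(3, mapped)
            labels.add(
                classify_triad(net.dyad_state(0, 1), net.dyad_state(0, 2),
                               net.dyad_state(1, 2)))
        assert len(labels) == 1


def test_census_trivial_networks():
    empty = Network(24)
    c = triad_census(empty)
    assert c["003"] == 2024 and c.total() == 2024
    full = Network(4, [(i, j) for i in range(4) for j in range(4) if i != j])
    c = triad_census(full)
    assert c["300"] == 4 and c.total() == 4


def test_census_warns_below_three_units():
    with pytest.warns(UserWarning):
        c = triad_census(Network(2, [(0, 1)]))
    assert c.total() == 0


def test_census_matches_networkx_on_random_digraphs(rng):
    for _ in range(100):
        net = random_network(rng, int(rng.integers(3, 13)), rng.uniform(0.1, 0.6))
        ours = triad_census(net)
        theirs = nx.triadic_census(net.to_networkx())
        assert all(ours[lab] == theirs[lab] for lab in MAN_LABELS)
        n = net.n
        assert ours.total() == n * (n - 1) * (n - 2) // 6


def test_arc_reversal_swaps_up_and_down_labels(rng):
    """Reversing every arc is the U<->D duality; other labels are fixed."""
    swap = {"021U": "021D", "021D": "021U", "120U": "120D", "120D": "120U",
            "111U": "111D", "111D": "111U"}
    for _ in range(20):
        net = random_network(rng, 10, 0.35)
        fwd = triad_census(net)
        rev = triad_census(net.reversed())
        for lab in MAN_LABELS:
            assert fwd[lab] == rev[swap.get(lab, lab)]


def test_census_delta_equals_recount_for_random_toggles(rng):
    for _ in range(200):
        net = random_network(rng, int(rng.integers(3, 10)), 0.4)
        n = net.n
        toggles = []
        A = net.A.copy()
        for _ in range(int(rng.integers(1, 3))):
            i, j = rng.choice(n, 2, replace=False)
            op = "remove" if A[i, j] else "add"
            toggles.append((int(i), int(j), op))
            A[i, j] ^= 1
        delta = census_delta(net, toggles)
        after = census_array(Network.from_adjacency(A))
        assert np.array_equal(census_array(net) + delta, after)


def test_census_delta_add_then_remove_is_zero():
    net = Network(5)
    delta = census_delta(net, [(0, 1, "add"), (0, 1, "remove")])
    assert not delta.any()


def test_census_delta_single_add_on_empty():
    delta = census_delta(Network(5), [(0, 1, "add")])
    expected = np.zeros(16, dtype=int)
    expected[MAN_LABELS.index("012")] = 3
    expected[MAN_LABELS.index("003")] = -3
    assert np.array_equal(delta, expected)


def test_census_delta_rejects_inapplicable_toggle():
    with pytest.raises(ValueError, match=r"\(0, 1\)"):
        census_delta(Network(5), [(0, 1, "remove")])


def _brute_three_paths(net, distinct_units):
    arcs = net.arcs()
    count = 0
    for a1, a2, a3 in itertools.product(arcs, repeat=3):
        if len({a1, a2, a3}) != 3:
            continue
        if a1[1] != a2[0] or a2[1] != a3[0]:
            continue
        if distinct_units and len({a1[0], a1[1], a2[1], a3[1]}) != 4:
            continue
        count += 1
    return count


@pytest.mark.parametrize(
    "arcs, n, expected",
    [
        ([(0, 1), (1, 2), (2, 3)], 4, 1),   # simple chain
        ([(0, 1), (1, 2), (2, 0)], 3, 3),   # 3-cycle: three rotations
        ([], 4, 0),
    ],
)
def test_three_paths_examples(arcs, n, expected):
    assert count_three_paths(Network(n, arcs)) == expected


def test_three_paths_matches_brute_force(rng):
    for _ in range(30):
        net = random_network(rng, int(rng.integers(3, 8)), 0.4)
        assert count_three_paths(net) == _brute_three_paths(net, False)
        assert count_three_paths(net, distinct_units=True) == \
            _brute_three_paths(net, True)


@given(st.integers(3, 8), st.integers(0, 2**32 - 1))
def test_census_sums_to_triple_count(n, seed):
    net = random_network(np.random.default_rng(seed), n, 0.5)
    assert triad_census(net).total() == n * (n - 1) * (n - 2) // 6


def test_network_validation():
    with pytest.raises(ValueError, match="self-loop"):
        Network(3, [(1, 1)])
    with pytest.raises(ValueError, match="out of range"):
        Network(3, [(0, 3)])
    with pytest.raises(ValueError, match="diagonal"):
        Network.from_adjacency(np.eye(3))
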