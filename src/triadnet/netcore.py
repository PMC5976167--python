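"""Core directed-network container and triad-level statistics.

The central local statistic throughout this package is the triad census:
the counts of the 16 isomorphism classes of directed three-node subgraphs,
labelled with the Holland-Leinhardt M-A-N convention.  A label's three
digits give the number of mutual, asymmetric and null dyads in the triad;
where that signature is ambiguous a trailing letter disambiguates the
orientation (C = cyclic, T = transitive, U = up, D = down).

Orientation convention (matching the one used by statnet's ``sna`` and by
:func:`networkx.triadic_census`):

* ``021D`` - one sender to two receivers (``A<-B->C``)
* ``021U`` - two senders to one receiver (``A->B<-C``)
* ``021C`` - a two-step chain (``A->B->C``)
* ``111D`` - ``A<->B<-C``;  ``111U`` - ``A<->B->C``
* ``030T`` - transitive triple (``A->B<-C, A->C``); ``030C`` - 3-cycle
* ``120D`` - ``A<-B->C, A<->C``;  ``120U`` - ``A->B<-C, A<->C``;
  ``120C`` - ``A->B->C, A<->C``

All classification goes through a single 64-entry lookup table built at
import time from canonical representatives, so the same convention is used
by the scalar classifier, the full census and the incremental deltas.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MAN_LABELS",
    "LABEL_INDEX",
    "Network",
    "DyadState",
    "TriadCensus",
    "classify_triad",
    "triad_census",
    "census_delta",
    "count_three_paths",
]

#: The 16 MAN triad-type labels in canonical order.
MAN_LABELS: tuple[str, ...] = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: Label -> position in :data:`MAN_LABELS`.
LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(MAN_LABELS)}

# Canonical representative arc sets on the node triple (0, 1, 2).
_REPRESENTATIVES: dict[str, frozenset[tuple[int, int]]] = {
    "003": frozenset(),
    "012": frozenset({(0, 1)}),
    "102": frozenset({(0, 1), (1, 0)}),
    "021D": frozenset({(1, 0), (1, 2)}),
    "021U": frozenset({(0, 1), (2, 1)}),
    "021C": frozenset({(0, 1), (1, 2)}),
    "111D": frozenset({(0, 1), (1, 0), (2, 1)}),
    "111U": frozenset({(0, 1), (1, 0), (1, 2)}),
    "030T": frozenset({(0, 1), (2, 1), (0, 2)}),
    "030C": frozenset({(0, 1), (1, 2), (2, 0)}),
    "201": frozenset({(0, 1), (1, 0), (0, 2), (2, 0)}),
    "120D": frozenset({(1, 0), (1, 2), (0, 2), (2, 0)}),
    "120U": frozenset({(0, 1), (2, 1), (0, 2), (2, 0)}),
    "120C": frozenset({(0, 1), (1, 2), (0, 2), (2, 0)}),
    "210": frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)}),
    "300": frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}),
}

# Bit layout of a triple (i, j, k):
#   bit 5: i->j, bit 4: j->i, bit 3: i->k, bit 2: k->i, bit 1: j->k, bit 0: k->j
_BIT_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1),
)


def _code_to_arcs(code: int) -> frozenset[tuple[int, int]]:
    return frozenset(p for b, p in enumerate(reversed(_BIT_PAIRS)) if code >> b & 1)


def _build_table() -> np.ndarray:
    perms = list(itertools.permutations(range(3)))
    table = np.full(64, -1, dtype=np.int8)
    for code in range(64):
        arcs = _code_to_arcs(code)
        for perm in perms:
            mapped = frozenset((perm[a], perm[b]) for a, b in arcs)
            for lab, rep in _REPRESENTATIVES.items():
                if mapped == rep:
                    table[code] = LABEL_INDEX[lab]
                    break
            if table[code] >= 0:
                break
    assert (table >= 0).all()
    return table


#: code (6 adjacency bits) -> triad-type index; isomorphism-invariant.
TRIAD_TABLE: np.ndarray = _build_table()


class DyadState(enum.Enum):
    """State of an unordered pair of units, viewed from the first unit."""

    NULL = "null"
    MUTUAL = "mutual"
    ASYM_OUT = "asym_out"  # first -> second only
    ASYM_IN = "asym_in"    # second -> first only

    @property
    def bits(self) -> tuple[int, int]:
        """(forward, backward) arc indicators."""
        return {
            DyadState.NULL: (0, 0),
            DyadState.MUTUAL: (1, 1),
            DyadState.ASYM_OUT: (1, 0),
            DyadState.ASYM_IN: (0, 1),
        }[self]


class Network:
    """A directed, binary, loop-free graph on ``n`` labelled units.

    Stored as a dense ``uint8`` adjacency matrix ``A`` with ``A[i, j] = 1``
    iff the arc ``i -> j`` is present.  Units are 0-based internally; file
    formats that are 1-based (Pajek) translate at the boundary.
    """

    __slots__ = ("A",)

    def __init__(self, n: int, arcs: Iterable[tuple[int, int]] = ()):
        if n < 0:
            raise ValueError("n must be non-negative")
        A = np.zeros((n, n), dtype=np.uint8)
        for i, j in arcs:
            if i == j:
                raise ValueError(f"self-loop ({i}, {j}) not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"arc ({i}, {j}) out of range for n={n}")
            A[i, j] = 1
        self.A = A

    @classmethod
    def from_adjacency(cls, A: np.ndarray) -> "Network":
        A = np.asarray(A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if np.diagonal(A).any():
            raise ValueError("self-loops (non-zero diagonal) not allowed")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        net = cls.__new__(cls)
        net.A = A.astype(np.uint8, copy=True)
        return net

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return int(self.A.sum())

    @property
    def density(self) -> float:
        n = self.n
        return self.m / (n * (n - 1)) if n > 1 else 0.0

    def arcs(self) -> list[tuple[int, int]]:
        """All arcs in lexicographic order."""
        ii, jj = np.nonzero(self.A)
        return list(zip(ii.tolist(), jj.tolist()))

    def has_arc(self, i: int, j: int) -> bool:
        return bool(self.A[i, j])

    def copy(self) -> "Network":
        net = Network.__new__(Network)
        net.A = self.A.copy()
        return net

    def dyad_state(self, i: int, j: int) -> DyadState:
        fwd, bwd = self.A[i, j], self.A[j, i]
        if fwd and bwd:
            return DyadState.MUTUAL
        if fwd:
            return DyadState.ASYM_OUT
        if bwd:
            return DyadState.ASYM_IN
        return DyadState.NULL

    def reversed(self) -> "Network":
        """Network with every arc reversed."""
        return Network.from_adjacency(self.A.T)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.arcs())
        return g

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Network) and np.array_equal(self.A, other.A)

    def __repr__(self) -> str:
        return f"Network(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class TriadCensus(Mapping):
    """Counts of the 16 MAN triad types; behaves as a read-only mapping."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != 16:
            raise ValueError("census needs exactly 16 counts")

    def __getitem__(self, label: str) -> int:
        return self.counts[LABEL_INDEX[label]]

    def __iter__(self):
        return iter(MAN_LABELS)

    def __len__(self) -> int:
        return 16

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def total(self) -> int:
        return int(sum(self.counts))

    def to_table(self) -> str:
        """16-row ``label,count`` table."""
        return "\n".join(f"{lab},{c}" for lab, c in zip(MAN_LABELS, self.counts))


def classify_triad(dyad_ab: DyadState, dyad_ac: DyadState, dyad_bc: DyadState) -> str:
    """Classify a labelled triple (a, b, c) by its three dyad states.

    The result is invariant under relabelling the three units.
    """
    ab_f, ab_b = dyad_ab.bits
    ac_f, ac_b = dyad_ac.bits
    bc_f, bc_b = dyad_bc.bits
    code = ab_f << 5 | ab_b << 4 | ac_f << 3 | ac_b << 2 | bc_f << 1 | bc_b
    return MAN_LABELS[TRIAD_TABLE[code]]


# per-n cache of the C(n,3) triples as three index arrays
_TRIPLES_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _triples(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n not in _TRIPLES_CACHE:
        combos = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
        if combos.size == 0:
            combos = combos.reshape(0, 3)
        _TRIPLES_CACHE[n] = (combos[:, 0], combos[:, 1], combos[:, 2])
    return _TRIPLES_CACHE[n]


def _codes_for_triples(A: np.ndarray, i, j, k) -> np.ndarray:
    a = A.astype(np.int16, copy=False)
    return (
        (a[i, j] << 5) | (a[j, i] << 4) | (a[i, k] << 3)
        | (a[k, i] << 2) | (a[j, k] << 1) | a[k, j]
    )


def census_array(net: Network) -> np.ndarray:
    """Triad census as an ``int64`` vector in :data:`MAN_LABELS` order."""
    n = net.n
    if n < 3:
        warnings.warn(f"triad census of a network with n={n} < 3 units is empty")
        return np.zeros(16, dtype=np.int64)
    i, j, k = _triples(n)
    codes = _codes_for_triples(net.A, i, j, k)
    return np.bincount(TRIAD_TABLE[codes], minlength=16).astype(np.int64)


def triad_census(net: Network) -> TriadCensus:
    """Count the 16 triad types over all C(n,3) unit triples."""
    return TriadCensus(tuple(census_array(net).tolist()))


def toggle_delta(A: np.ndarray, i: int, j: int) -> np.ndarray:
    """Census change if arc (i, j) were toggled in adjacency matrix ``A``.

    Only the n-2 triples containing both i and j are revisited; toggling
    (i, j) flips bit 5 of each of their codes.
    """
    n = A.shape[0]
    ks = np.concatenate((np.arange(0, min(i, j)),
                         np.arange(min(i, j) + 1, max(i, j)),
                         np.arange(max(i, j) + 1, n)))
    if ks.size == 0:
        return np.zeros(16, dtype=np.int64)
    before = _codes_for_triples(A, np.full(ks.shape, i), np.full(ks.shape, j), ks)
    after = before ^ 32
    return (np.bincount(TRIAD_TABLE[after], minlength=16)
            - np.bincount(TRIAD_TABLE[before], minlength=16)).astype(np.int64)


def census_delta(
    net: Network, toggles: Sequence[tuple[int, int, str]]
) -> np.ndarray:
    """Signed census change from applying ``toggles`` in order.

    Each toggle is ``(i, j, "add" | "remove")`` and must be applicable when
    its turn comes.  The input network is not modified.  Applying the
    toggles and recounting from scratch equals ``census + delta``.
    """
    A = net.A.copy()
    delta = np.zeros(16, dtype=np.int64)
    for i, j, op in toggles:
        if i == j:
            raise ValueError(f"self-loop toggle ({i}, {j})")
        if op == "add":
            if A[i, j]:
                raise ValueError(f"cannot add ({i}, {j}): arc already present")
        elif op == "remove":
            if not A[i, j]:
                raise ValueError(f"cannot remove ({i}, {j}): arc absent")
        else:
            raise ValueError(f"unknown toggle op {op!r}")
        delta += toggle_delta(A, i, j)
        A[i, j] ^= 1
    return delta


def count_three_paths(net: Network, distinct_units: bool = False) -> int:
    """Number of directed three-arc trails (a->b, b->c, c->d).

    By default the three arcs must be distinct but units may repeat (so
    a == c or b == d is allowed); this is the edge-based count that also
    covers cluster-level walks such as 1 -> 2 -> 3 -> 2.  With
    ``distinct_units=True`` only strict paths on four distinct units are
    counted.
    """
    A = net.A.astype(np.int64)
    if not distinct_units:
        walks3 = int((A @ A @ A).sum())
        mutual_ordered = int((A * A.T).sum())  # one degenerate walk per ordered mutual pair
        return walks3 - mutual_ordered
    # strict paths: sum over arcs (b, c) of (in(b) \ {c}) x (out(c) \ {b}),
    # minus the choices with a == d (a in in(b) and out(c)).
    din = A.sum(axis=0)
    dout = A.sum(axis=1)
    A2 = A @ A
    bb, cc = np.nonzero(A)
    terms = (din[bb] - A[cc, bb]) * (dout[cc] - A[cc, bb]) - A2[cc, bb]
    return int(terms.sum())
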