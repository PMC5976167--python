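"""Ideal blockmodel construction, level-of-errors perturbation, randomization.

A blockmodel under structural equivalence partitions the ``n`` units into
``K`` clusters (positions) and prescribes, for every ordered cluster pair,
either a *null* block (no arcs) or a *complete* block (all arcs).  A
network that realizes its image exactly is an *ideal* blockmodel.

Deviation from the ideal is parameterized by a level of errors
``LE in [0, 1]``: ``k = round(LE * (m - m^2 / (n^2 - n)))`` arcs are moved
from complete-block positions to empty null-block positions.  At ``LE = 0``
the network is ideal; at ``LE = 1`` complete- and null-block densities are
equal, so the partition is no longer recoverable and the network behaves
like a totally randomized one of the same density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .netcore import Network

__all__ = [
    "BLOCKMODEL_TYPES",
    "BlockImage",
    "BlockmodelSpec",
    "default_image",
    "default_sizes",
    "default_spec",
    "build_ideal",
    "links_to_relocate",
    "perturb",
    "randomize",
    "as_rng",
]

#: The seven supported blockmodel types.
BLOCKMODEL_TYPES: tuple[str, ...] = (
    "cohesive",
    "core_periphery_symmetric",
    "core_periphery_asymmetric",
    "hierarchical_null_diag",
    "hierarchical_complete_diag",
    "transitivity_null_diag",
    "transitivity_complete_diag",
)


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BlockImage:
    """K x K image with entries 1 = complete block, 0 = null block."""

    cells: np.ndarray

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=np.uint8)
        if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
            raise ValueError("image must be square")
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("image cells must be 0 (null) or 1 (complete)")
        object.__setattr__(self, "cells", cells)

    @property
    def K(self) -> int:
        return self.cells.shape[0]

    def transposed(self) -> "BlockImage":
        """Flip the direction convention (e.g. hierarchy up vs. down)."""
        return BlockImage(self.cells.T.copy())


def default_image(type: str, K: int) -> BlockImage:
    """The canonical image for a blockmodel type.

    Conventions: for core-periphery, cluster 1 is the core; for the layered
    types (hierarchical / transitivity), cluster 1 is the top level and
    lower clusters send arcs upward (hierarchical: to the adjacent level
    only; transitivity: to every upper level).
    """
    if type not in BLOCKMODEL_TYPES:
        raise ValueError(f"unknown blockmodel type {type!r}")
    if type.startswith("core_periphery"):
        if K != 2:
            raise ValueError(f"{type} requires K=2, got {K}")
        if type == "core_periphery_symmetric":
            cells = np.array([[1, 1], [1, 0]])
        else:  # only the peripheral units are linked to the core ones
            cells = np.array([[1, 0], [1, 0]])
        return BlockImage(cells)
    if K < 2 and type != "cohesive":
        raise ValueError(f"{type} requires K >= 2, got {K}")
    if K < 1:
        raise ValueError("K must be >= 1")
    cells = np.zeros((K, K), dtype=np.uint8)
    if type == "cohesive":
        np.fill_diagonal(cells, 1)
    elif type.startswith("hierarchical"):
        for c in range(K - 1):
            cells[c + 1, c] = 1
        if type.endswith("complete_diag"):
            np.fill_diagonal(cells, 1)
    else:  # transitivity
        cells[np.tril_indices(K, -1)] = 1
        if type.endswith("complete_diag"):
            np.fill_diagonal(cells, 1)
    return BlockImage(cells)


def default_sizes(type: str) -> tuple[int, ...]:
    """Default cluster sizes for n = 24 units: (8, 16) core/periphery for
    the core-periphery types, (8, 8, 8) for the three-cluster types."""
    if type.startswith("core_periphery"):
        return (8, 16)
    return (8, 8, 8)


@dataclass(frozen=True)
class BlockmodelSpec:
    """A blockmodel type together with concrete cluster sizes and image."""

    type: str
    sizes: tuple[int, ...]
    image: BlockImage

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be strictly positive")
        if self.image.K != len(self.sizes):
            raise ValueError("image dimension must equal the number of clusters")
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @property
    def n(self) -> int:
        return sum(self.sizes)

    @property
    def K(self) -> int:
        return len(self.sizes)

    def membership(self) -> np.ndarray:
        """0-based cluster label per unit (units ordered by cluster)."""
        return np.repeat(np.arange(self.K), self.sizes)


def default_spec(type: str, sizes: tuple[int, ...] | None = None) -> BlockmodelSpec:
    """Spec with the canonical image and, unless given, the default sizes."""
    if sizes is None:
        sizes = default_sizes(type)
    return BlockmodelSpec(type, tuple(sizes), default_image(type, len(sizes)))


def build_ideal(spec: BlockmodelSpec) -> Network:
    """The ideal network: arc (i, j), i != j, iff its block is complete."""
    z = spec.membership()
    A = spec.image.cells[np.ix_(z, z)].astype(np.uint8)
    np.fill_diagonal(A, 0)
    return Network.from_adjacency(A)


def links_to_relocate(m: int, n: int, LE: float) -> int:
    """Number of arcs to relocate for a given level of errors.

    ``k = round(LE * (m - m^2 / (n^2 - n)))`` with half-up rounding; k = 0
    at LE = 0, and at LE = 1 relocating k arcs equalizes the densities of
    complete and null blocks.
    """
    if not 0.0 <= LE <= 1.0:
        raise ValueError(f"LE must be in [0, 1], got {LE}")
    if n < 2:
        raise ValueError("n must be >= 2")
    if m < 0:
        raise ValueError("m must be >= 0")
    x = LE * (m - m * m / (n * n - n))
    return int(np.floor(x + 0.5))


def perturb(ideal: Network, spec: BlockmodelSpec, LE: float, seed=None) -> Network:
    """Relocate k arcs from complete-block to null-block positions.

    Donor arcs are drawn uniformly without replacement from the (occupied)
    complete-block positions, acceptor slots uniformly from the empty
    null-block positions; the arc count is preserved.  ``k`` is capped
    (with a warning) if either side runs out of positions.
    """
    rng = as_rng(seed)
    z = spec.membership()
    n = ideal.n
    complete = spec.image.cells[np.ix_(z, z)].astype(bool)
    np.fill_diagonal(complete, False)
    offdiag = ~np.eye(n, dtype=bool)
    A = ideal.A.astype(bool)
    donors = np.flatnonzero((A & complete).ravel())
    acceptors = np.flatnonzero((~A & ~complete & offdiag).ravel())
    k = links_to_relocate(ideal.m, n, LE)
    if k > min(donors.size, acceptors.size):
        warnings.warn(
            f"k={k} exceeds available donor arcs ({donors.size}) or acceptor "
            f"slots ({acceptors.size}); capping"
        )
        k = min(donors.size, acceptors.size)
    out = ideal.A.copy()
    if k:
        rem = rng.choice(donors, size=k, replace=False)
        add = rng.choice(acceptors, size=k, replace=False)
        out.ravel()[rem] = 0
        out.ravel()[add] = 1
    return Network.from_adjacency(out)


def randomize(net: Network, seed=None) -> Network:
    """Uniform random digraph on n units with exactly the same arc count."""
    rng = as_rng(seed)
    n = net.n
    positions = np.flatnonzero(~np.eye(n, dtype=bool).ravel())
    chosen = rng.choice(positions, size=net.m, replace=False)
    A = np.zeros(n * n, dtype=np.uint8)
    A[chosen] = 1
    return Network.from_adjacency(A.reshape(n, n))
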