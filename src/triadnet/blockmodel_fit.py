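"""Pre-specified (generalized) blockmodeling under structural equivalence.

Given a network and a fixed K x K block image, the criterion function P
counts the inconsistencies between the network plus a candidate partition
and the image: arcs sitting in null blocks plus missing arcs in complete
blocks.  ``fit_prespecified`` minimizes P by steepest-descent local search
over single-unit moves and pairwise unit exchanges, repeated from many
random starting partitions.

Because the image pre-specifies cluster roles, cluster labels are *not*
interchangeable for asymmetric images (hierarchy, core-periphery); the
random restarts are what explore the role assignments.

The search evaluates whole neighborhoods at once: the block arc-count
matrix ``B = Z' A Z`` is maintained and each candidate move/exchange is
scored through its rank-one update of B, vectorized per cluster pair, so
a 100-restart fit on a few dozen units takes a fraction of a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blockmodels import BlockImage, as_rng
from .netcore import Network

__all__ = ["Partition", "FitResult", "criterion", "fit_prespecified"]


@dataclass(frozen=True)
class Partition:
    """Cluster assignment per unit (0-based labels in 0..K-1)."""

    labels: np.ndarray
    K: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.intp)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-d array")
        counts = np.bincount(labels, minlength=self.K)
        if counts.size > self.K or (counts == 0).any():
            raise ValueError("every cluster in 0..K-1 must be non-empty")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class FitResult:
    """Best partition found, its criterion value, and per-restart values."""

    partition: Partition
    P: int
    restarts: int
    restart_values: tuple[int, ...]


def _possible(sizes: np.ndarray) -> np.ndarray:
    p = np.outer(sizes, sizes).astype(np.int64)
    np.fill_diagonal(p, sizes * (sizes - 1))
    return p


def _errors(B: np.ndarray, sizes: np.ndarray, complete: np.ndarray) -> int:
    poss = _possible(sizes)
    return int(np.where(complete, poss - B, B).sum())


def criterion(net: Network, part: Partition | np.ndarray, image: BlockImage) -> int:
    """Total inconsistencies: arcs in null blocks + non-arcs in complete blocks."""
    labels = part.labels if isinstance(part, Partition) else np.asarray(part, dtype=np.intp)
    K = image.K
    if labels.max() >= K:
        raise ValueError("partition uses more clusters than the image has")
    Z = np.zeros((net.n, K), dtype=np.int64)
    Z[np.arange(net.n), labels] = 1
    B = Z.T @ net.A.astype(np.int64) @ Z
    sizes = Z.sum(axis=0)
    return _errors(B, sizes, image.cells.astype(bool))


def _random_partition(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    # one unit per cluster guarantees non-emptiness; the rest uniform
    labels = rng.integers(0, K, size=n)
    anchors = rng.choice(n, size=K, replace=False)
    labels[anchors] = np.arange(K)
    return labels.astype(np.intp)


def _descend(A: np.ndarray, labels: np.ndarray, complete: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Steepest-descent over single-unit moves and pairwise exchanges."""
    n = A.shape[0]
    K = complete.shape[0]
    A64 = A.astype(np.int64)
    corr = (A64 + A64.T)  # used by exchange corrections

    while True:
        Z = np.zeros((n, K), dtype=np.int64)
        Z[np.arange(n), labels] = 1
        B = Z.T @ A64 @ Z
        sizes = Z.sum(axis=0)
        P = _errors(B, sizes, complete)
        out = A64 @ Z   # out[u, s] = arcs u -> cluster s
        inn = A64.T @ Z  # inn[u, r] = arcs cluster r -> u

        candidates: list[tuple[int, tuple]] = []

        members = [np.flatnonzero(labels == c) for c in range(K)]

        # single-unit moves a -> b
        for a in range(K):
            if sizes[a] <= 1:
                continue  # moving would empty the cluster
            ua = members[a]
            o, i_ = out[ua], inn[ua]
            for b in range(K):
                if b == a:
                    continue
                dB = np.zeros((ua.size, K, K), dtype=np.int64)
                dB[:, a, :] -= o
                dB[:, b, :] += o
                dB[:, :, a] -= i_
                dB[:, :, b] += i_
                sizes2 = sizes.copy()
                sizes2[a] -= 1
                sizes2[b] += 1
                poss2 = _possible(sizes2)
                B2 = B[None] + dB
                err2 = np.where(complete[None], poss2[None] - B2, B2).sum(axis=(1, 2))
                deltas = err2 - P
                j = int(np.argmin(deltas))
                if deltas[j] < 0:
                    candidates.append((int(deltas[j]), ("move", int(ua[j]), b)))

        # pairwise exchanges across clusters a < b
        poss = _possible(sizes)
        for a in range(K):
            ua = members[a]
            oU, iU = out[ua], inn[ua]
            for b in range(a + 1, K):
                ub = members[b]
                oV, iV = out[ub], inn[ub]
                dB = np.zeros((ua.size, ub.size, K, K), dtype=np.int64)
                dB[:, :, a, :] -= oU[:, None, :]
                dB[:, :, b, :] += oU[:, None, :]
                dB[:, :, :, a] -= iU[:, None, :]
                dB[:, :, :, b] += iU[:, None, :]
                dB[:, :, b, :] -= oV[None, :, :]
                dB[:, :, a, :] += oV[None, :, :]
                dB[:, :, :, b] -= iV[None, :, :]
                dB[:, :, :, a] += iV[None, :, :]
                w = corr[np.ix_(ua, ub)]
                dB[:, :, a, b] += w
                dB[:, :, b, a] += w
                dB[:, :, a, a] -= w
                dB[:, :, b, b] -= w
                B2 = B[None, None] + dB
                err2 = np.where(complete[None, None], poss[None, None] - B2, B2)
                deltas = err2.sum(axis=(2, 3)) - P
                flat = int(np.argmin(deltas))
                d = int(deltas.ravel()[flat])
                if d < 0:
                    iu, iv = np.unravel_index(flat, deltas.shape)
                    candidates.append((d, ("swap", int(ua[iu]), int(ub[iv]))))

        improving = [c for c in candidates if c[0] < 0]
        if not improving:
            return labels, P
        dmin = min(c[0] for c in improving)
        ties = [c for c in improving if c[0] == dmin]
        _, action = ties[rng.integers(len(ties))]
        if action[0] == "move":
            labels = labels.copy()
            labels[action[1]] = action[2]
        else:
            labels = labels.copy()
            labels[action[1]], labels[action[2]] = (
                labels[action[2]], labels[action[1]])


def fit_prespecified(
    net: Network, image: BlockImage, K: int | None = None,
    restarts: int = 100, seed=None,
) -> FitResult:
    """Minimize the criterion over partitions by restarted local search.

    Each restart draws a uniform random partition with no empty cluster and
    descends (steepest first, random tie-break) until no single-unit move
    or pairwise exchange strictly improves P; the minimum over restarts is
    returned.  Reproducible under ``seed``.
    """
    if K is None:
        K = image.K
    if K != image.K:
        raise ValueError("K must match the image dimension")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if net.n < K:
        raise ValueError(f"need at least K={K} units, got n={net.n}")
    rng = as_rng(seed)
    complete = image.cells.astype(bool)
    best_labels, best_P = None, None
    values = []
    for _ in range(restarts):
        labels = _random_partition(net.n, K, rng)
        labels, P = _descend(net.A, labels, complete, rng)
        values.append(P)
        if best_P is None or P < best_P:
            best_labels, best_P = labels, P
    return FitResult(
        partition=Partition(best_labels, K),
        P=int(best_P),
        restarts=restarts,
        restart_values=tuple(values),
    )
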