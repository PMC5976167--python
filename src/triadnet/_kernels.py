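"""Numba-compiled inner loops for the RL and ERGM generators.

Both generators spend essentially all their time proposing single-arc
changes and updating the triad census incrementally, so those loops are
compiled.  All randomness is pre-drawn with numpy from the caller's seeded
Generator and passed in as arrays, which keeps runs bit-reproducible and
independent of numba's own RNG.

The arc / non-arc bookkeeping uses the classic swap-delete indexed lists:
``arc_list[:n_arcs]`` holds the flat off-diagonal positions of present
arcs, ``slot_of[pos]`` the position's index in whichever list holds it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .netcore import TRIAD_TABLE

_TABLE = TRIAD_TABLE.astype(np.int64)


@njit(cache=True)
def _census_toggle(A, i, j, delta):
    """Add the census change of toggling (i, j) into delta (16,)."""
    n = A.shape[0]
    for k in range(n):
        if k == i or k == j:
            continue
        code = (A[i, j] << 5) | (A[j, i] << 4) | (A[i, k] << 3) \
            | (A[k, i] << 2) | (A[j, k] << 1) | A[k, j]
        delta[_TABLE[code]] -= 1
        delta[_TABLE[code ^ 32]] += 1


@njit(cache=True)
def _three_paths(A):
    """Directed three-arc trails: walks of length 3 minus the degenerate
    a->b->a->b walks (one per ordered mutual pair)."""
    n = A.shape[0]
    A2 = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for k in range(n):
            if A[i, k]:
                for j in range(n):
                    A2[i, j] += A[k, j]
    # walks of length 3 = sum_{i,j} (A @ A2)[i, j]
    w3 = 0
    for i in range(n):
        for k in range(n):
            if A[i, k]:
                for j in range(n):
                    w3 += A2[k, j]
    mut = 0
    for i in range(n):
        for j in range(n):
            if A[i, j] and A[j, i]:
                mut += 1
    return w3 - mut


@njit(cache=True)
def _init_lists(A, arc_list, nonarc_list, slot_of):
    n = A.shape[0]
    na = 0
    nn = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p = i * n + j
            if A[i, j]:
                arc_list[na] = p
                slot_of[p] = na
                na += 1
            else:
                nonarc_list[nn] = p
                slot_of[p] = nn
                nn += 1
    return na, nn


@njit(cache=True)
def _swap_lists(p_arc, p_non, arc_list, nonarc_list, slot_of):
    """Move position p_arc to the non-arc list and p_non to the arc list."""
    sa = slot_of[p_arc]
    sn = slot_of[p_non]
    arc_list[sa] = p_non
    nonarc_list[sn] = p_arc
    slot_of[p_non] = sa
    slot_of[p_arc] = sn


@njit(cache=True)
def _stat_values(census, m, tp, stat_kind, stat_idx, out):
    for s in range(stat_kind.size):
        if stat_kind[s] == 0:
            out[s] = census[stat_idx[s]]
        elif stat_kind[s] == 1:
            out[s] = m
        else:
            out[s] = tp


@njit(cache=True)
def rl_chain(A, stat_kind, stat_idx, target, u_arc, u_non, cr_trace,
             accepted, dist_trace):
    """Relocating-links chain; mutates A in place, returns final distance.

    stat_kind: 0 = census label (stat_idx = label index), 1 = edges,
    2 = three-arc trails.  u_arc/u_non: uniform(0,1) draws per iteration.
    """
    n = A.shape[0]
    M = u_arc.size
    track_tp = False
    for s in range(stat_kind.size):
        if stat_kind[s] == 2:
            track_tp = True

    arc_list = np.empty(n * n, dtype=np.int64)
    nonarc_list = np.empty(n * n, dtype=np.int64)
    slot_of = np.empty(n * n, dtype=np.int64)
    na, nn = _init_lists(A, arc_list, nonarc_list, slot_of)

    census = np.zeros(16, dtype=np.int64)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                code = (A[i, j] << 5) | (A[j, i] << 4) | (A[i, k] << 3) \
                    | (A[k, i] << 2) | (A[j, k] << 1) | A[k, j]
                census[_TABLE[code]] += 1
    tp = _three_paths(A) if track_tp else 0

    g = stat_kind.size
    cur = np.empty(g, dtype=np.float64)
    prop = np.empty(g, dtype=np.float64)
    _stat_values(census, na, tp, stat_kind, stat_idx, cur)
    dist = 0.0
    for s in range(g):
        dist += (cur[s] - target[s]) ** 2

    delta = np.zeros(16, dtype=np.int64)
    for it in range(M):
        p_arc = arc_list[int(u_arc[it] * na)]
        p_non = nonarc_list[int(u_non[it] * nn)]
        i1, j1 = divmod(p_arc, n)
        i2, j2 = divmod(p_non, n)
        delta[:] = 0
        _census_toggle(A, i1, j1, delta)
        A[i1, j1] = 0
        _census_toggle(A, i2, j2, delta)
        A[i2, j2] = 1
        tp_new = _three_paths(A) if track_tp else 0
        _stat_values(census + delta, na, tp_new, stat_kind, stat_idx, prop)
        dist_p = 0.0
        for s in range(g):
            dist_p += (prop[s] - target[s]) ** 2
        if dist_p == 0.0:
            cr = np.inf if dist > 0.0 else 1.0
        else:
            cr = dist / dist_p
        cr_trace[it] = cr
        if cr > 1.0:
            accepted[it] = True
            census += delta
            tp = tp_new
            dist = dist_p
            _swap_lists(p_arc, p_non, arc_list, nonarc_list, slot_of)
        else:
            A[i1, j1] = 1
            A[i2, j2] = 0
        dist_trace[it] = dist
    return dist


@njit(cache=True)
def ergm_chain(A, stat_kind, stat_idx, theta, fixed_density,
               u_arc, u_non, u_acc):
    """Metropolis-Hastings chain; mutates A in place.

    In fixed-density mode each step swaps a uniform arc with a uniform
    non-arc; in free mode it toggles a uniform off-diagonal position
    (u_arc picks the position, u_non is unused).  Acceptance with
    probability min(1, exp(theta . delta_g)).
    """
    n = A.shape[0]
    M = u_arc.size
    track_tp = False
    for s in range(stat_kind.size):
        if stat_kind[s] == 2:
            track_tp = True

    arc_list = np.empty(n * n, dtype=np.int64)
    nonarc_list = np.empty(n * n, dtype=np.int64)
    slot_of = np.empty(n * n, dtype=np.int64)
    na, nn = _init_lists(A, arc_list, nonarc_list, slot_of)

    census = np.zeros(16, dtype=np.int64)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                code = (A[i, j] << 5) | (A[j, i] << 4) | (A[i, k] << 3) \
                    | (A[k, i] << 2) | (A[j, k] << 1) | A[k, j]
                census[_TABLE[code]] += 1
    tp = _three_paths(A) if track_tp else 0

    g = stat_kind.size
    cur = np.empty(g, dtype=np.float64)
    prop = np.empty(g, dtype=np.float64)
    _stat_values(census, na, tp, stat_kind, stat_idx, cur)

    delta = np.zeros(16, dtype=np.int64)
    for it in range(M):
        if fixed_density:
            p_arc = arc_list[int(u_arc[it] * na)]
            p_non = nonarc_list[int(u_non[it] * nn)]
            i1, j1 = divmod(p_arc, n)
            i2, j2 = divmod(p_non, n)
            delta[:] = 0
            _census_toggle(A, i1, j1, delta)
            A[i1, j1] = 0
            _census_toggle(A, i2, j2, delta)
            A[i2, j2] = 1
            m_new = na
        else:
            # uniform off-diagonal position: index in 0..n(n-1)-1
            q = int(u_arc[it] * (n * n - n))
            i1 = q // (n - 1)
            j1 = q % (n - 1)
            if j1 >= i1:
                j1 += 1
            delta[:] = 0
            _census_toggle(A, i1, j1, delta)
            removing = A[i1, j1] == 1
            A[i1, j1] ^= 1
            m_new = na - 1 if removing else na + 1
            p_arc = i1 * n + j1
            i2 = -1
        tp_new = _three_paths(A) if track_tp else 0
        _stat_values(census + delta, m_new, tp_new, stat_kind, stat_idx, prop)
        logr = 0.0
        for s in range(g):
            logr += theta[s] * (prop[s] - cur[s])
        if logr >= 0.0 or u_acc[it] < np.exp(logr):
            census += delta
            tp = tp_new
            for s in range(g):
                cur[s] = prop[s]
            if fixed_density:
                _swap_lists(p_arc, p_non, arc_list, nonarc_list, slot_of)
            else:
                # position moved between lists
                if m_new > na:  # added
                    sn = slot_of[p_arc]
                    nn -= 1
                    last = nonarc_list[nn]
                    nonarc_list[sn] = last
                    slot_of[last] = sn
                    arc_list[na] = p_arc
                    slot_of[p_arc] = na
                    na += 1
                else:  # removed
                    sa = slot_of[p_arc]
                    na -= 1
                    last = arc_list[na]
                    arc_list[sa] = last
                    slot_of[last] = sa
                    nonarc_list[nn] = p_arc
                    slot_of[p_arc] = nn
                    nn += 1
        else:
            if fixed_density:
                A[i1, j1] = 1
                A[i2, j2] = 0
            else:
                A[i1, j1] ^= 1
    return na


def stat_layout(ids) -> tuple[np.ndarray, np.ndarray]:
    """Map statistic ids to (kind, index) arrays for the kernels:
    kind 0 = triad label, 1 = edges, 2 = three-arc trails."""
    from .netcore import LABEL_INDEX

    kind = np.empty(len(ids), dtype=np.int64)
    idx = np.zeros(len(ids), dtype=np.int64)
    for s, sid in enumerate(ids):
        if sid in LABEL_INDEX:
            kind[s] = 0
            idx[s] = LABEL_INDEX[sid]
        elif sid == "edges":
            kind[s] = 1
        elif sid == "three_paths":
            kind[s] = 2
        else:
            raise ValueError(f"unknown statistic id {sid!r}")
    return kind, idx
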