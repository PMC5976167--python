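"""The Relocating Links (RL) generator.

Starting from a random network of the target density, each iteration picks
one arc and one non-arc uniformly at random and proposes swapping them
(dissolve the arc, establish the non-arc).  The proposal is accepted
exactly when it brings the vector of tracked local statistics strictly
closer, in squared distance, to the target vector T taken from an ideal
blockmodel:

    CR = sum_i (T_current,i - T_i)^2 / sum_i (T_proposed,i - T_i)^2

with acceptance iff CR > 1.  (With the current state's distance in the
numerator, CR > 1 is literally "the proposal is closer"; ties, CR = 1, are
rejected, which makes the distance trace strictly decreasing over accepted
states and guarantees termination of the descent.)  The arc count is
invariant throughout, so the generator explores the fixed-density space.

The accept rule is greedy, not stochastic: the only randomness is in the
proposal draws, and a run is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import rl_chain, stat_layout
from .blockmodels import BlockmodelSpec, as_rng, build_ideal, randomize
from .netcore import Network
from .triad_profiles import TargetVector

__all__ = ["RLResult", "cr_ratio", "generate_rl", "initial_network"]


@dataclass(frozen=True)
class RLResult:
    """Final network plus the per-iteration CR trace and audit data."""

    network: Network
    cr_trace: np.ndarray          # CR value of every proposal
    accepted: np.ndarray          # bool per iteration
    distance_trace: np.ndarray    # squared distance to T after each iteration


def cr_ratio(T: np.ndarray, T_current: np.ndarray, T_proposed: np.ndarray) -> float:
    """Closeness ratio of a proposal; > 1 means the proposal is strictly
    closer to the target vector.

    Returns ``inf`` when the proposal hits the target exactly while the
    current state does not, and 1.0 (a rejecting tie) when both are exact.
    """
    T = np.asarray(T, dtype=np.float64)
    Tc = np.asarray(T_current, dtype=np.float64)
    Tp = np.asarray(T_proposed, dtype=np.float64)
    if not (T.shape == Tc.shape == Tp.shape):
        raise ValueError("statistic vectors must share one length")
    num = float(((Tc - T) ** 2).sum())
    den = float(((Tp - T) ** 2).sum())
    if den == 0.0:
        return float("inf") if num > 0.0 else 1.0
    return num / den


def initial_network(spec: BlockmodelSpec, seed=None) -> Network:
    """Uniform random digraph with the ideal network's arc count."""
    return randomize(build_ideal(spec), seed)


def generate_rl(
    initial: Network, T: TargetVector, M: int = 6000, seed=None,
) -> RLResult:
    """Run M relocating-links iterations from ``initial`` toward ``T``."""
    if M < 1:
        raise ValueError("M must be >= 1")
    n = initial.n
    if initial.m == 0 or initial.m == n * (n - 1):
        raise ValueError("initial network must have at least one arc and one non-arc")
    rng = as_rng(seed)
    kind, idx = stat_layout(T.ids)
    A = initial.A.astype(np.int64)
    cr_trace = np.empty(M)
    accepted = np.zeros(M, dtype=np.bool_)
    dist_trace = np.empty(M)
    rl_chain(A, kind, idx, T.targets.astype(np.float64),
             rng.random(M), rng.random(M), cr_trace, accepted, dist_trace)
    return RLResult(
        network=Network.from_adjacency(A.astype(np.uint8)),
        cr_trace=cr_trace,
        accepted=accepted,
        distance_trace=dist_trace,
    )
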