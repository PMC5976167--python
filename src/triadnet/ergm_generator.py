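"""Fixed-coefficient ERGM Metropolis-Hastings sampling.

Networks are drawn from the exponential-family distribution

    P(Y = y) = exp(theta . g(y)) / kappa(theta)

where g(y) is a vector of local statistics (triad-type counts, optionally
the arc count and the three-arc-trail count) and theta is *fixed*, not
estimated: +2 for allowed and -2 for forbidden statistics by default.  The
normalizing constant kappa never needs to be computed because Metropolis-
Hastings only uses probability ratios.

Two symmetric proposal distributions are provided:

* ``free_density`` - toggle one uniformly chosen ordered pair; the arc
  count is itself random, so an ``edges`` coefficient (tuned by
  :func:`tune_edges`) controls the expected density.
* ``fixed_density`` - swap one uniformly chosen arc with one uniformly
  chosen non-arc, conserving the arc count exactly.

Both proposals are symmetric, so the Hastings q-ratio is 1 and a proposal
is accepted with probability ``min(1, exp(theta . delta_g))``.

For the hierarchical blockmodel without complete diagonal blocks, triad
statistics alone produce chains running both up and down the hierarchy;
:func:`hierarchical_fix_model` adds the three-arc-trail count as a
forbidden statistic (theta = -2) and boosts one 021-chain coefficient
(default 021C at +4) to recover three levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import ergm_chain, stat_layout
from .blockmodels import BlockmodelSpec, as_rng, build_ideal, default_spec, randomize
from .netcore import LABEL_INDEX, Network, census_array, count_three_paths
from .triad_profiles import THREE_PATHS, _labels_for_choice

EDGES = "edges"

__all__ = [
    "ErgmModel",
    "SamplerConfig",
    "triad_model",
    "hierarchical_fix_model",
    "acceptance_probability",
    "sample",
    "tune_edges",
]


@dataclass(frozen=True)
class ErgmModel:
    """Ordered statistic ids with one fixed coefficient each."""

    statistics: tuple[str, ...]
    theta: np.ndarray

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=np.float64)
        if theta.size != len(self.statistics):
            raise ValueError("theta must have one coefficient per statistic")
        if len(self.statistics) != len(set(self.statistics)):
            raise ValueError("duplicate statistic ids")
        object.__setattr__(self, "theta", theta)

    def with_stat(self, stat: str, coefficient: float) -> "ErgmModel":
        """Copy with ``stat`` added, or its coefficient replaced."""
        if stat in self.statistics:
            theta = self.theta.copy()
            theta[self.statistics.index(stat)] = coefficient
            return ErgmModel(self.statistics, theta)
        return ErgmModel(
            self.statistics + (stat,),
            np.append(self.theta, coefficient),
        )

    def g(self, net: Network) -> np.ndarray:
        """Evaluate the statistic vector on a network."""
        census = census_array(net)
        out = np.empty(len(self.statistics))
        for i, s in enumerate(self.statistics):
            if s in LABEL_INDEX:
                out[i] = census[LABEL_INDEX[s]]
            elif s == EDGES:
                out[i] = net.m
            elif s == THREE_PATHS:
                out[i] = count_three_paths(net)
            else:
                raise ValueError(f"unknown statistic id {s!r}")
        return out


@dataclass(frozen=True)
class SamplerConfig:
    """How to run the chain: proposal mode, budget, burn-in, seed."""

    mode: str = "fixed_density"
    iterations: int = 10_000
    burn_in: int = 0
    seed: object = None

    def __post_init__(self):
        if self.mode not in ("fixed_density", "free_density"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def triad_model(
    spec: BlockmodelSpec,
    set_choice: str = "all",
    theta_allowed: float = 2.0,
    theta_forbidden: float = -2.0,
    edges_theta: float | None = None,
    selected_forbidden: frozenset[str] | None = None,
) -> ErgmModel:
    """Model over the chosen triad set: allowed types get ``theta_allowed``,
    forbidden ones ``theta_forbidden``; optionally an edges term."""
    ideal = build_ideal(spec)
    labels = _labels_for_choice(spec, set_choice, ideal, selected_forbidden)
    counts = census_array(ideal)
    theta = [theta_allowed if counts[LABEL_INDEX[l]] > 0 else theta_forbidden
             for l in labels]
    model = ErgmModel(tuple(labels), np.asarray(theta))
    if edges_theta is not None:
        model = model.with_stat(EDGES, edges_theta)
    return model


def hierarchical_fix_model(
    boost: float = 4.0,
    boost_label: str = "021C",
    edges_theta: float | None = None,
) -> ErgmModel:
    """Augmented model for the hierarchical blockmodel with null diagonal:
    selected triads at +/-2, three-arc trails at -2, and one 021-chain
    statistic raised to ``boost`` (default 021C at 4; 021D is the
    alternative convention)."""
    if boost_label not in ("021C", "021D"):
        raise ValueError("boost_label must be '021C' or '021D'")
    spec = default_spec("hierarchical_null_diag")
    model = triad_model(spec, "selected")
    model = model.with_stat(THREE_PATHS, -2.0)
    model = model.with_stat(boost_label, boost)
    if edges_theta is not None:
        model = model.with_stat(EDGES, edges_theta)
    return model


def acceptance_probability(
    model: ErgmModel, current: Network, proposal: Network
) -> float:
    """min(1, exp(theta . (g(proposal) - g(current)))); symmetric proposals
    make the Hastings correction 1."""
    dg = model.g(proposal) - model.g(current)
    return float(min(1.0, np.exp(model.theta @ dg)))


def sample(
    model: ErgmModel,
    config: SamplerConfig,
    spec: BlockmodelSpec | None = None,
    initial: Network | None = None,
) -> Network:
    """Run the Metropolis-Hastings chain and return the final state.

    The initial network defaults to a randomized ideal network of ``spec``
    (same density as the ideal, no blockmodel structure), which keeps the
    free-density chain from drifting to empty or complete networks.
    """
    rng = as_rng(config.seed)
    if initial is None:
        if spec is None:
            raise ValueError("either spec or initial must be given")
        initial = randomize(build_ideal(spec), rng)
    n = initial.n
    fixed = config.mode == "fixed_density"
    if fixed and (initial.m == 0 or initial.m == n * (n - 1)):
        raise ValueError("fixed-density sampling needs a non-degenerate initial network")
    kind, idx = stat_layout(model.statistics)
    A = initial.A.astype(np.int64)
    total = config.burn_in + config.iterations
    ergm_chain(A, kind, idx, model.theta.astype(np.float64), fixed,
               rng.random(total), rng.random(total), rng.random(total))
    return Network.from_adjacency(A.astype(np.uint8))


def tune_edges(
    model: ErgmModel,
    spec: BlockmodelSpec,
    window: float = 0.05,
    reps: int = 30,
    iterations: int = 10_000,
    seed=None,
    bracket: tuple[float, float] = (-10.0, 10.0),
    max_steps: int = 30,
) -> tuple[float, float]:
    """Find an edges coefficient for free-density sampling by bisection.

    Searches ``theta_edges`` in ``bracket`` until the mean density of
    ``reps`` generated networks lies within ``window`` of the ideal
    network's density.  Returns ``(theta_edges, achieved_mean_density)``.
    Mean density is monotone increasing in the edges coefficient, which is
    what bisection exploits.  When the interval collapses onto an end of
    the initial bracket (the root lies outside it - typical for models
    with a strongly penalized statistic such as three-arc trails, where a
    large edges coefficient must offset the penalty before any arcs
    survive), the bracket is expanded geometrically up to +/-100.
    """
    rng = as_rng(seed)
    ideal = build_ideal(spec)
    target = ideal.density

    def mean_density(theta_edges: float) -> float:
        m = model.with_stat(EDGES, theta_edges)
        dens = []
        for _ in range(reps):
            cfg = SamplerConfig("free_density", iterations=iterations,
                                seed=rng.integers(2**31))
            dens.append(sample(m, cfg, spec=spec).density)
        return float(np.mean(dens))

    limit = 100.0
    lo, hi = bracket
    steps = max_steps

    # bracketing phase: make sure the root (if any) lies inside [lo, hi]
    d_hi = mean_density(hi)
    steps -= 1
    if abs(d_hi - target) <= window:
        return hi, d_hi
    while d_hi < target and hi < limit and steps > 0:
        lo, hi = hi, min(2 * max(hi, 1.0), limit)
        d_hi = mean_density(hi)
        steps -= 1
        if abs(d_hi - target) <= window:
            return hi, d_hi
    if d_hi < target:
        raise RuntimeError(
            f"mean density {d_hi:.3f} stays below the ideal density "
            f"{target:.3f} even at theta_edges={hi}; widen the bracket"
        )
    d_lo = mean_density(lo)
    steps -= 1
    if abs(d_lo - target) <= window:
        return lo, d_lo
    while d_lo > target and lo > -limit and steps > 0:
        lo, hi = max(2 * min(lo, -1.0), -limit), lo
        d_lo = mean_density(lo)
        steps -= 1
        if abs(d_lo - target) <= window:
            return lo, d_lo
    if d_lo > target:
        raise RuntimeError(
            f"mean density {d_lo:.3f} stays above the ideal density "
            f"{target:.3f} even at theta_edges={lo}; widen the bracket"
        )

    while steps > 0:
        mid = 0.5 * (lo + hi)
        d = mean_density(mid)
        steps -= 1
        if abs(d - target) <= window:
            return mid, d
        if d < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"edges tuning did not reach |density - {target:.3f}| <= {window} "
        f"within {max_steps} evaluations; widen the bracket {bracket} "
        f"or the window"
    )
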