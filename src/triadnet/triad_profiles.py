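"""Allowed/forbidden/selected triad-type classification and target vectors.

For each blockmodel type, a triad type is *allowed* when its count in the
ideal network is positive and *forbidden* when it is zero.  The A-measure
grades how diagnostic an allowed type is: the ratio of its ideal-network
count to its mean count in totally randomized networks of the same
density (values near 1 mean the count is explained by density alone).

The *selected* subsets further trim the allowed sets.  Two trims are fixed
here: the chain triad 021C is dropped for the hierarchical blockmodel
without complete diagonal blocks, and the complete triad 300 for the
transitivity blockmodel with complete diagonal blocks (in both cases the
type is common in the ideal network but barely more common than in random
networks of that density).  Selected forbidden subsets are configuration
supplied; by default the full forbidden set is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blockmodels import (
    BLOCKMODEL_TYPES,
    BlockmodelSpec,
    as_rng,
    build_ideal,
    default_spec,
    randomize,
)
from .netcore import MAN_LABELS, Network, census_array, count_three_paths

__all__ = [
    "TRIAD_SETS",
    "THREE_PATHS",
    "TargetVector",
    "TriadProfile",
    "a_measure",
    "classify",
    "selected_sets",
    "target_vector",
    "profile",
    "profile_table",
]

logger = logging.getLogger(__name__)

#: Recognized triad-set choices for building targets / models.
TRIAD_SETS: tuple[str, ...] = (
    "all", "allowed", "forbidden", "selected", "selected_allowed",
    "selected_forbidden",
)

#: Statistic id for the three-arc-trail count (not a triad type).
THREE_PATHS = "three_paths"

# allowed types dropped from the selected sets, per blockmodel type
_SELECTED_ALLOWED_DROPS: dict[str, frozenset[str]] = {
    "hierarchical_null_diag": frozenset({"021C"}),
    "transitivity_complete_diag": frozenset({"300"}),
}


@dataclass(frozen=True)
class TargetVector:
    """Ordered statistic ids with their ideal-network target counts."""

    ids: tuple[str, ...]
    targets: np.ndarray

    def __post_init__(self):
        targets = np.asarray(self.targets, dtype=np.int64)
        if len(self.ids) != targets.size:
            raise ValueError("ids and targets must have equal length")
        if len(self.ids) == 0:
            raise ValueError("target vector must contain at least one statistic")
        object.__setattr__(self, "targets", targets)

    @property
    def g(self) -> int:
        return len(self.ids)


def classify(ideal: Network) -> tuple[frozenset[str], frozenset[str]]:
    """Exact (allowed, forbidden) partition of the 16 labels."""
    counts = census_array(ideal)
    allowed = frozenset(lab for lab, c in zip(MAN_LABELS, counts) if c > 0)
    return allowed, frozenset(MAN_LABELS) - allowed


def a_measure(ideal: Network, reps: int = 10_000, seed=None) -> dict[str, float]:
    """A-measure per label: ideal count / mean count in ``reps`` randomized
    networks of the same density.  0 for forbidden labels; ``inf`` when the
    ideal count is positive but the Monte-Carlo mean is zero."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = as_rng(seed)
    ideal_counts = census_array(ideal).astype(float)
    mean = np.zeros(16)
    for _ in range(reps):
        mean += census_array(randomize(ideal, rng))
    mean /= reps
    out = {}
    for lab, ic, mc in zip(MAN_LABELS, ideal_counts, mean):
        if ic == 0:
            out[lab] = 0.0
        elif mc == 0:
            out[lab] = float("inf")
        else:
            out[lab] = float(ic / mc)
    return out


def selected_sets(
    type: str, selected_forbidden: frozenset[str] | None = None
) -> tuple[frozenset[str], frozenset[str]]:
    """(selected allowed, selected forbidden) label sets for a blockmodel type.

    The selected allowed set is the allowed set of the default ideal
    network minus the type-specific drops.  Unless supplied, the selected
    forbidden set defaults to the full forbidden set.
    """
    if type not in BLOCKMODEL_TYPES:
        raise ValueError(f"unknown blockmodel type {type!r}")
    allowed, forbidden = classify(build_ideal(default_spec(type)))
    sel_allowed = allowed - _SELECTED_ALLOWED_DROPS.get(type, frozenset())
    if selected_forbidden is None:
        sel_forbidden = forbidden
    else:
        unknown = selected_forbidden - forbidden
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} are not forbidden for {type}")
        sel_forbidden = frozenset(selected_forbidden)
    return sel_allowed, sel_forbidden


def _labels_for_choice(
    spec: BlockmodelSpec,
    set_choice: str,
    ideal: Network,
    selected_forbidden: frozenset[str] | None = None,
) -> tuple[str, ...]:
    allowed, forbidden = classify(ideal)
    if set_choice in ("selected", "selected_forbidden") and selected_forbidden is None:
        logger.warning(
            "selected forbidden triad types are configuration-supplied; "
            "defaulting to the full forbidden set for %s", spec.type,
        )
    if set_choice == "all":
        labels = MAN_LABELS
    elif set_choice == "allowed":
        labels = [l for l in MAN_LABELS if l in allowed]
    elif set_choice == "forbidden":
        labels = [l for l in MAN_LABELS if l in forbidden]
    else:
        sel_a, sel_f = selected_sets(spec.type, selected_forbidden)
        if set_choice == "selected_allowed":
            labels = [l for l in MAN_LABELS if l in sel_a]
        elif set_choice == "selected_forbidden":
            labels = [l for l in MAN_LABELS if l in sel_f]
        elif set_choice == "selected":
            labels = [l for l in MAN_LABELS if l in (sel_a | sel_f)]
        else:
            raise ValueError(f"unknown triad-set choice {set_choice!r}")
    return tuple(labels)


def target_vector(
    spec: BlockmodelSpec,
    set_choice: str = "all",
    extra_stats: tuple[str, ...] = (),
    ideal: Network | None = None,
    selected_forbidden: frozenset[str] | None = None,
) -> TargetVector:
    """Exact ideal-network counts for the chosen statistic set.

    ``extra_stats`` may include :data:`THREE_PATHS`; forbidden-only choices
    yield all-zero targets.
    """
    if ideal is None:
        ideal = build_ideal(spec)
    labels = _labels_for_choice(spec, set_choice, ideal, selected_forbidden)
    counts = census_array(ideal)
    ids = list(labels)
    targets = [int(counts[MAN_LABELS.index(l)]) for l in labels]
    for stat in extra_stats:
        if stat == THREE_PATHS:
            ids.append(THREE_PATHS)
            targets.append(count_three_paths(ideal))
        else:
            raise ValueError(f"unknown extra statistic {stat!r}")
    return TargetVector(tuple(ids), np.asarray(targets, dtype=np.int64))


@dataclass(frozen=True)
class TriadProfile:
    """Per-label profile of one blockmodel type."""

    type: str
    ideal_counts: dict[str, int]
    a_values: dict[str, float]
    allowed: frozenset[str]
    selected_allowed: frozenset[str]
    selected_forbidden: frozenset[str]

    @property
    def forbidden(self) -> frozenset[str]:
        return frozenset(MAN_LABELS) - self.allowed


def profile(
    spec: BlockmodelSpec, reps: int = 10_000, seed=None,
    selected_forbidden: frozenset[str] | None = None,
) -> TriadProfile:
    """Full profile (counts, A-measure, classifications) for one spec."""
    ideal = build_ideal(spec)
    counts = census_array(ideal)
    allowed, _ = classify(ideal)
    sel_a, sel_f = selected_sets(spec.type, selected_forbidden)
    return TriadProfile(
        type=spec.type,
        ideal_counts={l: int(c) for l, c in zip(MAN_LABELS, counts)},
        a_values=a_measure(ideal, reps=reps, seed=seed),
        allowed=allowed,
        selected_allowed=sel_a,
        selected_forbidden=sel_f,
    )


def profile_table(
    types: tuple[str, ...] = BLOCKMODEL_TYPES, reps: int = 2_000, seed=None,
) -> pd.DataFrame:
    """A-measure values as a label-by-blockmodel table (blank = forbidden)."""
    rng = as_rng(seed)
    cols = {}
    for t in types:
        vals = a_measure(build_ideal(default_spec(t)), reps=reps, seed=rng)
        cols[t] = [vals[l] if vals[l] > 0 else np.nan for l in MAN_LABELS]
    return pd.DataFrame(cols, index=list(MAN_LABELS))
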