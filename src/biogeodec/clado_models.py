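"""Anagenetic rate matrices and cladogenetic event tables.

Range evolution has two components:

* **Anagenesis** along branches — a continuous-time Markov chain in which a
  range gains an area at dispersal rate ``d`` per (source-area, target-area)
  pair and loses an area at extirpation rate ``e`` per occupied area.  The
  empty (null) range is absorbing.

* **Cladogenesis** at speciation nodes — the parent range is partitioned
  between the two daughters.  The three classic model families differ in
  which partitions are allowed:

  - DEC: single-area sympatric copying, subset sympatry (one daughter
    inherits one area of a widespread range) and narrow vicariance (split
    with one singleton daughter);
  - DIVALIKE: single-area copying and all vicariant bipartitions,
    including widespread daughters, but no subset sympatry;
  - BAYAREALIKE: exact copying of the full range only.

  Each family can additionally allow founder-event ("jump") speciation,
  where one daughter colonises a single area outside the parent range,
  with per-event weight ``j``.  Per-event weights of the non-jump types are
  ``(3-j)/3`` (DEC), ``(2-j)/2`` (DIVALIKE) and ``1-j`` (BAYAREALIKE),
  matching the conventions used throughout the historical-biogeography
  literature; event probabilities are normalised within each parent range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .range_space import RangeState, StateSpace

__all__ = [
    "ModelParams",
    "ModelFamily",
    "CladoEvent",
    "CladoEventTable",
    "J_CEILING",
    "build_anagenetic_matrix",
    "enumerate_clado_events",
    "build_clado_table",
    "branch_transition_matrix",
    "TransitionMatrixCache",
]

EventType = Literal["sympatry", "subset", "vicariance", "jump"]

#: Maximum admissible j per family: the non-jump per-event weight
#: ((3-j)/3, (2-j)/2, 1-j) must stay positive.
J_CEILING: Dict[str, float] = {"DEC": 3.0, "DIVALIKE": 2.0, "BAYAREALIKE": 1.0}


@dataclass(frozen=True)
class ModelFamily:
    """One of the three cladogenetic families, with or without founder events."""

    family: Literal["DEC", "DIVALIKE", "BAYAREALIKE"]
    jump: bool = False

    def __post_init__(self):
        if self.family not in J_CEILING:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.jump else "")

    @property
    def n_free_params(self) -> int:
        return 3 if self.jump else 2

    @property
    def j_ceiling(self) -> float:
        return J_CEILING[self.family]


@dataclass(frozen=True)
class ModelParams:
    """Rates of the range-evolution process.

    d : dispersal rate per source-area/target-area pair (events/Myr)
    e : extirpation rate per occupied area (events/Myr)
    j : founder-event per-event weight (dimensionless)
    """

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self):
        if self.d < 0 or self.e < 0 or self.j < 0:
            raise ValueError("rates d, e and weight j must be non-negative")

    def validate_for(self, model: ModelFamily) -> None:
        if not model.jump and self.j != 0.0:
            raise ValueError(f"{model.name} has no jump parameter but j={self.j}")
        if self.j >= model.j_ceiling:
            raise ValueError(
                f"j={self.j} must be below the {model.family} ceiling "
                f"{model.j_ceiling}"
            )


@dataclass(frozen=True)
class CladoEvent:
    left: RangeState
    right: RangeState
    type: EventType
    prob: float = 0.0


class CladoEventTable:
    """Per-parent-range enumeration of daughter pairs with probabilities.

    ``events[parent_index]`` lists the allowed (left, right) daughter pairs
    for that parent state.  Probabilities sum to one for every non-null
    parent; the null range cannot cladogenerate and has an empty list.

    For likelihood computation the table is also exposed as flat numpy
    arrays (``parent_idx``, ``left_idx``, ``right_idx``, ``prob``) so that a
    node's conditional likelihood is one vectorised gather-multiply-scatter.
    """

    def __init__(self, space: StateSpace, model: ModelFamily, j: float):
        self.space = space
        self.model = model
        self.j = j
        self.events: List[List[CladoEvent]] = []
        p_idx: List[int] = []
        l_idx: List[int] = []
        r_idx: List[int] = []
        probs: List[float] = []
        for pi, parent in enumerate(space.states):
            if parent.is_null:
                self.events.append([])
                continue
            raw = enumerate_clado_events(parent, model, space)
            weights = np.array([_event_weight(ev.type, model.family, j) for ev in raw])
            total = weights.sum()
            if total <= 0:
                raise ValueError(
                    f"no positive-weight cladogenetic event for parent "
                    f"{parent.label(space.area_names)}"
                )
            weights = weights / total
            evs = [
                CladoEvent(ev.left, ev.right, ev.type, float(w))
                for ev, w in zip(raw, weights)
            ]
            self.events.append(evs)
            for ev in evs:
                p_idx.append(pi)
                l_idx.append(space.index_of[ev.left.bits])
                r_idx.append(space.index_of[ev.right.bits])
                probs.append(ev.prob)
        self.parent_idx = np.asarray(p_idx, dtype=np.intp)
        self.left_idx = np.asarray(l_idx, dtype=np.intp)
        self.right_idx = np.asarray(r_idx, dtype=np.intp)
        self.prob = np.asarray(probs, dtype=float)

    def combine(self, down_left: np.ndarray, down_right: np.ndarray) -> np.ndarray:
        """Conditional likelihood at a node given the two daughters' branch
        contributions: ``L(parent) = sum_events p * left(l) * right(r)``."""
        vals = self.prob * down_left[self.left_idx] * down_right[self.right_idx]
        return np.bincount(
            self.parent_idx, weights=vals, minlength=self.space.n_states
        )

    def to_records(self) -> List[Tuple[str, str, str, str, float]]:
        """Audit serialization: (parent, left, right, type, prob) rows."""
        names = self.space.area_names
        rows = []
        for parent, evs in zip(self.space.states, self.events):
            for ev in evs:
                rows.append(
                    (
                        parent.label(names),
                        ev.left.label(names),
                        ev.right.label(names),
                        ev.type,
                        ev.prob,
                    )
                )
        return rows


def _event_weight(etype: EventType, family: str, j: float) -> float:
    if etype == "jump":
        return j
    if family == "DEC":
        return (3.0 - j) / 3.0
    if family == "DIVALIKE":
        return (2.0 - j) / 2.0
    return 1.0 - j  # BAYAREALIKE


def enumerate_clado_events(
    parent: RangeState, model: ModelFamily, space: StateSpace
) -> List[CladoEvent]:
    """List the daughter pairs a parent range can produce (unweighted).

    Ordered (left, right) pairs are listed both ways; symmetric self-pairs
    such as the sympatric copy appear once.  Jump events target every area
    outside the parent range.
    """
    if parent.is_null:
        raise ValueError("the null range cannot cladogenerate")
    bits = parent.bits
    areas = parent.areas()
    events: List[CladoEvent] = []
    seen: set = set()

    def add(l: int, r: int, etype: EventType):
        key = (l, r, etype)
        if key not in seen:
            seen.add(key)
            events.append(CladoEvent(RangeState(l), RangeState(r), etype))

    fam = model.family
    if fam == "DEC":
        if len(areas) == 1:
            add(bits, bits, "sympatry")
        else:
            for a in areas:
                single = 1 << a
                rest = bits & ~single
                add(bits, single, "subset")
                add(single, bits, "subset")
                add(single, rest, "vicariance")
                add(rest, single, "vicariance")
    elif fam == "DIVALIKE":
        if len(areas) == 1:
            add(bits, bits, "sympatry")
        else:
            # every ordered bipartition into two non-empty disjoint parts
            n = len(areas)
            for sub in range(1, 1 << n):
                if sub == (1 << n) - 1:
                    continue
                l = sum(1 << areas[i] for i in range(n) if sub >> i & 1)
                r = bits & ~l
                add(l, r, "vicariance")
    elif fam == "BAYAREALIKE":
        add(bits, bits, "sympatry")

    if model.jump:
        for b in range(space.n_areas):
            if not bits >> b & 1:
                single = 1 << b
                add(bits, single, "jump")
                add(single, bits, "jump")
    return events


def build_clado_table(
    model: ModelFamily, j: float, space: StateSpace
) -> CladoEventTable:
    """Build the normalised cladogenetic event table for a family and j."""
    if j >= J_CEILING[model.family]:
        raise ValueError(f"j={j} >= {model.family} ceiling {J_CEILING[model.family]}")
    if not model.jump and j > 0:
        raise ValueError("j > 0 requires a +J model (jump=True)")
    return CladoEventTable(space, model, j)


def build_anagenetic_matrix(
    space: StateSpace,
    params: ModelParams,
    dispersal_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Dense anagenetic generator Q over the state space (per Myr).

    Off-diagonal rates: range expansion ``R -> R+{b}`` at
    ``d * sum_{a in R} mult[a, b]`` (only while the cap allows it) and
    contraction ``R -> R-{a}`` at ``e`` per occupied area; single-area
    ranges contract to the null range, which is absorbing.  Rows sum to
    zero.
    """
    n = space.n_areas
    if dispersal_multipliers is None:
        mult = np.ones((n, n))
    else:
        mult = np.asarray(dispersal_multipliers, dtype=float)
        if mult.shape != (n, n):
            raise ValueError(f"multiplier matrix must be {n}x{n}, got {mult.shape}")
        if (mult < 0).any():
            raise ValueError("dispersal multipliers must be non-negative")

    S = space.n_states
    q = np.zeros((S, S))
    for i, state in enumerate(space.states):
        if state.is_null:
            continue
        areas = state.areas()
        # expansions
        if state.size < space.max_range_size:
            for b in range(n):
                if not state.contains_area(b):
                    target = state.bits | (1 << b)
                    ti = space.index_of.get(target)
                    if ti is not None:
                        q[i, ti] = params.d * sum(mult[a, b] for a in areas)
        # contractions
        for a in areas:
            target = state.bits & ~(1 << a)
            ti = space.index_of.get(target)
            if ti is not None:
                q[i, ti] += params.e
        q[i, i] = -q[i].sum() + q[i, i]  # q[i,i] was 0
    return q


def branch_transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities over a branch of duration t: expm(Q t)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(q.shape[0])
    p = expm(q * t)
    # expm can leave tiny negative round-off
    np.clip(p, 0.0, None, out=p)
    return p


class TransitionMatrixCache:
    """Caches expm(Q t) per branch length for a fixed generator.

    A dated tree reuses branch lengths across likelihood evaluations of
    the same parameter vector; the cache makes the pruning pass one expm
    per distinct length.
    """

    def __init__(self, q: np.ndarray):
        self.q = q
        self._cache: Dict[float, np.ndarray] = {}

    def __call__(self, t: float) -> np.ndarray:
        p = self._cache.get(t)
        if p is None:
            p = branch_transition_matrix(self.q, t)
            self._cache[t] = p
        return p
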