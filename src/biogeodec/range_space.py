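"""Discrete geographic ranges as bitmasks over a set of areas.

A lineage's geographic *range* is a set of one or more discrete *areas*
(here, tectonic plates).  Ranges are encoded as bitmasks so that set
operations are cheap and each range has a canonical integer identity.  The
state space of a biogeographic Markov model is the ordered collection of
all allowed ranges: the null (empty) range plus every non-empty range up
to a maximum size cap.

The module also ships the nine-plate squamate scheme (Africa with
Madagascar lumped in, Arabia, Australia, Caribbean, Eurasia, India, North
America, South America, Sunda) and the post-hoc composite labels
(Laurasia, Gondwana, Northern Pangaea, Pangaea) used to summarise
reconstructions on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

__all__ = [
    "Area",
    "RangeState",
    "StateSpace",
    "CompositeScheme",
    "build_state_space",
    "classify_composite",
    "enforce_range_cap",
    "ranges_containing",
    "SQUAMATE_AREAS",
    "squamate_scheme",
    "squamate_state_space",
]


@dataclass(frozen=True)
class Area:
    """A single biogeographic unit (e.g. one tectonic plate)."""

    index: int
    name: str


@dataclass(frozen=True, order=True)
class RangeState:
    """A set of areas encoded as a bitmask; ``bits == 0`` is the null range."""

    bits: int

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_null(self) -> bool:
        return self.bits == 0

    def areas(self) -> List[int]:
        """Indices of the areas in this range, ascending."""
        return [i for i in range(self.bits.bit_length()) if self.bits >> i & 1]

    def contains_area(self, area_index: int) -> bool:
        return bool(self.bits >> area_index & 1)

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "RangeState":
        bits = 0
        for i in indices:
            bits |= 1 << i
        return cls(bits)

    def label(self, area_names: Sequence[str], sep: str = "+") -> str:
        if self.is_null:
            return "null"
        return sep.join(area_names[i] for i in self.areas())


NULL_RANGE = RangeState(0)


class StateSpace:
    """Ordered collection of allowed ranges over a fixed set of areas.

    Ordering is deterministic: the null range first (if included), then by
    range size, then by ascending bitmask value.  Indices are therefore
    stable across runs and usable as matrix row/column ids.
    """

    def __init__(
        self,
        areas: Sequence[Area],
        max_range_size: int,
        include_null: bool = True,
    ):
        names = [a.name for a in areas]
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ValueError("area names must be unique and non-empty")
        if [a.index for a in areas] != list(range(len(areas))):
            raise ValueError("area indices must be contiguous from 0")
        if not 1 <= max_range_size <= len(areas):
            raise ValueError(
                f"max_range_size must be in [1, {len(areas)}], got {max_range_size}"
            )
        self.areas: List[Area] = list(areas)
        self.max_range_size = max_range_size
        self.include_null = include_null

        states: List[RangeState] = []
        if include_null:
            states.append(NULL_RANGE)
        n = len(areas)
        for k in range(1, max_range_size + 1):
            masks = sorted(
                sum(1 << i for i in combo) for combo in combinations(range(n), k)
            )
            states.extend(RangeState(m) for m in masks)
        self.states: List[RangeState] = states
        self.index_of: Dict[int, int] = {s.bits: i for i, s in enumerate(states)}

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def area_names(self) -> List[str]:
        return [a.name for a in self.areas]

    def __len__(self) -> int:
        return self.n_states

    def __contains__(self, state: RangeState) -> bool:
        return state.bits in self.index_of

    def area_by_name(self, name: str) -> Area:
        for a in self.areas:
            if a.name == name:
                return a
        raise KeyError(f"unknown area: {name!r}")

    def state_label(self, index: int, sep: str = "+") -> str:
        return self.states[index].label(self.area_names, sep=sep)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StateSpace(n_areas={self.n_areas}, max_range_size={self.max_range_size},"
            f" include_null={self.include_null}, n_states={self.n_states})"
        )


def build_state_space(
    n_areas: int,
    max_range_size: int,
    include_null: bool = True,
    area_names: Sequence[str] | None = None,
) -> StateSpace:
    """Build the capped range state space.

    The cardinality is ``(1 if include_null else 0) + sum_{k=1..m} C(n, k)``;
    for nine areas capped at four with the null range that is 256 states.
    """
    if area_names is None:
        area_names = [f"A{i}" for i in range(n_areas)]
    if len(area_names) != n_areas:
        raise ValueError("area_names length must equal n_areas")
    areas = [Area(i, name) for i, name in enumerate(area_names)]
    space = StateSpace(areas, max_range_size, include_null)
    expected = (1 if include_null else 0) + sum(
        comb(n_areas, k) for k in range(1, max_range_size + 1)
    )
    assert space.n_states == expected
    return space


@dataclass(frozen=True)
class CompositeScheme:
    """Post-hoc composite labels over a bipartition of the areas.

    ``laurasia`` and ``gondwana`` are disjoint bitmasks covering every
    area; ``pivot`` is the single Gondwanan area (Africa in the squamate
    scheme) whose mixture with Laurasian areas is labelled Northern
    Pangaea rather than Pangaea.
    """

    laurasia: int
    gondwana: int
    pivot: int  # area index, must be a member of gondwana

    LABELS = ("Laurasia", "Gondwana", "Northern Pangaea", "Pangaea")

    def __post_init__(self):
        if self.laurasia & self.gondwana:
            raise ValueError("laurasia and gondwana must be disjoint")
        if not (self.gondwana >> self.pivot & 1):
            raise ValueError("pivot area must belong to gondwana")


def classify_composite(range_state: RangeState, scheme: CompositeScheme) -> str:
    """Assign one of the four composite labels to a non-null range.

    Precedence: purely Laurasian -> "Laurasia"; purely Gondwanan ->
    "Gondwana"; mixed with the pivot as the only Gondwanan member ->
    "Northern Pangaea"; any other mixture -> "Pangaea".
    """
    if range_state.is_null:
        raise ValueError("cannot classify the null range")
    bits = range_state.bits
    gond_part = bits & scheme.gondwana
    laur_part = bits & scheme.laurasia
    if gond_part == 0:
        return "Laurasia"
    if laur_part == 0:
        return "Gondwana"
    if gond_part == (1 << scheme.pivot):
        return "Northern Pangaea"
    return "Pangaea"


def enforce_range_cap(
    tip_ranges: Mapping[str, RangeState],
    max_size: int,
    overrides: Mapping[str, RangeState] | None = None,
) -> Dict[str, RangeState]:
    """Apply a maximum range size to a tip-range table.

    Ranges already within the cap pass through; an over-cap taxon must
    have an explicit override (itself within the cap) or an error names
    it.  This mirrors the practice of collapsing the handful of very
    widespread species (e.g. pelagic seasnakes) to a designated range.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(tip_ranges)
    if unknown:
        raise KeyError(f"overrides for unknown taxa: {sorted(unknown)}")
    for taxon, rng in overrides.items():
        if rng.size > max_size:
            raise ValueError(
                f"override for {taxon!r} has size {rng.size} > cap {max_size}"
            )
    out: Dict[str, RangeState] = {}
    for taxon, rng in tip_ranges.items():
        if rng.size <= max_size:
            out[taxon] = overrides.get(taxon, rng) if taxon in overrides else rng
        elif taxon in overrides:
            out[taxon] = overrides[taxon]
        else:
            raise ValueError(
                f"taxon {taxon!r} has range size {rng.size} exceeding the cap "
                f"{max_size} and no override was provided"
            )
    return out


def ranges_containing(area: Area | int | str, space: StateSpace) -> np.ndarray:
    """Boolean mask over ``space.states``: True where the state includes *area*.

    The null range is never marked.  Used to compute per-area inclusion
    proportions of ancestral range estimates.
    """
    if isinstance(area, Area):
        idx = area.index
        if idx >= space.n_areas or space.areas[idx].name != area.name:
            raise KeyError(f"area {area} not in this state space")
    elif isinstance(area, str):
        idx = space.area_by_name(area).index
    else:
        idx = int(area)
        if not 0 <= idx < space.n_areas:
            raise KeyError(f"area index {idx} out of range")
    return np.array([s.contains_area(idx) for s in space.states], dtype=bool)


# --- the nine-plate squamate preset -------------------------------------

SQUAMATE_AREAS: List[str] = [
    "Africa",      # includes Madagascar
    "Arabia",
    "Australia",
    "Caribbean",
    "Eurasia",
    "India",
    "NorthAmerica",
    "SouthAmerica",
    "Sunda",
]

_LAURASIAN = ("Eurasia", "Caribbean", "NorthAmerica", "Sunda")
_GONDWANAN = ("Australia", "Africa", "Arabia", "India", "SouthAmerica")


def squamate_scheme() -> CompositeScheme:
    """Composite scheme for the nine-plate preset (pivot area: Africa)."""
    name_to_idx = {n: i for i, n in enumerate(SQUAMATE_AREAS)}
    laur = sum(1 << name_to_idx[n] for n in _LAURASIAN)
    gond = sum(1 << name_to_idx[n] for n in _GONDWANAN)
    return CompositeScheme(laurasia=laur, gondwana=gond, pivot=name_to_idx["Africa"])


def squamate_state_space(max_range_size: int = 4) -> StateSpace:
    """The nine-plate state space with ranges capped at four areas (256 states)."""
    return build_state_space(
        9, max_range_size, include_null=True, area_names=SQUAMATE_AREAS
    )
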