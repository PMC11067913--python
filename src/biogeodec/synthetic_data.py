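"""Forward simulation of range evolution on dated trees.

Generates test data under exactly the generative model the likelihood
assumes: a pure-birth (Yule) tree, a root range, anagenetic
dispersal/extirpation as a continuous-time Markov chain along branches,
and one cladogenetic event per node drawn from the model's event table.
Every simulated dataset carries its full event log and true node states,
so inference and event-counting can be checked against a known history.

Also provides a hand-built miniature squamate backbone with the four
Jurassic/early-Cretaceous fossil node constraints (each requiring
Eurasia), for exercising constrained analyses at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np

from .clado_models import (
    CladoEventTable,
    ModelFamily,
    ModelParams,
    build_anagenetic_matrix,
    build_clado_table,
)
from .inference import NodeConstraint
from .range_space import (
    SQUAMATE_AREAS,
    RangeState,
    StateSpace,
    build_state_space,
    squamate_state_space,
)
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "SimOutput",
    "EventRecord",
    "simulate_tree",
    "simulate_history",
    "replay_event_log",
    "make_fixture",
    "squamate_backbone_fixture",
    "BackboneFixture",
]

SUBSEED_STRIDE = 1_000_003  # replicate r reuses seed + r * stride


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one forward simulation."""

    n_tips: int
    n_areas: int
    max_range_size: int
    model: ModelFamily
    params: ModelParams
    birth_rate: float = 0.1  # per Myr; keeps trees shallow enough that
    # whole-replicate rejection (any lineage reaching the null range)
    # stays cheap at the default extirpation rates
    root_range: Union[RangeState, Literal["random"]] = "random"
    seed: int = 0
    max_rejections: int = 100

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("need at least two tips")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")

    def state_space(self) -> StateSpace:
        return build_state_space(self.n_areas, self.max_range_size, include_null=True)


@dataclass(frozen=True)
class EventRecord:
    """One event of the simulated history.

    ``time`` is Myr from the root; ``node`` is the post-order id of the
    branch's child node for anagenetic events, or of the splitting node
    for cladogenetic events.  ``detail`` holds the states involved as
    bitmask integers.
    """

    time: float
    node: int
    type: str  # dispersal | extirpation | sympatry | subset | vicariance | jump
    detail: Dict[str, int]


@dataclass
class SimOutput:
    tree: Phylogeny
    tips: Dict[str, RangeState]
    true_states: Dict[int, RangeState]  # split-point states; tips: final states
    event_log: List[EventRecord]
    config: SimConfig
    n_rejections: int = 0


def simulate_tree(n_tips: int, birth_rate: float, seed: int = 0) -> Phylogeny:
    """Pure-birth tree with exactly *n_tips* extant tips, ultrametric.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears the process runs for one further exponential waiting time so
    terminal branches have positive length.  Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # node records: (birth_time, children or None); root splits at time 0
    birth: List[float] = [0.0, 0.0]
    kids: List[Optional[Tuple[int, int]]] = [None, None]
    active: List[int] = [0, 1]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        l, r = len(birth), len(birth) + 1
        birth.extend([t, t])
        kids.extend([None, None])
        kids[v] = (l, r)
        active.extend([l, r])
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))

    # convert to post-order arrays; root is a synthetic node joining 0 and 1
    children_po: List[Optional[Tuple[int, int]]] = []
    lengths_po: List[float] = []
    labels_po: List[Optional[str]] = []
    po_id: Dict[int, int] = {}
    tip_counter = [0]

    def visit(v: int) -> int:
        ch = kids[v]
        if ch is None:
            tip_counter[0] += 1
            children_po.append(None)
            labels_po.append(f"t{tip_counter[0]}")
            lengths_po.append(present - birth[v])
        else:
            a = visit(ch[0])
            b = visit(ch[1])
            split = birth[kids[v][0]]
            children_po.append((a, b))
            labels_po.append(None)
            lengths_po.append(split - birth[v])
        po_id[v] = len(children_po) - 1
        return po_id[v]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n_tips + 100))
    try:
        a = visit(0)
        b = visit(1)
    finally:
        sys.setrecursionlimit(old)
    children_po.append((a, b))
    labels_po.append(None)
    lengths_po.append(0.0)
    return Phylogeny(children_po, lengths_po, labels_po)


_ANAGENETIC_TYPE = {True: "dispersal", False: "extirpation"}


def draw_clado_event(clado: CladoEventTable, state_index: int, rng: np.random.Generator):
    """Draw one cladogenetic event for a parent state from the event table."""
    evs = clado.events[state_index]
    if not evs:
        raise ValueError("the null range cannot cladogenerate")
    probs = np.array([e.prob for e in evs])
    return evs[int(rng.choice(len(evs), p=probs))]


def _simulate_branch(
    state: int,
    t0: float,
    t1: float,
    node: int,
    q: np.ndarray,
    space: StateSpace,
    rng: np.random.Generator,
    log: List[EventRecord],
) -> int:
    """Exact CTMC simulation from t0 to t1; returns the end state index."""
    t = t0
    while True:
        total = -q[state, state]
        if total <= 0:
            return state
        t += rng.exponential(1.0 / total)
        if t >= t1:
            return state
        rates = q[state].copy()
        rates[state] = 0.0
        nxt = int(rng.choice(len(rates), p=rates / rates.sum()))
        gained = space.states[nxt].size > space.states[state].size
        log.append(
            EventRecord(
                time=t,
                node=node,
                type=_ANAGENETIC_TYPE[gained],
                detail={
                    "from_state": space.states[state].bits,
                    "to_state": space.states[nxt].bits,
                },
            )
        )
        state = nxt


def _attempt(
    tree: Phylogeny, config: SimConfig, space: StateSpace, q: np.ndarray,
    clado: CladoEventTable, seed: int
) -> Optional[SimOutput]:
    rng = np.random.default_rng(seed)
    depth = tree.node_depths()
    null_idx = space.index_of[0]

    if config.root_range == "random":
        nonnull = [i for i in range(space.n_states) if i != null_idx]
        root_state = int(rng.choice(nonnull))
    else:
        root_state = space.index_of[config.root_range.bits]

    log: List[EventRecord] = []
    true_states: Dict[int, RangeState] = {}
    tips: Dict[str, RangeState] = {}
    # pre-order: state at each node's split point
    start_state: Dict[int, int] = {tree.root: root_state}
    for v in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[v]
        s = start_state[v]
        true_states[v] = space.states[s]
        if s == null_idx:
            return None  # lineage went globally extinct: reject the replicate
        if ch is None:
            tips[tree.labels[v]] = space.states[s]
            continue
        ev = draw_clado_event(clado, s, rng)
        log.append(
            EventRecord(
                time=depth[v],
                node=v,
                type=ev.type,
                detail={"parent": space.states[s].bits,
                        "left": ev.left.bits, "right": ev.right.bits},
            )
        )
        for child, st in ((ch[0], ev.left), (ch[1], ev.right)):
            end = _simulate_branch(
                space.index_of[st.bits], depth[v], depth[child], child,
                q, space, rng, log,
            )
            start_state[child] = end
    log.sort(key=lambda r: (r.time, r.node))
    return SimOutput(tree, tips, true_states, log, config)


def simulate_history(tree: Phylogeny, config: SimConfig) -> SimOutput:
    """Simulate ranges forward along an existing tree.

    Replicates in which any tip goes globally extinct (reaches the null
    range) are rejected and redrawn with an incremented sub-seed; the
    number of rejections is reported on the output.
    """
    config.params.validate_for(config.model)
    space = config.state_space()
    if isinstance(config.root_range, RangeState):
        if config.root_range.bits not in space.index_of or config.root_range.is_null:
            raise ValueError("root range must be a non-null state of the space")
    q = build_anagenetic_matrix(space, config.params)
    clado = build_clado_table(config.model, config.params.j, space)
    for r in range(config.max_rejections + 1):
        out = _attempt(tree, config, space, q, clado, config.seed + r * SUBSEED_STRIDE)
        if out is not None:
            out.n_rejections = r
            return out
    raise RuntimeError(
        f"all {config.max_rejections + 1} attempts hit a null tip range; "
        "the extirpation rate is too high for this tree depth"
    )


def replay_event_log(
    tree: Phylogeny, log: Sequence[EventRecord], space: StateSpace
) -> Dict[int, RangeState]:
    """Reconstruct every node and tip state purely from the event log.

    Used to verify that the log is a complete, consistent account of the
    simulated history: the result must equal ``SimOutput.true_states``.
    """
    clado_at: Dict[int, EventRecord] = {}
    branch_events: Dict[int, List[EventRecord]] = {}
    for rec in log:
        if rec.type in ("dispersal", "extirpation"):
            branch_events.setdefault(rec.node, []).append(rec)
        else:
            clado_at[rec.node] = rec
    states: Dict[int, RangeState] = {}

    root_rec = clado_at[tree.root]
    states[tree.root] = RangeState(root_rec.detail["parent"])
    for v in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[v]
        if ch is None:
            continue
        rec = clado_at[v]
        if rec.detail["parent"] != states[v].bits:
            raise ValueError(f"event log inconsistent at node {v}")
        for child, bits in ((ch[0], rec.detail["left"]), (ch[1], rec.detail["right"])):
            state = bits
            for ev in sorted(branch_events.get(child, []), key=lambda r: r.time):
                if ev.detail["from_state"] != state:
                    raise ValueError(f"event log inconsistent on branch {child}")
                state = ev.detail["to_state"]
            states[child] = RangeState(state)
    return states


def make_fixture(config: SimConfig, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write a simulated dataset bundle to disk.

    Files: ``tree.nwk`` (Newick), ``geography.data`` (Lagrange-style),
    ``true_states.tsv``, ``events.tsv``, ``config.json``.  Idempotent for
    a fixed config.
    """
    from .io import write_geography  # local import avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_tips, config.birth_rate, config.seed)
    out = simulate_history(tree, config)
    space = config.state_space()
    names = space.area_names

    paths = {
        "tree": out_dir / "tree.nwk",
        "geography": out_dir / "geography.data",
        "true_states": out_dir / "true_states.tsv",
        "events": out_dir / "events.tsv",
        "config": out_dir / "config.json",
    }
    paths["tree"].write_text(tree.to_newick() + "\n")
    write_geography(paths["geography"], names, out.tips)
    with open(paths["true_states"], "w") as fh:
        fh.write("node\tlabel\trange\n")
        for node in sorted(out.true_states):
            lab = tree.labels[node] or ""
            fh.write(f"{node}\t{lab}\t{out.true_states[node].label(names)}\n")
    with open(paths["events"], "w") as fh:
        fh.write("time\tnode\ttype\tdetail\n")
        for rec in out.event_log:
            fh.write(
                f"{rec.time:.6f}\t{rec.node}\t{rec.type}\t{json.dumps(rec.detail)}\n"
            )
    cfg = {
        "n_tips": config.n_tips,
        "n_areas": config.n_areas,
        "max_range_size": config.max_range_size,
        "model": config.model.name,
        "d": config.params.d,
        "e": config.params.e,
        "j": config.params.j,
        "birth_rate": config.birth_rate,
        "root_range": "random"
        if config.root_range == "random"
        else config.root_range.bits,
        "seed": config.seed,
        "n_rejections": out.n_rejections,
    }
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths


# --- miniature squamate backbone with fossil constraints ------------------


@dataclass
class BackboneFixture:
    """A synthetic 14-tip squamate backbone for constrained analyses.

    The topology and node ages are a hand-built caricature of the major
    squamate clades (Dibamia, Gekkota, Scincomorpha, Laterata,
    Anguimorpha, Iguania, Serpentes); tip ranges are plausible
    present-day codings on the nine-plate scheme.  The four constraints
    mirror the Jurassic/early-Cretaceous fossil occurrences used to pin
    deep nodes to Eurasia: a stem snake for Toxicofera, an early iguanian
    for Iguania+Anguimorpha, a paleoanguimorph for Paleoanguimorpha and
    an early lateratan for Laterata.
    """

    tree: Phylogeny
    constraints: List[NodeConstraint]
    tip_ranges: Dict[str, RangeState]
    space: StateSpace
    clade_mrcas: Dict[str, Tuple[str, str]]


_BACKBONE_NEWICK = (
    "(Dibamus_novaeguineae:195,"
    "((Gekko_gecko:60,Sphaerodactylus_macrolepis:60):130,"
    "((Scincus_scincus:70,Plestiodon_fasciatus:70):115,"
    "((Tupinambis_teguixin:150,Lacerta_agilis:150):30,"
    "((Python_regius:110,Naja_naja:110):60,"
    "((Anolis_carolinensis:120,Iguana_iguana:120):45,"
    "(Anguis_fragilis:140,"
    "(Shinisaurus_crocodilurus:100,Varanus_komodoensis:100):40"
    "):25):5):10):5):5):5);"
)

_BACKBONE_RANGES: Dict[str, Tuple[str, ...]] = {
    "Dibamus_novaeguineae": ("Sunda",),
    "Gekko_gecko": ("Eurasia", "Sunda"),
    "Sphaerodactylus_macrolepis": ("Caribbean",),
    "Scincus_scincus": ("Africa", "Arabia"),
    "Plestiodon_fasciatus": ("NorthAmerica",),
    "Tupinambis_teguixin": ("SouthAmerica",),
    "Lacerta_agilis": ("Eurasia",),
    "Python_regius": ("Africa",),
    "Naja_naja": ("Eurasia", "India"),
    "Anolis_carolinensis": ("NorthAmerica", "Caribbean"),
    "Iguana_iguana": ("SouthAmerica", "Caribbean"),
    "Anguis_fragilis": ("Eurasia",),
    "Shinisaurus_crocodilurus": ("Eurasia",),
    "Varanus_komodoensis": ("Sunda", "Australia"),
}


def squamate_backbone_fixture() -> BackboneFixture:
    """Miniature dated backbone plus the four Eurasia node constraints."""
    tree = Phylogeny.from_newick(_BACKBONE_NEWICK)
    space = squamate_state_space()
    name_to_idx = {n: i for i, n in enumerate(SQUAMATE_AREAS)}
    tips = {
        taxon: RangeState.from_indices(name_to_idx[a] for a in areas)
        for taxon, areas in _BACKBONE_RANGES.items()
    }
    constraints = [
        NodeConstraint(
            "Toxicofera", ("Python_regius", "Anolis_carolinensis"), ("Eurasia",)
        ),
        NodeConstraint(
            "Iguania+Anguimorpha",
            ("Anolis_carolinensis", "Varanus_komodoensis"),
            ("Eurasia",),
        ),
        NodeConstraint(
            "Paleoanguimorpha",
            ("Shinisaurus_crocodilurus", "Varanus_komodoensis"),
            ("Eurasia",),
        ),
        NodeConstraint(
            "Laterata", ("Tupinambis_teguixin", "Lacerta_agilis"), ("Eurasia",)
        ),
    ]
    clade_mrcas = {
        "Squamata": ("Dibamus_novaeguineae", "Lacerta_agilis"),
        "Unidentata": ("Scincus_scincus", "Lacerta_agilis"),
        "Episquamata": ("Tupinambis_teguixin", "Naja_naja"),
        "Toxicofera": ("Python_regius", "Anolis_carolinensis"),
        "Gekkota": ("Gekko_gecko", "Sphaerodactylus_macrolepis"),
        "Scincomorpha": ("Scincus_scincus", "Plestiodon_fasciatus"),
        "Laterata": ("Tupinambis_teguixin", "Lacerta_agilis"),
        "Anguimorpha": ("Anguis_fragilis", "Varanus_komodoensis"),
        "Iguania": ("Anolis_carolinensis", "Iguana_iguana"),
        "Serpentes": ("Python_regius", "Naja_naja"),
    }
    return BackboneFixture(tree, constraints, tips, space, clade_mrcas)
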