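"""Likelihood, ML fitting and ancestral range estimation on dated trees.

The likelihood of tip ranges under a dispersal-extinction-cladogenesis
model is computed by Felsenstein pruning: tip conditional likelihoods are
indicators of the observed range; each branch propagates its child's
vector through ``expm(Q t)``; each internal node combines its two
daughters through the cladogenetic event table.  Fossil-based node
constraints zero out ancestral states that do not include the required
areas, exactly as a hard structural prior.  The root prior is flat over
the non-null states and a cladogenetic event is applied at the root like
at any other node.

Per-node rescaling with accumulated log factors keeps the computation in
double precision on trees of thousands of tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .clado_models import (
    CladoEventTable,
    ModelFamily,
    ModelParams,
    TransitionMatrixCache,
    build_anagenetic_matrix,
    build_clado_table,
)
from .range_space import RangeState, StateSpace
from .trees import Phylogeny

__all__ = [
    "NodeConstraint",
    "FitResult",
    "AncestralEstimate",
    "prune_likelihood",
    "constraint_masks",
    "apply_node_constraints",
    "fit_ml",
    "fit_all_models",
    "marginal_ancestral_states",
    "brute_force_likelihood",
    "MODEL_ORDER",
]

MODEL_ORDER: Tuple[ModelFamily, ...] = (
    ModelFamily("DEC", False),
    ModelFamily("DEC", True),
    ModelFamily("DIVALIKE", False),
    ModelFamily("DIVALIKE", True),
    ModelFamily("BAYAREALIKE", False),
    ModelFamily("BAYAREALIKE", True),
)

# optimizer box for the per-Myr rates; the lower bound doubles as the
# reported value when a rate is effectively zero
RATE_FLOOR = 1e-12
RATE_CEIL = 5.0
J_EPS = 1e-5


@dataclass(frozen=True)
class NodeConstraint:
    """Force an internal node's range to include a set of areas.

    The node is addressed as the MRCA of two or more tips; the required
    areas come from a fossil occurrence confidently assigned to the clade.
    """

    name: str
    mrca_taxa: Tuple[str, ...]
    required_areas: Tuple[str, ...]

    def __post_init__(self):
        if len(self.mrca_taxa) < 2:
            raise ValueError(
                f"constraint {self.name!r}: at least two MRCA taxa required"
            )
        if not self.required_areas:
            raise ValueError(f"constraint {self.name!r}: no required areas")


def constraint_masks(
    constraints: Sequence[NodeConstraint],
    tree: Phylogeny,
    space: StateSpace,
) -> Dict[int, np.ndarray]:
    """Resolve constraints to {node id: boolean state mask}.

    A state passes only if it contains *all* required areas.  Multiple
    constraints on the same node intersect.
    """
    masks: Dict[int, np.ndarray] = {}
    for c in constraints:
        node = tree.mrca(c.mrca_taxa)
        required = 0
        for name in c.required_areas:
            required |= 1 << space.area_by_name(name).index
        mask = np.array(
            [(s.bits & required) == required for s in space.states], dtype=bool
        )
        masks[node] = mask if node not in masks else (masks[node] & mask)
    return masks


def apply_node_constraints(
    partials: Mapping[int, np.ndarray],
    constraints: Sequence[NodeConstraint],
    space: StateSpace,
    tree: Phylogeny,
) -> Dict[int, np.ndarray]:
    """Zero the entries of per-node state vectors disallowed by constraints."""
    masks = constraint_masks(constraints, tree, space)
    out: Dict[int, np.ndarray] = {}
    for node, vec in partials.items():
        vec = np.asarray(vec, dtype=float)
        if node in masks:
            vec = np.where(masks[node], vec, 0.0)
        out[node] = vec
    return out


def _tip_indicator(space: StateSpace, rng: RangeState) -> np.ndarray:
    if rng.is_null:
        raise ValueError("tips cannot have the null range")
    idx = space.index_of.get(rng.bits)
    if idx is None:
        raise ValueError(
            f"tip range of size {rng.size} is outside the state space "
            f"(cap {space.max_range_size})"
        )
    vec = np.zeros(space.n_states)
    vec[idx] = 1.0
    return vec


def _root_prior(space: StateSpace) -> np.ndarray:
    prior = np.ones(space.n_states)
    if space.include_null:
        prior[space.index_of[0]] = 0.0
    return prior / prior.sum()


@dataclass
class PruneResult:
    """Everything the pruning pass computed, for reuse by downstream passes."""

    lnL: float
    partials: Dict[int, np.ndarray]      # rescaled post-mask conditionals
    log_scale: Dict[int, float]          # accumulated log rescaling factors
    down: Dict[int, np.ndarray]          # branch contribution of each non-root node
    masks: Dict[int, np.ndarray]
    pcache: TransitionMatrixCache
    clado: CladoEventTable
    prior: np.ndarray


def _check_inputs(
    tree: Phylogeny, tips: Mapping[str, RangeState], space: StateSpace
) -> None:
    missing = [l for l in tree.tip_labels() if l not in tips]
    if missing:
        raise ValueError(f"tips without range data: {missing[:5]}")
    if not space.include_null:
        raise ValueError("inference requires a state space that includes the null range")


def prune_likelihood(
    tree: Phylogeny,
    tips: Mapping[str, RangeState],
    space: StateSpace,
    model: ModelFamily,
    params: ModelParams,
    constraints: Sequence[NodeConstraint] = (),
    dispersal_multipliers: Optional[np.ndarray] = None,
) -> PruneResult:
    """Log-likelihood of the tip ranges by post-order pruning.

    Returns a :class:`PruneResult` whose ``lnL`` is ``-inf`` (not an
    exception) when constraints or data give the model zero likelihood.
    """
    _check_inputs(tree, tips, space)
    params.validate_for(model)
    q = build_anagenetic_matrix(space, params, dispersal_multipliers)
    pcache = TransitionMatrixCache(q)
    clado = build_clado_table(model, params.j, space)
    masks = constraint_masks(constraints, tree, space)
    prior = _root_prior(space)

    partials: Dict[int, np.ndarray] = {}
    log_scale: Dict[int, float] = {}
    down: Dict[int, np.ndarray] = {}

    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if ch is None:
            vec = _tip_indicator(space, tips[tree.labels[v]])
            log_scale[v] = 0.0
        else:
            a, b = ch
            down[a] = pcache(tree.lengths[a]) @ partials[a]
            down[b] = pcache(tree.lengths[b]) @ partials[b]
            vec = clado.combine(down[a], down[b])
            log_scale[v] = log_scale[a] + log_scale[b]
        if v in masks:
            vec = np.where(masks[v], vec, 0.0)
        m = vec.max()
        if m > 0:
            vec = vec / m
            log_scale[v] += math.log(m)
        partials[v] = vec

    root = tree.root
    total = float(prior @ partials[root])
    lnL = -math.inf if total <= 0 else math.log(total) + log_scale[root]
    return PruneResult(lnL, partials, log_scale, down, masks, pcache, clado, prior)


@dataclass
class AncestralEstimate:
    """Marginal (split-point) state probabilities at every internal node."""

    space: StateSpace
    probs: Dict[int, np.ndarray]  # internal node id -> probability vector
    lnL: float

    def __getitem__(self, node: int) -> np.ndarray:
        return self.probs[node]

    def nodes(self) -> List[int]:
        return sorted(self.probs)


def marginal_ancestral_states(
    tree: Phylogeny,
    tips: Mapping[str, RangeState],
    space: StateSpace,
    model: ModelFamily,
    params: ModelParams,
    constraints: Sequence[NodeConstraint] = (),
    dispersal_multipliers: Optional[np.ndarray] = None,
) -> AncestralEstimate:
    """Marginal probability of each range at each internal node.

    These are split-point marginals: ``P(state at node = R | data)`` equals
    ``exp(lnL with the node constrained to exactly R - total lnL)``.  They
    are computed in one extra pre-order pass rather than by re-running the
    pruning once per node and state; the equivalence with the masking
    identity is a tested invariant.
    """
    res = prune_likelihood(
        tree, tips, space, model, params, constraints, dispersal_multipliers
    )
    if not math.isfinite(res.lnL):
        raise ValueError("likelihood is zero; no ancestral estimate exists")

    up: Dict[int, np.ndarray] = {}
    probs: Dict[int, np.ndarray] = {}
    clado = res.clado
    S = space.n_states
    root = tree.root
    up[root] = res.prior.copy()

    for v in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[v]
        if ch is None:
            continue
        u = up[v]
        if v in res.masks:
            u = np.where(res.masks[v], u, 0.0)
        joint = u * res.partials[v]
        total = joint.sum()
        probs[v] = joint / total
        a, b = ch
        for child, sib in ((a, b), (b, a)):
            vals = clado.prob * u[clado.parent_idx] * res.down[sib][
                clado.right_idx if child == a else clado.left_idx
            ]
            w = np.bincount(
                clado.left_idx if child == a else clado.right_idx,
                weights=vals,
                minlength=S,
            )
            u_child = res.pcache(tree.lengths[child]).T @ w
            s = u_child.sum()
            if s > 0:
                u_child = u_child / s
            up[child] = u_child
    return AncestralEstimate(space, probs, res.lnL)


@dataclass
class FitResult:
    """One fitted model: parameters, log-likelihood and bookkeeping."""

    model: ModelFamily
    params: ModelParams
    lnL: float
    n_tips: int
    converged: bool
    n_starts: int
    seed: int
    best_start: int = 0

    @property
    def k(self) -> int:
        return self.model.n_free_params

    @property
    def name(self) -> str:
        return self.model.name


def fit_ml(
    tree: Phylogeny,
    tips: Mapping[str, RangeState],
    space: StateSpace,
    model: ModelFamily,
    constraints: Sequence[NodeConstraint] = (),
    n_starts: int = 1,
    seed: int = 0,
    dispersal_multipliers: Optional[np.ndarray] = None,
) -> FitResult:
    """Maximum-likelihood estimates of (d, e[, j]) for one model family.

    Box-constrained quasi-Newton optimisation on log10-transformed rates
    (j untransformed), from the default start d = e = 0.01 (j = 0.01 for
    +J models) plus ``n_starts - 1`` seeded random restarts.  Ties are
    broken by lowest start index, so results are deterministic given the
    seed.
    """
    _check_inputs(tree, tips, space)
    jump = model.jump
    j_hi = model.j_ceiling - J_EPS

    def unpack(x: np.ndarray) -> ModelParams:
        d, e = 10.0 ** x[0], 10.0 ** x[1]
        j = float(x[2]) if jump else 0.0
        return ModelParams(d=d, e=e, j=j)

    def neg_lnL(x: np.ndarray) -> float:
        lnL = prune_likelihood(
            tree, tips, space, model, unpack(x), constraints, dispersal_multipliers
        ).lnL
        return 1e10 if not math.isfinite(lnL) else -lnL

    lo, hi = math.log10(RATE_FLOOR), math.log10(RATE_CEIL)
    bounds = [(lo, hi), (lo, hi)] + ([(0.0, j_hi)] if jump else [])

    rng = np.random.default_rng(seed)
    starts: List[np.ndarray] = [
        np.array([-2.0, -2.0] + ([0.01] if jump else []))
    ]
    for _ in range(n_starts - 1):
        s = [rng.uniform(-4, 0), rng.uniform(-4, 0)]
        if jump:
            s.append(rng.uniform(0.0, min(1.0, j_hi) * 0.5))
        starts.append(np.array(s))

    best = None
    best_idx = -1
    for i, x0 in enumerate(starts):
        opt = minimize(neg_lnL, x0, method="L-BFGS-B", bounds=bounds)
        if opt.fun >= 1e10:
            continue
        if best is None or opt.fun < best.fun - 1e-12:
            best, best_idx = opt, i
    if best is None:
        raise RuntimeError(
            f"{model.name}: non-finite likelihood at every start "
            f"(n_starts={n_starts}, seed={seed})"
        )
    return FitResult(
        model=model,
        params=unpack(best.x),
        lnL=-float(best.fun),
        n_tips=tree.n_tips,
        converged=bool(best.success),
        n_starts=n_starts,
        seed=seed,
        best_start=best_idx,
    )


def fit_all_models(
    tree: Phylogeny,
    tips: Mapping[str, RangeState],
    space: StateSpace,
    constraints: Sequence[NodeConstraint] = (),
    n_starts: int = 1,
    seed: int = 0,
) -> List[FitResult]:
    """Fit all six candidate models in the canonical comparison order."""
    return [
        fit_ml(tree, tips, space, m, constraints, n_starts=n_starts, seed=seed)
        for m in MODEL_ORDER
    ]


def brute_force_likelihood(
    tree: Phylogeny,
    tips: Mapping[str, RangeState],
    space: StateSpace,
    model: ModelFamily,
    params: ModelParams,
    constraints: Sequence[NodeConstraint] = (),
    max_assignments: int = 2_000_000,
) -> float:
    """Likelihood by explicit summation over joint ancestral assignments.

    Test oracle: enumerates every assignment of a state to every internal
    node and sums root prior x cladogenetic probabilities x branch
    transition probabilities.  Only feasible on tiny instances; guarded by
    ``max_assignments``.
    """
    _check_inputs(tree, tips, space)
    params.validate_for(model)
    q = build_anagenetic_matrix(space, params)
    pcache = TransitionMatrixCache(q)
    clado = build_clado_table(model, params.j, space)
    masks = constraint_masks(constraints, tree, space)
    prior = _root_prior(space)

    internal = tree.internal_ids()
    S = space.n_states
    if S ** len(internal) > max_assignments:
        raise ValueError(
            f"{S}^{len(internal)} assignments exceed the brute-force guard"
        )
    tip_state = {
        i: space.index_of[tips[tree.labels[i]].bits]
        for i in range(tree.n_nodes)
        if tree.is_tip(i)
    }
    # candidate states per internal node: non-null, and passing any mask
    candidates: List[List[int]] = []
    for v in internal:
        ok = [
            i
            for i, s in enumerate(space.states)
            if not s.is_null and (v not in masks or masks[v][i])
        ]
        candidates.append(ok)

    pmats = {v: pcache(tree.lengths[v]) for v in range(tree.n_nodes) if v != tree.root}

    total = 0.0
    for assignment in product(*candidates):
        state_of = dict(zip(internal, assignment))
        state_of.update(tip_state)
        like = prior[state_of[tree.root]]
        for v in internal:
            a, b = tree.children[v]
            sa, sb = state_of[a], state_of[b]
            factor = 0.0
            for ev in clado.events[state_of[v]]:
                l = space.index_of[ev.left.bits]
                r = space.index_of[ev.right.bits]
                factor += ev.prob * pmats[a][l, sa] * pmats[b][r, sb]
            like *= factor
            if like == 0.0:
                break
        total += like
    return -math.inf if total <= 0 else math.log(total)
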