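"""Model selection tables and biogeographic event summaries.

Covers the standard downstream products of an ancestral-range analysis:
AICc model comparison with Akaike weights and likelihood-ratio tests,
per-area inclusion proportions of the marginal estimates, most-probable
ranges per node, and counts of dispersal, area-loss and composite-range
transitions painted onto the tree from the most-probable states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .inference import AncestralEstimate, FitResult
from .range_space import CompositeScheme, RangeState, StateSpace, classify_composite, ranges_containing
from .trees import Phylogeny

__all__ = [
    "aicc",
    "akaike_weights",
    "likelihood_ratio_test",
    "model_comparison_table",
    "area_inclusion_proportions",
    "most_probable_ranges",
    "EventCounts",
    "count_events",
    "count_composite_transitions",
]


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)`` with n the number of tips.
    """
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k+1 (got n={n}, k={k})")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Relative model support: ``w_i = exp(-d_i/2) / sum exp(-d_m/2)``
    with ``d_i = AICc_i - min AICc``.  Invariant to adding a constant."""
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no AICc values")
    delta = vals - np.nanmin(vals)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def likelihood_ratio_test(
    lnL_null: float, lnL_alt: float, df: int, tol: float = 1e-8
) -> Tuple[float, float]:
    """LRT of a nested pair: statistic ``2(lnL_alt - lnL_null)`` against
    a chi-square with *df* degrees of freedom; returns (statistic, p)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -tol:
        raise ValueError(
            f"alternative lnL {lnL_alt} is below the null {lnL_null}; "
            "the models are not nested or a fit failed"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def model_comparison_table(fits: Sequence[FitResult], n: int | None = None) -> pd.DataFrame:
    """One row per fitted model with AICc and Akaike weights.

    Rows are emitted in the canonical order DEC, DEC+J, DIVALIKE,
    DIVALIKE+J, BAYAREALIKE, BAYAREALIKE+J (models actually present).
    """
    if not fits:
        raise ValueError("no fits to compare")
    sizes = {f.n_tips for f in fits}
    if n is None:
        if len(sizes) != 1:
            raise ValueError(f"fits disagree on sample size: {sorted(sizes)}")
        n = sizes.pop()
    order = ["DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J", "BAYAREALIKE", "BAYAREALIKE+J"]
    fits = sorted(fits, key=lambda f: order.index(f.name))
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.name,
                "lnL": f.lnL,
                "k": f.k,
                "d": f.params.d,
                "e": f.params.e,
                "j": f.params.j,
                "AICc": aicc(f.lnL, f.k, n),
            }
        )
    df = pd.DataFrame(rows)
    df["weight"] = akaike_weights(df["AICc"].to_numpy())
    return df


def area_inclusion_proportions(
    est: AncestralEstimate,
    nodes: Mapping[str, int],
    space: StateSpace | None = None,
) -> pd.DataFrame:
    """Per-area inclusion proportion of the ancestral estimate at named nodes.

    Cell (node, area) is the summed probability of all states containing
    the area.  A node estimated 70% {Africa}, 25% {Africa+Arabia} and 5%
    {Arabia} therefore has an Africa cell of 0.95.  Rows and columns need
    not sum to one.
    """
    space = space or est.space
    masks = {a.name: ranges_containing(a, space) for a in space.areas}
    rows = {}
    for label, node in nodes.items():
        if node not in est.probs:
            raise KeyError(f"node {node} ({label!r}) has no ancestral estimate")
        p = est.probs[node]
        rows[label] = {name: float(p[m].sum()) for name, m in masks.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[space.area_names]


def most_probable_ranges(est: AncestralEstimate) -> Dict[int, RangeState]:
    """Argmax range per internal node; ties go to the lowest state index."""
    return {
        node: est.space.states[int(np.argmax(p))] for node, p in est.probs.items()
    }


@dataclass
class EventCounts:
    """Dispersal, area-loss and composite-transition tallies over branches."""

    dispersal: pd.DataFrame          # directed area x area weights
    losses: pd.Series                # per-area loss counts
    composite_transitions: pd.DataFrame | None = None


def _branch_states(
    tree: Phylogeny, node_ranges: Mapping[int, RangeState]
) -> List[Tuple[RangeState, RangeState]]:
    pairs = []
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if ch is None:
            continue
        for c in ch:
            parent, child = node_ranges[v], node_ranges[c]
            if parent.is_null or child.is_null:
                raise ValueError("null range in branch state painting")
            pairs.append((parent, child))
    return pairs


def count_events(
    tree: Phylogeny,
    node_ranges: Mapping[int, RangeState],
    space: StateSpace,
) -> EventCounts:
    """Count range changes along branches of a state-painted tree.

    ``node_ranges`` must give a (non-null) range for every node, tips
    included — typically the most-probable ancestral ranges plus the
    observed tip ranges.  Each area present in the child but not the
    parent counts as one dispersal unit, split equally over the parent's
    areas as sources; each area present in the parent but not the child
    counts as one loss for that area.
    """
    names = space.area_names
    n = space.n_areas
    disp = np.zeros((n, n))
    losses = np.zeros(n)
    for parent, child in _branch_states(tree, node_ranges):
        gained = child.bits & ~parent.bits
        lost = parent.bits & ~child.bits
        if gained:
            sources = parent.areas()
            w = 1.0 / len(sources)
            for b in RangeState(gained).areas():
                for a in sources:
                    if a != b:
                        disp[a, b] += w
        for a in RangeState(lost).areas():
            losses[a] += 1
    return EventCounts(
        dispersal=pd.DataFrame(disp, index=names, columns=names),
        losses=pd.Series(losses, index=names, name="losses"),
    )


def count_composite_transitions(
    tree: Phylogeny,
    node_ranges: Mapping[int, RangeState],
    scheme: CompositeScheme,
) -> pd.DataFrame:
    """Count branches whose parent and child carry different composite labels."""
    labels = list(CompositeScheme.LABELS)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for parent, child in _branch_states(tree, node_ranges):
        lp = classify_composite(parent, scheme)
        lc = classify_composite(child, scheme)
        if lp != lc:
            counts.loc[lp, lc] += 1
    return counts
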