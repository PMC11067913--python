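"""Readers and writers for trees, geography files and constraint tables.

The geography format is the Lagrange/PHYLIP-style layout used across
historical-biogeography tools: a header line ``n_taxa n_areas (name1
name2 ...)`` followed by one ``taxon presence-string`` row per species,
where the presence string is a 0/1 character per area in header order.
Both space- and tab-separated input are accepted; the writer emits
tab-separated with area names.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

from .inference import NodeConstraint
from .range_space import RangeState
from .trees import Phylogeny

__all__ = [
    "read_tree",
    "write_tree",
    "read_geography",
    "write_geography",
    "read_constraints",
    "write_constraints",
]

PathLike = Union[str, Path]


def read_tree(path: PathLike) -> Phylogeny:
    """Parse a rooted, binary, dated Newick tree.

    Polytomies, duplicate tip labels and missing branch lengths are
    rejected with specific errors.
    """
    return Phylogeny.from_newick(Path(path).read_text())


def write_tree(path: PathLike, tree: Phylogeny) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


_HEADER_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s*(?:\(([^)]*)\))?\s*$")


def read_geography(path: PathLike) -> Tuple[List[str], Dict[str, RangeState]]:
    """Read a geography file; returns (area names, taxon -> range).

    Area bit order equals header column order.  Rows of all zeros (null
    tip ranges) are rejected.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty geography file")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise ValueError(f"{path}: malformed header {lines[0]!r}")
    n_taxa, n_areas = int(m.group(1)), int(m.group(2))
    if m.group(3):
        names = m.group(3).split()
        if len(names) != n_areas:
            raise ValueError(
                f"{path}: header names {len(names)} != n_areas {n_areas}"
            )
    else:
        names = [f"A{i}" for i in range(n_areas)]
    rows = lines[1:]
    if len(rows) != n_taxa:
        raise ValueError(f"{path}: header says {n_taxa} taxa, found {len(rows)} rows")
    table: Dict[str, RangeState] = {}
    for row in rows:
        parts = row.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed row {row!r}")
        taxon, presence = parts
        if taxon in table:
            raise ValueError(f"{path}: duplicate taxon {taxon!r}")
        if len(presence) != n_areas or set(presence) - {"0", "1"}:
            raise ValueError(
                f"{path}: presence string for {taxon!r} must be {n_areas} "
                f"characters of 0/1, got {presence!r}"
            )
        bits = sum(1 << i for i, c in enumerate(presence) if c == "1")
        if bits == 0:
            raise ValueError(f"{path}: taxon {taxon!r} has a null (all-zero) range")
        table[taxon] = RangeState(bits)
    return names, table


def write_geography(
    path: PathLike, area_names: Sequence[str], table: Mapping[str, RangeState]
) -> None:
    n_areas = len(area_names)
    with open(path, "w") as fh:
        fh.write(f"{len(table)}\t{n_areas}\t({' '.join(area_names)})\n")
        for taxon in table:
            rng = table[taxon]
            presence = "".join(
                "1" if rng.contains_area(i) else "0" for i in range(n_areas)
            )
            fh.write(f"{taxon}\t{presence}\n")


def read_constraints(
    path: PathLike,
    tree: Phylogeny,
    area_names: Sequence[str] | None = None,
) -> List[NodeConstraint]:
    """Read a node-constraint TSV: name, mrca_taxa (comma-sep), required_areas.

    Each constraint is resolved against the tree immediately so unknown
    tips fail at load time; if *area_names* is given, unknown areas fail
    too.
    """
    constraints: List[NodeConstraint] = []
    seen = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"constraint rows need 3 tab-separated fields: {raw!r}")
        name, taxa_s, areas_s = parts
        if name in seen:
            raise ValueError(f"duplicate constraint name {name!r}")
        seen.add(name)
        taxa = tuple(t.strip() for t in taxa_s.split(",") if t.strip())
        areas = tuple(a.strip() for a in areas_s.split(",") if a.strip())
        c = NodeConstraint(name, taxa, areas)
        tree.mrca(taxa)  # raises KeyError naming unknown tips
        if area_names is not None:
            unknown = [a for a in areas if a not in area_names]
            if unknown:
                raise ValueError(f"constraint {name!r}: unknown areas {unknown}")
        constraints.append(c)
    return constraints


def write_constraints(path: PathLike, constraints: Sequence[NodeConstraint]) -> None:
    with open(path, "w") as fh:
        for c in constraints:
            fh.write(f"{c.name}\t{','.join(c.mrca_taxa)}\t{','.join(c.required_areas)}\n")
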