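"""Residue interaction network (RIN) construction.

A RIN is an undirected :class:`networkx.Graph` whose nodes are residues and
whose edges connect residue pairs with a minimal inter-atom distance inside a
window (default 2.5-5.0 Å, inclusive on both ends).  Pairs closer than the
lower bound are excluded — they are presumed covalent or clashing, exactly as
the distance rule reads.  Covalently adjacent residues that satisfy the rule
are included without special-casing.

Node keys are ``(chain_id, number, icode)`` tuples; node attributes carry the
residue name, gene and compartment so downstream stages (interface typing,
centrality tables) never have to touch coordinates again.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import Residue, Structure

__all__ = [
    "DistanceWindow",
    "build_rin",
    "interface_edges",
    "export_edge_list",
    "read_edge_list",
    "export_graphml",
]


@dataclass(frozen=True)
class DistanceWindow:
    d_min: float = 2.5
    d_max: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError(f"require 0 < d_min < d_max, got [{self.d_min}, {self.d_max}]")

    def contains(self, d: float) -> bool:
        return self.d_min <= d <= self.d_max


def build_rin(s: Structure, window: DistanceWindow | None = None) -> nx.Graph:
    """Build the residue interaction network of a structure.

    Uses a KD-tree over all atoms so full-complex builds stay near-linear;
    the result is identical to a brute-force scan over every atom pair (the
    true minimal distance of a pair within the window is always realised by
    an atom pair at most ``d_max`` apart).
    """
    window = window or DistanceWindow()
    g = nx.Graph(window=(window.d_min, window.d_max))

    residues: list[Residue] = []
    for chain in s.chains:
        for res in chain.residues:
            residues.append(res)
            g.add_node(
                res.key,
                aa3=res.aa3,
                protein=chain.protein,
                compartment=chain.compartment,
            )
    if len(residues) < 2:
        return g

    coords = np.concatenate([r.coords() for r in residues])
    owner = np.concatenate(
        [np.full(len(r.atoms), i, dtype=np.int64) for i, r in enumerate(residues)]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(window.d_max, output_type="ndarray")
    if len(pairs) == 0:
        return g

    ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
    mask = ri != rj
    if not mask.any():
        return g
    d = np.linalg.norm(coords[pairs[mask, 0]] - coords[pairs[mask, 1]], axis=1)
    lo = np.minimum(ri[mask], rj[mask])
    hi = np.maximum(ri[mask], rj[mask])

    min_d: dict[tuple[int, int], float] = {}
    for a, b, dist in zip(lo, hi, d):
        key = (int(a), int(b))
        if dist < min_d.get(key, np.inf):
            min_d[key] = float(dist)

    for (a, b), dist in min_d.items():
        if window.contains(dist):
            g.add_edge(residues[a].key, residues[b].key, min_distance=dist)
    return g


def interface_edges(g: nx.Graph, protein_a: str, protein_b: str) -> list[tuple]:
    """Edges with one endpoint on each of two named proteins.

    Returns ``[(node_a, node_b, min_distance), ...]`` with the endpoint on
    ``protein_a`` first; symmetric in its arguments up to that ordering.
    """
    present = {d.get("protein") for _, d in g.nodes(data=True)}
    for p in (protein_a, protein_b):
        if p not in present:
            raise KeyError(f"protein {p!r} not in graph; present: {sorted(x for x in present if x)}")
    out = []
    for u, v, d in g.edges(data=True):
        pu, pv = g.nodes[u].get("protein"), g.nodes[v].get("protein")
        if {pu, pv} == {protein_a, protein_b} and pu != pv:
            if pu == protein_a:
                out.append((u, v, d["min_distance"]))
            else:
                out.append((v, u, d["min_distance"]))
    out.sort(key=lambda e: (e[0], e[1]))
    return out


def _node_str(node: tuple, g: nx.Graph) -> str:
    chain, number, icode = node
    return f"{chain}:{g.nodes[node]['aa3']}{number}{icode}"


def export_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write one row per edge (two residues and their minimal distance)."""
    rows = []
    for u, v, d in g.edges(data=True):
        a, b = sorted([u, v])
        rows.append((a, b, d["min_distance"]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\tmin_distance\n")
        for a, b, dist in rows:
            fh.write(f"{_node_str(a, g)}\t{_node_str(b, g)}\t{dist:.3f}\n")


def read_edge_list(path: str | Path) -> set[tuple[str, str, float]]:
    """Read back an exported edge list as a set of (a, b, distance) rows."""
    out = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("residue_a"):
            raise ValueError(f"{path}: not an edge-list file")
        for line in fh:
            a, b, d = line.rstrip("\n").split("\t")
            out.add((a, b, float(d)))
    return out


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export for graph-viewer interoperability."""
    h = nx.Graph()
    for n, data in g.nodes(data=True):
        h.add_node("|".join(str(x) for x in n), **{k: v for k, v in data.items() if v is not None})
    for u, v, data in g.edges(data=True):
        h.add_edge("|".join(str(x) for x in u), "|".join(str(x) for x in v), **data)
    nx.write_graphml(h, str(path))
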