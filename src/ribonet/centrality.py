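"""Node centrality measures on residue interaction networks.

Four measures are computed — betweenness (BCA), closeness (CCA), degree
(DCA) and eigenvector (ECA) — each standardised into a per-network Z-score
(population standard deviation over the network's nodes).  Residues with
Z >= 2 are flagged central.  Graphs are treated as unweighted for the
path-based measures: edge minimal distances are annotations, not weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Hashable

import networkx as nx
import numpy as np

__all__ = [
    "CentralityVector",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "compute_all",
    "zscore",
    "central_residues",
    "MEASURES",
]


@dataclass
class CentralityVector:
    measure: str
    values: dict[Hashable, float]
    zscores: dict[Hashable, float] | None = None
    params: dict = field(default_factory=dict)


def _require_nonempty(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("centrality of an empty graph is undefined")


def degree_centrality(g: nx.Graph) -> CentralityVector:
    """DCA: raw value = neighbour count."""
    _require_nonempty(g)
    return CentralityVector("DCA", {n: float(d) for n, d in g.degree()})


def closeness_centrality(g: nx.Graph, mode: str = "corrected") -> CentralityVector:
    """CCA: reciprocal of the summed shortest-path lengths from a node.

    Disconnected graphs: paths are computed within the node's component.
    ``mode='corrected'`` (default) applies the Wasserman-Faust factor
    (r-1)/(n-1), with r the component size, so values are comparable across
    components; ``mode='component'`` leaves the raw reciprocal.  Singleton
    components get 0.
    """
    _require_nonempty(g)
    if mode not in ("component", "corrected"):
        raise ValueError(f"unknown closeness mode {mode!r}")
    n = g.number_of_nodes()
    values: dict[Hashable, float] = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        total = sum(lengths.values())
        r = len(lengths)
        if total == 0:  # singleton component
            values[node] = 0.0
            continue
        c = 1.0 / total
        if mode == "corrected" and n > 1:
            c *= (r - 1) / (n - 1)
        values[node] = c
    return CentralityVector("CCA", values, params={"mode": mode})


def betweenness_centrality(g: nx.Graph) -> CentralityVector:
    """BCA: node betweenness over unweighted shortest paths.

    Pair-normalised (divided by (n-1)(n-2)/2), endpoints excluded; Z-scores
    are invariant to this normalisation choice.
    """
    _require_nonempty(g)
    raw = nx.betweenness_centrality(g, normalized=True, endpoints=False)
    return CentralityVector("BCA", {n: float(v) for n, v in raw.items()})


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityVector:
    """ECA: principal eigenvector of the adjacency matrix.

    Computed by power iteration on the largest connected component,
    non-negative and L2-normalised; nodes outside that component get 0.
    """
    _require_nonempty(g)
    values = {n: 0.0 for n in g.nodes}
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    largest = components[0]
    if len(largest) == 1:
        values[next(iter(largest))] = 1.0
        return CentralityVector("ECA", values)
    sub = g.subgraph(largest)
    try:
        # networkx converges on sum|x - x_last| < N*tol; request per-node tol
        ec = nx.eigenvector_centrality(sub, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"eigenvector centrality did not converge within {max_iter} iterations"
        ) from exc
    norm = math.sqrt(sum(v * v for v in ec.values()))
    for n, v in ec.items():
        values[n] = float(abs(v) / norm)
    return CentralityVector("ECA", values)


MEASURES = {
    "BCA": betweenness_centrality,
    "CCA": closeness_centrality,
    "DCA": degree_centrality,
    "ECA": eigenvector_centrality,
}


def compute_all(g: nx.Graph, measures: tuple[str, ...] = ("BCA", "CCA", "DCA", "ECA")) -> dict[str, CentralityVector]:
    """All requested measures, Z-scored."""
    return {m: zscore(MEASURES[m](g)) for m in measures}


def zscore(v: CentralityVector) -> CentralityVector:
    """Standardise raw values over the network: Z = (c - mean) / sd.

    Population standard deviation; if sd == 0 every Z is 0.
    """
    vals = np.array(list(v.values.values()), dtype=float)
    mean = vals.mean()
    sd = vals.std()  # population sd
    if sd == 0:
        z = {n: 0.0 for n in v.values}
    else:
        z = {n: float((c - mean) / sd) for n, c in v.values.items()}
    return replace(v, zscores=z)


def central_residues(v: CentralityVector, threshold: float = 2.0) -> set:
    """Nodes whose Z-score meets the centrality flag (Z >= threshold)."""
    if v.zscores is None:
        raise ValueError("Z-scores not computed; call zscore() first")
    return {n for n, z in v.zscores.items() if z >= threshold}
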