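import numpy as np
import pytest

from ribonet.structure import Atom, Chain, Residue, Structure
from ribonet.synthetic import ToyDimerSpec, make_toy_dimer

CHAIN_MAP = {
    "rps11": {"chain": "A", "compartment": "plastid", "offset": 0, "suffix": "k"},
    "rps21": {"chain": "B", "compartment": "nuclear", "offset": 0, "suffix": "u"},
}


@pytest.fixture
def chain_map():
    return {k: dict(v) for k, v in CHAIN_MAP.items()}


@pytest.fixture
def toy_dimer():
    """Small two-chain structure with three in-window planted contacts."""
    spec = ToyDimerSpec(
        n_residues_per_chain=5,
        contact_plan=((1, 1, 3.47), (2, 3, 3.12), (4, 4, 4.50)),
        seed=11,
    )
    return make_toy_dimer(spec)


def make_residue(aa3, atoms, chain_id="A", number=1, icode=""):
    """Residue from (name, element, xyz) triples — for constructed geometries."""
    return Residue(
        chain_id=chain_id,
        number=number,
        icode=icode,
        aa3=aa3,
        atoms=[Atom(name=n, element=e, position=np.asarray(p, float)) for n, e, p in atoms],
    )


def single_residue_structure(res, structure_id="test"):
    chain = Chain(chain_id=res.chain_id, residues=[res])
    return Structure(id=structure_id, chains=[chain])


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation's code paths)
# ---------------------------------------------------------------------------

def brute_force_rin_edges(structure, d_min=2.5, d_max=5.0):
    """O(n² m²) all-atom-pair scan; the reference for build_rin."""
    residues = list(structure.residues())
    edges = {}
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            best = np.inf
            for a in residues[i].atoms:
                for b in residues[j].atoms:
                    d = float(np.linalg.norm(a.position - b.position))
                    best = min(best, d)
            if d_min <= best <= d_max:
                key = tuple(sorted([residues[i].key, residues[j].key]))
                edges[key] = best
    return edges


def graph_matrices(g):
    nodes = sorted(g.nodes, key=repr)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in g.edges:
        A[index[u], index[v]] = A[index[v], index[u]] = 1
    return nodes, A


def floyd_warshall(A):
    n = len(A)
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    return D


def shortest_path_counts(A, D):
    """N[s, t] = number of shortest s-t paths, by dynamic programming."""
    n = len(A)
    N = np.zeros((n, n))
    np.fill_diagonal(N, 1.0)
    order = np.argsort(D, axis=1)
    for s in range(n):
        for t in order[s]:
            if t == s or not np.isfinite(D[s, t]):
                continue
            total = 0.0
            for u in range(n):
                if A[u, t] and D[s, u] + 1 == D[s, t]:
                    total += N[s, u]
            N[s, t] = total
    return N


def betweenness_oracle(g):
    nodes, A = graph_matrices(g)
    n = len(nodes)
    D = floyd_warshall(A)
    N = shortest_path_counts(A, D)
    raw = {node: 0.0 for node in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]) or N[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if D[s, v] + D[v, t] == D[s, t]:
                    raw[nodes[v]] += N[s, v] * N[v, t] / N[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        for node in raw:
            raw[node] /= norm
    return raw


def closeness_oracle(g, corrected=True):
    nodes, A = graph_matrices(g)
    D = floyd_warshall(A)
    n = len(nodes)
    out = {}
    for i, node in enumerate(nodes):
        reach = np.isfinite(D[i])
        total = D[i][reach].sum()
        r = int(reach.sum())
        if total == 0:
            out[node] = 0.0
            continue
        c = 1.0 / total
        if corrected and n > 1:
            c *= (r - 1) / (n - 1)
        out[node] = c
    return out


def eigenvector_oracle(g):
    nodes, A = graph_matrices(g)
    D = floyd_warshall(A)
    comps = []
    seen = set()
    for i in range(len(nodes)):
        if i in seen:
            continue
        comp = {j for j in range(len(nodes)) if np.isfinite(D[i, j])}
        seen |= comp
        comps.append(sorted(comp))
    largest = max(comps, key=len)
    out = {node: 0.0 for node in nodes}
    if len(largest) == 1:
        out[nodes[largest[0]]] = 1.0
        return out
    sub = A[np.ix_(largest, largest)]
    w, V = np.linalg.eigh(sub)
    v = np.abs(V[:, np.argmax(w)])
    v = v / np.linalg.norm(v)
    for idx, val in zip(largest, v):
        out[nodes[idx]] = float(val)
    return out
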