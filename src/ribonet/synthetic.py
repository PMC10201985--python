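"""Synthetic inputs for every pipeline stage, plus packaged table fixtures.

Everything here is generated programmatically and deterministically from a
seed, so the whole analysis can be exercised without downloading any real
structure or sequence data:

* toy two-chain structures with exactly controlled inter-chain minimal
  distances (and the resulting ground-truth interaction-network edge set);
* per-lineage protein alignments with planted fixed differences;
* closed-form graph families for centrality oracles;
* machine-readable fixtures of the published 28 interface interaction
  records and the published 16 x 17 centrality Z-score tables, shipped as
  TSV data files.

Toy residues use an idealized compact backbone; only minimal distances
matter, chemical realism is not a goal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import InteractionRecord
from .pca import CentralityTable
from .structure import Atom, Chain, Residue, Structure
from .variants import LineageAlignment

__all__ = [
    "ToyDimerSpec",
    "PlantedAlignmentSpec",
    "GenerationError",
    "make_toy_dimer",
    "make_lineage_alignment",
    "write_alignment_fasta",
    "table1_fixture",
    "table3_fixture",
    "make_graph_fixture",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(ValueError):
    """Raised when a generator spec cannot be realised."""


# ---------------------------------------------------------------------------
# toy dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDimerSpec:
    """Two-chain toy structure with planted inter-chain contacts.

    ``contact_plan`` lists ``(residue_a, residue_b, target_min_distance)``
    with 1-based residue numbers on chains A and B.  Every planned pair's
    minimal inter-atom distance equals its target exactly; all unplanned
    inter-chain residue pairs stay at least 6 Å apart.
    """

    n_residues_per_chain: int = 6
    contact_plan: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0
    proteins: tuple[str, str] = ("rps11", "rps21")

    def __post_init__(self) -> None:
        n = self.n_residues_per_chain
        if n < 1:
            raise GenerationError("need at least one residue per chain")
        seen: dict[tuple[int, int], float] = {}
        for i, j, d in self.contact_plan:
            if not (1 <= i <= n and 1 <= j <= n):
                raise GenerationError(f"contact ({i},{j}) outside 1..{n}")
            if d <= 0:
                raise GenerationError(f"contact ({i},{j}): target distance {d} must be > 0")
            if (i, j) in seen:
                raise GenerationError(f"conflicting targets for pair ({i},{j})")
            seen[(i, j)] = d


_BACKBONE_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.00, 1.10, 0.0]),
    "O": np.array([2.20, 1.05, 0.0]),
}
_SPACING = 10.0  # Å between residue centres along a chain
_CHAIN_GAP = 20.0  # Å between the two chains


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[Structure, list[tuple]]:
    """Build the toy dimer and its ground-truth edge list.

    Returns ``(structure, edges)`` where ``edges`` holds
    ``(key_a, key_b, distance)`` for every planted pair whose target lies in
    the default interaction window [2.5, 5.0].
    """
    rng = np.random.default_rng(spec.seed)
    structure = Structure(id=f"toy-dimer-{spec.seed}")
    for chain_id, protein, compartment, y0 in (
        ("A", spec.proteins[0], "plastid", 0.0),
        ("B", spec.proteins[1], "nuclear", _CHAIN_GAP),
    ):
        chain = Chain(chain_id=chain_id, protein=protein, compartment=compartment)
        for num in range(1, spec.n_residues_per_chain + 1):
            centre = np.array([_SPACING * num, y0, 0.0])
            jitter = rng.uniform(-0.15, 0.15, size=3)
            atoms = [
                Atom(name=name, element=name[0], position=centre + off + jitter)
                for name, off in _BACKBONE_OFFSETS.items()
            ]
            chain.residues.append(
                Residue(chain_id=chain_id, number=num, icode="", aa3="GLY", atoms=atoms)
            )
        structure.chains.append(chain)

    edges = []
    mid = _CHAIN_GAP / 2.0
    for k, (i, j, d) in enumerate(spec.contact_plan):
        z = 8.0 * (k + 1)
        x = _SPACING * i
        pa = np.array([x, mid - d / 2.0, z])
        pb = np.array([x, mid + d / 2.0, z])
        structure.chain("A").get(i).atoms.append(
            Atom(name=f"X{k + 1}", element="C", position=pa)
        )
        structure.chain("B").get(j).atoms.append(
            Atom(name=f"Y{k + 1}", element="C", position=pb)
        )
        if 2.5 <= d <= 5.0:
            edges.append((("A", i, ""), ("B", j, ""), float(d)))
    return structure, edges


# ---------------------------------------------------------------------------
# planted alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAlignmentSpec:
    """Per-lineage alignment with planted fixed amino-acid differences.

    ``planted`` lists ``(position, {lineage: amino_acid})`` with 1-based
    positions; each planted position is monomorphic within every lineage.
    ``n_polymorphic``/``n_gap_columns`` add columns that the detector must
    reject (within-lineage polymorphism, gaps).
    """

    gene: str = "rps21"
    lineages: tuple[str, ...] = ("E1", "W1", "W2", "W3")
    n_seq_per_lineage: int = 4
    length: int = 60
    planted: tuple[tuple[int, dict], ...] = ()
    n_polymorphic: int = 0
    n_gap_columns: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.planted]
        if len(positions) != len(set(positions)):
            raise GenerationError("duplicate planted positions")
        for pos, mapping in self.planted:
            if not 1 <= pos <= self.length:
                raise GenerationError(f"planted position {pos} outside 1..{self.length}")
            missing = set(self.lineages) - set(mapping)
            if missing:
                raise GenerationError(f"planted position {pos}: lineages {sorted(missing)} missing")
        needed = len(self.planted) + self.n_polymorphic + self.n_gap_columns
        if needed > self.length:
            raise GenerationError("more special columns than alignment length")


def make_lineage_alignment(
    spec: PlantedAlignmentSpec,
) -> tuple[LineageAlignment, dict[int, dict[str, str]]]:
    """Generate the alignment and the truth table of fixed differences.

    The reference sequence is ungapped, so alignment position equals
    reference residue number.  The truth table maps position -> per-lineage
    amino acid, for exactly the planted positions that actually differ
    between lineages.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.choice(list(AA20), size=spec.length)
    planted_pos = {p for p, _ in spec.planted}
    free = [i for i in range(1, spec.length + 1) if i not in planted_pos]
    rng.shuffle(free)
    poly_pos = free[: spec.n_polymorphic]
    gap_pos = free[spec.n_polymorphic: spec.n_polymorphic + spec.n_gap_columns]

    seqs = {
        lin: [list(base) for _ in range(spec.n_seq_per_lineage)]
        for lin in spec.lineages
    }
    for pos, mapping in spec.planted:
        for lin in spec.lineages:
            for s in seqs[lin]:
                s[pos - 1] = mapping[lin]
    for pos in poly_pos:
        lin = spec.lineages[int(rng.integers(len(spec.lineages)))]
        k = int(rng.integers(spec.n_seq_per_lineage))
        current = seqs[lin][k][pos - 1]
        alternatives = [a for a in AA20 if a != current]
        seqs[lin][k][pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
    for pos in gap_pos:
        lin = spec.lineages[int(rng.integers(len(spec.lineages)))]
        k = int(rng.integers(spec.n_seq_per_lineage))
        seqs[lin][k][pos - 1] = "-"

    aln = LineageAlignment(
        gene=spec.gene,
        sequences={lin: ["".join(s) for s in group] for lin, group in seqs.items()},
        reference="".join(base),
    )
    truth = {
        pos: dict(mapping)
        for pos, mapping in spec.planted
        if len(set(mapping.values())) > 1
    }
    return aln, truth


def write_alignment_fasta(aln: LineageAlignment, path: str | Path) -> None:
    """Write the alignment with lineage-tagged ids and the reference."""
    with open(path, "w") as fh:
        if aln.reference is not None:
            fh.write(f">reference|Spinacia\n{aln.reference}\n")
        for lineage, seqs in aln.sequences.items():
            for k, seq in enumerate(seqs, start=1):
                fh.write(f">{lineage}|s{k}\n{seq}\n")


# ---------------------------------------------------------------------------
# packaged table fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ribonet.data").joinpath(name)


def table1_fixture() -> list[InteractionRecord]:
    """The 28 published interface interaction records, machine-readable.

    Each record carries the interacting plastid and nuclear residues, the
    per-lineage amino acids (``-`` means identical to the spinach
    reference), the interface distance and the interaction type before and
    after mutation.  Dual-lineage outcomes (e.g. "hydrophobic/none") keep
    the raw call in ``after_raw`` while ``after`` holds the effective state
    used for change categorisation.
    """
    records = []
    with _data_path("table1.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                InteractionRecord(
                    plastid_gene=row["plastid_gene"],
                    plastid_residue=row["plastid_residue"],
                    nuclear_gene=row["nuclear_gene"],
                    nuclear_residue=row["nuclear_residue"],
                    distance=float(row["distance"]),
                    before=row["before"],
                    after=row["after"],
                    plastid_aa={l: row[f"plastid_{l}"] for l in ("E1", "W1", "W2", "W3")},
                    nuclear_aa={l: row[f"nuclear_{l}"] for l in ("E1", "W1", "W2", "W3")},
                    after_raw=row["after_raw"],
                )
            )
    return records


def table3_fixture(measure: str) -> CentralityTable:
    """The published 16-combination x 17-residue centrality Z-score matrix.

    ``measure`` is ``"BCA"`` (betweenness) or ``"CCA"`` (closeness).
    Residue columns are labelled ``<number>.k`` (plastid rps11) and
    ``<number>.u`` (nuclear rps21); rows are the plastid_nuclear
    combination labels E1_E1 ... W3_W3.
    """
    measure = measure.upper()
    if measure not in ("BCA", "CCA"):
        raise ValueError(f"no fixture for measure {measure!r} (BCA or CCA)")
    with _data_path(f"table3_{measure.lower()}.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return CentralityTable(measure=measure, data=df)


# ---------------------------------------------------------------------------
# graph fixtures
# ---------------------------------------------------------------------------

def make_graph_fixture(kind: str, n: int = 5) -> nx.Graph:
    """Closed-form graph families used as centrality oracles.

    ``kind``: ``path``, ``star``, ``complete`` (on ``n`` nodes) or
    ``two_cliques_bridge`` (two ``n``-cliques joined through one bridge
    node, which then carries the maximal betweenness).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "two_cliques_bridge":
        g = nx.Graph()
        left = [f"L{i}" for i in range(n)]
        right = [f"R{i}" for i in range(n)]
        for group in (left, right):
            g.add_edges_from(
                (a, b) for idx, a in enumerate(group) for b in group[idx + 1:]
            )
        g.add_edge(left[0], "bridge")
        g.add_edge("bridge", right[0])
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    mapping = {node: ("X", i + 1, "") for i, node in enumerate(sorted(g.nodes, key=str))}
    g = nx.relabel_nodes(g, mapping)
    nx.set_node_attributes(g, "GLY", "aa3")
    return g
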