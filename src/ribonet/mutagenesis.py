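"""In-silico point mutagenesis and cytonuclear combination models.

A substitution keeps the backbone (N, CA, C, O) of the target residue
bit-identical and rebuilds the side chain from an idealized-geometry
template (the chemical component dictionary entry bundled with biotite),
superposed onto the residue's own N/CA/C frame.  Chi angles come from a
small built-in backbone-independent rotamer library; the candidate with the
fewest hard clashes (heavy-atom pairs under 2.5 Å against the rest of the
structure, the residue's own backbone excluded) wins, ties broken by the
library prior and then by chi-angle order.  An optional deterministic
grid relaxation (15° coordinate descent over the chi angles) relieves
residual clashes.  No force-field minimization is performed: rotamer choice
plus clash relief is this package's documented stand-in for energy
minimization of mutant models.

Combination models pair one lineage's plastid-encoded substitutions
(maternal side) with another lineage's nuclear-encoded substitutions
(paternal side); L lineages yield L² models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure.info as _struc_info

from .structure import (
    AA1_TO_3,
    STANDARD_AA3,
    Atom,
    ChainMapError,
    Residue,
    Structure,
)
from .variants import SubstitutionSet

__all__ = [
    "CombinationId",
    "CombinationModel",
    "enumerate_combinations",
    "substitute_residue",
    "choose_rotamer",
    "relax_side_chain",
    "build_combination_model",
    "clash_score",
    "CLASH_CUTOFF",
]

BACKBONE = ("N", "CA", "C", "O", "OXT")

#: Heavy-atom distance under which a non-bonded pair counts as a clash (Å).
CLASH_CUTOFF = 2.5

#: Chi dihedral definitions (atom name quadruples), per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],  # ring closure to N; chis are kept at template values
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

_CHI1 = [(-60.0, 0.52), (180.0, 0.33), (60.0, 0.15)]
_SP3 = [(-60.0, 0.40), (180.0, 0.40), (60.0, 0.20)]
_AROM = [(90.0, 0.5), (-90.0, 0.5)]
_CARBOX = [(-30.0, 0.40), (30.0, 0.30), (90.0, 0.30)]

#: Candidate values (angle, prior) per chi position, per residue type.
_CHI_CANDIDATES: dict[str, list[list[tuple[float, float]]]] = {
    "ARG": [_CHI1, _SP3, _SP3, [(180.0, 0.5), (-90.0, 0.25), (90.0, 0.25)]],
    "ASN": [_CHI1, _CARBOX],
    "ASP": [_CHI1, _CARBOX],
    "CYS": [_CHI1],
    "GLN": [_CHI1, _SP3, _CARBOX],
    "GLU": [_CHI1, _SP3, _CARBOX],
    "HIS": [_CHI1, _AROM],
    "ILE": [_CHI1, _SP3],
    "LEU": [_CHI1, _SP3],
    "LYS": [_CHI1, _SP3, _SP3, _SP3],
    "MET": [_CHI1, _SP3, _SP3],
    "PHE": [_CHI1, _AROM],
    "PRO": [],
    "SER": [_CHI1],
    "THR": [_CHI1],
    "TRP": [_CHI1, _AROM],
    "TYR": [_CHI1, _AROM],
    "VAL": [_CHI1],
    "ALA": [],
    "GLY": [],
}


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R @ mobile_centered + t ≈ target."""
    mc, tc = mobile.mean(0), target.mean(0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, tc - R @ mc


@dataclass(frozen=True)
class _Template:
    names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    adjacency: dict[str, frozenset[str]]


@lru_cache(maxsize=None)
def _template(aa3: str) -> _Template:
    arr = _struc_info.residue(aa3)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[keep]
    names = tuple(arr.atom_name.tolist())
    index = {n: i for i, n in enumerate(names)}
    adj: dict[str, set[str]] = {n: set() for n in names}
    bonds, _ = arr.bonds.get_all_bonds()
    for i, partners in enumerate(bonds):
        for j in partners:
            if j >= 0:
                adj[names[i]].add(names[j])
    return _Template(
        names=names,
        elements=tuple(arr.element.tolist()),
        coords=np.asarray(arr.coord, dtype=float),
        adjacency={k: frozenset(v) for k, v in adj.items()},
    )


def canonical_sidechain_atoms(aa3: str) -> tuple[str, ...]:
    """Heavy side-chain atom names of a standard residue (CB outward)."""
    t = _template(aa3)
    return tuple(n for n in t.names if n not in BACKBONE)


def _distal_atoms(adj: Mapping[str, frozenset], start: str, blocked: str) -> set[str]:
    # atoms reachable from `start` without passing through `blocked`
    seen = {start}
    stack = [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb != blocked and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _build_sidechain(
    aa3: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray, chis: tuple[float, ...]
) -> list[tuple[str, str, np.ndarray]]:
    """Side-chain atoms (name, element, position) at the requested chi angles."""
    t = _template(aa3)
    template = {name: t.coords[i] for i, name in enumerate(t.names)}
    # superpose the template backbone frame onto the (possibly non-ideal)
    # target backbone, then set chis in world coordinates so the dihedrals
    # measured against the real backbone atoms equal the requested values
    mobile = np.array([template["N"], template["CA"], template["C"]])
    R, trans = _kabsch(mobile, np.array([n, ca, c]))
    coords = {"N": n, "CA": ca, "C": c}
    for name in t.names:
        if name not in BACKBONE:
            coords[name] = R @ template[name] + trans
    for quad, target in zip(CHI_ATOMS[aa3], chis):
        a1, a2, a3, a4 = quad
        current = _dihedral(coords[a1], coords[a2], coords[a3], coords[a4])
        rot = _rotation(coords[a3] - coords[a2], target - current)
        pivot = coords[a3]
        for name in _distal_atoms(t.adjacency, a3, blocked=a2) - {a3}:
            if name in coords and name not in ("N", "CA", "C"):
                coords[name] = rot @ (coords[name] - pivot) + pivot
    elements = dict(zip(t.names, t.elements))
    return [
        (name, elements[name], coords[name])
        for name in t.names
        if name not in BACKBONE
    ]


# ---------------------------------------------------------------------------
# clash scoring and rotamer choice
# ---------------------------------------------------------------------------

def _environment_tree(s: Structure, exclude_key) -> cKDTree | None:
    pts = []
    for res in s.residues():
        if res.key == exclude_key:
            continue  # excludes the target's backbone and old side chain
        pts.append(res.coords())
    if not pts:
        return None
    return cKDTree(np.concatenate(pts))


def clash_score(sidechain: np.ndarray, env: cKDTree | None, cutoff: float = CLASH_CUTOFF) -> int:
    """Number of heavy-atom pairs closer than ``cutoff`` between a candidate
    side chain and the rest of the structure."""
    if env is None or len(sidechain) == 0:
        return 0
    return int(sum(len(hits) for hits in env.query_ball_point(sidechain, cutoff)))


def rotamer_candidates(aa3: str) -> list[tuple[tuple[float, ...], float]]:
    """Coarse backbone-independent rotamers: (chi angles, prior)."""
    per_chi = _CHI_CANDIDATES[aa3]
    if not per_chi:
        if CHI_ATOMS[aa3]:
            raise AssertionError(aa3)
        return [((), 1.0)] if aa3 != "PRO" else [(tuple(), 1.0)]
    out = []
    for combo in itertools.product(*per_chi):
        chis = tuple(a for a, _ in combo)
        prior = float(np.prod([p for _, p in combo]))
        out.append((chis, prior))
    return out


def choose_rotamer(
    s: Structure,
    chain_id: str,
    number: int,
    aa3: str,
    icode: str = "",
    candidates: list[tuple[tuple[float, ...], float]] | None = None,
) -> tuple[tuple[float, ...], int]:
    """Pick the chi angles minimising the clash score for a rebuilt side chain.

    Ties go to the higher library prior, then to the lowest chi tuple.
    Returns ``(chis, clash_count)``; a candidate is always returned.
    """
    res = s.get_residue(chain_id, number, icode)
    n, ca, c = (res.atom(x).position for x in ("N", "CA", "C"))
    env = _environment_tree(s, res.key)
    cands = candidates if candidates is not None else rotamer_candidates(aa3)
    if not cands:
        raise ValueError("empty rotamer candidate set")
    best = None
    for chis, prior in cands:
        atoms = _build_sidechain(aa3, n, ca, c, chis)
        coords = np.array([p for _, _, p in atoms]) if atoms else np.empty((0, 3))
        score = clash_score(coords, env)
        key = (score, -prior, chis)
        if best is None or key < best[0]:
            best = (key, chis, score)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# substitution
# ---------------------------------------------------------------------------

def substitute_residue(
    s: Structure,
    chain_id: str,
    number: int,
    new_aa: str,
    icode: str = "",
    relax: bool = False,
) -> Structure:
    """Return a copy of ``s`` with one residue substituted.

    ``new_aa`` is a one-letter (or three-letter) amino-acid code.  Backbone
    atoms are untouched; the side chain is rebuilt from the idealized
    template at the rotamer chosen by :func:`choose_rotamer` (Gly removes
    the side chain entirely).  ``relax=True`` additionally runs the 15°
    chi-grid clash relief.
    """
    new_aa3 = AA1_TO_3.get(new_aa.upper(), new_aa.upper())
    if new_aa3 not in STANDARD_AA3:
        raise ValueError(f"unsupported target residue {new_aa!r}")
    out = s.copy()
    res = out.get_residue(chain_id, number, icode)  # raises on absent residue
    if res.aa3 not in STANDARD_AA3:
        raise ValueError(
            f"cannot substitute non-standard residue {res.aa3} at {chain_id}:{number}{icode}"
        )
    backbone = [a for a in res.atoms if a.name in BACKBONE]
    if not all(res.has_atom(x) for x in ("N", "CA", "C")):
        raise ValueError(f"residue {chain_id}:{number}{icode} lacks a complete N/CA/C frame")
    res.aa3 = new_aa3
    res.atoms = backbone
    if new_aa3 != "GLY":
        chis, _ = choose_rotamer(out, chain_id, number, new_aa3, icode)
        n, ca, c = (res.atom(x).position for x in ("N", "CA", "C"))
        for name, element, pos in _build_sidechain(new_aa3, n, ca, c, chis):
            res.atoms.append(Atom(name=name, element=element, position=pos))
        if relax:
            out = relax_side_chain(out, chain_id, number, icode)
    return out


def measure_chis(res: Residue) -> tuple[float, ...]:
    """Chi dihedral angles of a residue's current side chain."""
    chis = []
    for quad in CHI_ATOMS.get(res.aa3, []):
        if not all(res.has_atom(a) for a in quad):
            break
        chis.append(_dihedral(*(res.atom(a).position for a in quad)))
    return tuple(chis)


def relax_side_chain(
    s: Structure,
    chain_id: str,
    number: int,
    icode: str = "",
    step: float = 15.0,
) -> Structure:
    """Deterministic chi-grid clash relief (coordinate descent, 15° steps).

    Each chi angle is scanned over the full circle in turn, keeping any
    strict improvement of the clash score; sweeps repeat until no chi moves.
    The backbone never changes and the score never increases.
    """
    out = s.copy()
    res = out.get_residue(chain_id, number, icode)
    if res.aa3 not in CHI_ATOMS or not CHI_ATOMS[res.aa3]:
        return out  # nothing rotatable
    n, ca, c = (res.atom(x).position for x in ("N", "CA", "C"))
    env = _environment_tree(out, res.key)

    def score_at(chis):
        atoms = _build_sidechain(res.aa3, n, ca, c, chis)
        return clash_score(np.array([p for _, _, p in atoms]), env), atoms

    chis = list(measure_chis(res))
    if len(chis) != len(CHI_ATOMS[res.aa3]):
        raise ValueError(
            f"residue {chain_id}:{number}{icode} ({res.aa3}) has an incomplete side chain"
        )
    best_score, best_atoms = score_at(tuple(chis))
    if best_score == 0:
        return out  # already clash-free; nothing to improve
    grid = [-180.0 + step * k for k in range(int(round(360.0 / step)))]
    improved = True
    sweeps = 0
    while improved and best_score > 0 and sweeps < 20:
        improved = False
        sweeps += 1
        for i in range(len(chis)):
            for angle in grid:
                trial = list(chis)
                trial[i] = angle
                sc, atoms = score_at(tuple(trial))
                if sc < best_score:
                    best_score, best_atoms = sc, atoms
                    chis = trial
                    improved = True
    backbone = [a for a in res.atoms if a.name in BACKBONE]
    res.atoms = backbone + [Atom(name=nm, element=el, position=p) for nm, el, p in best_atoms]
    return out


# ---------------------------------------------------------------------------
# combination models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationId:
    """A plastid-nuclear combination: maternal (plastid-donor) lineage first."""

    plastid_lineage: str
    nuclear_lineage: str

    @property
    def label(self) -> str:
        return f"{self.plastid_lineage}_{self.nuclear_lineage}"


def enumerate_combinations(lineages: list[str]) -> list[CombinationId]:
    """All L² ordered plastid x nuclear pairings (16 for four lineages)."""
    return [CombinationId(p, n) for p in lineages for n in lineages]


@dataclass
class CombinationModel:
    id: CombinationId
    structure: Structure
    applied: list[tuple[str, str, int, str, str]] = field(default_factory=list)
    # (compartment, gene, number, old_aa3, new_aa3)
    unapplicable: list[tuple[str, str, int, str]] = field(default_factory=list)


def build_combination_model(
    template: Structure,
    cid: CombinationId,
    sets: Mapping[str, SubstitutionSet],
    chain_map: Mapping[str, Mapping],
    relax: bool = False,
) -> CombinationModel:
    """Apply the maternal lineage's plastid substitutions and the paternal
    lineage's nuclear substitutions to the template structure."""
    for lin in (cid.plastid_lineage, cid.nuclear_lineage):
        if lin not in sets:
            raise KeyError(f"no substitution set for lineage {lin!r}")
    model = CombinationModel(id=cid, structure=template.copy())
    plan: list[tuple[str, str, int, str]] = []  # (compartment, gene, number, aa)
    for compartment, lineage in (
        ("plastid", cid.plastid_lineage),
        ("nuclear", cid.nuclear_lineage),
    ):
        for gene, ref_number, aa in sets[lineage].substitutions:
            if gene not in chain_map:
                raise ChainMapError(f"gene {gene!r} not in chain map")
            if chain_map[gene]["compartment"] != compartment:
                continue  # substitution belongs to the other parent's side
            plan.append((compartment, gene, ref_number, aa))
    for compartment, gene, ref_number, aa in plan:
        entry = chain_map[gene]
        chain_id = entry["chain"]
        number = ref_number + entry.get("offset", 0)
        try:
            old = model.structure.get_residue(chain_id, number).aa3
        except KeyError:
            model.unapplicable.append((compartment, gene, number, aa))
            continue
        model.structure = substitute_residue(
            model.structure, chain_id, number, aa, relax=relax
        )
        new = model.structure.get_residue(chain_id, number).aa3
        model.applied.append((compartment, gene, number, old, new))
    return model
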