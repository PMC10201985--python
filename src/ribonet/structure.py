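"""Coordinate data model and I/O for ribosome structures.

A lightweight hierarchical model (Structure -> Chain -> Residue -> Atom) sits
on top of :mod:`gemmi` for PDB/mmCIF parsing and PDB writing.  Chains are
annotated with the gene ("protein") they encode and the genomic compartment
that encodes them (plastid vs nuclear), supplied by a small chain-map config,
because the downstream analysis is organised around plastid-nuclear gene
pairs rather than raw chain identifiers.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ChainMapError",
    "StructureParseError",
    "load_chain_map",
    "parse_structure",
    "select_chains",
    "min_residue_distance",
    "write_structure",
]

COMPARTMENTS = ("plastid", "nuclear", "rna", "other")

#: The 20 standard three-letter residue names.
STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class ChainMapError(ValueError):
    """Raised when the chain-map config is inconsistent with the structure."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_AA3

    def coords(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError(f"residue {self.chain_id}:{self.number}{self.icode} has no atoms")
        return np.array([a.position for a in self.atoms])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {self.aa3} {self.chain_id}:{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def label(self) -> str:
        return f"{self.aa3}{self.number}{self.icode}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    protein: str | None = None
    compartment: str = "other"

    def get(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"no residue {number}{icode} in chain {self.chain_id}")


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in structure {self.id}: {sorted(ids)}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def chain_by_protein(self, protein: str) -> Chain:
        for c in self.chains:
            if c.protein == protein:
                return c
        available = sorted(c.protein for c in self.chains if c.protein)
        raise KeyError(f"no chain for protein {protein!r}; available: {available}")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        return self.chain(chain_id).get(number, icode)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


# ---------------------------------------------------------------------------
# chain map
# ---------------------------------------------------------------------------

def load_chain_map(source: str | Path | Mapping) -> dict[str, dict]:
    """Load a chain map ``{protein: {chain, compartment[, offset][, suffix]}}``.

    Accepts a YAML/JSON path or an already-parsed mapping.  ``offset`` is an
    optional per-gene residue-numbering offset (alignment numbering + offset =
    structure author numbering); ``suffix`` an optional short residue-label
    suffix used in centrality tables.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        raw = dict(source)
    cmap: dict[str, dict] = {}
    for protein, entry in raw.items():
        if not isinstance(entry, Mapping) or "chain" not in entry:
            raise ChainMapError(f"chain map entry for {protein!r} must name a 'chain'")
        comp = entry.get("compartment", "other")
        if comp not in COMPARTMENTS:
            raise ChainMapError(
                f"chain map entry for {protein!r}: compartment {comp!r} not in {COMPARTMENTS}"
            )
        cmap[protein] = {
            "chain": str(entry["chain"]),
            "compartment": comp,
            "offset": int(entry.get("offset", 0)),
            "suffix": entry.get("suffix"),
        }
    return cmap


def annotate_chains(s: Structure, chain_map: Mapping[str, dict]) -> Structure:
    """Attach protein/compartment annotations in place; returns ``s``."""
    by_chain = {}
    for protein, entry in chain_map.items():
        if entry["chain"] in by_chain:
            raise ChainMapError(f"chain {entry['chain']!r} mapped to more than one protein")
        by_chain[entry["chain"]] = (protein, entry["compartment"])
    known = {c.chain_id for c in s.chains}
    missing = set(by_chain) - known
    if missing:
        raise ChainMapError(
            f"chain map references chain id(s) absent from structure: {sorted(missing)}"
        )
    for c in s.chains:
        if c.chain_id in by_chain:
            c.protein, c.compartment = by_chain[c.chain_id]
        else:
            c.protein, c.compartment = None, "other"
    return s


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _best_altloc(atoms: list[Atom]) -> Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occupancy, a.altloc))[0]


def parse_structure(
    path: str | Path,
    format: str = "auto",
    chain_map: str | Path | Mapping | None = None,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Waters and non-polymer ligands are excluded; amino-acid and nucleic-acid
    residues are retained (RNA chains get compartment ``rna`` unless mapped
    otherwise).  For alternate locations only the highest-occupancy conformer
    of each atom is kept.  Only the first model of multi-model files is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    out = Structure(id=st.name or path.stem)
    model = st[0]
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is not None:
                if info.is_water():
                    continue
                if not (info.is_amino_acid() or info.is_nucleic_acid()):
                    continue  # ions, ligands, sugars
            # group altlocs per atom name, keep the best conformer
            by_name: dict[str, list[Atom]] = {}
            for ga in gres:
                if ga.is_hydrogen():
                    # hydrogens participate in distances when present, but
                    # cryo-EM/X-ray depositions analysed here have none
                    pass
                atom = Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                )
                by_name.setdefault(ga.name, []).append(atom)
            atoms = [_best_altloc(v) for v in by_name.values()]
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            chain.residues.append(
                Residue(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    icode=icode,
                    aa3=gres.name,
                    atoms=atoms,
                )
            )
            is_na = info is not None and info.is_nucleic_acid()
            if is_na:
                chain.compartment = "rna"
        if chain.residues:
            out.chains.append(chain)
    if chain_map is not None:
        cmap = chain_map if isinstance(chain_map, dict) and all(
            isinstance(v, dict) and "offset" in v for v in chain_map.values()
        ) else load_chain_map(chain_map)
        annotate_chains(out, cmap)
    return out


def select_chains(s: Structure, proteins: Iterable[str]) -> Structure:
    """Return a sub-structure containing exactly the named proteins' chains."""
    wanted = list(proteins)
    chains = []
    for p in wanted:
        chains.append(s.chain_by_protein(p))  # raises with available names
    sub = Structure(id=s.id, chains=_copy.deepcopy(chains))
    return sub


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def min_residue_distance(a: Residue, b: Residue) -> float:
    """Minimal Euclidean distance (Å) over all atom pairs of two residues."""
    ca, cb = a.coords(), b.coords()
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min())


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write the structure as PDB (coordinates to 3 decimals)."""
    if format != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa3
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
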