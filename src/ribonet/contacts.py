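"""Interface contact typing and mutation-induced change categories.

Interface residue-residue interactions are classified into four types —
salt bridge, hydrogen bond, hydrophobic, polar — or none (Ø).  The
geometric rules below are a deterministic rendering of what is usually done
by eye on a structure viewer: no hydrogen positions are assumed (heavy-atom
distances only, no angle terms), and the thresholds are exposed so they can
be tightened or relaxed per study.

Comparing the typed contact map of a mutant model against the reference
model yields per-pair records categorised as loss (typed -> Ø), gain
(Ø -> typed), type change, or unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np

from .structure import Residue

__all__ = [
    "InteractionType",
    "TypingThresholds",
    "InteractionRecord",
    "classify_interaction",
    "compare_models",
    "categorize_changes",
    "subtype_tally",
]

#: Legal interaction type labels ("none" encodes Ø).
InteractionType = ("h_bond", "salt_bridge", "hydrophobic", "polar", "none")

CATEGORIES = ("loss", "gain", "type_change", "unchanged")

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Positively charged side-chain nitrogens (salt-bridge donors).
CHARGED_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}

#: Carboxylate side-chain oxygens (salt-bridge acceptors).
CARBOXYLATE_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

#: Residues whose side chains are taken as wholly apolar.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "TRP"}

#: Side-chain carbons not bonded to N/O (apolar carbons) per residue.
APOLAR_CARBONS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "CYS": {"CB"},
    "THR": {"CG2"},
    "ARG": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "HIS": {"CB"},
    "SER": set(),
    "GLY": set(),
}


@dataclass(frozen=True)
class TypingThresholds:
    """Distance cutoffs (Å) of the typing rules, in priority order."""

    salt_bridge: float = 4.0
    h_bond: float = 3.5
    hydrophobic: float = 4.5
    window: tuple[float, float] = (2.5, 5.0)


def classify_interaction(
    a: Residue, b: Residue, thresholds: TypingThresholds | None = None
) -> str:
    """Type the interaction between two residues; first matching rule wins.

    Priority: salt bridge (charged N vs carboxylate O within 4.0 Å), hydrogen
    bond (any N/O pair within 3.5 Å), hydrophobic (apolar side-chain carbons
    within 4.5 Å), polar (any pair inside the RIN window with >= 1 N/O),
    else none.  Symmetric in its arguments.
    """
    th = thresholds or TypingThresholds()
    ca, cb = a.coords(), b.coords()
    diff = ca[:, None, :] - cb[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    def pairs_within(cut: float):
        ii, jj = np.nonzero(dist <= cut)
        return zip(ii.tolist(), jj.tolist())

    # rule 1: salt bridge
    for i, j in pairs_within(th.salt_bridge):
        aa, ab = a.atoms[i], b.atoms[j]
        if (
            aa.name in CHARGED_N.get(a.aa3, ())
            and ab.name in CARBOXYLATE_O.get(b.aa3, ())
        ) or (
            ab.name in CHARGED_N.get(b.aa3, ())
            and aa.name in CARBOXYLATE_O.get(a.aa3, ())
        ):
            return "salt_bridge"

    # rule 2: hydrogen bond (heavy-atom donor/acceptor distance only)
    for i, j in pairs_within(th.h_bond):
        if a.atoms[i].element in ("N", "O") and b.atoms[j].element in ("N", "O"):
            return "h_bond"

    # rule 3: hydrophobic
    both_apolar_res = a.aa3 in APOLAR_RESIDUES and b.aa3 in APOLAR_RESIDUES
    for i, j in pairs_within(th.hydrophobic):
        aa, ab = a.atoms[i], b.atoms[j]
        if aa.element != "C" or ab.element != "C":
            continue
        if aa.name in BACKBONE_ATOMS or ab.name in BACKBONE_ATOMS:
            continue
        if both_apolar_res or (
            aa.name in APOLAR_CARBONS.get(a.aa3, ())
            and ab.name in APOLAR_CARBONS.get(b.aa3, ())
        ):
            return "hydrophobic"

    # rule 4: polar
    lo, hi = th.window
    ii, jj = np.nonzero((dist >= lo) & (dist <= hi))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if a.atoms[i].element in ("N", "O") or b.atoms[j].element in ("N", "O"):
            return "polar"

    return "none"


def categorize(before: str, after: str) -> str:
    """Change category of a contact: loss / gain / type_change / unchanged."""
    for t in (before, after):
        if t not in InteractionType:
            raise ValueError(f"unknown interaction type {t!r}")
    if before == after:
        return "unchanged"
    if after == "none":
        return "loss"
    if before == "none":
        return "gain"
    return "type_change"


@dataclass
class InteractionRecord:
    """One interface residue pair with its typing before/after mutation."""

    plastid_gene: str
    plastid_residue: str
    nuclear_gene: str
    nuclear_residue: str
    distance: float
    before: str
    after: str
    plastid_aa: dict[str, str] = field(default_factory=dict)
    nuclear_aa: dict[str, str] = field(default_factory=dict)
    after_raw: str | None = None

    @property
    def category(self) -> str:
        return categorize(self.before, self.after)


def _as_mapping(contacts) -> dict[Hashable, str]:
    if isinstance(contacts, Mapping):
        return dict(contacts)
    out: dict[Hashable, str] = {}
    for key, typ in contacts:
        if key in out:
            raise ValueError(f"duplicate contact key {key!r}")
        out[key] = typ
    return out


def compare_models(
    wt,
    mut,
    distances: Mapping[Hashable, float] | None = None,
) -> list[tuple[Hashable, str, str, str]]:
    """Compare typed contact maps of a reference and a mutant model.

    ``wt`` and ``mut`` map residue-pair keys to interaction types (or are
    ``(key, type)`` iterables; duplicate keys are an error).  Pairs present
    in ``wt`` only are losses, in ``mut`` only gains, in both with equal
    type unchanged, otherwise type changes.  Returns sorted
    ``(key, before, after, category)`` tuples.
    """
    wt_map, mut_map = _as_mapping(wt), _as_mapping(mut)
    records = []
    for key in sorted(set(wt_map) | set(mut_map), key=repr):
        before = wt_map.get(key, "none")
        after = mut_map.get(key, "none")
        if before == "none" and after == "none":
            continue
        records.append((key, before, after, categorize(before, after)))
    return records


def categorize_changes(records: Iterable) -> dict[str, int]:
    """Counts of change categories over interaction records.

    Accepts :class:`InteractionRecord` objects or the tuples returned by
    :func:`compare_models`.
    """
    counts = Counter()
    total = 0
    for rec in records:
        cat = rec.category if isinstance(rec, InteractionRecord) else rec[3]
        counts[cat] += 1
        total += 1
    out = {c: counts.get(c, 0) for c in CATEGORIES}
    out["total"] = total
    return out


def subtype_tally(records: Iterable, category: str) -> dict[str, int]:
    """Per-type counts within one change category.

    For losses the "before" type is tallied, for gains the "after" type;
    for other categories both would be ambiguous so "before" is used.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counts = {t: 0 for t in InteractionType if t != "none"}
    for rec in records:
        if isinstance(rec, InteractionRecord):
            cat, before, after = rec.category, rec.before, rec.after
        else:
            _, before, after, cat = rec
        if cat != category:
            continue
        t = after if category == "gain" else before
        if t != "none":
            counts[t] += 1
    return counts
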