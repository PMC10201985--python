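"""Detection of amino-acid differences fixed between lineages.

Works on pre-aligned per-gene protein alignments in which every sequence id
encodes its lineage ("lineage|sample").  A column is a *fixed difference*
when it is monomorphic within every lineage but not identical across
lineages; columns polymorphic within any lineage, or containing a gap in
any lineage sequence, are excluded (a conservative convention that avoids
indel artifacts).  Detected columns are then mapped onto the ungapped
reference (spinach) residue numbering so they can be located on the
deposited structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "LineageAlignment",
    "Substitution",
    "SubstitutionSet",
    "read_lineage_fasta",
    "detect_fixed_differences",
    "map_to_reference",
    "build_substitution_sets",
    "write_substitutions_tsv",
    "read_substitutions_tsv",
]

GAP_CHARS = {"-", "."}


@dataclass
class LineageAlignment:
    """Aligned sequences of one gene, grouped by lineage, plus the reference."""

    gene: str
    sequences: dict[str, list[str]]
    reference: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for seqs in self.sequences.values() for s in seqs}
        if self.reference is not None:
            lengths.add(len(self.reference))
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged alignment (lengths {sorted(lengths)})")
        if not lengths:
            raise ValueError(f"{self.gene}: empty alignment")
        for lin, seqs in self.sequences.items():
            if not seqs:
                raise ValueError(f"{self.gene}: lineage {lin!r} has no sequences")
        self.length = lengths.pop()


@dataclass
class Substitution:
    """One differentially fixed alignment column."""

    gene: str
    column: int  # 0-based alignment column
    lineage_aa: dict[str, str]
    ref_number: int | None = None  # 1-based ungapped reference numbering
    ref_aa: str | None = None
    mappable: bool = True


@dataclass
class SubstitutionSet:
    """Per-lineage substitutions relative to the reference sequence."""

    lineage: str
    substitutions: list[tuple[str, int, str]] = field(default_factory=list)  # (gene, ref_number, aa)

    def __post_init__(self) -> None:
        keys = [(g, n) for g, n, _ in self.substitutions]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.lineage}: duplicate (gene, position) in substitution set")


def read_lineage_fasta(
    path: str | Path, gene: str | None = None, reference_prefix: str = "reference"
) -> LineageAlignment:
    """Read an aligned FASTA; ids are "lineage|sample", the reference
    sequence id starts with ``reference_prefix``."""
    path = Path(path)
    sequences: dict[str, list[str]] = {}
    reference = None
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split("|")[0]
        if name == reference_prefix:
            reference = str(rec.seq).upper()
        else:
            sequences.setdefault(name, []).append(str(rec.seq).upper())
    if not sequences:
        raise ValueError(f"{path}: no lineage sequences found")
    return LineageAlignment(gene=gene or path.stem, sequences=sequences, reference=reference)


def detect_fixed_differences(aln: LineageAlignment) -> list[Substitution]:
    """Columns monomorphic within every lineage but differing between lineages."""
    out = []
    for col in range(aln.length):
        fixed: dict[str, str] = {}
        ok = True
        for lineage, seqs in aln.sequences.items():
            chars = {s[col] for s in seqs}
            if chars & GAP_CHARS or len(chars) > 1:
                ok = False  # gap or within-lineage polymorphism
                break
            fixed[lineage] = chars.pop()
        if not ok:
            continue
        if len(set(fixed.values())) > 1:
            out.append(Substitution(gene=aln.gene, column=col, lineage_aa=fixed))
    return out


def map_to_reference(aln: LineageAlignment, subs: list[Substitution]) -> list[Substitution]:
    """Fill reference numbering and amino acid for detected columns.

    The alignment column index is converted into a 1-based position over the
    ungapped reference.  Columns aligned to a reference gap are flagged
    unmappable (``mappable=False``), never silently dropped.
    """
    if aln.reference is None:
        raise ValueError(f"{aln.gene}: no reference sequence in alignment")
    # cumulative count of reference residues up to each column
    numbering = []
    n = 0
    for ch in aln.reference:
        if ch in GAP_CHARS:
            numbering.append(None)
        else:
            n += 1
            numbering.append(n)
    out = []
    for sub in subs:
        num = numbering[sub.column]
        if num is None:
            out.append(
                Substitution(sub.gene, sub.column, dict(sub.lineage_aa), None, None, False)
            )
        else:
            out.append(
                Substitution(
                    sub.gene, sub.column, dict(sub.lineage_aa),
                    num, aln.reference[sub.column], True,
                )
            )
    return out


def build_substitution_sets(
    subs: list[Substitution], lineages: list[str]
) -> dict[str, SubstitutionSet]:
    """Per-lineage substitutions away from the reference amino acid.

    A lineage's set contains (gene, ref_number, aa) for every mapped column
    where that lineage's fixed amino acid differs from the reference;
    positions equal to the reference are omitted.
    """
    sets = {lin: [] for lin in lineages}
    for sub in subs:
        if not sub.mappable:
            continue
        if sub.ref_aa is None or sub.ref_number is None:
            raise ValueError(f"{sub.gene} column {sub.column}: not mapped to reference")
        for lin in lineages:
            if lin not in sub.lineage_aa:
                raise ValueError(f"{sub.gene} column {sub.column}: lineage {lin!r} missing")
            aa = sub.lineage_aa[lin]
            if aa != sub.ref_aa:
                sets[lin].append((sub.gene, sub.ref_number, aa))
    return {lin: SubstitutionSet(lineage=lin, substitutions=v) for lin, v in sets.items()}


def write_substitutions_tsv(subs: list[Substitution], path: str | Path) -> None:
    lineages = sorted({lin for s in subs for lin in s.lineage_aa})
    with open(path, "w") as fh:
        fh.write("gene\tcolumn\tref_number\tref_aa\tmappable\t" + "\t".join(lineages) + "\n")
        for s in subs:
            fh.write(
                f"{s.gene}\t{s.column}\t{s.ref_number if s.ref_number is not None else '-'}\t"
                f"{s.ref_aa or '-'}\t{int(s.mappable)}\t"
                + "\t".join(s.lineage_aa.get(l, "-") for l in lineages) + "\n"
            )


def read_substitutions_tsv(path: str | Path) -> list[Substitution]:
    subs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lineages = header[5:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            subs.append(
                Substitution(
                    gene=f[0],
                    column=int(f[1]),
                    ref_number=None if f[2] == "-" else int(f[2]),
                    ref_aa=None if f[3] == "-" else f[3],
                    mappable=bool(int(f[4])),
                    lineage_aa={l: aa for l, aa in zip(lineages, f[5:])},
                )
            )
    return subs
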