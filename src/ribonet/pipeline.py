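"""End-to-end orchestration: structure -> mutant models -> RIN -> centrality -> PCA.

Given a template structure, a chain map, per-lineage substitutions and an
interface gene pair, the pipeline builds every plastid x nuclear
combination model, writes its coordinates, interaction network, typed
interface report and centrality tables, and finishes with a PCA over the
combinations x residues Z-score matrix per measure.  A stage failure
aborts with the stage name and offending input; reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .centrality import compute_all
from .contacts import TypingThresholds, classify_interaction, compare_models
from .mutagenesis import CombinationModel, build_combination_model, enumerate_combinations
from .pca import DegenerateInputError, assemble_centrality_matrix, reciprocal_cross_separation, run_pca
from .rin import DistanceWindow, build_rin, export_edge_list, interface_edges
from .structure import Structure, load_chain_map, parse_structure, select_chains, write_structure
from .variants import (
    build_substitution_sets,
    detect_fixed_differences,
    map_to_reference,
    read_lineage_fasta,
    read_substitutions_tsv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    structure: str
    chain_map: str
    lineages: list[str]
    proteins: list[str]  # interface gene pair, plastid gene first
    output_dir: str
    substitutions: str | None = None  # TSV of mapped substitutions
    alignments_dir: str | None = None  # or: per-gene aligned FASTA files
    structure_format: str = "auto"
    d_min: float = 2.5
    d_max: float = 5.0
    measures: tuple[str, ...] = ("BCA", "CCA", "DCA", "ECA")
    pca_center: bool = True
    pca_scale: bool = True
    relax: bool = False
    typing: TypingThresholds = field(default_factory=TypingThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "typing" in raw:
            raw["typing"] = TypingThresholds(**raw["typing"])
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.lineages:
            raise ValueError("lineage list is empty")
        if len(self.proteins) != 2:
            raise ValueError("'proteins' must name the interface gene pair")
        for attr in ("structure", "chain_map"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.substitutions is None and self.alignments_dir is None:
            raise ValueError("need either 'substitutions' or 'alignments_dir'")

    def digest(self) -> str:
        payload = asdict(self)
        payload["typing"] = asdict(self.typing)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _residue_label(node, g, suffixes: Mapping[str, str]) -> str:
    chain, number, icode = node
    protein = g.nodes[node].get("protein")
    suffix = suffixes.get(protein, chain.lower())
    return f"{number}{icode}.{suffix}"


def _typed_contacts(s: Structure, proteins, window, thresholds):
    """Typed interface contact map {(res_a, res_b): type} for a gene pair."""
    sub = select_chains(s, proteins)
    g = build_rin(sub, window)
    contacts = {}
    for u, v, _d in interface_edges(g, proteins[0], proteins[1]):
        ra = sub.get_residue(u[0], u[1], u[2])
        rb = sub.get_residue(v[0], v[1], v[2])
        key = (f"{u[1]}{u[2]}", f"{v[1]}{v[2]}")
        contacts[key] = (classify_interaction(ra, rb, thresholds), _d)
    return contacts


def _stage(name: str, context: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                where = f" ({context})" if context else ""
                raise PipelineError(f"stage '{name}' failed{where}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a manifest of outputs and key results."""
    cfg.validate()
    out = Path(cfg.output_dir)
    for sub in ("models", "rin", "interface", "centrality", "tables", "pca"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    window = DistanceWindow(cfg.d_min, cfg.d_max)
    manifest: dict = {"combinations": [], "outputs": {}, "notes": []}

    with _stage("parse_structure", cfg.structure):
        chain_map = load_chain_map(cfg.chain_map)
        template = parse_structure(cfg.structure, cfg.structure_format, chain_map)

    with _stage("substitutions", cfg.substitutions or cfg.alignments_dir or ""):
        if cfg.substitutions is not None:
            subs = read_substitutions_tsv(cfg.substitutions)
        else:
            subs = []
            for fasta in sorted(Path(cfg.alignments_dir).glob("*.fasta")):
                aln = read_lineage_fasta(fasta)
                subs.extend(map_to_reference(aln, detect_fixed_differences(aln)))
        sets = build_substitution_sets([s for s in subs if s.mappable], cfg.lineages)

    combos = enumerate_combinations(cfg.lineages)
    suffixes = {
        p: (e.get("suffix") or e["chain"].lower()) for p, e in chain_map.items()
    }
    wt_contacts = _typed_contacts(template, cfg.proteins, window, cfg.typing)

    models: dict[str, CombinationModel] = {}
    zmaps: dict[str, dict[str, dict[str, float]]] = {m: {} for m in cfg.measures}
    column_order: list[str] | None = None

    for cid in combos:
        label = cid.label
        with _stage("models", label):
            model = build_combination_model(template, cid, sets, chain_map, relax=cfg.relax)
            write_structure(model.structure, out / "models" / f"{label}.pdb")
            models[label] = model
        with _stage("rin", label):
            sub = select_chains(model.structure, cfg.proteins)
            g = build_rin(sub, window)
            export_edge_list(g, out / "rin" / f"{label}_edges.tsv")
        with _stage("interface", label):
            mut_contacts = _typed_contacts(model.structure, cfg.proteins, window, cfg.typing)
            records = compare_models(
                {k: t for k, (t, _) in wt_contacts.items()},
                {k: t for k, (t, _) in mut_contacts.items()},
            )
            with open(out / "interface" / f"{label}_interface.tsv", "w") as fh:
                fh.write("residue_a\tresidue_b\tdistance\tbefore\tafter\tcategory\n")
                for key, before, after, cat in records:
                    dist = (wt_contacts.get(key) or mut_contacts.get(key))[1]
                    fh.write(f"{key[0]}\t{key[1]}\t{dist:.3f}\t{before}\t{after}\t{cat}\n")
        with _stage("centrality", label):
            vectors = compute_all(g, cfg.measures)
            labels = {n: _residue_label(n, g, suffixes) for n in g.nodes}
            if column_order is None:
                ordered = sorted(
                    g.nodes,
                    key=lambda n: (
                        0 if g.nodes[n].get("compartment") == "plastid" else 1,
                        n[1], n[2],
                    ),
                )
                column_order = [labels[n] for n in ordered]
            frame = pd.DataFrame(index=[labels[n] for n in g.nodes])
            for m, vec in vectors.items():
                frame[f"{m}_raw"] = [vec.values[n] for n in g.nodes]
                frame[f"{m}_z"] = [vec.zscores[n] for n in g.nodes]
                zmaps[m][label] = {labels[n]: vec.zscores[n] for n in g.nodes}
            frame = frame.loc[column_order]
            frame.to_csv(out / "centrality" / f"{label}.csv", index_label="residue")
        manifest["combinations"].append(label)

    pca_results = {}
    for m in cfg.measures:
        with _stage("tables", m):
            table = assemble_centrality_matrix(
                zmaps[m], m,
                residue_subset=column_order,
                row_order=[c.label for c in combos],
            )
            table.data.to_csv(out / "tables" / f"{m}.csv", index_label="combination")
        with _stage("pca", m):
            data = table.data
            variable = data.columns[data.std(axis=0, ddof=1) > 0]
            dropped = [c for c in data.columns if c not in set(variable)]
            if dropped:
                manifest["notes"].append(
                    f"{m}: dropped constant column(s) before PCA: {dropped}"
                )
            if len(variable) < 2 or len(data) < 3:
                manifest["notes"].append(f"{m}: too little variance for PCA; skipped")
                continue
            from .pca import CentralityTable as _CT

            try:
                res = run_pca(_CT(m, data[variable]), cfg.pca_center, cfg.pca_scale)
            except DegenerateInputError as exc:
                manifest["notes"].append(f"{m}: PCA skipped ({exc})")
                continue
            pca_results[m] = res
            res.variance_pct.to_csv(out / "pca" / f"{m}_variance.csv")
            res.scores.to_csv(out / "pca" / f"{m}_scores.csv", index_label="combination")
            res.loadings.to_csv(out / "pca" / f"{m}_loadings.csv", index_label="residue")
            res.contributions_pct.to_csv(
                out / "pca" / f"{m}_contributions.csv", index_label="residue"
            )
            reciprocal_cross_separation(res).to_csv(
                out / "pca" / f"{m}_reciprocal.csv", index=False
            )

    manifest["outputs"] = {
        "models": sorted(p.name for p in (out / "models").glob("*.pdb")),
        "pca_measures": sorted(pca_results),
    }
    log = {
        "package_version": __version__,
        "config_sha256": cfg.digest(),
        "n_combinations": len(combos),
        "notes": manifest["notes"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    manifest["pca"] = pca_results
    manifest["models"] = models
    return manifest
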