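# ribonet

Structure-based screening of plastid–nuclear incompatibility (PNI)
candidates in the plastid ribosome.

## The problem

Plastid protein complexes are mosaics: some subunits are encoded by the
plastid genome (maternally inherited, slowly mutating), others by nuclear
genes whose products are imported into the plastid (nuPt genes).  Residue
contacts between the two classes of subunits demand tight co-adaptation.
When isolated lineages accumulate amino-acid substitutions independently,
an interlineage hybrid pairs a plastid genome with a half-foreign nuclear
background, and mismatched residue contacts can contribute to hybrid
breakdown.  The plastid ribosome — essential for plastid translation — is a
prime candidate complex: in *Silene nutans*, four diverged lineages (E1,
W1, W2, W3) show strong, asymmetric reproductive isolation, and the
ribosomal gene pair *rps11* (plastid) / *rps21* (nuclear) concentrates the
lineage-specific substitutions at the subunit interface.

`ribonet` implements the complete in-silico screen that connects sequence
divergence to structural consequence:

1. **Fixed differences.** From per-gene protein alignments, find columns
   monomorphic within each lineage but divergent between lineages, and map
   them onto the reference (spinach) residue numbering used by the
   deposited ribosome structure.
2. **Combination models.** For L lineages, build all L² plastid×nuclear
   hybrid models (16 for four lineages): combination P_N carries lineage
   P's substitutions on plastid-encoded chains and lineage N's on
   nuclear-encoded chains.  Side chains are rebuilt from idealized
   templates with a coarse rotamer library and deterministic clash relief
   (no force-field minimization); backbones never move.
3. **Residue interaction networks (RINs).** Nodes are residues; an edge
   joins residues whose minimal inter-atom distance lies in a window
   (default 2.5–5.0 Å, inclusive), annotated with that distance.
4. **Interface typing.** Plastid–nuclear contacts are classified as salt
   bridge, hydrogen bond, hydrophobic, or polar by deterministic geometric
   rules; comparing mutant against reference maps yields losses, gains,
   type changes, and unchanged contacts.
5. **Centrality Z-scores.** Betweenness (BCA), closeness (CCA), degree
   (DCA) and eigenvector (ECA) centralities per network, standardized as
   Z = (c − mean)/sd over the network's nodes; residues with Z ≥ 2 are
   flagged central.
6. **PCA across combinations.** The combinations × residues Z-score matrix
   is ordinated by a centred, scaled PCA (`prcomp`-style); variance shares,
   per-residue contributions (squared loadings, % per component), and
   distances between reciprocal crosses in the PC1–PC2 plane quantify
   whether cross type and direction separate.

Packaged with the code are machine-readable fixtures of the published
28 interface interaction records and the published 16 × 17 BCA/CCA
centrality Z-score tables, plus generators for toy structures with exactly
controlled contact geometry and alignments with planted fixed differences,
so every stage is testable without downloading the real structure.

## Worked example

```python
from ribonet import table3_fixture, run_pca, reciprocal_cross_separation

res = run_pca(table3_fixture("BCA"))   # centred, scaled PCA, 16 x 17
print(res.summary())
```

```
PCA of BCA centrality Z-scores (16 combinations x 17 residues, center=True, scale=True)

component  eigenvalue  variance%  cumulative%
      PC1      5.7053       33.6         33.6
      PC2      4.9649       29.2         62.8
      PC3      2.5055       14.7         77.5
      PC4      1.9901       11.7         89.2
      PC5      0.8265        4.9         94.1

top contributors to PC1: 119.k (11.4%), 135.k (10.5%), 134.k (10.4%)

top contributors to PC2: 116.u (18.9%), 90.u (16.3%), 117.k (11.8%)
```

The first two components carry ~63% of the variance, and the residues
driving them (labels `<number>.k` for *rps11*, `<number>.u` for *rps21*)
include the interface partners Lys135(k)/Glu127(u) and the substituted
90.u/116.u region.  Reciprocal crosses separate in the PC1–PC2 plane:

```python
print(reciprocal_cross_separation(res).to_string(index=False))
```

```
 pair forward reverse  distance
E1-W1   E1_W1   W1_E1  7.666539
E1-W2   E1_W2   W2_E1  5.893663
E1-W3   E1_W3   W3_E1  6.054079
W1-W2   W1_W2   W2_W1  0.097638
W1-W3   W1_W3   W3_W1  3.725853
W2-W3   W2_W3   W3_W2  5.632126
```

Crosses involving E1 as one parent sit far from their reciprocals
(distances ≈ 6–8), while W1×W2 reciprocals are nearly coincident — the
centrality signature tracks which lineage donates the plastid.

A full synthetic end-to-end run (toy dimer, four mock lineages, 16 models,
RINs, interface reports, centrality tables, PCA):

```sh
ribonet fixtures --out demo --seed 1     # writes toy inputs + fixtures
ribonet rin --structure demo/toy_dimer.pdb --out demo/edges.tsv
ribonet run --config run.yaml            # full pipeline (see docs/methods.md)
```

## Layout

- `src/ribonet/structure.py` — coordinate model, PDB/mmCIF I/O, chain map,
  minimal inter-residue distances
- `src/ribonet/variants.py` — fixed-difference detection and reference mapping
- `src/ribonet/mutagenesis.py` — side-chain rebuilding, rotamer choice,
  clash relief, combination models
- `src/ribonet/rin.py` — interaction-network construction and export
- `src/ribonet/contacts.py` — interface contact typing and change categories
- `src/ribonet/centrality.py` — BCA/CCA/DCA/ECA with Z-scores
- `src/ribonet/pca.py` — centrality matrices, PCA results, contributions
- `src/ribonet/synthetic.py` — generators and packaged table fixtures
- `src/ribonet/pipeline.py`, `src/ribonet/cli.py` — orchestration and CLI
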