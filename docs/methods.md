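# Methods

This note documents the models, conventions and numerical choices behind
`ribonet`, in the order the pipeline applies them, together with what the
synthetic generators do and do not emulate.

## Coordinate model and chain map

Structures are parsed with gemmi (PDB or mmCIF; format auto-detected) into
a plain Structure → Chain → Residue → Atom hierarchy.  Waters, ions and
non-polymer ligands are dropped; amino-acid and nucleic-acid polymer
residues are kept.  RNA chains remain in the model (compartment `rna`) but
are excluded from the default analysis selection — only protein–protein
contacts are analysed.  For alternate locations, the highest-occupancy
conformer of each atom is kept, ties broken by altloc letter order.
Residue numbering is the deposited author numbering; no renumbering is
performed, so residue labels match the structure as published.  If a
sequence alignment numbers residues differently from the structure, the
chain map carries a per-gene integer `offset` (alignment number + offset =
author number; default 0).

The chain map is a small YAML/JSON file

```yaml
rps11: {chain: "x", compartment: plastid, suffix: k}
rps21: {chain: "u", compartment: nuclear, suffix: u}
```

linking gene names to chain identifiers, encoding compartment, and an
optional short label suffix used in centrality tables.  The real
structure's chain assignments must come from the PDB entry metadata; the
package never guesses them.  Unmapped chains get compartment `other` and
are ignored by compartment-specific stages.

"Any one atom" in the distance rule means every atom present in the
coordinate file.  Cryo-EM/X-ray depositions analysed here carry no
hydrogens; if hydrogens are present they participate.

## Fixed-difference detection

A column of a per-gene protein alignment is a fixed difference when it is
monomorphic within every lineage and at least two lineages differ.
Columns with a gap in any lineage sequence, or polymorphic within any
lineage, are excluded — a deliberately conservative rule that avoids indel
artifacts; the cost is silence at genuinely divergent sites adjacent to
indels.  Mapping to the reference converts the alignment column to a
1-based position over the ungapped reference sequence; columns aligned to
a reference gap are flagged unmappable rather than dropped, so they remain
visible in reports.  A lineage's substitution set then contains every
mapped position where that lineage's fixed amino acid differs from the
reference amino acid.

## Combination models and side-chain rebuilding

For lineages L the pipeline builds all L² plastid×nuclear combinations
(16 for four).  The first lineage is the maternal, plastid-donor side: its
substitutions are applied to plastid-compartment chains; the second
lineage's substitutions to nuclear-compartment chains.  Nuclear
heterozygosity of a real F1 is deliberately ignored — each model carries a
single nuclear allele set, matching the combination definition.

A substitution keeps the residue's backbone atoms (N, CA, C, O, OXT)
bit-identical and rebuilds the side chain from the idealized residue
geometry of the chemical component dictionary (bundled with biotite),
superposed onto the residue's own N/CA/C frame by least-squares.  Chi
angles are then set *in world coordinates*, measured against the actual
backbone atoms, so requested and realised dihedrals agree exactly even on
distorted backbones.  Glycine targets simply remove the side chain.

Rotamers come from a small built-in, backbone-independent library of
canonical chi combinations with priors (e.g. chi1 −60°/180°/+60° with
priors 0.52/0.33/0.15; ±90° for aromatic chi2).  The chosen rotamer
minimises a hard clash count: heavy-atom pairs closer than 2.5 Å between
the new side chain and all atoms of other residues (the residue's own
atoms are excluded).  Ties go to the higher prior, then the lexicographically
smallest chi tuple — fully deterministic.  An optional relaxation runs
coordinate descent over the chi angles on a 15° grid, accepting only
strict improvements, so the clash score never increases and the procedure
terminates.  Proline's ring is kept at template geometry (its chis are not
searched).

No force-field minimization is performed.  This is the package's principal
simplification: energy minimization of mutant models would shift contact
distances by fractions of an Ångström and can flip marginal interaction
type calls, so downstream "after mutation" typings and centrality values
from this package are expected to differ in detail from analyses that
minimize.  The packaged interaction-record fixture therefore stores the
published type calls as data, and agreement of this package's geometric
typing with them is reported, not asserted.

## Interaction networks

An edge joins residues A and B when min over atom pairs of the Euclidean
distance lies in [d_min, d_max], default [2.5, 5.0] Å, inclusive on both
ends.  Pairs closer than d_min are excluded as presumed covalent contacts
or clashes — the literal reading of the window rule.  Covalently adjacent
residues are not special-cased.  Construction uses a KD-tree over all
atoms (near-linear in practice) and is bit-identical to the brute-force
all-atom-pair scan, which the test suite verifies on every synthetic
structure.  Edge distances are annotations; all path-based measures treat
the graph as unweighted.

The default analysis graph is the two-chain selection of the interface
gene pair (rps11 + rps21).  Whether surrounding ribosomal chains should
contribute nodes is genuinely open; the two-chain choice matches the
published network figure, and any selection up to the full complex can be
requested.

## Interface typing

Four types, decided by the first matching rule:

1. **salt bridge** — side-chain charged N (Arg NE/NH1/NH2, Lys NZ, His
   ND1/NE2) within 4.0 Å of a side-chain carboxylate O (Asp OD1/OD2, Glu
   OE1/OE2);
2. **hydrogen bond** — any N/O heavy-atom pair within 3.5 Å (no hydrogen
   positions are assumed, hence no angle term);
3. **hydrophobic** — side-chain carbon–carbon contact within 4.5 Å where
   both residues are wholly apolar (Ala, Val, Leu, Ile, Met, Phe, Pro,
   Trp) or both carbons are apolar (not bonded to N/O) per a fixed table;
4. **polar** — any pair inside the interaction window with at least one
   N/O;
5. otherwise **none** (Ø).

The thresholds are conventions standing in for by-eye calls on a
structure viewer and are exposed in `TypingThresholds`.  They will not
reproduce every published label (e.g. a 4.57 Å C–C dominated contact
labelled polar); the change *categories* — loss (typed → Ø), gain (Ø →
typed), type change, unchanged — are the robust quantity, and on the
packaged records the category tallies match the published counts exactly
(8 losses, 4 gains, 16 unchanged of 28).  Dual-lineage outcomes such as
"hydrophobic/Ø" keep the raw call in `after_raw`; the effective `after`
used for categorisation follows the published tally.

## Centrality

* **DCA** degree: neighbour count.
* **CCA** closeness: 1 / Σ(shortest-path lengths), computed within the
  node's connected component; by default multiplied by the
  Wasserman–Faust factor (r−1)/(n−1) so values are comparable across
  components (`mode="component"` disables it).  Singletons get 0.
* **BCA** betweenness: unweighted shortest-path betweenness,
  pair-normalised (÷ (n−1)(n−2)/2), endpoints excluded.
* **ECA** eigenvector: principal adjacency eigenvector on the largest
  component via power iteration (tolerance 1e-10-per-node, max 1000
  iterations; non-convergence raises), non-negative, L2-normalised;
  other components get 0.

Path algorithms are delegated to networkx; the test suite checks all four
measures against independent brute-force oracles (Floyd–Warshall plus
path-count dynamic programming, dense eigendecomposition) on closed-form
graph families and hundreds of random graphs.

Z-scores standardise each measure per network: Z = (c − mean)/sd with the
population sd over the network's nodes; sd = 0 yields all-zero Z.  Z is
invariant to shifting or positively scaling the raw values, so the
betweenness normalisation choice and the closeness (n−1) convention do not
affect it.  Residues with Z ≥ 2 are flagged central.

## PCA

Rows are combinations, columns residue labels (`98.k` … `127.u`; plastid
residues first).  Columns are centred and scaled to unit sample variance —
a correlation PCA.  Scaling is the shipped default because the package's
own reproduction check on the packaged Z-score tables decides it: unscaled
PCA concentrates 69% (BCA) / 54% (CCA) of the variance on PC1, while the
correlation PCA yields 33.6/29.2 (BCA) and 39.4/22.7 (CCA), matching the
published 36/31 and 40/23 pattern; the published analysis evidently scaled.
Decomposition is by SVD; eigenvalues use the sample-covariance convention
(σ²/(n−1)); component signs are fixed so each loading column's
largest-magnitude entry is positive, making outputs stable across
linear-algebra backends.  A variable's contribution to a component is its
squared loading as a percentage of that component's squared-loading sum,
with 100/p as the uniform reference.  Reciprocal-cross separation is the
Euclidean distance between P_N and N_P scores in the PC1–PC2 plane.

**Precision caveat.**  The packaged tables print Z-scores to two decimals.
Columns whose true range is comparable to 0.01 (e.g. 134.k/135.k in the
BCA table, 134.k in the CCA table) are quantised to a few distinct values;
after scaling to unit variance this quantisation noise replaces their real
correlation structure.  Consequently the variance shares and especially
the contribution percentages recovered from the printed tables deviate by
up to ~5 percentage points from full-precision values for exactly those
near-constant columns, while well-resolved quantities (CCA variance
shares, BCA PC2) agree within rounding.  This is a property of the printed
input, not of the decomposition — the package's PCA matches R's
`prcomp(center=TRUE, scale.=TRUE)` to machine precision on the same
matrices.

## Synthetic data

The toy-dimer generator places two chains of compact idealized backbones
20 Å apart (residues 10 Å apart along each chain) and realises each
planned contact with a dedicated pair of atoms on separate z-planes, so
every planned pair's minimal distance is analytically exact and every
unplanned inter-chain pair stays ≥ 6 Å — the expected network edge set is
known by construction.  Backbone positions receive a small seeded jitter;
outputs are byte-identical for equal seeds.  The generator emulates
controlled contact geometry only: no secondary structure, no realistic
packing, no chemistry.  Tests passing on it validate the distance rule,
network construction, bookkeeping and determinism — not the biological
realism of any model.

The alignment generator produces monomorphic lineages with planted fixed
differences (plus optional within-lineage polymorphic columns and gap
columns that the detector must reject) and an ungapped reference, so
alignment position equals reference number and recovery can be scored
exactly.  Real alignments additionally contain indels, ragged coverage and
within-lineage variation beyond single columns; the detector's gap and
polymorphism rules are conservative by design.

Published tables ship as TSV data files under `ribonet/data/`, transcribed
once and guarded by checksum tests.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| d_min, d_max | 2.5, 5.0 Å | interaction window (inclusive) |
| salt-bridge cutoff | 4.0 Å | charged N – carboxylate O |
| H-bond cutoff | 3.5 Å | N/O – N/O heavy atoms |
| hydrophobic cutoff | 4.5 Å | apolar C – C |
| clash cutoff | 2.5 Å | hard-clash heavy-atom distance |
| relax grid | 15° | chi coordinate-descent step |
| Z flag | 2.0 | central-residue threshold |
| PCA | center + scale | correlation PCA over combinations |

## Known limitations

- No energy model: side-chain placement is clash-count only; marginal
  contacts and typing calls near thresholds are sensitive to this.
- Backbones are frozen; substitutions that would perturb the backbone
  (e.g. to/from proline in constrained turns) are modelled rigidly.
- No π-stacking, cation–π or water-mediated interactions.
- RNA–protein contacts are excluded from the analysis selection.
- Closeness/eigenvector conventions for disconnected graphs are choices;
  Z-scores soften but do not erase them.
- The 17-residue column set for the PCA mirrors the published table; the
  pipeline uses all residues of the selected chains by default, so column
  sets differ between reproduction (fixture) and fresh runs.
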