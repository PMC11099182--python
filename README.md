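# clonsig

Paired-chain BCR clonal-family inference, somatic-mutation rates,
public-clonotype matching, repertoire diversity/overlap statistics, and
per-cell pre-ranked GSEA signature projection — the computational workflow
for tracking the recruitment of antibody-secreting cells into bone-marrow
plasma-cell compartments from single-cell repertoire and transcriptome data.

It is written for immunologists and computational biologists who have
per-cell V(D)J annotation tables (AIRR Rearrangement TSV) and UMI count
matrices (Matrix Market + features/barcodes) and want the repertoire and
signature statistics of that workflow as tested, reusable components. A
fully ground-truthed simulator of both data modalities makes every stage
verifiable without any external data.

## The statistics at the core

- **Clonal families.** Cells *c*, *c′* are clonally related when they share
  donor, V/J genes and CDR3 length on both chains and CDR3 nucleotide
  identity exceeds 80% *strictly* on each chain (identity = 1 − normalised
  Hamming distance). Families must satisfy the rule between *all* members,
  so they are built by deterministic complete-linkage agglomeration within
  each (donor, V, J, length) group.
- **Diversity.** Per cell cluster: family richness and the Gini–Simpson
  index 1 − Σ pᵢ² (probability that two randomly drawn cells belong to
  different families). Between-cluster family sharing is tested against a
  permutation null (family labels shuffled across cells, 1000 permutations,
  add-one p-value estimator).
- **Mutation rates.** Per cell and region group (FR1–3 or CDR1–3):
  (heavy + light mutation counts) / (heavy + light nt length), from the
  gapped-germline mutation table.
- **Public clones.** A cell matches an antigen-specific reference clone
  when CDR3 lengths agree on both chains and the pooled identity
  (identical nt / total length) reaches 80% *inclusively*.
- **Per-cell GSEA.** Each cell is ranked by score(g) = log-normalised
  expression − gene mean over the analysed set, with
  log values ln(10,000·UMIs_g/UMIs_total + 1); the enrichment score is the
  weighted Kolmogorov–Smirnov running sum (weight 1); significance comes
  from 1000 random same-size gene sets per cell, with NES, nominal p and an
  NES-pooled FDR; a cell is significantly enriched when FDR ≤ 0.50 and
  p < 0.05. Signatures themselves are derived as genes with
  target-vs-rest ROC AUC > 0.6 and adjusted Mann–Whitney p ≤ 0.05.

See `docs/methods.md` for models, defaults, numerical choices and
limitations.

## Worked example

```python
import clonsig as cs
from clonsig.io import pairs_from_table

table, truth = cs.simulate_repertoire(n_cells=120, n_clones=15,
                                      donor_labels=("D1", "D2"), seed=42)
pairs, report = pairs_from_table(table)
part = cs.partition_families(pairs.values())
grouping = {c: f"k{i % 3}" for i, c in enumerate(sorted(pairs))}

reference, pub_truth = cs.plant_public_clones(table, n_public=4,
                                              divergence=0.05, seed=7)
rpairs, _ = pairs_from_table(reference)
matches = cs.match_public(pairs.values(), rpairs.values())

adata, _ = cs.simulate_expression(n_genes=2000, n_cells=500, n_clusters=5, seed=1)
cs.log_normalize(adata)
sig = cs.derive_signature(adata, ("cluster", "c0"), name="c0_markers")
res = cs.gsea_per_cell(adata, {"c0_markers": sig.genes}, n_perm=1000, seed=2)
summary, _ = cs.summarize_clusters(
    res, dict(zip(adata.obs_names, adata.obs["cluster"].astype(str))))
```

Output:

```
108 of 120 cells keep a full heavy/light pair
15 clonal families inferred
families per cluster: {'k0': 8, 'k1': 8, 'k2': 12}
Simpson index per cluster: {'k0': 0.647, 'k1': 0.67, 'k2': 0.633}
8 public cells recovered (truth: 8)
signature 'c0_markers': 50 genes, top AUC 0.913
cluster  frac_significant_pos  nes_q50
     c0                   1.0    2.224
     c1                   0.0      NaN
```

Reading: 12 of 120 simulated cells lack a valid heavy/light pair and are
dropped (as real annotation pipelines drop 5–15% of cells); the clusterer
recovers exactly the 15 simulated clones; family richness and Simpson
diversity describe how families distribute over the (here arbitrary)
cell clusters; all 8 cells belonging to the 4 planted public clones are
found and no others; the 50-gene planted module is recovered as a marker
signature, and projecting it back by per-cell GSEA flags every cell of the
planted cluster c0 as significantly positively enriched (median NES 2.22)
and no cell elsewhere.

The same pipeline is scriptable from a shell via the `clonsig` command
(`simulate-repertoire`, `simulate-expression`, `clones`, `public`,
`signatures`, `gsea`, `report`); every stage writes TSV artefacts and a
JSON provenance record.

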