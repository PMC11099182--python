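# Methods

`clonsig` implements the computational workflow used to relate single-cell
B-cell-receptor (BCR) repertoires to single-cell transcriptomes in studies of
plasma-cell recruitment: clonal-family inference from paired heavy/light
chains, somatic-hypermutation quantification, public-clonotype matching,
repertoire diversity and overlap statistics, and projection of marker-gene
signatures onto individual cells by pre-ranked gene-set enrichment analysis
(GSEA). All stages are exercised end to end on synthetic data with known
ground truth; this note records the models, the defaults and why, and what the
synthetic data does and does not establish.

## Contig selection and the BCR data model

Single-cell V(D)J assembly yields several contigs per cell barcode. Per cell
and chain, contigs are filtered to productive and fully sequenced ones —
"fully sequenced" meaning all five V regions (FR1, CDR1, FR2, CDR2, FR3) are
present with non-zero length and the junction (CDR3) is complete — and the
most abundant survivor is selected. Abundance is the UMI count
(`duplicate_count`), with read count (`consensus_count`) and then the
lexicographically smallest contig identifier as tie-breakers, so selection is
deterministic. Cells that do not retain both a heavy and a light contig are
dropped and counted in the run report.

Each contig carries the gapped FR1–FR3 alignment of its V region together
with a mutation table of (region, gapped position, germline base, observed
base) entries, the form in which germline-annotation services tabulate
somatic substitutions. Reverting every listed substitution reconstructs the
gapped germline exactly; entries at gap columns or outside their stated
region are rejected, and a no-op entry (germline equal to observed) raises a
warning.

Somatic-mutation rates are computed per cell as
(heavy-chain mutations + light-chain mutations) / (heavy + light nucleotide
length) over a region group, either the frameworks FR1–3 or the CDRs.
Region lengths are gap-excluded nucleotide counts; the alignment gaps are a
numbering artefact, not sequence. The junction has no germline in a V-region
mutation table, so CDR3 contributes to the CDR-group rate only when an
explicit CDR3 mutation count is supplied.

## Clonal families

Two cells belong to the same clonal family when they come from the same
donor, use the same V and J genes on both chains, have equal CDR3 lengths on
both chains, and their CDR3 nucleotide identity exceeds 80% — strictly — on
each chain (identity = 1 − normalised Hamming distance; 3 mismatches over 15
nt is exactly 80% and does *not* qualify). Because the rule must hold
*between all members* of a family, families are built by complete-linkage
agglomeration within each candidate key group. A minimum clique cover would
be the exact formulation but is NP-hard; complete linkage is the standard
deterministic surrogate that still guarantees every intra-family pair
satisfies the rule. Merging is deterministic: cells are sorted by identifier,
the closest cluster pair is merged first, and ties are broken by the smallest
member identifiers. Options: single linkage, a `joint` chain mode that pools
both chains' CDR3s into one identity, and an additional key on the
reconstructed germline FR1–FR3 strings (off by default — on a library
without alleles, V/J + donor + length are already decisive; enabling it
makes the key maximally literal).

Numerics: pair distances are computed as one integer division
(mismatches/length), so a distance rationally equal to a decimal boundary
resolves to the boundary's own float; the merge cut subtracts 1e−9 from
1 − threshold to keep the strict inequality exact for thresholds that are
not binary-representable. Distinct CDR3 distances are spaced at least
1/length² apart, orders of magnitude above the guard.

Diversity per cell cluster is summarised as the number of distinct families
(richness) and the Gini–Simpson index 1 − Σ pᵢ², the probability that two
cells drawn with replacement belong to different families; an unbiased
without-replacement variant 1 − Σ nᵢ(nᵢ−1)/(N(N−1)) is available (which of
the two conventions the original analyses used is generally not stated in
publications; with replacement is the default here). Family sharing between
clusters is the count of families with members in both; its significance is
assessed by permuting the family annotation across cells (cluster labels
fixed; 1000 permutations by default) with the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm), which cannot return zero.

## Public clonotypes

A repertoire cell is putatively antigen-specific ("public") when its paired
CDR3s are near-identical to an experimentally validated reference clone:
CDR3 lengths must agree on both chains and identity must reach 80%
*inclusively* — the matching rule is a minimum requirement, unlike the
strict clustering rule, and both semantics are honoured as stated. The
default `joint` mode counts identical nucleotides over the pooled
heavy+light CDR3 length; `per_chain` requires each chain to reach the
threshold separately. V/J agreement is not required by default (the matching
criteria are length and identity only) but can be switched on. Length
bucketing is an optimisation; matching is verified against a brute-force
all-pairs scan in the tests.

## Expression, signatures, per-cell GSEA

Counts are depth-normalised and log-transformed as
ln(10,000 × UMIs_gene / UMIs_total + 1) (natural log; zero counts map to 0).
Marker signatures for a group of cells (e.g. a vaccination time point) are
genes with target-vs-rest ROC AUC strictly greater than 0.6 and adjusted
two-sided Mann–Whitney p ≤ 0.05. The AUC is rank-based (U/(n₁n₀), ties
mid-ranked). Adjustment defaults to Bonferroni — the most conservative
reading of "adjusted p" — with Benjamini–Hochberg available.

For projection, each cell is converted to a ranked list: score(gene) =
cell's log value − mean log value over all cells of the analysed set
(joint centering over the whole matrix; ties broken by gene identifier so
the ranking is total). The enrichment score of a gene set is the weighted
Kolmogorov–Smirnov running sum with weight exponent 1 (the cited method's
default): member genes add |score|/Σ_members|score|, non-members subtract
1/(N−m), and ES is the signed maximum deviation, in [−1, 1]. If every
member score is zero the hit weights fall back to uniform.

The null is "gene permutation" flavoured: per cell, `n_perm` (default 1000)
random same-size gene sets are drawn uniformly from the measured genes.
NES divides ES by the mean magnitude of same-sign null scores; the nominal
p-value is the add-one tail fraction among same-sign null scores; the FDR
q-value follows the NES-pooled procedure of the standard GSEA method,
computed within each cell across gene sets and separately by sign
(a Benjamini–Hochberg variant on the nominal p is available as a
cross-check). A (cell, set) result is significant when FDR ≤ 0.50 and
nominal p < 0.05; for recruitment-style summaries the quantity of interest
is the positively enriched significant fraction per cluster, and cluster
NES distributions are compared by two-sided Mann–Whitney tests.

Known property of the gene-sampling null: it is exchangeable over genes, so
a gene set whose members are systematically more expressed (hence more
variable in deviation score) than average is anti-conservative under it —
uniformly drawn sets are calibrated (~5% of cells flagged at the rule's
p < 0.05 under the simulated null), whereas expression-biased sets inflate
the flagged fraction. This is intrinsic to gene-permutation GSEA, not a
defect of the implementation, and is why the null-calibration experiments
draw their sets uniformly.

## The synthetic-data generator

Repertoire: clones draw donor, V/J segments per chain from a bundled
synthetic germline library (6 heavy V, 3 heavy J, 4 light V, 3 light J; V
segments share a fixed 300-column gapped layout with loop gaps centred in
CDR1/CDR2), and a random CDR3 per chain (length a multiple of 3 in 30–60 nt).
Clone sizes follow a truncated power law with α = 2 (skewed, as real
repertoires are) after seeding every clone with one cell; `uniform` is
available. Somatic hypermutation is i.i.d. per-base substitution on the V
region (default rate 0.02/nt) recorded in the mutation table — no indels and
no hotspot model, since the downstream statistics consume substitution
counts only.

Separability is engineered, not left to chance: each clone owns a mutable
CDR3 position set of size ⌊divergence × length⌋ per chain and cells vary
only inside it, so intra-clone identity is ≥ 1 − divergence on every chain
(the naive reading — each cell independently mutated — would only bound
pairwise divergence by twice the per-cell value). Decoy clones share donor,
V/J and CDR3 lengths with a partner but differ at ⌈(1 − ceiling) × length⌉
positions per chain; configurations must satisfy
ceiling + 2 × divergence ≤ identity threshold, which bounds worst-case
cross-clone identity at the threshold so strict clustering can never merge
them. Nuisance structure exercises contig selection: a configurable fraction
of cells lack a light contig (default 10%, mirroring the share of cells
real pipelines fail to annotate with a full receptor), and a fraction carry
an extra heavy contig that is unproductive, partial, or a corrupted
low-abundance duplicate — none of which may ever win selection.

Expression: negative-binomial UMI counts with gene-wise log-normal baseline
means (median 0.5 counts/cell, log-SD 1), per-cell log-normal library-size
factors (log-SD 0.3), and common inverse-dispersion 10. Modules of member
genes are upregulated by exp(log-fold) in their target clusters only;
member genes are drawn from genes whose baseline mean is at least 0.5 —
marker genes of real cell states are expressed genes, and a doubling of a
0.02-count gene is not recoverable at any realistic depth. Clusters are
equal contiguous blocks; a configurable fraction of genes is labelled
mitochondrial for QC plumbing.

What the simulations do not emulate: V(D)J junctional biology (TdT,
palindromic nucleotides), indel hypermutation, isotype class-switch
dynamics, batch effects, cell-type mixtures within clusters, and
gene–gene correlation beyond the planted modules. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated generative assumptions, not performance on real data.

## Verification experiment sizes

The shipped verification suite uses problem sizes chosen to make each
property measurable with comfortable statistical margin on a single CPU:
500 random candidate groups of ≤ 10 cells against an exact-arithmetic
complete-linkage reference; 50 seeded repertoires (60 cells, 10 clones,
divergence 0.10, decoy ceiling 0.60) for exact recovery; 500 null datasets
of 600 cells, 200 families and 4 clusters at 200 permutations for
overlap-test calibration — at coarser granularity (e.g. 200 cells, 50
families) the discreteness of the overlap statistic pushes the test's
empirical type-I error below 3%, so the finer design is the informative
one; 1000 random ranked lists of 2000 genes for the ES oracle; and planted
modules of 50 genes at natural-log-fold 1.0 in 2000-gene matrices (1000
cells for signature derivation, 500 for per-cell GSEA at 1000
randomisations).

## Known limitations

- Complete-linkage agglomeration approximates the clique-cover formulation;
  partitions are order-canonical but not guaranteed optimal in family count.
- The Simpson convention (with replacement) and the GSEA randomisation
  flavour (gene sampling) are defaults among defensible alternatives; both
  alternatives are implemented behind flags.
- The FR-region mutation-rate estimator treats all positions as equally
  mutable; with hotspot-biased mutation it remains unbiased for the mean
  rate but understates per-cell variance.
- Public-clone matching cannot distinguish convergent from truly clonal
  sequences; it is a similarity screen, not a specificity prediction.
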