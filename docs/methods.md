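# Methods

This note documents the model implemented by the package, the parameters
that matter, the synthetic study the tests run on, and the numerical and
design choices made where more than one reasonable option existed.

## Pathway model

A signaling pathway is a chain L → R → EM → T: a ligand emitted by a sender
cell group binds a receptor on a receiver group, the receptor relays to an
effector molecule (kinase, second messenger, transcription factor), and the
effector regulates a target gene. Admissibility requires each consecutive
pair to be documented in the corresponding interaction-database layer, the
ligand to be a sender gene, the downstream components to be receiver genes,
and R, EM, T to be pairwise distinct. The ligand may coincide with a
downstream component (receptors can be re-used as effectors in autocrine
contexts); `exclude_ligand_overlap=True` forbids it. Autocrine pairs
(sender = receiver) are enumerated by default. Longer chains are represented
implicitly: the RE and ET layers may contain indirect interactions, so one
RE edge can stand for a multi-step relay. The LR layer is restricted to
direct physical interactions by construction.

Kinase-substrate predictions can be appended to the database against its
*unmodified* snapshot: a receptor substrate adds a receptor→kinase RE edge,
an effector substrate adds kinase→EM (RE) and EM→kinase (ET) edges, a
target substrate adds a kinase→target ET edge. A substrate holding several
roles triggers every matching rule. An alternative reading of the fourth
rule (treating it as a second effector rule) is available via
`em_rule_literal=True`; the default covers the target role, the only role
otherwise unaddressed, which keeps the rule set symmetric.

## Average expression

Counts are normalized per cell to a fixed library size of 10 000 followed by
log1p — the ubiquitous normalization of the single-cell ecosystem (tested
against scanpy's implementation). Group-level average expression is Tukey's
trimean AE = Q2/2 + (Q1+Q3)/4 of the normalized values, a robust location
estimate that discounts the heavy tails of droplet data. Quartiles use
linear interpolation of order statistics (NumPy's default `method="linear"`,
configurable); the convention is pinned because it shifts AE slightly and
reproducibility requires one fixed choice. AE is computed on the
log-normalized scale directly, not de-logged. Cells present in the matrix
but missing from the annotation are a hard error — silently dropping them
hides label bugs.

## Signaling probability

P is the product of three Hill factors h(x) = x^N/(x^N + Kh^N) evaluated at
the consecutive expression products (AE_L·AE_R, AE_R·AE_EM, AE_EM·AE_T),
with N = 2 and Kh = 0.5 by default. P ∈ [0, 1); any silent component forces
P = 0. Kh rescales absolute probabilities without changing their ordering
across pathways, so it is effectively a display parameter.

## Significance

Per condition, the group labels of that condition's cells are permuted
M = 100 times and P is recomputed; p = #{m : P(m) > P_obs}/M with strict
inequality and no (M+1) correction, so p = 0 is attainable. One shared set
of M permutations serves every pathway of a condition — the marginal null
is identical per pathway and the cost drops by the pathway count.
Benjamini-Hochberg adjustment (via statsmodels) is applied once per
condition across all tested pathways; padj < 0.05 flags significance.

*Degenerate ties.* When a pathway's probability is constant across
permutations (e.g. every component's trimean is 0 because the genes are
detected in under a quarter of cells), the strict inequality yields p = 0
and the pathway is flagged significant despite carrying no signal. This is
a property of the printed counting rule, kept deliberately; consumers
should read significance jointly with the probability itself (the filter
`min_probability` exists for exactly this). The null-calibration test
therefore simulates genes at mean 2 counts/cell, where the statistic is
continuous and the test is calibrated (empirical type-I ≈ 5/(M+1) ≈ 0.05).

## Differential scores

The adjusted fold change aFC(x, y) = log2(x/y) · min{2·max(x,y)²/(max(x,y)²
+ a²), 1} shrinks fold changes between two values that are both small
relative to the threshold *a*, killing the "10⁻⁴ vs 10⁻⁶" false positives
of the raw log ratio. *a* defaults to the 75th percentile of the pooled
positive values of the quantity being compared — signaling probabilities
for T-PDS, pathway-component levels for each modality — so the smallness
notion lives on each quantity's own scale; a fixed override is available in
the config. Zeros entering an aFC are replaced by the smallest positive
observed value of that quantity × 10⁻³ (pseudo-count policy).

T-PDS is the logistic transform 2/(1+exp(−k·aFC)) − 1 of the probability
aFC, k = 2; an aFC of 1 (a doubling) maps to ≈ 0.7616. P-PDS and the
per-dataset Ph-PDS average the same transform over the four components'
modality levels (ligand read in the sender group, R/EM/T in the receiver
group). A component missing from a modality contributes 0 to the 4-term
average — the denominator is *not* renormalized — and a per-record coverage
field reports how many of 4 were measured, so sparsely covered scores are
visibly diluted rather than silently extrapolated.

The multi-modal score is DS = T-PDS + Σᵢ λᵢwᵢ·(modality score), λᵢ the
availability indicator and wᵢ = 0.5; conflicting modalities cancel by
construction. K-PDS picks the SiK-score of the condition DS says is
dominant (their mean at DS = 0). The final score is
PDS = DS + w₄·K-PDS·sign(DS), sign(0) = +1, w₄ = 0.5: the kinase term
reinforces whichever condition dominates. Adding it always with a plus sign
would drag condition-2-dominant (negative-DS) pathways toward zero, i.e.
kinase *support* would weaken the call; this is judged an unintended
artifact of writing the formula for the positive branch, so the sign-aware
form is the default and the literal form is kept behind
`ScoringConfig(pds_literal=True)`.

## Exclusiveness index and kinases

EI of a gene in a focal group is 0 when expression is flat across groups, 1
when the focal AE exceeds α (= 10) times the second-highest group, and
otherwise 0.99 · (AE_focal − min)/(max − min). The second-highest value is
the second order statistic with ties allowed: two groups sharing the
maximum make EI = 1 unattainable. Signaling-involved kinases (SiKs) are
pathway components predicted to phosphorylate another component of the same
pathway; each pathway has six ordered candidate pairs (R→EM, R→T, EM→T,
EM→R, T→R, T→EM) and SiK-score = Σ χᵢ·EIᵢ/6 with χ the prediction indicator
and EI that of the *kinase* gene in the receiver group (the formula's
reading; the motivating prose mentions substrate expression, but the
formula governs). Predicted kinases of a component that are not themselves
pathway members are signaling-related kinases (SrKs): the top-EI SrK per
component is annotated (EI maximized over conditions, for a single compact
column) and excluded from scoring.

## Debulking

Bulk (phospho)proteomic values are allocated to cell groups proportionally
to each gene's share of raw transcript counts aggregated per (gene, group,
condition); a zero aggregate is imputed to 1 before proportioning, so
shares are always positive and allocation conserves the bulk value exactly
(Σ_groups allocation = bulk, tolerance 10⁻⁹). Imputation is applied at the
(gene, group, condition) aggregate — the granularity debulking consumes —
rather than per sample. Phosphosite features ("GENE_S473") use the whole
gene's transcript proportions; the gene symbol is the part before the first
underscore (configurable regex, since site-identifier dialects vary).
Condition-level modality levels are arithmetic means over that condition's
samples — at the typical n ≈ 3 replicates a robust mean buys nothing.
Within-plex TMT normalization and technical-replicate averaging are assumed
done upstream; the module accepts any strictly positive matrix.

## Synthetic study

The generator's defaults define the study the tests run on: 3 groups × 2
conditions × 500 cells each; two planted pathways (sender g1 → receiver g2,
one up-regulated in each condition, effect size 4 on the raw count mean —
ligand in the sender group, R/EM/T in the receiver group, applied before
normalization so effects survive it); 8 decoy chains over background genes
disjoint from planted genes; negative-binomial counts (constant dispersion
2, gene-level means log-normally jittered, σ = 0.3). Signal genes sit at
0.5 mean counts/cell while 20 "filler" genes at mean 50 carry the library
size, so normalized signal AEs land in the Hill factors' dynamic range
(products near Kh) as they do for sparsely detected signaling genes in real
data. Bulk matrices are per-condition pseudo-bulk sums × unit-mean
lognormal noise (CV 0.1, triplicates); exact zeros are nudged to half a
count to keep the matrices strictly positive. Kinase predictions make each
planted EM a SiK for its target and add decoy kinases (background genes
outside every chain) phosphorylating planted receptors, which become SrKs.

What the generator does *not* emulate: cluster substructure, batch effects,
ambient contamination, realistic dropout-vs-mean relationships, peptide-
level proteomics noise, or gene-gene correlation. Passing the recovery and
calibration tests therefore shows the statistical machinery behaves as
specified under its own assumptions — not that effect sizes of real
datasets are recoverable.

## Reproducibility and problem sizes

Every stochastic step flows from one integer seed (config `seed`;
permutations use a per-condition child generator, the simulator derives
per-modality streams). Runs are bit-reproducible given (inputs, config,
seed). The shipped test suite uses 20 seeds of the default study for
recovery, and 5 replicate null datasets × 40 chains × 2 conditions = 400
null pathways for calibration — sizes chosen to make the Monte-Carlo error
of the checked rates small relative to their tolerances.

## Known limitations

- The interaction database content is user-supplied; the package implements
  merge/filter/append mechanics only and ships no curated interactions.
- Per-gene differential expression annotation is a naive pseudo-bulk
  log2((mean₁+1)/(mean₂+1)) labelled `naive_fc`; it feeds no score.
- The permutation scheme permutes group labels within a condition only;
  condition labels are taken as fixed design, not exchangeable.
- p = 0 under ties (see above); interpret significance jointly with P.
- Exports are static JSON/CSV structures for downstream plotting tools; no
  interactive visualization is included.
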