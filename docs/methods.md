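# Methods

## Clonotype identity and QC

A cell's functional TCR is its dominant productive α/β chain pair. QC is
two-step: (1) contigs must be cell-associated, high-confidence, productive
and full-length, and their barcode must appear in the cell metadata
whitelist — the whitelist *represents* upstream scRNA-seq quality control
(gene-count, mitochondrial and doublet filters), which this package does
not re-implement; (2) per cell and locus, the dominant contig is the one
with the most UMIs, ties broken by read count, then by lexicographically
smallest nucleotide CDR3. The last tie-break carries no biology; it exists
so the selection is a total order and the pipeline is deterministic. Cells
lacking a surviving chain at either locus are dropped.

Clonotype identity is exact string equality of (V, J, CDR3) for both
chains. Nucleotide CDR3 is the default because it is the stricter
definition and matches how upstream assemblers distinguish convergent
rearrangements; `key_mode="aa"` switches to amino-acid grouping, which
merges nucleotide variants encoding the same CDR3 peptide. Dual-TCR cells
are deliberately out of scope: exactly one chain per locus survives.

## Diversity metrics

With clone frequencies pᵢ = copyᵢ/Σcopy and richness N:

- **clonality** = 1 − H/log N, H = −Σ pᵢ log pᵢ. The logarithm base cancels
  between numerator and denominator, so the value is base-invariant (tested
  to 1e-12). N = 1 is 0/0; a singleton repertoire is trivially even, so
  clonality defaults to 0 there, configurable to NaN for users who prefer
  explicit missingness.
- **Gini** = Σᵢ Σⱼ |pᵢ − pⱼ| / (2N²p̄), computed via the equivalent sorted
  form Σᵢ (2i − N − 1) p₍ᵢ₎ / (N²p̄) in O(N log N). It equals the
  Lorenz-curve formulation exactly, which the tests verify to 1e-9 against
  an independent trapezoid-rule oracle.
- **copy-number spectra** bin clonotypes at edges (1, 2, 11, 51), i.e.
  singletons, moderately expanded, and the two "highly expanded" regimes
  (copy number > 10, > 50). Bin counts sum to richness; proportions are
  cell-weighted.

Stratified summaries pool cells within each stratum before computing
metrics (pooled mode is the default; per-patient strata are the
`by=("patient", "timepoint")` special case). Strata with fewer than 3
clonotypes are flagged low-confidence rather than suppressed.

## Expansion classes

Classification is a function of whole-specimen (pre, post) copy numbers
only: novel expanded (0, ≥2), persistent expanded (≥1, ≥2, post > pre),
novel nonexpanded (0, 1), other. The four rules partition every valid
pair, which the tests verify exhaustively on [0, 50]². Clones with
pre ≥ 1, post = 0 fall in "other" but carry a `lost` tag so pre-treatment
contraction stays visible. Classes are assigned at the specimen level and
projected onto subsets — a clone spanning Tem and Tex keeps one class —
because the categories are defined on treatment timepoints, not on cell
states; per-subset copy numbers would conflate clonal dynamics with cell-
state transitions.

## Ro/e

Expected counts follow the chi-square independence model
E = (row total × column total) / grand total; Ro/e = O/E elementwise. The
expected-weighted row mean of Ro/e is exactly 1 by construction, a useful
internal check. Conditions default to response × timepoint, pooling
patients. No significance test is attached — the ratio is descriptive, and
"enriched" thresholds are presentation-layer decisions. The post−pre
difference of a ratio has no canonical definition; where a difference
column is wanted the package exports roe(post) − roe(pre) and labels it
interpretive.

## Sharing permutation test

The statistic is the shared-clonotype count between two subsets within a
user-chosen cell pool (one response × timepoint group, typically). The
null permutes subset labels over the pool, preserving subset sizes and the
clone structure of cells, and the p-value is the add-one estimator
(1 + #{null ≥ obs}) / (1 + n_permutations), so p ≥ 1/(n+1) and the test is
valid (super-uniform) under exchangeability. Because the statistic is a
small integer, the test is mildly conservative: calibration runs show
empirical type-I error of roughly 3–6% at nominal 5% depending on the null
family's discreteness. A Spearman correlation between the shared clones'
cell counts in the two subsets is reported descriptively alongside; it is
NaN when either count vector is constant. Neither statistic claims to
reproduce any published p-value — the upstream figure's test is not
specified — and both are labelled accordingly in outputs.

## Pathway scoring

Per cell, genes are ordered by descending expression with ties broken by
gene name (the gene list is pre-sorted alphabetically and the descending
sort is stable, giving one deterministic total order). With
k = ⌈top_fraction · n_genes⌉ (default 5%), the score is
AUC = Σ_{r=1..k} c(r) / Σ_{r=1..k} min(r, |S|), where c(r) counts set
genes among the top r. The score is rank-based, hence invariant to any
monotone transform of a cell's expression, and weakly monotone in the rank
of each set gene. The name-based tie-break matters mostly for sparse data,
where many genes tie at zero; with the default 5% threshold zero-tied
genes rarely enter the scored prefix. Group means are z-scored across
groups with the sample standard deviation; two-group contrasts use the
Welch (unequal-variance) two-sided t-test, with p = 1 by convention for
fully degenerate input. Significance tiers: ** p < 0.01, * p < 0.05, else
ns. Gene sets are user-supplied GMT files; the synthetic module plants its
own.

## Synthetic cohort generator

The generator emulates the study conditions: 5 patients (2 PCR, 1 MPR,
2 non-MPR), paired pre/post specimens of 2000 cells each, 14 T-cell
subsets with a fixed composition vector (Tn/Tem/Treg/Tex CD4 clusters,
seven CD8 clusters, two NKT, one proliferating cluster; baseline
proportions between 3% and 12%), and background clone sizes from a
discrete power law (zeta) with exponent α = 2.5 truncated at 100 copies —
a standard null for repertoire clone-size distributions.

Treatment effect is planted per specimen pair: 50 novel expanded clones
(post = 2 + Poisson(b−1)), 50 persistent expanded clones (pre ∈ {1,2,3},
post = max(2, pre + 1 + Poisson((b−1)·pre))), and 100 novel nonexpanded
singletons, with boost b = 5. Planted clones' cells choose their subset
with the target subset's odds multiplied by b (CD8 Tem-GZMA for PCR/MPR,
CD4 Treg-FOXP3 for non-MPR); background cells draw subsets independently
from the baseline composition.

Background carry-forward is a multivariate-hypergeometric subsample of the
pre-treatment background cell pool at the depth left after planting: each
background cell either persists or not, so a background clone's post copy
number never exceeds its pre copy number, and contracted/`lost`/"other"
clones arise naturally. This persistence-without-proliferation model is a
deliberate choice: under with-replacement resampling, ordinary sampling
noise pushes hundreds of background clones over the (post ≥ 2, post > pre)
threshold, i.e. the class definitions would label sampling fluctuation as
expansion. Fixing the expansion signal entirely in the planted clones
gives the generator an unambiguous ground truth: recovery precision and
recall are then meaningful at the clone level, and the end-to-end tests
require both ≥ 0.95 under the default conditions. The corresponding caveat
is stated below under limitations.

Synthetic CDR3s are random nucleotide strings, 27–45 nt in multiples of 3,
with V/J names from a small fixed vocabulary — enough for exact-match
clonotyping, with no biophysical realism intended. The amino-acid CDR3
column is a deterministic codon-indexed pseudo-translation (degenerate
like the real code, but not the real code). About 5% of cells get an extra
nonproductive contig and ~2.5% a weaker secondary productive TRA, so the
QC and dominance rules are actually exercised. The subset label of each
cell is drawn independently given its clone, so no *correlated* subset
preference exists between subsets — inter-subset sharing in synthetic
cohorts is null-like by construction, which is what makes the cohorts
usable for calibration checks of the sharing test.

The expression simulator draws negative-binomial counts (dispersion 2,
lognormal gene means), multiplies the two planted pathway sets' means by
(1 + δ) in designated cells (default: post-treatment non-MPR cells of
planted clones in the Treg subset), and gives a PDCD1-like marker positive
counts in 40% of Treg/Tex cells and 10% of others, exact zeros elsewhere.

Everything is reproducible from the configuration seed (per-patient
generators are spawned from a seed sequence), down to byte-identical
fixture bundles.

## Problem sizes in the test suite

The suite exercises the full default conditions where the property under
test demands them (20-seed recovery at 2000 cells/specimen; 200-dataset
calibration at 1000 permutations; 20-seed power runs at 500 cells/group)
and hand-sized fixtures everywhere else. The whole suite runs in well
under a minute on one CPU; the acceptance script completes in seconds.

## Known limitations

- Background clones cannot expand in the generator; real repertoires mix
  sampling noise into observed expansion, so real-data precision for
  expansion calls will be lower than the synthetic estimate. The synthetic
  results validate the bookkeeping, not the biological error rate.
- The sharing test's null is label exchangeability within the supplied
  pool; it does not model subset-specific clone-size distributions under
  the null, and its p-values are mildly conservative.
- Clonotype matching is exact; convergent or near-match TCRs (one-mismatch
  CDR3s, similarity networks) are out of scope.
- Composition analysis expects the caller to provide malignant/T-cell
  flags; no malignancy inference is performed.
- The pathway scorer implements one rank-recovery AUC; scores are
  comparable within a run, not across tools.
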