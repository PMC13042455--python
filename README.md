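# tcrdyn

Paired pre-/post-treatment single-cell TCR repertoire dynamics, as used to
study how neoadjuvant immunochemotherapy reshapes the T-cell compartment of
solid tumors. The package is for computational immunologists who have 10x
Genomics V(D)J contig tables and cell metadata for the same patients at two
timepoints and want to quantify clonal expansion and its cell-state context:
which clones grew, in which T-cell subsets, and with what transcriptional
program.

## What it computes

**Clonotype calling.** Two-step QC on contig tables: keep cell-associated,
high-confidence, productive, full-length contigs on whitelisted cells; then
pick the dominant TRA and TRB per cell (UMIs, then reads, then smallest
CDR3 as tie-breaks). A clonotype is the exact (V, J, CDR3) pair of both
chains; a clone's copy number is its cell count in a specimen.

**Diversity metrics.** For clone frequencies *pᵢ* and richness *N*:

- clonality = 1 − Pielou's evenness = 1 − (−Σ pᵢ log pᵢ) / log N
- Gini = Σᵢ Σⱼ |pᵢ − pⱼ| / (2 N² p̄)
- copy-number spectra over bins {1}, [2,10], [11,50], [51,∞)

**Expansion tracking.** Clonotypes matched across a patient's pre/post
specimens and classified: novel expanded (pre = 0, post ≥ 2), persistent
expanded (pre ≥ 1, post ≥ 2, post > pre), novel nonexpanded (pre = 0,
post = 1), other (with a `lost` tag for pre-only clones). Classes are
assigned per specimen and projected onto T-cell subsets.

**Composition and enrichment.** T-cell fractions per specimen with post−pre
deltas (specimens under 20 T cells excluded), and Ro/e — observed over
chi-square-expected cell counts per subset × condition.

**Clonal sharing.** Shared-clonotype counts between subsets with a
label-permutation p-value, p = (1 + #{null ≥ obs}) / (1 + n).

**Pathway scoring.** AUCell-style per-cell score: the AUC of the gene-set
recovery curve over the top 5% of genes ranked by expression, plus z-scored
group means, Welch t-tests, and grouping helpers for clone-size strata
(expanded: copy number > 2) and PDCD1⁺/PDCD1⁻ stratification.

**Synthetic cohorts.** A generator that emulates the study design (paired
specimens, PCR/MPR/non-MPR labels, 14 T-cell subsets, power-law clone
sizes) with planted novel/persistent expanded clones concentrated in a
CD8 Tem-like subset for responders and the Treg subset for nonresponders,
plus a toy expression matrix with planted pathway activity. Every stage of
the pipeline is testable against this planted truth.

## Worked example

```python
from tcrdyn import CloneTable, ClonotypeKey, clonality, gini, richness

key = lambda k: ClonotypeKey("TRAV1", "TRAJ1", f"A{k}", "TRBV1", "TRBJ1", f"B{k}")
t = CloneTable(("P1", "post"), {key("a"): 8, key("b"): 1, key("c"): 1})
print(richness(t), round(clonality(t), 4), round(gini(t), 4))
```

prints `3 0.4183 0.4667`: three clonotypes, with one clone holding 8 of 10
cells — high clonality (uneven frequencies) and high Gini (unequal clone
sizes). A uniform repertoire gives 0 for both.

The narrative scripts in `examples/` cover each capability;
`examples/07_synthetic_cohort.py` generates a two-patient cohort, runs the
full file-based pipeline and ends with

```
planted expanded clones recovered: 60/60 (false positives: 0)
```

— every planted expanded clone is recovered because, in the generator,
copy-number growth only ever comes from planted proliferating clones.

There is also a thin CLI (`tcrdyn clonotypes|metrics|dynamics|roe|sharing|
score|make-fixtures|run`); `tcrdyn run --config run.yaml` executes all
stages and writes a digest-bearing manifest.

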