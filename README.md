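# drivermod

Integrative discovery of candidate **driver genes of drug resistance** from
two-condition tumor genomics data: gene expression, copy-number segments,
and somatic mutations for a cohort split into (canonically) *resistant* and
*sensitive* groups.

The package is aimed at computational biologists analyzing heterogeneous
cancer cohorts — e.g. platinum response in high-grade serous ovarian
carcinoma — where within-group expression is multi-modal, copy-number
profiles of the two groups look alike, and mean-based differential
statistics (t tests, linear regression of expression on copy number) lose
power.

## Method

The workflow has three stages.

**1. Differential gene selection.** Genes enter the integrative analysis if
any of four criteria holds (union):

- expression differs between groups by Earth Mover's Distance with
  permutation FDR *q* < 0.1.  Per gene, each group's values are binned over
  the pooled range (100 equal-width bins) and
  `EMD = Σ_k |F_A(k) − F_B(k)|` is the 1-D optimal-transport distance
  between the two histograms — sensitive to any distributional difference,
  not only a mean shift;
- gene-level copy number (log2 ratio, obtained by overlap-weighted mapping
  of segments onto gene coordinates) differs by the same EMD test;
- amplification or deletion frequency (calls at log2 > 0.3 / < −0.3)
  differs between groups by more than 20 percentage points;
- the gene is somatically mutated in more than 2 % of a group's tumors.

**2. Module-network learning, per condition.** Selected genes are clustered
into co-expression modules (k-means on z-scored profiles); each module's
expression is explained by a binary regression tree whose internal nodes
split the samples on the state of a **candidate modulator** — a gene
aberrant at high frequency *within that condition* (mutation > 2 % or CNV
aberration > 70 %) — using its expression, CNV log2 value, or mutation
indicator.  Leaves pool all module-gene values over the leaf samples and are
scored by the normal-gamma log marginal likelihood

```
log m(x) = lnΓ(α_n) − lnΓ(α_0) + α_0 ln β_0 − α_n ln β_n
           + ½(ln κ_0 − ln κ_n) − (n/2) ln 2π
κ_n = κ_0+n,  α_n = α_0+n/2,
β_n = β_0 + ½Σ(x_i−x̄)² + κ_0 n (x̄−μ_0)² / (2κ_n)
```

Splits are accepted when the score gain exceeds a fixed penalty; learning
alternates tree search with exact reassignment of genes to the module whose
tree explains them best, so the total network score is non-decreasing.
Genes used as split variables are the condition's **modulators** — aberrant
genes that also control their module's expression, i.e. driver candidates.

**3. Comparative leave-one-out cross-validation.** Each iteration removes
one sample from each group and reruns the whole funnel (selection, both
condition networks).  The final **signature** is the set of genes appearing
as modulators in more than 80 % of iterations for the resistant condition
and at most 20 % for the sensitive one.

Because the method's original cohort-scale inputs are not shippable, the
package includes a first-class synthetic-data generator
(`drivermod.synthetic`) that plants known modulator→module programs —
including group-specific drivers, segment-level CNV, sparse mutations, and
a 30 % off-program (non-responder) subpopulation per group — so every stage
is validated against ground truth.

## Worked example

Generate a synthetic cohort with one shared, two resistant-only and two
sensitive-only planted drivers, then run the full pipeline:

```
$ drivermod simulate --out demo --seed 1 \
    --n-samples 60 --n-modules 5 --module-size 20 \
    --n-shared-modulators 1 --n-group-a-modulators 2 --n-group-b-modulators 2
wrote synthetic cohort to demo

$ drivermod all --expr demo/expression.tsv --seg demo/cnv.seg \
    --bed demo/genes.bed --maf demo/mutations.maf --labels demo/labels.tsv \
    --out demo/run --seed 1 --n-iterations 10
signature: 3 genes
```

`demo/run/signature.txt` then contains

```
G02_19
MOD01
MOD02
```

`MOD01` and `MOD02` are exactly the two planted resistant-only drivers
(`demo/truth.json`); `G02_19` is a gene from the module MOD02 drives,
picked up as a correlated secondary split.  `demo/run/crossval.tsv` holds the
per-gene modulator frequencies behind the signature (e.g. `MOD01  1.0  0.0`),
`ranking_<group>.tsv` the per-condition modulator tables, and
`manifest_all.json` the seeds, thresholds and input checksums needed to
reproduce the run.

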