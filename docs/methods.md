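# Methods

This note documents the statistical model, the tunable parameters, the
synthetic benchmark, and the numerical and design choices behind
`drivermod`, at the level of detail a user needs to judge what the results
do and do not establish.

## Differential selection

### EMD scoring

For gene *g* with values `x_A`, `x_B` in the two groups, the pooled finite
range is split into `n_bins` (default 100) equal-width bins; values equal to
an interior edge fall in the right bin and the last bin is right-closed.
With `F_A`, `F_B` the cumulative proportions of the two unit-mass
histograms, the score is `Σ_k |F_A(k) − F_B(k)|` — the 1-D
optimal-transport (Wasserstein-1) distance with inter-bin distance 1.
Measuring in bins rather than data units makes scores scale-free across
genes, which the cross-gene FDR estimator below requires; the
`emd_1d(values_a, values_b, bin_edges)` primitive, which takes explicit
edges, reports data-axis units instead (`× bin width`).

A constant gene scores 0.  Genes with more than 20 % missing values in
either group, or fewer than 2 non-missing values in a group, are excluded
(score and q-value NaN) rather than imputed: the EMD compares whole
distributions and tolerates unequal group sizes, so remaining missing
values are simply dropped per gene.

### Permutation q-values

Group labels are shuffled `n_permutations` times (default 100; group sizes
preserved) and all gene scores recomputed per shuffle.  For observed score
*s*: `FDR(s) = median_p #{scores in permutation p ≥ s} / #{observed ≥ s}`,
capped at 1.  A gene is called at every threshold at or below its own
score, so the reported q-value is the running minimum of FDR over
thresholds ≤ *s*, which is non-increasing in the score and assigns tied
scores identical q-values.  One hundred permutations resolve q-values to
roughly 0.01 granularity near the top of the ranking; the CLI warns below
100.  Selection uses q < 0.1 (strict).

### Frequency filters and thresholds

Gene-level CNV is the overlap-length-weighted mean of segment log2 ratios
over the gene's interval (1-based inclusive; BED input converted from
0-based half-open).  A gene fully covered by one segment takes that
segment's value exactly.  Calls: amplified iff log2 > 0.3, deleted iff
log2 < −0.3.  All selection thresholds are strict inequalities ("more
than"): log2 exactly 0.3 is neutral, a frequency difference of exactly
20 % fails, a LOO frequency of exactly 0.8 is excluded.  The mutation
filter (> 2 %) and the frequency-difference filter (> 20 %, amplification
and deletion tested separately, OR-combined) are evaluated per group; a
pooled-mutation variant and direction-specific CNV variants are available
in `SelectionConfig`.

Candidate modulators for a condition are genes with within-condition
mutation frequency > 2 % **or** amplified-or-deleted fraction > 70 %.  The
OR combiner is deliberate: the two routes admit different aberration
classes, and an AND rule would admit almost nothing at realistic mutation
rates.  An AND variant is available.

## Module networks

### Score

Each module's genes share one conditional distribution per tree leaf.  A
leaf pools `{x[g,s] : g in module, s in leaf}` and is scored with the
normal-gamma log marginal likelihood (conjugate prior on mean and
precision; parameters μ₀=0, κ₀=1, α₀=1, β₀=1).  Expression is z-scored per
gene across the run's samples before scoring so this prior is on the data
scale.  The closed form is validated against the sequential Student-t
posterior-predictive product to 1e-10.  An empty pool scores 0.

### Tree search

Greedy top-down: at each node every candidate modulator is tried with every
signal source it has — z-scored expression, CNV log2 ratio, mutation
indicator — at every midpoint between consecutive distinct signal values
(for a binary mutation signal that is exactly the 0.5 threshold).  A split
is kept when `score(left) + score(right) − score(node)` exceeds the penalty
(default 2.0 log-units, AIC-like; the structure prior is otherwise flat).
Regularization: `min_leaf` 5 samples, `max_depth` 3.  Ties break toward the
earlier candidate in the module's gain-ordered list, then the lower
threshold, making the search deterministic.  The greedy search is exact at
depth 1 (verified against exhaustive enumeration).

Missing signal values are imputed to the neutral state (0 on the z-scale /
neutral log2 / unmutated) before split search, so every sample can be
routed; the alternative — dropping samples per split — would make leaf
sample sets signal-dependent and the score non-comparable across splits.

A module member may act as a split variable for its own module through its
CNV or mutation signal, but not through its expression.  Cis drivers make
this necessary: a modulator's own expression typically joins the module it
drives, and banning the gene outright would remove precisely the genomic
aberration signal the method is designed to find.  Banning only the
expression signal removes the degenerate self-explanatory split while
keeping the cis-aberration parent admissible.

### Learning loop

1. Initial modules: k-means (fixed seed, 10 restarts) on z-scored gene
   profiles, `k = ceil(n_genes / 20)`.
2. Initial association: each candidate modulator is assigned to the module
   where its best single root split gains most (ties to the lowest module
   id; zero-gain candidates are still assigned); each module's candidate
   list is gain-ordered, and modules left without candidates receive the
   globally strongest 5.
3. Iterate: relearn each module's tree, then reassign every gene to the
   module whose current tree maximizes the gene's exact incremental
   contribution to the pooled leaf scores (sequential updates; ties keep
   the gene where it is).  Stop when no gene moves or after `max_iter`
   (default 20) iterations; an assignment-cycle guard stops at the
   best-scoring iterate.

Two details guarantee the non-decreasing score trace that is asserted on
every run: the freshly learned greedy tree is kept only if it scores at
least as high as the previous tree on the module's current membership
(greedy search does not dominate an arbitrary fixed tree), and sequential
exact reassignment can only increase the total.  Dropping a module emptied
by reassignment removes its split penalties and cannot decrease the score.

"Modulator" means any gene used as a split variable in the final network;
a roots-only mode is available (`root_only`).  The ranking orders
modulators by summed local split gains (leaf(left) + leaf(right) −
leaf(node) − penalty), which decompose the tree score exactly.

## Comparative analysis and cross-validation

The module-member gene list is computed once from the two-group funnel;
candidate modulators are recomputed within each condition; each condition's
network is trained on its own samples only.  Cross-validation removes one
sample from each group per iteration — a seeded random pairing, with
`min(n_A, n_B)` iterations by default and an all-pairs option — and reruns
selection plus both condition networks.  The signature keeps genes with
modulator frequency > 0.8 (strict) in the first condition and ≤ 0.2 in the
second; the sensitive-side tolerance exists because a gene can leak into a
handful of iterations through chance background mutations, and "not a
modulator of the sensitive group" is operationally "rarely one".  Failed
iterations (e.g. empty selection) are skipped and counted; more than 20 %
failures aborts the run.  Frequencies are over completed iterations, and
the signature is exactly recomputable from the stored per-iteration
modulator lists.

## Synthetic benchmark

The generator plants one modulator per module (CNV- and mutation-driven
programs alternating; amplifications and deletions alternating), drives it
in both groups or in one (shared vs. group-specific drivers), and emits the
exact file dialects the readers consume.  Default study conditions: 5
modules × 20 genes, 40 passenger genes, 60+60 samples, leaf-mean separation
3 × noise-sd, modulator aberration rate 0.85 (CNV) / 0.30 (mutation) within
the driving group, background rates 0.05 (segment CNV) and 0.01
(mutation), 30 % off-program fraction.

Heterogeneity model: an off-program ("non-responder") fraction of each
driving group's samples keeps baseline module expression regardless of the
modulator's state.  The aberrant samples are thereby split into two modes
(responders at +effect, non-responders at baseline), which flattens
group-mean differences to `(1−h)·p·effect` — the regime where t-type
statistics lose power but distribution- and tree-based methods do not.
This is a two-component mixture with shifted means, not a heavy-tail model,
so analytic expectations stay closed-form and are unit-tested.

CNV passengers are placed as genomic segments, not per-gene noise: whole
chromosomes are tiled with baseline segments (log2 ~ N(0, 0.03)) and
aberrations become separate segments covering the gene ± 50 kb, so the
segment-to-gene mapping is exercised and provably inverts the generator
(every gene lies inside exactly one segment).

What passing on this benchmark does **not** show: recovery at real-cohort
gene counts (tens of thousands) and the attendant multiple-testing burden;
robustness to assay artifacts, batch effects, or probe-level noise; correct
behaviour when modules overlap or drivers act combinatorially; or
calibration under correlated passenger genes.  Results on real cohorts
additionally depend on preprocessing choices the package does not make.

## Problem sizes and determinism

Validation runs use 10 seeded cohorts at the default conditions for driver
recovery, 10 (tests) or 5 (acceptance script) cohorts × 10 LOO iterations
for the comparative signature, and a 200-gene 20+20 null for FDR
calibration — sizes chosen so the whole suite runs on a laptop-class
machine in minutes while keeping Monte-Carlo noise well inside the asserted
margins.  Every stochastic step (generator, permutations, k-means, LOO
pairing) is seeded; the CLI forks one run seed into per-stage streams by
hashing fixed stage labels, so stage-level reruns are stable and two runs
with the same seed produce byte-identical artifacts.

## Known limitations

- The greedy tree search is exact only at depth 1; deeper programs are
  found when their marginal splits are individually favourable.
- The normal-gamma score favours small homogeneous leaves; with min_leaf 5
  a correlated non-candidate gene's expression can occasionally out-gain a
  true but unbalanced aberration split.  The LOO frequency filter is what
  removes such unstable splits from the signature.
- Candidate–module association happens once, before iteration; a candidate
  whose best module changes during reassignment is not re-associated.
- Single-condition runs cannot use aberrations present in fewer than
  `min_leaf` samples of that condition (e.g. a > (1 − min_leaf/n) aberrant
  CNV driver leaves too small a minority leaf).
- The LOO loop refits everything per iteration, so its cost is
  `iterations × (selection + 2 × network)`; the all-pairs variant is
  quadratic and intended for small cohorts only.
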