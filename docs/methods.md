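# Methods

`mirsynet` implements a serum-miRNA biomarker discovery analysis for
two-group microarray studies: a differential screen, correlation-stratified
classifier evaluation, a co-target synergy network, clique-percolation
modules and global topology summaries, plus a simulator that generates data
with exactly the structure the analysis assumes.  This note records the
models, the defaults, and the design choices made where the design was
genuinely open.

## Differential screen

Input is a miRNA x sample matrix of log2 intensities.  Preprocessing drops
probes whose missing fraction exceeds `max_missing_frac` (default 0.2; a
free parameter, since missing-value screening rules vary between labs) and
imputes remaining gaps with the probe median.

The default test is a **moderated t**: per-probe residual variances
s_g^2 (pooled two-group, df d = n1 + n2 - 2) are shrunk toward a prior
s_0^2 with prior df d_0,

    s_post^2 = (d_0 s_0^2 + d s_g^2) / (d_0 + d),
    t_g = (mean_case - mean_control) / (s_post * sqrt(1/n1 + 1/n2)),

with t_g referred to a t distribution on d + d_0 df (capped at the pooled
residual df across probes).  The prior is fit by moment matching on
log s_g^2: if z = log s^2 then E[z] and Var[z] are digamma/trigamma
functions of (d, d_0, s_0^2), giving closed-form moment equations solved
with a Newton trigamma inverse.  Zero-variance probes are excluded from the
moment fit.  On a frozen 6x8 fixture this implementation agrees with the
reference empirical-Bayes microarray fit to ~1e-12 relative on p-values;
the contract we promise is the shrinkage direction and null calibration,
not bit-level replication of any particular release.  A Welch
unequal-variance t (`welch_t`) is available as a fallback; for a probe
with zero variance in both groups, p = 1 when the means agree (documented
degenerate contract) and p -> 0 when they differ, an edge case the
moderated statistic never reaches because the prior keeps s_post > 0.

Probes pass the screen iff p < 0.05, |log2FC| >= 0.8 and BH FDR < 0.05.
Boundary conventions are strict `<` for p and FDR and `>=` for the fold
change.  log2FC is the difference of group means of log2 values; inputs
are assumed already log-transformed.  BH is the step-up definition
q_(i) = min_{j>=i} p_(j) m / j, capped at 1.

## Correlation strata and classifier evaluation

Pearson correlation (CE) is computed for all unordered pairs of the
screened miRNA set over **all samples pooled** (cases + controls).  The
sample subset for CE is not dictated by the screening thresholds
themselves; pooling is what makes a differential pair informative for
classification, and a per-group computation is available by subsetting the
matrix.  Missing values use pairwise-complete observations.  Pairs are
binned by sign and |CE| with default edges 0.6 / 0.7 / 0.8, giving six
strata; pairs at |CE| <= 0.6 are left unbinned, and |CE| exactly 0 or
undefined (zero-variance feature) pairs are excluded with a warning.

Feature sets (single miRNAs, pairs, stratum unions, combined panels) are
evaluated with an RBF-kernel SVM under stratified 5-fold cross-validation:
features standardised with training-fold statistics only, every sample
scored once out-of-fold, and the pooled decision scores fed to a single
ROC curve.  AUC equals the Mann-Whitney probability
(#concordant + 0.5 #tied) / (n_case * n_control).  SVM hyperparameters
default to C = 1 and the `scale` kernel-width heuristic
gamma = 1 / (n_features * var); they are recorded in the run summary.
Pooling scores into one curve (rather than averaging per-fold AUCs) was
chosen because it yields a single curve per feature set and is the less
optimistic of the two summaries at these sample sizes.

## Co-target synergy network

For a miRNA pair, co-targets are the exact intersection of the two target
sets in the consensus target map.  A (miRNA, gene) link enters the
consensus map when it appears in >= `min_db` of the supplied prediction
databases; the default is 4 ("more than three sources" read literally),
with `min_db=3` available for the inclusive reading.

For each pathway i the enrichment p-value is the hypergeometric upper
tail including the observed overlap,

    p_i = sum_{x=k}^{min(n, M_i)} C(M_i, x) C(N - M_i, n - x) / C(N, n),

with N the size of the target universe (the union of all consensus
targets, not the whole genome — a literal reading of "all targets"), M_i
the pathway size within that universe, n the co-target count and k the
co-target/pathway overlap.  The tail is an over-representation test; it
is evaluated through a log-space survival function and cross-checked in
the tests against exact enumeration.  Per pair, p-values are BH-adjusted
**across pathways within the pair**; an edge is created iff at least one
adjusted p < 0.05.  Candidate pairs default to all unordered pairs of the
screened set (an optional sampling mode covers sub-sampling workflows).
No |CE| floor is applied to edges; the CE annotation (sign and value) is
carried on each edge so downstream viewers can filter.

Pathway gene sets are restricted to the universe before testing;
pathways with no gene in the universe are skipped.

## Clique percolation and topology

CPM communities at clique size k are unions of k-cliques connected through
shared (k-1)-node overlaps; nodes may belong to several communities,
k-cliques to exactly one.  Implementation: pivoting maximal-clique search,
k-subset expansion (with a cap on the maximal-clique count as a guard),
then union-find keyed on shared (k-1)-subsets.  Default k = 3 — the
smallest nontrivial clique size and the common default; the pipeline
exposes k so module counts can be compared across k in {3, 4, 5}.

Topology conventions (the named statistics have no single canonical
formula, so these are pinned by oracle tests): unweighted shortest paths;
averages over node pairs within connected components; betweenness
normalised by (n-1)(n-2)/2 per component; closeness = reciprocal mean
distance to reachable nodes; clustering coefficient 0 for degree < 2;
average degree 2|E|/|V|.

## Synthetic data

The simulator emulates a two-arm serum microarray study: by default 38
cases vs 38 controls (a second supported arm is 10 vs 9), 900 probes,
baselines uniform on [6, 12] log2 units with Gaussian noise of SD 0.5 —
the noise scale and intensity range of the arrays are not published
quantities, so these are free parameters recorded in the config; 0.5 on
the log2 scale is a typical inter-array spread for serum arrays.  Planted
differential probes (default 20, alternating up/down at |log2FC| = 1.5)
shift the case-group mean.  Correlated blocks follow a unit-variance
latent-factor model

    x = baseline (+ effect) + noise_sd * (L * f + sqrt(1 - L^2) * eps),

so each probe keeps marginal SD `noise_sd` and two probes of a block have
expected CE = L^2 (loading L = 0.95 gives CE 0.9025, inside the top
stratum); correlation is induced by the factor rather than by a covariance
matrix so the structure is positive definite by construction.
Missingness is completely at random (no mechanism is assumed).

The annotation generator assigns each miRNA `targets_per_mirna` uniform
random targets from `n_genes`; each planted synergy pair shares exactly
`co_target_overlap` genes, all inside one designated pathway, with the
shared blocks of different pairs drawn from disjoint genes and the
remaining targets drawn away from every planted block — so non-planted
pairs share co-targets only by chance.

What the simulator does **not** emulate: probe-level scanner artifacts,
intensity-dependent (heteroscedastic) noise, batch effects, informative
missingness, serum RNA degradation, and the heavy-tailed target-count
distribution of real prediction databases.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated model, not the biological validity of any particular
marker panel on real cohorts.

## Problem sizes and determinism

The bundled experiments run at the study's own scale (900-1000 probes,
76 samples, 10-20 simulation seeds per experiment), which keeps the whole
suite and the acceptance script in the seconds-to-minutes range.  All
randomness flows from explicit seeds (`numpy.random.default_rng`,
stratified-fold shuffling); identical config + seed reproduces every
output byte-identically, and each pipeline run writes a summary recording
version, seed and all parameters.

## Known limitations

* The moderated fit assumes roughly Gaussian log intensities and a common
  variance prior across probes; strongly heteroscedastic arrays would
  need a mean-variance trend term, which is not implemented.
* AUCs from small cohorts (e.g. 10 vs 9) have very wide sampling
  variability; the pipeline reports the point estimate only.
* The synergy test conditions on the realised co-target set; it does not
  model uncertainty in target prediction itself.
* GEO series-matrix parsing covers the inner probe table and sample
  headers; platform-annotation blocks are ignored, and group labels must
  be assigned by the caller.
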