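# Methods

## The question and the quantities

A binding benchmark is a set of IC50 measurements for one (MHC allele,
peptide length) combination. A predictor's cross-validated AROC on such a
dataset is an *estimate* of its true performance; an independently
generated blind dataset for the same combination provides a second,
unbiased estimate. The analysis studies the signed deviation
`cv − blind` (in AROC units) across many dataset pairs, asks when it is
systematically positive (over-estimation), bands deviations into small
and large at the mean |cv − blind|, and models the probability of a large
deviation from dataset-composition features.

AROC is computed in Mann-Whitney form: binders are measurements with
IC50 strictly below 500 nM, lower predicted IC50 ranks as stronger
binding, tied predictions count one half. Single-class datasets have no
AROC and are excluded, not imputed. Pearson correlations are computed on
log10 IC50. Cross-validated performance pools the held-out predictions of
all five folds and scores the pool once.

## Similarity and the three fold strategies

Two peptides are similar iff they have equal length and ≥80% ungapped
positional identity. Redundancy reduction is Hobohm-1-like: peptides are
sorted by ascending neighbor count (computed once on the input; ties by
peptide string) and greedily accepted if dissimilar to all previously
accepted ones. For `cv_sr` the reduction runs separately within binders
and non-binders, so a binder similar to a non-binder can survive in both
classes — deliberate, since the evaluation classes are exactly those two
groups. For `cv_gs`, all peptides of a collection (pooled across alleles)
form an undirected similarity graph; connected components are clusters.
Clusters are processed largest first (ties by smallest member peptide)
and each is assigned whole to one fold: the allele with the most
measurements in the cluster is found (ties by allele name) and its
currently least-loaded fold taken (ties by lowest index), with running
per-(allele, fold) counts updated after each cluster. This greedy
least-loaded rule implements "as even as possible" without global
optimisation, bounds the per-allele fold-size spread by roughly the
largest cluster size, and makes a peptide's fold identical across all
alleles — the property a pan-allele method would otherwise exploit.
Random splits are shuffle-then-deal under a seeded generator, so fold
sizes differ by at most one.

## The stand-in predictor

The pipeline needs a trainable predictor, not a competitive one. A
position-specific scoring matrix is fit by ridge regression of the
transformed affinity `y = 1 − log(IC50)/log(50000)` (clamped to [0, 1];
1 nM → 1, 50 µM → 0) on one-indicator-per-(position, residue) encodings,
with penalty λ‖w‖² on the weights only (offset free), solved in closed
form by the normal equations. λ defaults to 1.0 on the transformed scale,
fixed rather than tuned, keeping every fit deterministic. The indicator
blocks make per-position weight offsets unidentifiable, so weight
recovery is assessed after centering each position's 20 weights.

## Composition features

Ten descriptors per (cv, blind) dataset pair: natural-log dataset sizes;
mean per-position Shannon entropy of the amino-acid distribution (nats;
0 for a constant set, ln 20 ≈ 3.00 for per-position-uniform sets); the
entropy of log10 IC50 binned into the five unit bins of [0, 5) (values
clamped into the terminal bins), computed for measured and predicted
affinities on both sides; and the bin-wise sum of minima of the cv and
blind affinity histograms (1 = identical distributions, 0 = disjoint).
Natural logs are used throughout — any fixed base only rescales features
and leaves the downstream logistic models invariant. Plug-in entropies
are biased low at small n; that bias is *information* here (small sets
genuinely cover less space), so no bias correction is applied.

## Reliability models

Each dataset pair is labelled `large` iff |cv − blind| strictly exceeds
the band threshold, which is frozen to the mean absolute deviation of the
reference method (equality labels small; a 1e-12 guard absorbs float
noise). Two-feature logistic regressions are fit by penalised maximum
likelihood on standardized features (means and scales from the training
split only) with a tiny ridge (1e-6) so complete separation at LOOCV
sample sizes cannot blow up the fit; scikit-learn's lbfgs solver does the
optimisation, verified in tests against statsmodels' unpenalised MLE and
the penalised score equations. Models are scored by leave-one-out AROC
with `large` positive. The exhaustive search evaluates all C(10,2) = 45
pairs, optionally restricted to cv-only or blind-only features. Presets:
the training-set model (log_size_cv, ent_meas_cv) and the blind-set model
(entss_bl, ent_pred_bl); the combined model takes the element-wise higher
probability of the two, with the held-out example excluded from both
component fits simultaneously (the only leakage-free reading). The
reporting split flags datasets with combined probability strictly above
0.2 as 'bad'.

Two estimator properties worth knowing: LOOCV held-out probabilities are
pessimistically biased (each held-out example's own class is
underrepresented by one in training), so under null labels the LOOCV AROC
sits *below* 0.5 rather than at it — tests assert no optimism rather than
exact chance; and with a single-class training fold (possible at n = 3)
the held-out probability falls back to a smoothed class prevalence.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with planted truth:

- **Sequences.** Per allele, each position gets an amino-acid
  distribution drawn from Dirichlet(α·1₂₀); α (default 5) controls
  evenness — α → ∞ approaches uniform sampling (entss → ln 20), small α
  gives motif-like concentration. A configurable fraction of peptides
  (default 0.1) are 1..⌊0.2 L⌋-point mutants of earlier peptides,
  guaranteeing ≥80%-identity clusters for 9-mers; a fraction (default
  0.1) is re-measured under a second allele's own planted model.
- **Affinities.** Planted per-allele PSSM weights ~ N(0, 0.25/√L) and
  offset 0.45 on the transformed scale, placing typical affinities around
  the 500 nM cutoff with both classes well populated; Gaussian noise
  (default sd 0.15) is added on the transformed scale — matching the
  regression's error model, rather than multiplicative on nM — and
  back-transformed IC50s are clipped to [1, 50000] nM.
- **Blind sets.** Fresh peptides from the same positional distributions
  and planted models, rejection-sampled so no blind peptide has ≥80%
  identity to any same-length cv peptide. In `historic` mode that is the
  only constraint; in `preselected` mode draws are additionally rejected
  until the measured IC50 falls in a window (default 100–1000 nM)
  bordering the binder cutoff, reproducing the affinity concentration of
  prediction-selected modern data. The rejection budget is 1000 draws per
  requested peptide, after which generation fails naming the constraint.

Defaults (two 9-mer alleles, 200 measurements, α = 5, noise 0.15) are a
mid-sized historic benchmark. The `benchmark_grid` used for the
reliability analysis instead centers on the real releases' averages
(cv 800, blind 300) and varies, one factor at a time: cv size 50–1600
fully crossed with planted affinity spread (0.5×/1×/1.5× the reference
weight scale) — the dominant axes of real benchmark heterogeneity — plus
small-blind rungs (50, 100), evenness rungs (α = 0.5, 2, 10) and
preselected-blind rungs (cv 100 and 800). Six replicates give 132 dataset
pairs, a scale chosen so the full grid runs in well under a minute while
keeping the LOOCV AROC estimates stable.

What the generator does *not* emulate: real allele-specific binding
motifs (weights are random, not PMBEC-like), non-linear residue
interactions (the planted model is exactly the model family the stand-in
predictor fits, so recovery is cleaner than reality), inequality-censored
measurements (qualifiers are carried but treated as exact), and
cross-laboratory assay heterogeneity. Passing tests therefore demonstrate
that the *pipeline* behaves as designed and that composition effects
alone reproduce the qualitative findings — not that the stand-in
predictor rivals published methods, nor the real-data AROC values, which
require the external predictors and the archived IEDB benchmark files.

## Numerical conventions and edge cases

Binder cutoff: strictly below 500 nM (exactly 500 is a non-binder).
Duplicate (allele, length, peptide) rows merge by geometric-mean IC50,
qualifier kept only if unanimous. Affinity log-bins are half-open [k,
k+1) with out-of-range values clamped. The one-sample deviation t-test
reports both one- and two-sided p-values (the strategy comparisons are
paired, one-sided in the direction "deviates less than cv_rnd");
zero-variance deviation vectors are reported as degenerate (t = ±∞ or 0)
rather than erroring. All randomness flows from explicit integer seeds
through numpy Generators; per-replicate seeds are derived with fixed
prime offsets and everything is reproducible bit-for-bit from the
top-level seed.
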