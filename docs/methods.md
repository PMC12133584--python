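# Methods

## Scope and inputs

`cpmkit` models a behavioral outcome from cortex-wide functional connectivity
(FC). Inputs are assumed preprocessed: per-subject symmetric parcel×parcel FC
matrices (any real scale; no Fisher-z or range constraint is applied), a
parcel→network atlas over the 12 canonical Gordon resting-state networks
(AUD, CO, CP, DAN, DMN, FPN, RSP, SAL, SM, SML, VAN, VIS; parcels may be
UNASSIGNED), and a behavior/covariate table keyed by subject id. Matrices are
vectorized to their strict upper triangle in row-major order, so a P-parcel
cohort has E = P(P−1)/2 edge features (55,278 for the 333-parcel atlas).
Subject ids must match one-to-one between connectomes and behavior; any
mismatch is an error rather than a silent drop. Symmetry is checked on read
(absolute tolerance 1e−8, configurable).

UNASSIGNED parcels' edges stay in the model input but are not lesionable:
lesioning is defined per named network, and how unassigned parcels should be
treated in a "cortex-wide" edge set is genuinely open; including them in
modeling while excluding them as lesion targets is this package's choice.

## The CPM pipeline

Per train/test split: (1) Pearson correlation of every edge with the outcome
across training subjects; two-sided p from t = r·√((n−2)/(1−r²)) with n−2 df.
Correlations are computed on raw scores (no rank transform). Constant edges
get r = 0, p = 1 with a warning; a constant outcome is an error. (2) Edges
with p < θ split by sign of r into positive and negative sets; θ defaults to
0.01 with 0.05 as the standard alternate. (3) Per-subject summary score:
combined = Σ positive − Σ negative (positive-only and negative-only modes
score one set). (4) OLS of outcome on the scalar score; at least three
distinct training scores are required. (5) Test subjects are scored with the
*training* masks and coefficients; split accuracy is the Pearson r between
predicted and observed test outcomes.

Splits are subject-level simple random 70/30 draws without stratification,
100 per run; duplicate training sets are rejected and redrawn. Each split's
RNG derives deterministically from (master seed, split index, attempt), so
any split is reproducible in isolation and the whole run is bit-reproducible.
A split whose required feature set is empty, or whose test-set correlation is
undefined (zero variance, ties), records a missing r, is excluded from the
mean, and is counted in the log; if more than half the splits fail, the run
aborts with guidance to relax θ. Reported accuracy is the mean of per-split r
— no MSE or q² by default.

External validation applies a model fitted on *all* source subjects (mask +
coefficients, serialized as JSON text) to a target cohort with the same
atlas, without refitting; it reports Pearson r and its two-sided parametric p.

## Permutation inference

The outcome vector is shuffled over subjects; the full cross-validated
pipeline — selection inside every split — reruns per permutation, and the
mean accuracy forms the null. The p-value is the proportion of null means
*strictly greater* than the observed mean (1000 permutations by default),
reported as "< 1/N" when no permutation exceeds it; the conventional
(k+1)/(N+1) estimator is available (`estimator="add_one"`). Bonferroni
correction over outcomes is min(1, m·p).

Two deliberate choices: permutations reuse the observed run's split
definitions, isolating the label shuffle as the only varying factor; and a
fast mode evaluates each permutation on the first k splits (logged
prominently) — the observed mean always uses all splits. The permutation
inner loop is algebraically vectorized: per split, the edge-outcome
correlations for *all* permutations are one matrix product, and selection is
applied through the equivalent critical |r| for θ at the training-set size.
The vectorized path is cross-checked against the scalar reference pipeline to
1e−12 in the tests. The type-I error of the whole construction (selection
inside CV, permutation outside) is verified empirically: over 200 null
datasets the rejection rate at α = 0.05 must land in the 95% binomial
interval [0.022, 0.085].

## Virtual lesioning

A lesion removes every edge *incident* to one network (either endpoint; a
within-network-only variant exists behind a flag) from the input edge matrix,
then reruns the full pipeline — re-selection included — with the same splits
as the intact run. Removing edges before selection follows from the goal of
measuring what the pipeline could still learn without that network; pruning a
fixed mask is available as a variant. Importance is the matched-split change
delta = r_lesioned − r_full, reported as mean ± SE over splits. Because no
named test accompanies published lesion tables of this kind, significance
uses a matched-split sign-flip permutation (10,000 flips, two-sided,
(k+1)/(N+1) estimator), Bonferroni-corrected over the 12 networks within each
(outcome, feature-set) family. Lesioning is evaluated separately for the
positive and negative feature sets; combined mode is computed but secondary.
Note that under the incidence rule, lesioning *either* endpoint network of a
concentrated edge cluster severs it — specificity claims should be read at
the level of network pairs.

Selection-fraction matrices summarize where features live: entry (A, B) is
the fraction of possible A–B edges selected, averaged over splits, per
feature set; edges touching UNASSIGNED parcels are not counted.

## Misclassification index and dissection

The outcome is median-split into low/high scorers (subjects exactly at the
median go low — a deterministic tie rule). For each left-out subject, 100
iterations each draw 80% of the remaining subjects, select edges against the
binary label (point-biserial correlation at θ), and train a linear-kernel
SVM (C = 1) on the standardized 2-D (positive-sum, negative-sum) score
representation; MI is the fraction of iterations misclassifying the held-out
subject. The SVM's representation, kernel, and the subsample fraction are not
dictated by the framework and are package choices (a raw-edge-input variant
exists behind `representation="edges"`). Iterations that cannot select any
feature or draw a single-class subsample fall back to the majority class and
are counted in the log. Each subject's iteration RNG is keyed on (master
seed, hash of subject id), making MI exactly invariant to input row order.

Dissection computes Pearson correlations (categorical covariates encoded as
lexicographic ordinal codes) in two families: MI vs covariate within low and
high scorers, and covariate vs outcome within correctly (MI < 0.5) and
frequently misclassified (MI > 0.5) subjects; strata with n < 4 or constant
variables are flagged not-computed rather than reported. Covariate-controlled
accuracy replaces each split's test-set correlation with the first-order
partial correlation of predicted and observed scores given the covariate
(regressing the covariate out of the outcome beforehand is the documented
alternative); the permutation machinery accepts the same covariate.

## Inverse model

A full-sample CPM is fitted on correctly classified subjects (MI < 0.4) and
applied to frequently misclassified ones (MI > 0.5), directly and with every
summary score negated before the *fixed* fitted linear map. Negating the
input of a fixed linear map negates the predicted-observed Pearson r exactly,
so r_inverted = −r_direct to machine rounding — the experiment is informative
through the *sign and size* of r_direct: strongly negative means the
misclassified subgroup's edge-behavior coupling opposes what the model
learned. A refit-after-inversion variant exists (under which the two
magnitudes can differ, since the inverted model is re-estimated).

## Synthetic generator

Each dataset draws a standard-normal latent trait c per subject. Planted
positive (negative) edges are baseline + β·c (− β·c) plus N(0, σ_e) noise;
non-planted edges are baseline + noise; per-edge baselines are N(0, 0.3) so
matrices look heterogeneous (edges are not squashed into [−1, 1] by default —
CPM is scale-free in edges; a tanh option exists). A *discordant* subject has
every planted coupling sign-flipped. The outcome is 100 + 15·z with z the
standardized sum of trait loading (1.0) and N(0, 0.5) noise — an
NIH-Toolbox-like scale. Covariates: parental SES couples to the trait at
+0.5 and antipsychotic exposure (months) at −0.5, *only in concordant
subjects* by default — the stereotype-breaking structure that makes
discordant subjects both mispredicted and exempt from the covariate-outcome
association; age, sex, race, PANSS scores, and head motion are drawn at
realistic marginals without trait coupling. The population correlation
between a planted positive edge and the outcome is
β·λ / (√(β²+σ_e²)·√(λ²+σ_y²)) — 0.4/1.25 ≈ 0.36 at the defaults — and the
generator is tested against this closed form at n = 5000 (±0.03).

Presets fix the study conditions: `study-scale` (92 subjects, the Gordon-like
333-parcel atlas with published community sizes and 47 unassigned parcels,
~1% planted edges split between DMN-VIS positive and SM-RSP negative),
`null` (β = 0, 46 parcels ≈ 1000 edges), `tiny` (24×20 smoke scale), and
`discordant` (92 subjects, 72 parcels, 120 planted edges spread over DMN-VIS
and DAN-VAN positive and SM-RSP and VIS-AUD negative, 30% discordant). The
discordant preset's planted density was calibrated once, by simulation,
against the observed misclassification structure in early-psychosis cohorts —
roughly one-third of subjects frequently misclassified, a classifier above
chance for the concordant majority — and then frozen; at a 1%-sparse planted
set the pooled point-biserial per edge (≈0.13 after 30% discordant dilution)
is too weak for selection at n ≈ 72, and the classifier degenerates to
chance for everyone, which is a statement about that configuration rather
than about the misprediction mechanism.

What the generator does *not* emulate: spatial autocorrelation of parcels,
site/scanner effects, FC-range marginals, non-Gaussian tails, or any
time-series structure. Benchmarks passing on it show the pipeline recovers
the structure it assumes at realistic n — not that real cohorts contain such
structure.

## Problem sizes and numerical choices

The test-suite simulations run at the smallest scale that preserves each
property being checked: the type-I benchmark uses 200 replicates × 200
permutations × 20 splits at ~1000 edges; recovery uses a 108-parcel atlas
(5778 edges) at the stated n = 92 and 1% planting; lesioning specificity uses
a 48-parcel, 12-network atlas over 20 replicates; misclassification
separation uses the discordant preset over 20 replicates at 30 iterations
(100 for the null-MI check, matching the MI definition's default). The
acceptance script runs the prediction arm at the full 92×333 scale and the
misclassification arm on the discordant preset. Seeds: one master seed; all
streams (splits, permutations, sign flips, per-subject MI) derive from it via
named SeedSequence spawn keys, so every stage is bit-reproducible and
replicate k of any simulation is independent of the others.

Tie and degeneracy rules are stated where they bite: at-median subjects go to
the low class; constant edges are never selected; empty required feature
sets, undefined test correlations, and constant test covariates record
missing values (never silent zeros); p-values of zero exceedances are
reported as bounds. Pearson r values are clipped to [−1, 1] against floating
point drift.

## Known limitations

Single linear summary-score model only — no ridge/regularized CPM, no
site-specific or subcortical variants, no parcel- or edge-level importance
beyond network lesioning, no SVM hyperparameter search, and no analytic
significance for mean-over-splits accuracy (permutation only). Whether
permutation nulls should re-draw splits per permutation is unsettled;
re-using the observed splits is the default and the alternative is a
one-line change around `splits_per_perm`/`generate_splits`. The incidence
lesioning rule cannot distinguish the two endpoint networks of a single
concentrated edge cluster.
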