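# Methods

## Model

Disease progression is modelled as an ordered accumulation of events over
R brain regions scored on the ordinal scale {0, 0.5, 1, 2, 3}. An event
is a region reaching integer severity level s ∈ {1, 2, 3}; level 0 is the
implicit baseline and is never an event. A progression sequence is a
permutation of the M = 3R events that respects, per region, the order
1 → 2 → 3. The stage axis runs 0..M: at stage k the first k events have
occurred and each region sits at the highest level it has reached.

Ratings are converted to per-level probabilities with a Gaussian kernel of
standard deviation σ = 0.5 centred on the rating, evaluated at the four
integer levels and normalised (densities, not CDF bins). The half-point
"sparse" rating 0.5 therefore splits evenly between levels 0 and 1, and a
missing rating is uniform over the four levels. Rating 0 is
kernel-converted like every other rating by default, so a pristine region
retains a little mass on level 1; a `hard_zero` flag instead pins rating 0
to level 0 exactly, for users who want the severity translation applied
only to positive ratings. The kernel width σ is the scale of rater
disagreement in rating units; 0.5 (one half-step) is the default and we
did not tune it.

The subject likelihood at stage k is the product over regions of the
probability of the implied level; the stage is marginalised with a
uniform prior over 0..M (stage 0 included, since subjects with no
detectable progression are a real category). The prior is a deliberate
choice — nothing in the data constrains it — and is exposed as an
argument. A C-subtype model is a mixture over sequences with fractions
f_c summing to 1; the dataset log likelihood is
Σ_subjects log Σ_c f_c · L(x | S_c).

All likelihood computation is in log space. Probabilities are floored at
1e-250 before logs so that deterministic inputs (noiseless synthetic
cohorts, hard-assigned zeros) cannot produce NaNs; the floor is ~200
orders of magnitude below anything the kernel produces for a 25-region
table, so it never affects the ordering of candidate solutions.

## Fitting

*Single sequence.* Multi-start greedy coordinate ascent: from a random
valid sequence, each event in turn is relocated to its best valid
position (all candidate positions are scored in one vectorised batch)
until a full sweep yields no improvement; the best of `n_starts` runs
(default 25) wins. Ties break toward the earliest position. On event
sets with M ≤ 8 the procedure matches exhaustive enumeration's global
optimum in ≈99% of random instances (the enumeration oracle is part of
the package and guarded at M ≤ 10).

*Uncertainty.* Metropolis–Hastings over valid sequences: the proposal
relocates one uniformly chosen event to a uniformly chosen valid
position; acceptance is min(1, L_new/L_old). Default 10,000 iterations
with 20% burn-in, thinned to at most 1,000 stored samples. The event ×
position frequency matrix of the stored samples backs the positional
variance diagrams. When a mixture is sampled, each subtype's chain
targets the sequence posterior of the subjects hard-assigned to that
subtype. The alternative — sampling one sequence under the full mixture
with the others fixed — was tried and rejected: a redundant component's
chain then wanders almost freely (the other component already explains
the data), overstating that model's sequence uncertainty and handing an
overfit mixture a spurious hedging advantage in held-out evaluation.

*Subtypes.* C subtypes are fit hierarchically from the (C−1)-subtype
model: for each cluster, random bipartitions of its members are tried, a
sequence is refit on each side, and the candidate model is polished with
hard-assignment EM (reassign each subject to its maximum-probability
subtype, refit each subtype's sequence by greedy ascent from its current
sequence, update the fractions). Fractions are add-one-smoothed cluster
shares, (count_c + 1)/(S + C) — the standard regularised multinomial
estimate — so a cluster that loses all its members keeps its last
sequence at a small nonzero weight and a mixture the data cannot support
degrades gracefully toward the smaller model rather than failing. On
single-subtype data the split sides typically both recover the one true
sequence, the tie-broken reassignment then empties one component, and
the fitted two-subtype model carries a near-dead component — which is
how CVIC sees the cost of the extra subtype (below). Subtypes are
reported sorted by descending fraction, and comparisons with ground truth
in tests are label-permutation invariant.

*Model selection.* CVIC(C) = −2 × Σ over 10 cross-validation folds of the
held-out log likelihood, computed by averaging each subtype's subject
likelihood over that subtype's MCMC samples and mixing with the fitted
fractions; the selected C minimises CVIC, with ties resolved toward the
smaller model. Folds are stratified by stage tertile of a preliminary
single-sequence staging so no fold is empty of a stage range. Two details
make the comparison across C well behaved. First, a redundant component's
diffuse conditional sequence posterior (sampled under the mixture
likelihood) is what penalises the larger model at held-out time — an
Occam factor: the dead component wastes mixture weight on sequences the
data reject. Second, within each fold the chains for every candidate C
share one random stream (common random numbers), so chain-to-chain Monte
Carlo noise largely cancels in CVIC(C) − CVIC(C′) instead of masking the
penalty, whose magnitude (≈ 2 × n × smoothed dead-component weight) is
only a few CVIC units at n = 200.

## Assignment and the two probabilities

Each subject gets the subtype maximising f_c · L(x | S_c), then the stage
maximising the stage posterior under that subtype, with the posterior
computed from the sample-averaged stage likelihood (integrate over MCMC
samples first, then normalise); ties go to the lower stage and lower
subtype index.

Two distinct probability summaries come out of a fitted model, and they
answer different questions:

* the **within-model fit probability** — the maximum of the subject's
  stage posterior under one group's model. It is bounded, comparable
  across models built on different region sets, and measures how
  *decisively* a model stages a subject. It is the feature fed to the
  logistic classifier and the quantity compared between heuristically
  classifiable and unclassifiable subjects. Being normalised within the
  model, it deliberately carries no information about absolute fit: a
  badly misfitting model can still be confidently peaked (usually at
  stage 0 or M).
* the **joint classification probability** — P(group g, stage k | x)
  normalised across every (group, stage) combination, with uniform stage
  priors. This is the quantity winner-takes-all classification feeds on,
  because it preserves absolute likelihood differences between group
  models. Group models built on fewer regions would otherwise enjoy
  systematically larger likelihoods (fewer ≤ 1 factors), so each model is
  completed to the shared region universe with a uniform 1/4 factor per
  region it excludes — the same convention used for a missing rating.
  A subject whose winning model stages them at 0 is "Unclassified" and
  excluded from classification metrics.

Subtype crossover detection traces the mean subtype-1 posterior across
assigned stages and flags any crossing of the 1/k chance level that lands
after stage 1 (k = 2 subtypes gives the 50% chance level); stages with no
subjects are skipped and reported.

## Classifiers

Winner-takes-all: argmax over group models of the joint max-stage
probability, with exact ties resolved by column order (a warning is
emitted). The logistic alternative is a multinomial L2 regression (lbfgs)
on the within-model fit probabilities, the winning model's stage, and age
at death; each of 100 repeats (configurable) draws an 80/20 split and
tunes C by inner 10-fold cross-validation over 10 *linearly* spaced
values between 1e-4 and 1e4 (log spacing available behind a flag;
the linear grid is the default deliberately, odd as it looks, to keep the
tuning procedure exactly as specified for the reference analysis).
Metrics recorded per split: accuracy, balanced accuracy (unweighted mean
of per-class recall), and weighted precision/recall/F1.

## Heuristic staging

A staging scheme is an ordered list of stages with member regions, stored
as editable YAML. A subject's composite score per stage is the mean of
their non-missing member ratings (a stage with all members missing is
undefined and flagged; missing members are excluded from the mean rather
than counted as 0, to avoid artificial under-staging). The subject is
assigned the highest stage m with composite ≥ 1 for stages 1..m; a
pattern where a later stage reaches threshold but an earlier one does not
is Unclassifiable; no stage at threshold is stage 0. A strict
greater-than variant is available behind a flag. The five bundled scheme
files are *provisional* region memberships reconstructed from the staging
literature — the exact published per-stage lists are not redistributed
here — and are marked as such in the files.

## Statistics

Stage–covariate associations use Pearson correlation by default
(Spearman optional). The classifiable-vs-unclassifiable comparison is a
Welch two-sample t-test on the within-model fit probability. Region-wise
subtype contrasts fit OLS of score ~ subtype + stage per region
(statsmodels), with the subtype regressor an indicator for the
largest-fraction subtype so a positive t means more severe pathology in
subtype 1; p-values are Benjamini–Hochberg corrected across regions.
Regions with degenerate designs are skipped with a warning.

## Synthetic cohorts

The generator draws, per subject, a subtype (mixture fractions), a stage
(uniform, or truncated geometric with parameter 0.08 — the default,
emulating the thinning of autopsy series toward late stages), sets the
true levels implied by the subtype's sequence at that stage, then flips
each observed rating to an adjacent point of the legal scale with
probability ε (0.5 sits between 0 and 1, so it is reachable from both;
interior levels split evenly between neighbours). Missingness is applied
per region; age at death follows intercept + slope × stage + N(0, σ_age).
Observation noise is adjacent-level flipping rather than sampling from
the Gaussian rating kernel the model assumes — a deliberate slight model
mismatch so that recovery results do not lean on a generator tailored to
the likelihood.

Three presets define the study cohorts: ALS-like (spinal-cord-first
sequence, n = 141, flat stage–age relation), FTLD-like (cortical-first,
n = 126, slope −0.25 y/stage), LATE-like (amygdala-first, n = 304, slope
+0.35 y/stage), over a 21-region battery with mean ages and post-mortem
intervals matching published demographics for such groups. Ground-truth
sequences are "staircase" interleavings of a region order (region i's
level-s event at rank position(i) + (s−1)·stagger), so early regions
worsen while later regions are still catching up. A few regions per
preset carry 35% missingness so the >25% exclusion rule is exercised
end-to-end (3 regions drop for the ALS-like cohort leaving 18, 1 for
FTLD-like leaving 20, 2 for LATE-like leaving 19 — 54/60/57 stages).

What the generator does **not** emulate: co-pathology mixtures, TDP-43
inclusion morphology, rater-specific biases, correlated missingness
(regions drop out independently), and non-linear stage-age dynamics.
Passing recovery tests therefore show the inference machinery is correct
and well calibrated under the stated noise model, not that real cohorts
will be staged this accurately.

## Validation studies and problem sizes

The standard studies (in `tdpstage.experiments`, reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) use 8
regions × 3 levels (M = 24), n = 200, ε = 0.1 with uniform stages for
recovery; 100 random instances at M ≤ 8 for the enumeration oracle;
3 × 100 subjects for classifier recovery at ε = 0.05 (uniform stages, so
classification is assessed along the whole trajectory); 10 seeded
replicates per truth for CVIC selection; and 500 null replicates × 20
regions for the false-discovery study. Recovery fits use 2–3 greedy
starts and 2,000-iteration chains (up to 800 stored samples): at M ≤ 24 more
starts change nothing (the oracle study shows the optimum is found
essentially always), while chain length matters for the CVIC comparison,
whose single-truth margin is small — the two half-data subtype sequences
are only slightly worse held-out than the one full-data sequence.

## Known limitations

* Hard-assignment EM is greedier than sampling fractions and sequences
  jointly; with strongly overlapping subtypes it can lock into a local
  split. Multiple split restarts mitigate but do not eliminate this.
* The MH proposal relocates single events; for very long sequences
  (M ≳ 100) mixing will be slow and chain settings should be raised.
* The joint classification probability's uniform completion treats a
  region a model excluded as fully uninformative under that model; if
  exclusion correlates with disease (regions missing *because* severe),
  this is generous to the smaller model.
* CVIC's single-truth preference rests on a small systematic penalty and
  is expected to mis-select occasionally (observed ~1 in 10 replicates).
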