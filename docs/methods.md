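# Methods

`lexcat` implements an analysis pipeline for lexical-categorization training
studies: scoring letter strings by word-likeness and categorization
uncertainty, extracting per-reader effect estimates from lexical-decision
response times with crossed-random-effects mixed models, and predicting each
reader's reading-speed training benefit with a consensus-nested leave-one-out
cross-validated model grid. This note documents the models, the synthetic
data generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Word-likeness and categorization uncertainty

Word-likeness is OLD20: the mean Levenshtein distance from a string to its 20
nearest neighbors in a reference lexicon of same-length words. When the
target is itself a lexicon word it is excluded from its own neighbor set;
otherwise every word would receive a spurious zero-distance neighbor and the
word/nonword contrast would be distorted. Edit distance uses unit
insert/delete/substitute costs without transposition. All strings are
upper-cased before comparison.

The lexical categorization model treats word/nonword decisions as a
classification on word-likeness. With class densities d_w and d_n (words and
nonwords) and prior pi, the posterior probability of "word" at word-likeness
x is

    p(x) = pi d_w(x) / (pi d_w(x) + (1 - pi) d_n(x)),

and the categorization uncertainty is the binary entropy H(p) in bits,
bounded in [0, 1] and maximal where the class densities overlap — the
inverted-U in word-likeness. Densities are Gaussian-kernel estimates with
Silverman's bandwidth on a 512-point grid spanning [min - 3h, max + 3h] of
the pooled samples; evaluation outside the grid clamps to the edge values, so
extreme strings inherit the heavier tail's posterior and the score is never
NaN. Densities are floored at 1e-12 before forming the posterior; if both
classes are below the floor the score is defined as maximal (1 bit) with a
logged warning. The prior defaults to 0.5, matching a training set with equal
word and nonword counts. Zero-variance samples fall back to a
minimum-bandwidth (1e-3) kernel.

Nonwords are derived from words: pseudowords replace every vowel with a
uniformly drawn *different* vowel (preserving the consonant skeleton, hence
pronounceable); consonant strings replace every vowel with a consonant
(unpronounceable). Both resample on lexicon collisions, up to 100 retries.
The vowel set defaults to A, E, I, O, U; umlauts are excluded from the
synthetic alphabet for portability. Nonwords have no corpus frequency; their
log-frequency is the pseudo-count-only value log10(1) = 0 (words get
log10(freq + 1) per million).

## Synthetic studies

The generator emulates the structure the analysis assumes, with every
planted parameter recoverable.

**Lexicon.** Unique fixed-length strings (default length 5, size 3110) with
a consonant-vowel alternation bias (85% compliance) and Zipf-biased letter
frequencies within each class. The letter-frequency bias matters: it
clusters words in edit-distance space the way morphology clusters a natural
lexicon, which is what makes uniform vowel substitution drift *away* from
the cluster and reproduces the empirical OLD20 ordering words < pseudowords
< consonant strings. Frequencies are Zipf (rank^-1), scaled to 1000 per
million at rank 1.

**Stimuli.** 2:1:1 words/pseudowords/consonant strings (study value: 1600
per session = 800/400/400), words drawn uniformly from the lexicon, nonwords
derived from vowel-bearing sampled words, all scored for OLD20, frequency,
and uncertainty (densities fitted on the stimulus set itself).

**Trials.** log RT follows a linear model with fixed effects on z-scored
uncertainty (+0.12), OLD20 (+0.02), log sequence index (-0.02), centered
session (-0.03), log frequency (-0.02), and deviation-coded lexicality
(-0.03), around an intercept of 7.0 (about 1100 ms — a language-learner
pace, chosen so that the 300/4000 ms analysis trim sits more than 3 SD from
the latent distribution and trims essentially only the contaminant; an
intercept near 700 ms lets the trim truncate the true distribution and
biases slope recovery). The uncertainty and session magnitudes follow the
coefficients reported for the preregistered experiment. Participants carry a
random intercept (SD 0.25) and random slopes for uncertainty (SD 0.05),
OLD20 and log sequence index (SD 0.02); stimuli carry a random intercept (SD
0.05); residual SD is 0.30. Accuracy is Bernoulli-logistic in uncertainty
(intercept 2.5, slope -1.5, about 92% correct at average uncertainty), and
error trials add +0.08 log-RT so the error regressor has signal. Two percent
of trials are contaminant fast guesses, uniform on (100, 300) ms, giving the
300 ms trim something to remove; implausible model RTs below 150 ms are
redrawn. Responses beyond the 10 s window are clipped and scored incorrect.
The phonics control arm zeroes the uncertainty effect while preserving
session learning. Stimulus order is freshly randomized per participant and
session.

**Outcomes.** The percent reading-speed change is planted as

    benefit = 23 + 150 * (uncertainty slope) - 8 * z(SLS_pre)
              - 15 * 1{week 2} + N(0, 25),

so responders are readers with strong uncertainty slopes, low incoming
reading speed, and first-week training — mirroring the direction of the
reported moderators. `config_for_planted_r2` rescales the noise to any
target signal share; the closed-form planted R² is validated against sample
regression. Pre-scores are counts (Normal(30, 8), floored at 5) under a 90 s
or 180 s test version; post = round(pre * (1 + benefit/100)).

**What the generator does not emulate.** Real RT distributions are not
exactly log-normal and real accuracy is not purely uncertainty-driven;
word-likeness in a natural lexicon carries morphological and phonotactic
structure only coarsely captured by letter-frequency bias; and the planted
benefit is exactly linear in its three drivers. Passing recovery tests shows
the estimators and the cross-validation machinery are correct under the
assumed model, not that the assumed model holds for any particular dataset.

## Preprocessing

Trials with RT outside [300, 4000] ms are removed; both bounds are kept
(the exclusion rule is read strictly as "below 300" / "above 4000").
Reading-speed counts from 90 s test versions are doubled to the 180 s scale;
a multiplier argument covers one-off administration corrections (e.g., a 25%
reduction for an over-time session). The outcome is the percent pre-to-post
change, tested against zero with a two-sided one-sample t test. Outliers are
flagged beyond mean ± k sample SD (default k = 2). RT is log-transformed
with the natural logarithm; the base only rescales coefficients.

## Crossed-random-effects mixed models

The group model fits log RT with the three-way interaction of uncertainty,
OLD20, and session (full factorial), plus frequency, lexicality, error,
log sequence index, and week where present; random effects are a participant
intercept with uncertainty, session, and uncertainty-by-session slopes,
crossed with a stimulus intercept (and a font-block intercept for the
font-change variant). Continuous predictors are z-scored per dataset,
session is centered numerically, binaries are deviation-coded; interactions
are products of the transformed mains. Standardization per dataset makes
BLUPs comparable across cross-validation folds.

Estimation is profiled REML on the penalized least-squares normal equations.
Random effects within participant use a *diagonal* covariance (uncorrelated
intercept and slopes): with up to ten slope terms at study sample sizes, a
full covariance is weakly identified, and simpler random structures were
also the preferred choice in this literature. Each variance block contributes
one relative-SD parameter theta; the bordered system

    [[Z*'Z* + I, Z*'X], [X'Z*, X'X]] [u; beta] = [Z*'y; X'y],  Z* = Z Lambda

is solved by dense Cholesky (the random-effect dimension at desk scale is a
few hundred), and the REML criterion log|Z*'Z*+I| + log|X'PX| +
(n-p)(1 + log(2 pi pwrss/(n-p))) is minimized over theta >= 0 with L-BFGS-B
(relative tolerance 1e-8, gradient tolerance 1e-6, at most 500 iterations;
cross-validation refits warm-start theta from the previous fold and use
1e-7/1e-5 — looser gradient tolerances were observed to pin small slope
variances to zero prematurely). Thetas below 1e-6 are pinned at zero with a
singular-fit warning. Fixed-effect covariances come from the profiled Schur
complement; t = FE/SE is reported without degrees-of-freedom approximations,
matching the |t| > 2 convention. The implementation reproduces statsmodels
MixedLM (participant-only random intercept) to four decimals and the
balanced-ANOVA moment estimator within 10%.

BLUPs (conditional modes) of the participant random effects are the
individual-difference features. For a participant held out of a fit, features
are the closed-form conditional modes given the training fit's fixed
effects, thetas, stimulus intercepts, and coding transforms — their data
enter no estimation, which is what the no-leakage tests assert. Shrinkage
guarantees BLUP variance never exceeds per-participant OLS slope variance.

## Feature pipeline and prediction

Level-1 features per participant: the random-effect BLUPs of the extraction
model plus incoming reading speed, training week, and the session-1 error
count. Level 2 expands all pairwise products ("A x B", name-sorted) and
filters with bidirectional stepwise linear regression minimizing AIC,
starting from the intercept-only model (forward step, then backward pruning,
ties broken by candidate name; exact duplicate columns dropped; collinearity
otherwise allowed, as only predictive accuracy matters). The Gram-matrix
formulation evaluates all forward candidates with one triangular solve.
Selections from the inner leave-one-out runs are aggregated by consensus: a
feature survives if selected in at least `cutoff` runs; the nine default
cutoffs are {5, 10, 15, 20, 30, 40, 50, 60, 70} (the grid prints only its
count and winner, so the intermediate values are a design choice).

The learner grid crosses 20 extraction models (five core structures for the
uncertainty/OLD20/sequence terms × four covariate sets, the most complex
being the winning full-factorial formula) × 9 cutoffs × 4 learners = 720
pipelines. Learners: multiple regression (pseudo-inverse OLS), SVM with
linear and radial kernels (cost 1, epsilon 0.1, radial scale 1/#features),
and a random forest (500 trees by default, ceil(p/3) candidate features per
split, seeded; reduced-scale runs use fewer trees). Features are
standardized inside each fold with training-fold statistics only.

Outer leave-one-out cross-validation yields one prediction per participant.
With nesting, an inner leave-one-out over the n-1 training participants
scores every grid point by squared error on the inner held-out participant
(failed fits score +infinity), and the *modal* winner across inner folds is
applied to the outer fold (ties: lowest mean inner error, then lexicographic
order). Without nesting, the single configured pipeline is applied with one
stepwise selection per training fold. Inner folds reuse the outer fold's
feature matrices: feature extraction never sees outcomes, so the inner loop
is purely hyperparameter consensus, and only the outer left-out participant
must be (and is) excluded from all fitting.

Evaluation: Pearson r between predicted and observed benefit, t =
r sqrt(n-2)/sqrt(1-r²), MSE, R² = r², and the Fisher-z 95% CI
tanh(atanh(r) ± 1.96/sqrt(n-3)).

A known property worth stating: under a null outcome, LOOCV predicted-vs-
observed correlation is slightly negative (a weak model's prediction tracks
the training-fold mean, which is linear in the held-out value with a minus
sign). Measured means are about -0.17 at n = 30 and -0.08 at n = 75; the
overfitting-control tests therefore run at the study-scale n = 75.

## Responder diagnostics

Observed responders have training effect strictly greater than zero.
Predicted responders meet the decision threshold (boundary inclusive). The
threshold maximizes Youden's J = sensitivity + specificity - 1 over
midpoints between sorted unique predictions plus the open extremes; ties go
to higher accuracy, then the smaller threshold. J is the standard
single-number sensitivity/specificity trade-off and yields a unique,
exhaustively verifiable optimum. Confusion metrics are rounded only at
reporting. The power of the two-sided one-sample t test uses the noncentral
t distribution with ncp = d sqrt(n).

## Problem sizes

Default generator values follow the study design (1600 trials/session, three
sessions, lexicon 3110). The test suite and the acceptance script run
reduced-scale studies chosen as the package's own desk-scale conditions:
group-model recovery at 30 participants × 400 trials × 2 sessions (50
seeds), BLUP recovery at 30 × 400, cross-validation recovery and null
control at n = 75 participants with truth-derived features (the CV machinery
is the object under test there; the mixed-model extraction path runs
end-to-end at n = 16 with a 2×2×2 grid and in the leakage tests).

## Known limitations

- The uncertainty estimator's density family and smoothing are a
  reconstruction; other kernel or parametric choices shift scores
  numerically while preserving the inverted-U.
- The diagonal random-effect covariance ignores intercept-slope
  correlations; fixed effects remain consistent, but correlated-structure
  BLUPs would differ.
- No degrees-of-freedom correction is applied to mixed-model t values.
- Stepwise AIC admits occasional weak noise candidates by construction; the
  consensus cutoff, not the per-run criterion, provides the stringency.
- LOOCV correlation is a noisy, slightly pessimistic estimate at these
  sample sizes; the nested consensus reduces but cannot remove selection
  instability.
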