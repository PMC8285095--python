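# Methods

This note documents the models, priors, numerical choices and known
limitations of `igt_pvl`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task environment

The payoff environment is the canonical 10-card cyclic IGT schedule:
decks A and B pay +100 per card with losses totalling 1250 per cycle
(A: five losses of 150/300/200/250/350; B: one loss of 1250), decks C and
D pay +50 with losses totalling 250 (C: five losses of 50; D: one loss of
250). Long-run net is −250 per 10 draws for A/B and +250 for C/D — the
defining advantage structure. The schedule is a value object
(`PayoffSchedule`) with CSV round-trip, so a lab's own payoff table can be
swapped in. Whether a given computerized IGT uses this fixed loss sequence
or a randomized variant differs across labs; the fixed cyclic schedule is
the default here.

Traditional scores: proportion advantageous over all trials, over trials
41–100 ("last 60") and over trials 21–100 (the windows used in the
literature disagree; both are reported), per-deck proportions, the
five-block learning curve, and the Net score `T*(2p - 1)` (so 30%
advantageous over 100 trials = −40, 80% = +60). Trial indices are 1-based;
block *b* covers trials `20(b-1)+1 .. 20b`; a final partial block is
dropped from the curve and logged. Polynomial trend tests over blocks use
orthogonal contrasts (centred Gram–Schmidt on powers of the block index,
which for 5 equally spaced blocks reproduces the textbook integer
contrasts) with the one-sample F on per-subject contrast scores,
df (1, n−1). Contrast scores below a relative tolerance of 1e−9 are
treated as exactly zero so that analytically flat curves yield F = 0
rather than floating-point noise ratios.

## PVL models

Four variants from two learning rules × two choice rules. Conventions:

- Net outcome `x = gain − loss` enters the utility (single-valence
  processing), scaled by 1/100 (`OUTCOME_SCALE`) so the power transform
  `x^alpha` operates on magnitudes near 1. `u(0) = 0` is enforced
  explicitly (the float expression `0**0` would give 1).
- Retention orientation: `A` is the delta-rule learning rate, and the
  decay-rule carry-over is `(1 − A)`, so that in both rules larger `A`
  means faster updating / shorter retention.
- Sensitivity: trial-dependent `theta(t) = (t/10)^c` with `c` in [−5, 5];
  trial-independent `theta = 3^c − 1` with `c` in [0, 5]. Both sit behind
  one `sensitivity()` function so alternates can be swapped.
- Initial expectancies are zero, so trial 1 always contributes log(1/4).
- Softmax is computed with max-subtraction; the likelihood accumulates
  `theta*(E_d − max E) − log(sum exp(...))`, which is overflow-safe for
  any finite `theta`.

The batch likelihood is a numba kernel looping subjects × trials; the test
suite checks it against an independently coded pure-Python per-trial loop
to 1e−10 on 200 random parameter/sequence/variant combinations. The
generative simulator uses the same single-step operations and a seeded
`numpy` Generator; identical seeds give identical sequences.

## Hierarchical estimation

Subject parameter vectors are independent truncated normals (bounds = the
parameter ranges); group means have uniform priors over the same ranges;
group variances are Inverse-Gamma(shape 5, scale 1). The reference
sampler is an adaptive random-walk Metropolis-within-Gibbs:

1. per parameter, a batched subject-level proposal (one likelihood
   evaluation for all subjects; out-of-bounds proposals auto-reject; the
   truncated-normal normalizing constant cancels);
2. a group-mean random walk (no likelihood needed — the data enter only
   through the subject parameters — but the truncation constant
   `Z(mu, sigma)` does not cancel and is included);
3. a group-variance random walk on `log sigma^2` with the IG prior and
   log-scale Jacobian.

Proposal scales adapt by Robbins–Monro (target acceptance 0.44, gain
`(iter+1)^-0.6`) during burn-in only, so kept draws come from a
fixed-kernel chain. Chains are seeded via `SeedSequence.spawn`, initialized
at jittered range midpoints with variances at the IG prior mean, and
re-initialized (up to 10 times) if the starting likelihood is non-finite.
Desk-scale defaults are 4 chains × 2,000 kept after 1,000 burn-in;
`MCMCSettings.published_scale()` holds the 4 × 75,000/25,000 configuration
(300,000 combined draws) used in the source analyses. The sampler
contract is only "seeded draws from the stated posterior", so a
gradient-based backend could be substituted without touching callers.

DIC uses `Dbar` (mean over kept draws of −2 × total log-likelihood,
thinned evenly to at most `max_draws=4000` draws) and `D(theta_bar)` at
the per-subject posterior means of the constrained parameters — the point
estimator is recorded in the result object since other plug-ins are
defensible. Draws with infinite deviance are excluded and counted; more
than 1% is a hard error. Comparisons across different cohorts are blocked
by a data fingerprint.

Convergence tooling: classic Gelman-Rubin `sqrt(Vhat/W)` (constant chains
are flagged, not reported as 1.0) and the Geweke first-10%/last-50%
z-score with window variances from a Bartlett-windowed (Newey–West)
spectral density at frequency zero, lag `sqrt(n)/2`. The convergence gate
used in reports: warn above R-hat 1.02, fail above 1.1.

## Posterior-propagating regression

Outcomes regress on the four PVL parameters, optionally plus age and
gender (screened by Pearson/point-biserial correlation at p < 0.10).
Priors: improper uniform on coefficients, Inverse-Gamma(3, 3) on the
residual variance (mean 1.5, variance 2.25). Per MCMC iteration one joint
draw of all subjects' PVL parameters is sampled uniformly from the stored
posterior (preserving cross-subject correlation), the design matrix is
rebuilt, and the regression parameters are drawn conditional on it. The
reference conditional draw is exact (normal for `beta | sigma^2`,
inverse-gamma for `sigma^2 | beta`); a Metropolis–Hastings option targets
the same conditionals and agrees within Monte-Carlo error. The PVL index
stream is seeded separately from the regression randomness, so different
regression specifications run under one seed consume identical PVL
parameter streams, and each chain uses an independent stream. Degenerate
designs are guarded: n must exceed the predictor count + 2, and a
zero-variance outcome is a hard error.

Credible intervals are central empirical quantiles with linear
interpolation between order statistics (so draws 1..100 give a 95%
interval of (3.475, 97.525)).

Propagation behaves like errors-in-variables on the design: intervals are
at least as wide as with a fixed design, and point estimates attenuate
toward zero as the PVL posterior widens. Consequently, power to *exclude
zero* for a true coefficient of −0.5 at n = 300 sits near 87% in the
package's own simulations (30 replicates at propagation SDs 0.10–0.15),
while coverage of the true value is essentially complete; calibration
under null effects is ~95–97% interval coverage of zero.

## Synthetic cohorts

The generator emulates the structure of a monthly-followed substance-using
cohort: per-subject PVL parameters from truncated normals, IGT sequences
simulated from those parameters, demographics (age normal, clipped to
18–90; gender Bernoulli, female = 1), linear outcomes with configurable
coefficients (all zero by default — the null construction) and normal
noise (SD 1.0), and monthly tables of substance-use days and four risk
behaviors. Randomness derives from one master seed via
`SeedSequence(master, spawn_key=(domain, subject))`, so adding subjects or
regenerating one table never perturbs another.

Three presets:

- `community()` (default moments): group means at the community sample's
  reported parameter medians (retention 0.208, consistency 0.353,
  attention to losses 0.192, attention to magnitude 0.556), SDs =
  IQR/1.349; age 43.1 (9.5), 21% female. Emulates gain-driven,
  loss-insensitive choice.
- `calibration()`: attention to losses near 0.9 (losses ≈ gains), younger
  and mostly female. Simulated cohorts from the two presets reproduce the
  qualitative performance contrast (community lower proportion
  advantageous).
- `recovery()`: means spanning the two presets' contrast and all group
  SDs 0.45, i.e. inside the bulk of the estimation model's IG(5, 1)
  group-variance prior. This is the preset for recovery studies: with the
  community preset's tight spreads (attention-to-losses SD ≈ 0.08),
  100-trial data barely identify the parameter, so rank-correlation
  recovery is noise; and when the generating variance sits in the far
  tail of the IG(5, 1) prior, the truncated-normal *location* posterior
  is prior-shifted away from the generating location (the location is not
  the population mean), making location-coverage checks uninterpretable.
  Recovery simulations in the test suite use 50 subjects × 100 trials
  (parameter recovery; desk-scale MCMC) and 40 × 100 over 10 replicates
  at reduced settings (model recovery), sizes chosen to characterize the
  estimator at laptop scale.

Substance-use days are zero-inflated: lifetime-use Bernoulli at the
configured prevalence (defaults near reported community rates: tobacco
0.92 … ecstasy 0.05), then monthly days Binomial(28, mean_days/28) for
users. Behavior occurrence uses a monthly rate chosen so the configured
*annual* any-occurrence prevalence holds (needle-sharing rare at 0.054,
pipe-sharing common at 0.616). What the generator does *not* emulate:
attrition and partially observed months, visit scheduling, within-subject
autocorrelation of use, reporting error, and any dependence of outcomes on
substance use itself — so passing tests demonstrate correctness of the
pipeline's computations and calibration under the stated generative model,
not robustness to those real-data features.

## Health-risk constructions

- Monthly harm score: published harm-to-self weight × days of use per
  28-day month, summed over substances (weights shipped in `HARM_INDEX`:
  tobacco 37.3, alcohol 56.1, crack cocaine 79.5, …). Non-28-day months
  are normalized to a 28-day rate. Unknown substances are a hard error
  naming the missing weight. Tobacco and prescribed methadone carry
  weights and are included by default; an exclusion list is available.
- Harm composite: mean over the months observed in the first study year;
  zero observed months excludes the subject.
- MAP index: of needle-sharing, unprotected sex, pipe-sharing and
  injection drug use, the count reported at least once in the year (0–4);
  recurrence never counts twice, and any observed month counts toward the
  window.
- Health-risk Index: "standardize the mean of the two components" is
  ambiguous; the default z-scores each component, averages, and
  re-standardizes the average, guaranteeing an exact z-score (mean 0,
  SD 1). The alternative (z-score the raw average) is behind
  `method="raw_average"`.
- Frequency codes: non-users 0; users rank-ordered and split into
  tertiles coded 1/2/3 by `ceil(rank / (n_users/3))` on average ranks, so
  tied frequencies always share a code (tie integrity beats group-size
  balance). With fewer than 3 users tertiles are undefined and all users
  are coded 2.
- EM imputation (questionnaire items, e.g. sensation-seeking scales):
  multivariate-normal working model, conditional-mean imputation with
  conditional covariances in the M-step, convergence when no imputed
  value moves more than 1e−6; observed entries are never modified;
  missingness above 5% (configurable) is a hard error recommending
  listwise deletion.

## Known limitations

- The random-walk sampler needs longer chains than a gradient-based
  sampler would for the same effective sample size; desk-scale defaults
  are sized for cohorts of tens of subjects.
- DIC is the only model-comparison criterion (by design); WAIC/LOO are
  out of scope.
- Alternative IGT models (EV, VPP, ORL) are not implemented; the
  `ModelSpec` seam is where they would go.
- The regression assumes a linear-Gaussian outcome; ordinal or count
  outcomes (e.g. the 0–4 MAP index used directly) are treated as
  continuous, as in the analyses this package mirrors.
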