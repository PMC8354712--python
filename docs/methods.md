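# Methods

This note documents the measurement conventions, the synthetic-cohort model,
the statistical machinery, and the design choices that were genuinely open.

## Task model and measurement conventions

Angles are degrees counter-clockwise from rightward horizontal, origin at the
start-point centre; the four target positions are 60°/240° (major mobility
axis, low cost) and 150°/330° (minor axis, high cost), at 10 cm with 1.5-cm
radius. Configurations pair adjacent positions: CONF1 {60,150} (upward),
CONF2 {150,240} (leftward), CONF3 {240,330} (downward), CONF4 {330,60}
(rightward) — every pair contains one LC and one HC target.

Hand traces are 100-Hz 2-D positions in cm. Conventions, each a named
configuration key with its task default:

- **start radius 0.3 cm** — the start point is a 0.6-cm-diameter disc;
  movement onset is the first sample strictly outside it.
- **stop threshold 0.04 cm/s** — "one pixel per second" converted via a
  20-inch 4:3 monitor at 1024×768 (~0.04 cm/pixel). Whether the original
  speeds were computed in screen or table coordinates is unknowable from the
  task description, so the key is exposed. Speeds use central finite
  differences on the 10-ms grid (one-sided at the ends). Movement end is the
  first post-onset sample below the threshold; it is a target hit if that
  sample lies inside a displayed target, else a missed-target candidate.
- **100-ms direction probe** — the initial-choice angle is the direction of
  the start-to-hand vector at the sample exactly ten frames after the onset
  sample (no interpolation). Position-based angles are robust at 100 Hz,
  where instantaneous velocity direction is noisy.
- **timing window ±150 ms**, inclusive at the boundary (only onsets strictly
  more than 150 ms from the go cue abort the trial, costing one point).
- **rescue radius 4 cm** — a missed movement ending within 4 cm of a target
  centre counts as finally choosing that target. The task description also
  phrases this as "1 cm around the edges", which is inconsistent with a
  1.5-cm radius; the 4-cm figure is taken as authoritative and both are
  configurable. Timing violations pre-empt all other exclusion labels; each
  trial carries exactly one exclusion reason.
- Success flags are defined only when a unique rewarded target exists
  (CONG/INCONG and rewarded 1T conditions). Initial success is judged on the
  ±45° quadrant even in 1T trials, whose *validity* window is ±90°; CTRL
  analyses use the LC-choice proportion instead.
- Points floor at 0 for slow movements; the −1 penalty applies only to
  timing violations. Rescued near misses still earn nothing (the reward
  required actually hitting the target).

## RT binning and the delay criterion

Success rates are per-subject percentages in thirteen 20-ms bins over
200–460 ms; bins are half-open `[low, low+20)` with the last bin closed —
edge handling is a convention, chosen so the bins tile the range. Trials
under 200 ms are dropped (the timed-response design makes them rare; see the
generator's RT model). Group summaries are unweighted means of subject rates
with t-based 95% CIs (`mean ± t(0.975, n−1)·SEM`); empty subject cells are
absent, never imputed. A condition *qualifies* at the earliest bin whose ci95
contains the criterion (95%). The delay between two conditions is the
difference of qualifying times, scoring a condition at its bin midpoint —
except a condition qualifying at the earliest analysable bin, which is
left-censored and scored at the bin's lower edge. With the faster condition
censored at 200 ms and the slower one qualifying at [340,360), the delay is
350 − 200 = 150 ms, carrying ±10 ms half-bin uncertainty.

## Statistics

- Pairwise comparisons: Shapiro–Wilk on the differences gates a paired t test
  (p ≥ 0.05) versus a Wilcoxon signed-rank test. The reported W is the
  positive-rank sum (bounded by n(n+1)/2). Paired Cohen's d is
  mean(diff)/sd(diff) — the variant is a convention, stated here. Bonferroni
  correction is min(1, m·p).
- Mixed models always include a subject random term. The gaussian family
  wraps statsmodels' MixedLM, fitted by ML so AICs are comparable across
  fixed-effect structures; random slopes via `re_formula`. The binomial
  family is a random-intercept logistic mixed model on per-subject-per-bin
  proportions weighted by trial counts, with the subject intercept
  integrated out by **adaptive Gauss–Hermite quadrature** (nodes recentred
  and rescaled at each subject's posterior mode; non-adaptive quadrature
  undersamples the sharply peaked integrand once subjects contribute
  hundreds of trials). Its log-likelihood is reported relative to the
  saturated model — the lme4/jamovi convention — which leaves AIC
  differences unchanged; the implementation is cross-checked against
  lme4::glmer in the test suite. Random slopes are not supported for the
  binomial family (the fit records a note); exact replication of any
  particular GLMM software's denominators and p-values is a non-goal.
- Marginal/conditional R² follow the Nakagawa variance partition, with π²/3
  as the binomial latent-scale residual variance.
- AIC selection returns the lowest-AIC fit; ties break toward fewer
  parameters; fits on different responses or data sizes are incomparable and
  raise.

## The synthetic cohort

The generator is a seeded forward model of a full study: 22 subjects ×
1,200 trials (720 two-target, 480 one-target, six blocks of 200), scheduled
pseudo-randomly so no condition repeats consecutively and a two-target trial
never re-shows the immediately preceding one-target trial's target. The
per-cell trial counts adopt a 60-trials-per-cell granularity (CONG and
INCONG: 60 per configuration; CTRL: 30 rewarded + 30 unrewarded per
configuration; 1T: 60 per position × colour); the exact interior split is
not dictated by the task description, so the balanced default is an
assumption.

**RT model.** Intended onset is go + N(0, 50 ms), but a movement cannot start
before the target has been processed for a per-trial floor ~ N(205, 15) ms.
The floor reproduces two structural facts of the timed-response design:
reaction times below 200 ms are rare, and the latest-appearing targets
(100 ms before go) cap RT at ≈250 ms. Plain gaussian jitter around the go
cue cannot produce that sparseness, since early-appearing targets would
otherwise yield many sub-200-ms RTs.

**Choices.** The probability that the initial direction lands in the
rewarded target's quadrant is a condition × RT-bin curve — the generative
quantity is exactly what the classifier measures. The default calibration
encodes the published bin-level structure: CONG at 0.944 in the first bin
and 0.955 after; INCONG = CONG minus the published binwise gaps
(41.5…10.5 points) through bin 7, 0.914 in bin 8, then relaxing linearly to
0.95; R-LC = CONG (the two 1T cost classes are indistinguishable from their
2T counterparts where stated); R-HC = INCONG plus the published
INCONG-vs-R-HC differences. CTRL trials instead use a per-configuration
LC-preference (default 0.75 — no proportion is printed; chosen as a clear
but non-saturated bias consistent with the reported signed-rank statistics).
Unsuccessful one-target trials start 50–88° off-target: outside the scored
quadrant but inside the 90° validity window, so misdirected 1T trials are
measured rather than mostly excluded.

**Between-subject heterogeneity.** Each subject carries one ability offset
added to every cell probability (clipped to [0,1]). Offsets are on the
probability scale: a logit-scale offset with a mean-preserving intercept
compresses near the ceiling and cannot produce the published CI widths at
the published means. The cohort is a *stratified* sample — offsets sit at
the gaussian mid-quantiles — and each cell's centre is solved against the
actual offset set, so every configured cell mean is exact by construction
and the pipeline's recovered means converge to the curves as trials grow at
fixed cohort size (the round-trip consistency property). The offset SD
(default 0.12) is calibrated to the two published ci95 half-widths (≈3.7
points for first-bin CONG, ≈6 points for INCONG at [340,360) ms); one SD
cannot match both exactly and lands at ≈3.7/≈5.5.

**Traces.** Minimum-jerk paths toward the initially chosen direction with 8°
directional noise, time-shifted so the start-circle crossing lands on the
drawn onset sample (keeping generative and measured RT aligned to one
sample). Movement times are N(280, 40) ms for LC reaches and N(330, 40) for
HC — directions consistent with the reported cost effect on MT; no MT values
are printed, so these are assumptions and configurable. Change of mind is a
late in-flight redirection (after the 100-ms probe) toward the rewarded
target; the redirect probability is scaled by the population failure rate so
final-choice success exceeds initial-choice success by the configured gain
(default 2.6 points) in expectation. 9% of trials stop just outside the
target; 80% of those land inside the 4-cm rescue zone (the interior split is
an assumption). The null configuration sets every choice probability to 0.5,
no misses, no redirection, no heterogeneity.

**What the generator does not emulate.** Trajectory curvature and online
feedback corrections beyond the single scripted redirection; trial-to-trial
RT autocorrelation, fatigue, or learning (block effects are absent by
construction); off-quadrant starts (directional noise makes the ~0.3%
exclusion class essentially empty); biomechanically realistic arm dynamics.
Passing round-trip tests therefore demonstrates that the *pipeline*
faithfully measures what the forward model generates — not that the forward
model exhausts real reaching data.

## Problem sizes

The shipped analyses and checks run full-scale cohorts (22 × 1,200 trials;
a few seconds to simulate and process). Unit and property tests use 2–8
subject cohorts and 10,000-case brute-force oracles; the paired-test
type-I-error check uses 2,000 replicates.

## Known limitations

- The binomial mixed model supports random intercepts only; the gaussian
  path must be used when random slopes matter.
- The delay estimator quantises to the 20-ms bin grid by design; its
  sampling variability under the calibrated cohort spans one bin in extreme
  draws.
- Wald omnibus tests (not Satterthwaite F approximations) summarise fixed
  factors, so denominator degrees of freedom are not reproduced.
- `score_points` treats rescued near misses as unrewarded; if an analysis
  needs the opposite accounting, score from `final_choice` directly.
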