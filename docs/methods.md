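# Methods

## Scientific setting

Sham-controlled transcranial direct current stimulation (tDCS) studies
presume that a brief placebo protocol — same ramp-up, a short plateau at
full intensity, same ramp-down — is perceptually indistinguishable from
minutes of active stimulation. `shamblind` implements an in-task test of
that presumption for a two-session within-subject crossover: every 30 s
participants answer *"Is the stimulation on?"* (yes/no) and *"How sure are
you?"* (0–10 visual-analogue scale), while performing a forced-choice
reaction-time (RT) task before, during and after stimulation.

## The blinding time-course analysis

**Weighted score.** Each probe pair collapses to
`score = (+1 if yes else -1) × confidence ∈ [-10, +10]`; +10 means
certain-on, −10 certain-off. A lapsed probe (no response inside the
answer window) is *missing*, not zero — zero is a meaningful maximally
unsure answer — and is excluded pairwise at that probe only.

**Bootstrap bands.** Per condition and probe time the group median score
is summarised with a percentile bootstrap over participants: resample
participants with replacement (default `n_boot = 5000`), take the median
of each resample, and report the (α/2, 1−α/2) quantiles of the bootstrap
median distribution at `level = 0.95`. The percentile method (not BCa) is
used; the statistic is the plain sample median. One seeded RNG stream is
spawned per condition (sorted label order) and probes are processed in
time order, making bands bit-reproducible for a given seed. A probe with
fewer than two non-missing scores is flagged and carries no band.

**Distinct windows.** Probe *k* is *distinct* when the two conditions'
intervals `[lo, hi]` have empty intersection (touching endpoints count as
overlap). Consecutive distinct probes merge into one window spanning
first-to-last probe time, so an isolated distinct probe contributes 0 s.
The summed span, divided by the difference in total current-on time
between protocols (ramps included; 660 − 80 = 580 s for the defaults),
gives the *percent of the stimulation-time difference* that was
perceptible. No multiplicity correction is applied across the 32 probe
comparisons; the window summary is descriptive.

**Per-individual logistic crossover.** A Bernoulli logistic regression of
answer on time estimates the time `−β₀/β₁` at which an individual's
yes-rate crosses 50%. Real response series often defeat this fit, so the
failure taxonomy is explicit: `degenerate_responses` (single-valued
answers), `nonconvergent`, `non_monotone` (Wald CI of the slope covers
zero), `crossover_out_of_range` (outside the 0–960 s task), else `ok`.
Complete separation with both classes present — a noiseless switcher —
has a well-identified threshold but a divergent MLE; it is fitted with a
light ridge penalty (λ = 10⁻³ on standardised-time coefficients), which
places the crossover inside the separating gap.

## Reaction-time analysis

Per participant, condition and block (1 = pre-stimulation baseline,
2–3 = during stimulation, 4 = after), the median RT of **correct,
responded** trials is taken; ΔRT subtracts the same session's baseline.
ΔRT is compared between conditions per block with one-tailed paired
t-tests (directional hypothesis: anodal facilitation, i.e. active
faster), computed on d = sham − active so facilitation yields positive t;
Cohen's dz = mean(d)/sd(d). Baseline equivalence uses the two one-sided
tests (TOST) procedure on dz bounds: `t_lower = (dz + bound)·√n`,
`t_upper = (dz − bound)·√n`, df = n−1, p = max of the two one-sided
p-values; the default bound is a moderate effect, dz = 0.4. Accuracy is
the group mean of per-participant accuracy (non-responses count as
errors) with a participant-level percentile-bootstrap CI. The exploratory
sub-block time course bootstraps the median RT of each 10-trial sub-block
(sub-block *k* mapped to *k*·30 s) and reuses the window machinery. No
outlier trimming is applied to RTs.

Block boundaries: sub-blocks 1–11 → block 2 (0–330 s), 12–22 → block 3
(330–660 s, the second half of stimulation), 23–32 → block 4; blocks 2–3
hold 220 trials, block 4 holds 100, the baseline 100 (≈200 s at a mean
trial length of 2.0 s).

## Questionnaire statistics and power

Side-effect ratings (five 1–5 scales) are compared with Wilcoxon
signed-rank tests: zero differences discarded (classical convention, not
Pratt), midranks on |d|, tie-corrected variance Σr²/4, z oriented so
positive means higher ranks under active, two-sided normal p, no
continuity correction. The normal approximation tracks the exhaustive
sign-flip enumeration to < 0.02 wherever the exact test decides (exact
p ≤ 0.05); in the body of the distribution the exact null at n_eff ≤ 10
carries point masses wider than 0.02, so only atom-width agreement is
possible there — the test suite asserts exactly that, plus a brute-force
oracle for the z arithmetic. The end-of-study sham guess is summarised as
a proportion with an exact one-sided binomial test against 0.5 ("above
chance" is directional). `required_sample_size` inverts the noncentral-t
power function of the paired t-test (smallest n reaching the target
power); at dz = 0.45, one-tailed α = 0.05, power 0.8 it returns n = 32
(achieved power 0.801; n = 31 gives 0.789).

## The synthetic cohort generator

The generator emulates the study design — 32 participants, two
counterbalanced sessions (even participant indices receive active first),
per session 100 baseline + 320 task trials in 32 ten-trial sub-blocks and
32 probes on the 30-s grid — so every stage runs with no download. It is
a study-structure emulator, not a mechanistic model of cutaneous
perception.

**Detection.** P(yes) = `p_off + (p_on − p_off)·s(t)` with salience
s(t) = 1 during ramps, `2^(−elapsed/halflife)` on the plateau (scalp
desensitisation), and a linear decay to 0 over `persistence_s` after
ramp-down (lingering sensation). Defaults: `p_on = 0.95`, `p_off = 0.05`,
`desensitization_halflife_s = 600`, `persistence_s = 45`,
`lapse_p = 0.02`. These were chosen once so the default cohort reproduces
the qualitative time-course structure: overlap of conditions through the
shared ramp-up probes, a sham band confidently below zero from 120 s
(shortly after the 80-s sham current-off plus after-sensation decay), an
active band above zero that widens as the plateau desensitises, and a
first distinct window no earlier than 90 s.

**Confidence.** Truncated normal on [0, 10], means 7.5 (yes) / 7.0 (no),
within-participant SD 2.0, plus a per-participant scale-use offset
(SD 1.5) held fixed across sessions. The between-participant component
matters: a homogeneous group makes the 32-draw bootstrap median CIs
unrealistically narrow, and probes with identical generating
distributions are then spuriously "distinct" in a non-trivial fraction of
cohorts. Confidence is continuous; the analysis accepts integer or real
confidences.

**Reaction times.** Log-normal trials,
`rt = exp(N(log(median), σ_log))` with σ_log = 0.2, participant intercept
SD 55 ms around a 430 ms group median, practice slope −2 ms/block, and
accuracy Bernoulli(0.956) (error trials share the RT law but are excluded
from medians). An anodal effect `anodal_dz` (default 0) shifts the median
of active blocks 2–3 down by `dz × SD_diff`, where SD_diff is the model's
own standard deviation of the paired baseline-corrected block-median
difference: asymptotic median variance `(median·σ_log)²·π/(2n)` per
block, n deflated by accuracy, four independent block medians summed, and
the whole inflated by `√(1 + (55/430)²)` because the multiplicative model
ties median-noise scale to the participant's own median. This calibration
was validated against an independent Monte-Carlo of the order statistics
(empirical/asymptotic SD ratio 0.999 at n ≈ 100); with `anodal_dz =
0.45` the one-tailed paired t on block-3 ΔRT rejects in ≈79–80% of
cohorts, matching the design power that sized the study at n = 32.

**Questionnaires.** Ratings are drawn from fixed ordinal base
distributions per scale (itching shifted up by one category under active
by default); the sham guess is correct with probability 25/32 ≈ 0.781
(the study's calibration value), with a truncated-normal 1–10 guess
confidence.

**What the generator does not emulate.** Response switching is i.i.d.
given s(t) — no within-participant autocorrelation, expectation or
priming effects, and no separate tingling/burning time courses; RTs have
no ex-Gaussian tail beyond log-normality and no fatigue beyond the linear
practice slope. Passing tests therefore certify the statistical machinery
and its operating characteristics under this idealised structure, not the
behaviour of real participants.

## Numerical choices and degenerate inputs

* Percentile quantiles use linear interpolation (`np.quantile` default);
  an exhaustive-enumeration mode (n ≤ 8) exists for oracle testing.
* `find_distinct_windows` requires matching probe grids and is symmetric;
  flagged/NaN probes are never distinct.
* Zero-variance paired differences raise (t undefined); all-zero Wilcoxon
  differences flag the result as undefined rather than raising, so a
  five-scale battery can proceed.
* Equal active/sham current-on times make the percentage denominator
  non-positive; this raises with an explicit message.
* All pipeline randomness flows from one seed (bands: one spawned stream
  per condition; accuracy CI: its own seeded generator), and every output
  file embeds the seed and a config hash, so re-runs are byte-identical.

## Problem sizes used by the verification suite

Coverage of the 95% median band: 2,000 simulated draws at n = 32 with
1,000 resamples each (coverage ≈ 0.945, inside the 93–97% band expected
for the percentile method at this n). TOST size at the equivalence bound
dz = ±0.4: 5,000 replications, compared against the exact noncentral-t
size (≈ 0.043 at n = 32). Power recovery at anodal_dz = 0.45: 2,000 full
synthetic cohorts. End-to-end qualitative structure: 20 seeded cohorts at
the full n_boot = 5,000.
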