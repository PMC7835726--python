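# Methods

## Observer model

Percepts of head-in-space (HIS) and body-in-space (BIS) roll tilt are
modeled as Gaussian cue combinations.  Three channels report on the
configuration (all angles in degrees): somatic graviceptors
`x_som ~ N(k_som·φ_P, σ_som)`, neck proprioceptors `x_pro ~ N(φ_N·𝟙[tilted], σ_pro)`,
and a combined visual+vestibular head sensor
`x_com ~ N(k_som·φ_P + φ_N·𝟙[tilted] + φ_AR, σ_com)` with
`σ_com = K_com·|φ_AR| + σ_com0`.  Treating vision and the vestibular sense
as one head sensor is deliberate: with only roll-tilt manipulations their
separate noise parameters are not jointly identifiable.  Body tilt is
equated with platform tilt (`k_som = 1` by default); the fitted gain
`k_som` and an SPV-specific neck offset are optional extensions for
idiosyncratic observers.

The direct estimates are `HISd = x_com` and `BISd = x_som`; the indirect
ones correct the other construct's sensor for neck tilt,
`HISi = x_som + x_pro` and `BISi = x_com − x_pro` (means add/subtract,
variances add).  The percept is the convex combination
`μ̂ = ω μ_d + (1−ω) μ_i`, `σ̂² = ω²σ_d² + (1−ω)²σ_i²`, with the direct
weight per regime: **fixed** ω=1, **free** a constant per-participant
parameter in (0,1), **mle** the inverse-variance optimum
`ω_d = σ_i²/(σ_d²+σ_i²)`, recomputed per condition because `σ_com` varies
with |φ_AR|.  That per-condition recomputation is what bends the mean
response curve into a sigmoid.

Task responses: the rod is set in head-display coordinates, so
`r_RFT ~ N(−μ̂_HIS, σ̂_HIS)`.  In the SPV task the participant chooses the
platform tilt that nulls the body percept.  Solving
`ω μ_BISd + (1−ω) μ_BISi = 0` for the platform setting — the neck terms in
`μ_com` and the proprioceptive correction cancel — gives the closed form
`μ_SPV = −(1−ω_BISd)·φ_AR / k_som` (plus the optional neck offset in
head-tilted blocks), with sd `σ_som`.  We use this self-consistent fixed
point rather than an expression with `ω` in the denominator: it is
algebraically equivalent at `k_som = 1` and numerically safe as `ω → 0`.

## Fitting and model comparison

Each participant's RFT and SPV trials are fitted jointly by maximum
likelihood (sum of Gaussian log-densities of the observed responses under
their trial-wise predictive distributions).  Parameter vectors: fixed
(φ_N, σ_som, σ_com0, K_com), k=4 — `σ_pro` never enters the fixed
predictions and would be unidentifiable, so it is excluded; mle adds
σ_pro (k=5); free adds ω_HISd, ω_BISd (k=7); each extension adds one.

Optimization is multi-start L-BFGS-B in a transformed space (log for the
σ's, logit for the ω's, identity otherwise) with Latin-hypercube starting
points over the bounds φ_N ∈ [−45,45]°, σ_som ∈ [0.05,30]°,
σ_pro, σ_com0 ∈ [0.1,60]°, K_com ∈ [0,2], ω ∈ [10⁻³, 1−10⁻³],
k_som ∈ [−10,10], SPV offset ∈ [−30,30]° — generous brackets around
plausibly human values that exclude degenerate zero noise.  Default 20
starts; the best start by final log-likelihood wins, ties go to the first
start index, and everything is deterministic under the seed.  Models are
ranked by BIC = k·ln(n) − 2·lnL with n the participant's retained trials
across both tasks; BIC differences are labeled negligible/positive/strong
below 2/6/10 and decisive at ≥10 (the boundary point 10 is labeled
decisive).  R² = 1 − SSE/SST from per-trial predicted means is reported
pooled over tasks and per task; the pooled value is the headline number,
and both are kept because the two tasks have very different response
variances.

**Identifiability remark.**  The three regimes are not nested families:
mle's weights vary with |φ_AR| and are functions of the σ's, free's are
constant, and fixed's ω=1 is only the σ_pro→∞ limit of mle (unreachable at
the σ_pro ≤ 60 bound).  Consequently the intuition "more flexible variants
always attain higher maximized likelihood" holds only approximately:
free ≥ fixed holds up to the ω-bound (~10⁻³), while free vs mle can order
either way depending on which structure generated the data.  The test
suite checks the ordering chain on free-generated data, where the free
family contains the generating model and the chain is structurally
expected, and checks free ≥ fixed across regimes.

## Preprocessing

Flagged trials (training, self-reported mistakes, COP-quality issues) are
removed first; then, per participant and task, the mean response over all
head-upright trials (all platform and camera levels pooled) is subtracted
from every response of that participant in that task.  This removes
constant biases such as display misalignment on the head that would
otherwise inflate fitted noise, and makes head-upright data zero-mean by
construction.  Exclusion precedes correction so flagged trials cannot leak
into the offsets; COP columns are never mean-corrected (the posture module
centers within participant itself).  Correction is per task rather than
pooled across tasks: the two tasks have different response reference
frames (display vs platform), so their constant biases have no reason to
coincide.

## Synthetic cohorts

The generator reproduces the study design: camera tilts
{−36,−13,−5,0,5,13,36}° × platform tilts {−3,0,3}° × head {upright,
tilted ≈15°} blocks with {3,2} repetitions, per task — 63 + 42 = 105
trials per task, 210 per participant.  Responses are drawn from the
model's predictive Gaussians under a chosen generating regime (mle by
default) at coefficients drawn around the published cohort medians
(φ_N 9.416°, σ_som 0.811°, σ_pro 9.276°, σ_com0 8.572°, K_com 0.249):
log-normal with log-sd 0.3/0.6/0.6 for σ_som/σ_pro/σ_com0, normal with sd
5° for φ_N and sd 0.12 for K_com, truncated to the fitting bounds.  These
dispersions roughly match the published cohort SDs while keeping most
draws inside the observed per-participant ranges; extreme draws are
possible but rare.  About 4% of trials are flagged for exclusion, with
reasons in the study's observed 72:3:10 proportions.

COP is static rigid-body geometry only: `100·(h/2)·tan(g·φ_P)` with
counteraction gain g = 0.73 in RFT trials (φ_P-term zero in SPV trials,
where the platform is returned to upright), plus a visual lean calibrated
so a 36° camera tilt shifts COP by −0.5 cm at a 0.93 m center of mass, and
0.3 cm Gaussian noise.  What this generator does *not* emulate: sway
dynamics and their autocorrelation, response drift or lapses, per-trial
motion profiles, and any non-Gaussian response behavior.  Passing recovery
tests therefore show that the estimator is consistent and well-conditioned
under the model's own assumptions, not that real observers satisfy them.

## Posture analysis

`expected_cop_shift(h_com, φ) = 100·h_com·tan φ` (cm) and its inverse
`cop_shift_to_tilt` convert between COP and tilt; the counteraction slope
is ordinary least squares of measured on expected COP over head-upright
RFT trials, with both series centered within participant so that stance
and harness offsets cancel.  OLS estimates the same fixed-effect slope a
random-slope mixed model targets and is its consistent estimator under
the generator; at ≤3° platform tilt the tan-linearization error is below
0.1%, so the slope recovers the generating gain essentially unbiased.

## Numerical choices and problem sizes

Likelihoods are evaluated vectorized over trials; non-finite predictive
means or non-positive sds yield −∞ rather than exceptions inside the
optimizer (relevant only when the fitted `k_som` crosses zero).  The
recovery simulations in the test suite use the study-scale 210-trial
design: 50 replicates for parameter recovery, a 10-participant cohort for
model recovery, 5 cohorts for the COP slope, and 10 optimizer starts per
fit, which keeps a full fit near a quarter second and the whole suite
under half a minute while leaving the multi-start search comfortably
converged (20 starts, the library default, gives identical optima on these
data).

## Known limitations

- No ocular counter-roll, no idiotropic (body-axis) prior, and no separate
  visual/vestibular decomposition — all unidentifiable or negligible in
  this design.
- No causal-inference (mixture) alternative to mandatory fusion.
- The descriptive group-level statistics are per-condition summaries and
  plain OLS; random-effect regression structure is out of scope.
- The SPV closed form assumes the participant can always reach the nulling
  platform tilt; the ±5° actuator limit of the real apparatus is not
  enforced.
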