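# Methods

This note documents the models implemented in `oculostop`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Race model and task simulation

Signal trials race an independent GO process against a STOP process that
starts after the tracked delay; the saccade is executed iff the GO finish
time precedes delay + STOP latency. Latencies are drawn from normal
distributions truncated at zero by resampling (`go_sd = 0` or
`stop_sd = 0` give constant latencies). Normality is the minimal
assumption that keeps an analytic oracle available for every test —
P(respond | delay) is a normal CDF — and an ex-Gaussian tail
(`go_tau`/`stop_tau`, default 0 = off) is available when a skewed GO
distribution is wanted. There is no trigger-failure parameter: every stop
signal launches a STOP process. That is a known extension point, left out
deliberately because the estimators implemented here assume the plain race.

Trial types are interleaved i.i.d. Bernoulli(p_signal) — 0.30 for the
stop-signal variant, 0.40 for the search-step variant — with no blocking.
The 1-up/1-down staircase starts at 225 ms (stop-signal) or 100 ms
(search-step), moves by 47 or 67 ms, is clamped at 0 ms and has no upper
bound; when frame snapping is enabled (search-step on a 60 Hz display) the
updated delay is rounded to the nearest multiple of 1000/60 ms. Whether
the original tasks bounded the delay above is unknowable from the task
description; an unbounded staircase is self-limiting anyway because long
delays are almost always failed, pulling the delay back down.

## SSRT/TSRT estimation

Integration method: sort no-signal RTs ascending, take the k-th order
statistic with k = clamp(⌈p_respond · N⌉, 1, N), subtract the mean signal
delay. No interpolation between order statistics — the ceiling convention
is the common integration-method reading and is exactly testable by hand
enumeration. `mean_delay` averages over *all presented* signal trials
(the tracked staircase sequence), including trials an online classifier
would label unchanged. Anticipatory responses (RT < 100 ms) are filtered
before any summary. Degenerate sessions (p_respond exactly 0 or 1) return
a summary flagged `degenerate` instead of raising, so cohort pipelines
keep running; the SSRT of such a session is the extreme order statistic
minus the mean delay and should not be interpreted.

Recovery behavior: with a constant STOP latency the estimate converges on
the generating latency (tested at 20 000 trials, tolerance ±5 ms, three
parameter settings). The estimator is exactly equivariant under shifts of
the RT distribution and of the mean delay.

## Gaze classification

Online positional rule for redirect trials: positions are drift-corrected
by the mean position in the ±50 ms window around array onset; the trial is
scored from the first run of more than two consecutive samples (≥ 3 at
60 Hz, i.e. > 33 ms) with eccentricity > 2° at times > 100 ms after array
onset. The mean displacement vector of that run is compared to the target
directions: within 90° of T2 → compensated, within 90° of T1 →
noncompensated, neither → unchanged. The task geometry guarantees ≥ 90°
separation between T1 and T2, so at most one target can be strictly
nearer; on the measure-zero boundary the nearer target wins. Offline
velocity-based saccade detection (Butterworth filtering) is out of scope;
the generators produce position traces directly.

## Behavioral statistics

Two-sample comparisons use the pooled-variance t (df = n1 + n2 − 2),
computable from printed group means/SDs/sizes — the printed degrees of
freedom in the reference tables match the pooled form, not Welch.

The mixed ANOVA covers one between-subjects factor crossed with one
balanced within-subjects factor. Generalized eta squared follows the
Olejnik–Algina partition with the group factor treated as observed: the
denominator of each effect adds the sums of squares of every source
involving the observed factor plus both error strata. This makes ges
invariant to adding a constant and bounded in [0, 1] (both property
tested); F values are verified against a from-scratch sums-of-squares
oracle to 1e-8 and against `pingouin.mixed_anova`. Greenhouse–Geisser
epsilon is computed from the eigenvalues of the double-centered pooled
within-group condition covariance, clamped to [1/(k−1), 1], and applied
to within-subject degrees of freedom only when k > 2 and epsilon < 1
(with two conditions sphericity is vacuous and epsilon is exactly 1).

Backward elimination fits OLS on all predictors and repeatedly removes the
largest-p predictor with p ≥ p_out (default 0.10, the conventional
removal threshold of this procedure; exposed in config), refitting until
all retained predictors pass. Ties are broken by removing the later
column, which makes the procedure deterministic and column-order invariant
up to exact p ties.

## Bilinear network model

dz/dt = J(u_redirect) z + C u_task with J off-diagonal a_ij + u_r·b_ij on
the 19 permitted edges and diagonal −0.5·exp(θ_i + u_r·b_ii). The
exponential self-connection keeps within-region decay strictly negative
for every finite θ, and the redirect modulation of a self-connection acts
inside the exponent, so "positive parameter = more self-inhibition" holds
for B as well as θ. The 19-edge structure is fixed in
`dcm_network.EDGES`; driving input reaches every region; all edges and
selves are modulated.

The edge list is a reconstruction from the anatomical statements the
network is built on (e.g. FEF projecting to SEF, caudate, thalamus and
colliculus; thalamic feedback to all three cortical regions; no ascending
collicular or caudate projection to cortex other than through thalamus).
It matches the stated count and every directional claim available, but a
figure-level, edge-by-edge confirmation is not possible from text alone —
a known limitation.

**Hemodynamics.** Standard balloon/Windkessel cascade per region
(vasodilatory signal κ = 0.65 s⁻¹, feedback γ = 0.41 s⁻¹, transit
τ = 0.98 s, stiffness α = 0.32, resting extraction E0 = 0.34, V0 = 0.04,
classic k1/k2/k3 readout), fixed rather than estimated. Fixing the
observation model is a deliberate simplification that reduces inversion to
the neural parameters; it is shared between the generator and the
inverter, so recovery tests validate the neural machinery, not robustness
to hemodynamic misspecification.

**Integration.** Fixed-step RK4 on the design's fine grid, default step
25 ms (50 ms in the group-level tests; both well inside the stability
region of these dynamics), observed at TR = 2 s. The event regressors are
rectangular pulses (default 0.5 s) on the fine grid; the driving regressor
is mean-centered so A reads as average effective connectivity, the
modulatory regressor stays binary. Trial onsets in the built-in design are
jittered uniformly (±1 s around a 4 s mean interval): jitter decorrelates
the two regressors and enriches the design's frequency content, which
measurably improves parameter identifiability.

**Inversion.** Damped Gauss–Newton (Levenberg-style) ascent on a
penalized Gaussian log-joint: per-region noise precisions (closed-form
updates, accepted only when they improve the objective), zero-mean
Gaussian priors (variance 1/16 on edges and modulation, 1/64 on self
log-scales, 1 on input gains; all config-exposed). Sensitivities are
forward finite differences (step 1e-3), refreshed every iteration during
burn-in and every second iteration thereafter — a stale sensitivity
matrix only proposes steps, it never scores them, so the economy cannot
corrupt the ascent. Candidate steps are rejected
unless the neural Jacobian stays strictly stable at both modulation
levels, so the accepted objective history is monotone by construction.
The full Laplace free energy (objective plus posterior-volume complexity
terms) is evaluated at the final iterate and is the model-comparison
score. Non-convergence within `max_iter` returns the best iterate with
`converged = False`.

**PEB.** Each parameter is modeled independently across subjects:
subject posterior means regressed on [1, group_code] with total variance
= subject posterior variance + between-subject variance τ, τ estimated by
EM; coefficients carry the first-level priors. Greedy Bayesian model
reduction switches a coefficient off (prior variance → 0) when the
Gaussian model evidence is higher without it; switched-off coefficients
report zero mean and zero posterior probability. For retained
coefficients the posterior probability is Φ(|μ|/σ) — the probability the
sign matches the posterior-mean sign — and "credible" means strictly
greater than 0.95. The per-parameter factorization ignores posterior
correlations between parameters at the group level; leakage of a planted
effect into strongly correlated connections is therefore possible at the
group level (observed occasionally in simulation), while the null
false-credibility rate stays far below the 10% bound.

## Synthetic cohorts

Behavioral: HC-like GO ~ N(269, 50), STOP ~ N(99, 20); REL-like GO ~
N(317, 35), STOP ~ N(136, 25) (ms) — matching the group means of the
reference populations, including the 37 ms stop-latency gap — with 10 ms
between-subject jitter on both latency means, group sizes 14/12 by
default. Network: the template parameter set has edge magnitudes
0.27–0.45 Hz with alternating signs, self log-scales ±0.25, modulation
+0.2 Hz on four edges, and per-region input gains 0.32–0.80; group
effects are planted symmetrically (±effect/2 by group code) with 0.05 Hz
between-subject jitter on edges, and noise is scaled per region to a
requested SNR (signal sd / noise sd). Subject draws that land unstable
are re-jittered (up to 20 attempts).

These magnitudes were chosen once, from an identifiability analysis on
noiseless and SNR-5 data: substantially weaker couplings are genuinely
not recoverable from two 5-minute runs of 6-region BOLD — the likelihood
is nearly flat along many parameter directions — which is a property of
the measurement, not of the estimator. Passing recovery tests therefore
show that the estimation machinery is correct and well-calibrated at
realistic-but-favorable effect sizes; they do not show that connectivity
of arbitrary magnitude is recoverable from real scans, nor do the
generators emulate physiological noise spectra, motion, or hemodynamic
variability across regions and subjects.

## Problem sizes used in the validation suite

Subject-level recovery runs 2 × 150 volumes (TR 2 s, step 25 ms) at
SNR 5 over 10 seeds; group-level recovery runs 10 cohorts of 8 + 8
subjects at 150 volumes (step 50 ms) and SNR 20; null-specificity runs
10 cohorts of 4 + 4 subjects at 60 volumes. These sizes keep the whole
suite at desk scale while leaving clear statistical margin on every
criterion they test.

## Known limitations

- The race model omits trigger failures and context-dependent GO slowing;
  SSRT estimates on real data are sensitive to both.
- The mixed ANOVA supports one within and one between factor (the designs
  analyzed here); it is not a general factorial engine.
- DCM inversion uses finite differences and a fixed hemodynamic model; it
  is a self-contained analogue of the established variational schemes,
  not a drop-in replacement for them.
- PEB treats parameters independently at the second level (no group-level
  posterior covariance), trading some sensitivity/specificity sharpness
  for robustness and speed.
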