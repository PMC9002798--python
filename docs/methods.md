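# Methods

## Model

Resting metabolism *M* of an endotherm at ambient temperature *T_a* is
modelled as a three-state mixture under the extended Scholander–Irving
model. Within the thermoneutral zone (above the lower critical temperature
*T_lc*) *M* scatters around the constant *M_TNZ*. Below *T_lc* a measurement
is either euthermic rest or torpor:

* euthermic line through (*T_lc*, *M_TNZ*) and (*T_be*, 0); *T_be* is the
  extrapolated zero-metabolism temperature, a proxy for euthermic body
  temperature under constant conductance;
* regulated-torpor line with the same slope (β_r = β_e, the empirical
  near-equality of euthermic and regulated-torpor thermal conductance)
  through (*T_bt*, 0), *T_bt* proxying the torpid setpoint;
* conforming-torpor exponential between the breakpoint
  *T_t* = *T_bt* + *TMR*/β_r (where the regulated line meets the torpid
  minimum *TMR*) and (*T_lc*, *M_r*), with
  β_c = ln(*M_r*/*TMR*)/(*T_lc* − *T_t*) and Q₁₀ = exp(10·β_c) capped at 5.

Scatter is Gaussian and state-specific: `sd_tnz` on the plateau, `sd_r` on
both linear branches, `sd_c` on the conforming branch. Euthermic rest below
the TNZ shares `sd_r` with regulated torpor — the most parsimonious reading
given the shared slope; the model lists no separate euthermic SD.
Measurements are divided by their dataset mean before any likelihood
computation and results are rescaled to input units on output; all SD priors
below are on that normalized scale.

Assumptions worth keeping in mind: steady-state resting or torpid
measurements only (no transitions, test drops or activity), no measurements
above the upper critical temperature, a linear euthermic curve, no body-mass
or circadian structure, no individual effects.

## Priors

Location parameters take Gaussian priors with mean 0 and precision 0.001
(SD ≈ 31.6), truncated to:

| parameter | support | rationale |
|---|---|---|
| *T_lc* (step 1 only) | [*T_lc_low*, max *T_a*] | the screen bounds it from below, the data from above |
| *T_be* | (*T_lc*, 50 °C] | body temperature above the TNZ boundary, below 50 °C |
| *T_bt* | [−5 °C, U] | super-cooling floor; U below |
| *TMR* | (0, 0.8·*M_TNZ*] | torpid minimum below 80% of the plateau rate |
| *M_r* | [*TMR*, *M_TNZ*] | torpid rate at *T_lc* between the minimum and the plateau |

`sd_r` ~ U(0, 3) (normalized scale), `sd_c` ~ U(`sd_r`/5, `sd_r`),
`sd_tnz` ~ U(`sd_r`/2, `sd_r`); the two mixing fractions take a flat
Dirichlet(1, 1). Truncation normalization constants are included in the
joint prior density because several bounds depend on other parameters.

The *T_bt* ceiling U enforces two constraints at every proposal:

    U = min( L95(T_lc),  T_lc − 10·ln(M_r/TMR)/ln 5 + TMR/|β_r| )

the second term is the exact Q₁₀ ≤ 5 condition expressed on *T_bt*; the
first keeps the torpor breakpoint below the lower 95% credible bound of
*T_lc* by bounding *T_bt* itself (which implies it, since *T_t* < *T_bt*).
This is deliberately tighter than the loosest bound satisfying the
breakpoint condition (L95 + *TMR*/|β_r|): because the two linear branches
share a slope, the looser bound lets the regulated-torpor line — whose
zero-intercept is free — impersonate the euthermic line whenever the *T_lc*
anchor is misplaced by a degree or so, which collapses torpor-free datasets
into spurious all-torpor fits. Biologically the tighter bound costs
nothing: the torpid setpoint lies below the TNZ in every species the model
describes. In step 1, where no credible interval exists yet, the constant
*T_lc_low* stands in for L95.

## Three steps

**Step 1.** Records sorted by descending *T_a*; OLS regressions on growing
windows (initial size 10; records tied on *T_a* enter together so a window
never splits a tie). A window triggers on a one-sided significantly
negative slope (α = 0.01) or a studentized (Koenker) Breusch–Pagan test
(α = 0.05); a significantly positive slope aborts the analysis (no
euthermic data below the TNZ). *T_lc_low* is the minimum *T_a* of the last
clean window. Because ~10 correlated window tests run at those levels, the
screen has an appreciable false-trigger probability inside the TNZ on short
plateau segments; a false trigger overestimates *T_lc_low* by up to the
local point spacing, so the "underestimates *T_lc*" property is statistical,
not certain (measured ≈ 60% on a 20-point plateau with 5% noise; triggers
caused by genuine sub-TNZ data are essentially always conservative). If the
*initial* window already triggers, the package raises rather than guessing.
The Bayesian run then uses only records at or below *T_lc_low*, with *T_lc*
free and *M_TNZ* fixed at the mean normalized *M* above *T_lc_low*;
afterwards *M_TNZ* is recomputed as the mean above the posterior-median
*T_lc*.

**Step 2.** Full-dataset run with *T_lc* fixed at the step-1 posterior
median. Records above *T_lc* are plateau by definition. Membership
probabilities are the fraction of retained draws assigning each record to
each state. If at least one record was assigned to torpor, automatic
overrides clamp records above the posterior-median euthermic curve to
euthermy and below the posterior-median torpor curve to torpor (membership
one). The median curve, not a credible-interval bound, is the "predicted"
curve — it is the central predictor.

**Step 3.** Re-run with the clamped records' indicators fixed; clamped
states count toward the mixing fractions. Reported parameter posteriors,
predicted curves and credible bands come from this run. The plateau's
"curve" is the constant *M_TNZ* (not sampled), so its credible band is
degenerate by construction.

**Confidence and validity.** Confidence = winning membership probability ×
probability the record sits on the correct side of *T_lc*, from the step-1
empirical posterior CDF with a midpoint tie convention (a record exactly at
the posterior median gets side probability 1/2). Validity treats the
retained draws (3 × 2,000 = 6,000) as Bernoulli trials with success count
round(confidence × draws) and applies an exact one-sided binomial test of
p ≤ 0.8 at α = 0.05 — a reconstruction, since only the test, its sidedness
and the 0.8 threshold are specified; any construction with this many trials
behaves as a sharp cut slightly above the threshold, and a confidence of
exactly 0.8 is never valid.

## Sampler

Adaptive random-walk Metropolis on the collapsed posterior: the per-record
state indicators are marginalized out (each free record contributes
p_e·N_e + p_t·N_t to the likelihood), the mixing fraction p_t is updated by
Metropolis under its flat prior, and proposals violating any truncation are
rejected. Indicators are re-drawn from their exact conditional at each
retained iteration, so the recorded joint draws target exactly the same
posterior as an explicit-indicator sampler. The collapsed kernel is a
deliberate choice: per-record Gibbs updates lock the chain into
label-switching local modes here, because the shared slope couples the two
states — a slope move that would let euthermy reclaim records is rejected
while torpor still owns them.

Proposal scales adapt every 50 iterations during burn-in toward ~35%
acceptance and are frozen afterwards. Chains initialize from joint prior
draws (scatter draws tempered into (0, 1]); initialization retries a
bounded number of times. Run protocol: 3 chains × 50,000 iterations, 30,000
burn-in, thinning 10 → 2,000 retained draws per chain. Convergence is
flagged (never raised) when any rank-normalized split R-hat (arviz) reaches
1.1. All entry points take explicit seeds; per-chain generators come from a
spawned SeedSequence.

## Identifiability

PPO = 100·∫ min(f_prior, f_posterior) from Gaussian KDEs (plug-in
bandwidth) on a shared 512-point grid padded 5% beyond both samples; prior
draws come from the same joint truncated prior used in sampling (10,000
draws). Overlap ≥ 75% marks a parameter unidentifiable. Calibration: two
unit Gaussians one SD apart overlap 2·Φ(−½) ≈ 61.7%; the KDE estimate is
reproduced within ±2 points at 50,000 draws. *T_bt* and *T_lc* PPOs are
reported but not decision-grade (their priors are data-dependent); the
diagnostic is aimed at *TMR* and *M_r*.

## Synthetic data

The generator draws *T_a* uniformly over [*T_bt* − 5, *T_lc* + 8] (so the
plateau always offers the screen's initial window), assigns below-*T_lc*
records to torpor with probability p_t, and adds state-specific Gaussian
noise around the exact model curves, redrawing non-positive values
(redrawing, rather than truncating, keeps the generating density essentially
the fitted likelihood at realistic noise levels). Shipped designs:
`deep_hibernator` (T_bt = 2 °C, TMR = 5% of M_TNZ, n = 120),
`shallow_daily` (T_bt = 25 °C, the hard case), `homeotherm` (p_t = 0,
n = 100), `inhibited` (M_r/M_TNZ = 0.35). Noise levels (5% of M_TNZ on the
plateau, 7% on the linear branches, 3% conforming) are typical of
steady-state respirometry.

What the generator does not emulate — torpor-bout dynamics, arousal
transitions, circadian modulation, body-mass heterogeneity, non-Gaussian
outliers — bounds what passing tests show: they demonstrate correct
inference under the model's own data-generating assumptions, not robustness
to every feature of real traces.

Problem sizes in the test and acceptance suites (n = 100–120 records, the
canonical run protocol for end-to-end checks, reduced protocols for unit
tests) match the mid-range of published respirometry datasets while keeping
a full pipeline run to a few minutes on one core.

## Numerical choices and edge cases

* `m_r == tmr` is admissible: the conforming branch is exactly flat
  (β_c = 0 as an exact limit). `m_r == m_tnz` (no inhibition) is admissible.
* Tied *T_a* values: tie groups enter screen windows atomically; an
  all-tied window passes trivially (no slope, no variance trend).
* The empirical *T_lc* CDF uses the midpoint convention at ties.
* Zero residual variance in the Breusch–Pagan test returns "no
  heteroscedasticity detectable" with a warning instead of failing.
* If no record lies above the posterior-median *T_lc* (possible only when
  *T_lc* presses against the warmest measurement), *M_TNZ* falls back to the
  step-1 value instead of a mean over an empty set.
* Degenerate (zero-variance) samples make the PPO raise — overlap of a
  point mass is undefined.

## Known limitations

* The step-1 screen's false-trigger behaviour (above) propagates: an
  overestimated *T_lc_low* truncates the *T_lc* prior above the truth, and
  *T_lc* is then overestimated by up to about the same margin. The
  downstream assignment machinery is deliberately robust to this (see the
  *T_bt* ceiling), but *T_lc* itself inherits the error.
* Parameters of curves with few supporting records (*TMR* with little
  regulated torpor, *M_r* with little conforming torpor) are honestly
  unidentifiable; the PPO report is the guard, not a fix.
* The binomial validity construction and the shared euthermic/regulated SD
  are reconstructions at points the method description leaves open; both are
  documented above and isolated behind small functions.
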