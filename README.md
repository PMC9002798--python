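# torpormix

Bayesian assignment of resting metabolic-rate measurements to **torpor**,
**euthermic rest** or **rest within the thermoneutral zone (TNZ)**, with joint
estimation of the thermoregulatory curve parameters of the extended
Scholander–Irving model.

## The problem

Respirometry studies of heterothermic endotherms (hibernators, daily
heterotherms) measure resting metabolic rate *M* across a range of ambient
temperatures *T<sub>a</sub>*. Deciding which measurements represent torpor
and which represent euthermic rest is easy for a deep hibernator at low
*T<sub>a</sub>* and genuinely hard near the TNZ, for shallow daily torpor, or
for thermolabile species — and ad-hoc thresholds make the literature
inconsistent. This package assigns each measurement probabilistically, under
an explicit thermal-physiology model, and tells you how confident that
assignment is.

It is aimed at thermal biologists and comparative physiologists analysing
laboratory respirometry data (steady-state resting/torpid measurements below
the upper critical temperature; transitions and heat stress are out of
scope).

## The model

Resting *M* is flat at *M*<sub>TNZ</sub> within the TNZ. Below the lower
critical temperature *T*<sub>lc</sub>:

* **Euthermic rest** — linear: *M*<sub>e</sub> = α<sub>e</sub> +
  β<sub>e</sub>·*T*<sub>a</sub>, anchored by
  *M*<sub>e</sub>(*T*<sub>lc</sub>) = *M*<sub>TNZ</sub> and
  *M*<sub>e</sub>(*T*<sub>be</sub>) = 0, where *T*<sub>be</sub> proxies
  euthermic body temperature.
* **Regulated torpor** (*T*<sub>a</sub> < *T*<sub>t</sub>) — linear with the
  *same* slope (β<sub>r</sub> = β<sub>e</sub>), zero at *T*<sub>bt</sub>, the
  torpid body-temperature setpoint.
* **Conforming torpor** (*T*<sub>t</sub> ≤ *T*<sub>a</sub> ≤ *T*<sub>lc</sub>)
  — exponential: *M*<sub>t</sub> = α<sub>c</sub>·exp(β<sub>c</sub>·*T*<sub>a</sub>),
  running from the torpid minimum *TMR* at *T*<sub>t</sub> up to
  *M*<sub>r</sub> at *T*<sub>lc</sub>, with Q₁₀ ≤ 5.
  *M*<sub>r</sub> < *M*<sub>TNZ</sub> quantifies additional metabolic
  inhibition beyond suppressed thermogenesis.

A three-step procedure fits this mixture by MCMC with truncated priors:

1. rolling regressions from the warmest measurements downward locate
   *T*<sub>lc_low</sub>, a conservative underestimate of *T*<sub>lc</sub>
   (significantly negative slope or Breusch–Pagan heteroscedasticity stops
   the window growth); a Bayesian run below *T*<sub>lc_low</sub> then
   estimates *T*<sub>lc</sub> and *M*<sub>TNZ</sub>;
2. a mixture run over the whole dataset yields per-measurement state
   membership probabilities; measurements above the predicted euthermic
   curve / below the predicted torpor curve are auto-assigned;
3. a final run with the automatic assignments clamped produces the reported
   parameter posteriors, per-measurement confidence (membership probability
   times the probability of sitting on the correct side of *T*<sub>lc</sub>)
   and a binomial validity test at confidence 0.8.

Prior–posterior overlap (PPO) flags unidentifiable parameters (overlap ≥ 75%
— e.g. *TMR* in a species that never enters torpor).

## Worked example

```python
from torpormix import TorporClassifier, default_fixtures, generate

data = generate(default_fixtures()["deep_hibernator"])   # known ground truth
clf = TorporClassifier(random_state=1).fit(data)

print(f"T_lc_low = {clf.tlc_low_:.2f}")
print(f"T_lc = {clf.tlc_:.2f} (95% CI {clf.tlc_ci_[0]:.2f}..{clf.tlc_ci_[1]:.2f})")
p = clf.params_
print(f"T_be = {p.t_be:.2f}  T_bt = {p.t_bt:.2f}")
print(f"TMR = {p.tmr:.4f}  M_r = {p.m_r:.3f}  T_t = {p.t_t:.2f}")
print(clf.assignment_["state"].value_counts().to_dict())
print({k: round(v, 1) for k, v in clf.ppo_.items()})
```

prints (generator truth: T_lc 30, T_be 38, T_bt 2, TMR 0.05, M_r 0.40):

```
T_lc_low = 29.31
T_lc = 30.15 (95% CI 29.82..30.53)
T_be = 38.20  T_bt = 1.91
TMR = 0.0564  M_r = 0.402  T_t = 1.46
{'torpor': 50, 'euthermy': 50, 'tnz': 20}
{'t_be': 1.4, 't_bt': 4.4, 'tmr': 4.2, 'm_r': 6.0}
```

Every measurement lands in its generating state; the low PPO values say all
four torpor-curve parameters are identifiable from these data. On the
`homeotherm` fixture the same pipeline assigns no valid measurement to torpor
and reports TMR PPO ≈ 95% — the unidentifiability signature expected when a
species never enters torpor.

The same pipeline is available from the shell:

```bash
torpormix simulate --fixture deep_hibernator --out data.csv
torpormix fit data.csv --out results/ --seed 1
torpormix evaluate results/assignment.csv data.csv
```

`fit` writes `assignment.csv` (per-measurement state, membership, confidence,
validity, predicted *M* with 95% credible band), `summary.json` (parameter
medians, credible intervals, R-hat, PPO) and a run log with the step-1 window
diagnostics.

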