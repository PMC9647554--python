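# Methods

## The model

`insomnia-cea` implements a decision-tree cost-effectiveness model for
pharmacological treatment of chronic insomnia in Japan.  Four strategies are
compared — lemborexant, suvorexant, zolpidem immediate release (IR), and
untreated insomnia — through their effect on three adverse-event pathways:
falls, motor vehicle collisions (MVC), and workplace accidents (WPA).  Each
event carries a treatment cost, a one-off utility decrement, and a
probability of death.  Outcomes are quality-adjusted life years (QALYs) and
direct medical costs in JPY from the payer perspective, accrued over a
six-month horizon with no discounting (the horizon is below one year).
Cost-effectiveness is judged by pairwise incremental comparison: dominance
when an option is cheaper and at least as effective, otherwise the
incremental cost-effectiveness ratio (ICER) against a willingness-to-pay
(WTP) threshold of JPY 5 million per QALY.

The tree is evaluated in expectation (no microsimulation).  For strategy
*s*, age group *a*, horizon *T* and utility norm *u*:

```
QALY(s,a) = u·T − (1−r_s)·d·T − Σ_e  E[n_e]·δ_e − P(death)·u·T/2
Cost(s,a) = c_drug,s·365.25·T·κ + v·12·T·c_visit·κ + Σ_e E[n_e]·c̄_e
```

where `r_s` is the responder rate (responders regain the population utility
norm; non-responders bear the insomnia disutility `d`), `E[n_e]` the
expected per-capita event count, `δ_e` and `c̄_e` the per-event utility loss
and expected cost, `v` the monthly physician-visit frequency, and
`κ = 1 − P(death)/2` the half-cycle factor: deaths occur at the horizon
midpoint, so decedents accrue half the period's utility and half of all
time-based costs.  Untreated insomnia accrues no drug or visit cost.  Events
are independent across types and expectations additive — a decision tree,
not a state-transition model, so no competing-risk adjustment is applied
within the six months.

A mixed-population result is the convex combination of the two age groups
(18–64 and ≥65) by configurable population weights; treatment efficacy is
age-independent, but baseline event risks are not.

## Risk composition

**Falls.**  The untreated-insomnia fall risk is the general-population
(good-sleeper) baseline times a relative risk of 1.48.  The orexin-receptor
antagonists chain their fall hazard ratios vs untreated insomnia onto that
factor (0.68 × 1.48 ≈ 1.01 for lemborexant, 0.85 × 1.48 ≈ 1.26 for
suvorexant).  Zolpidem's fall effect is taken from pooled observational
data and stored directly as a vs-general-population multiplier, because its
source compares hypnotic users against non-users rather than against
untreated insomniacs; the parameter is configurable if a user prefers to
chain it through 1.48.  Annual risks convert to the horizon by constant
hazard, `p_T = 1 − (1−p_annual)^T`.

Fallers fall more than once.  Survey data put the annual mean at 1.957
falls per faller (0.957 re-falls); the model carries a linear relationship
`falls/faller = 1.957 + slope·(p_faller − anchor_rate)` with a positive
slope (groups with more fallers contain more frequent fallers), floored at
one fall.  The slope is evaluated at the strategy's annual faller
probability and multiplies the period faller probability to give the
expected per-capita fall count.  The sign of the slope is a modelling
choice: the source material's verbal example is internally inconsistent, so
the conventional positive-association reading is used and the slope is an
ordinary, one-way-analysable parameter.

Conditional on a fall, the care pathway is a nested partition: 56% of
fallers receive any medical care, 8% are admitted (a subset of the 56%),
admissions split 32/68 into non-fracture vs fracture and fractures 47/53
into non-hip vs hip — giving admission cells of 2.56%, 2.56% and 2.88% of
all fallers, outpatient-only 48% and no care 44%.  Only admitted falls can
be fatal (6% non-fracture, 0.1% non-hip fracture, 20% hip fracture, applied
as printed in the source material even though the first two labels look
transposed; the parameters are individually configurable).  Unattended and
outpatient falls are minor injuries: no mortality, and (with non-fracture
admissions, conservatively) the plain fall disutility.

**MVC.**  Untreated insomnia carries an odds ratio of 2.7 vs baseline; all
three drugs share the zolpidem-derived effect, the only hypnotic with
published driving data.  Odds and hazard ratios are applied as
multiplicative risk factors, adequate at these baseline risks (≈1%/year).

**WPA.**  Non-responders carry an odds ratio of 1.79; the strategy-level
effect is the responder-weighted average `r·1.0 + (1−r)·1.79` (e.g. 1.63 at
r = 0.207).  Untreated insomnia has r = 0, so the weighting degenerates to
the full 1.79.  The older group's baseline accident rate is 24.3% of the
younger group's, the employment ratio at ≥65.  WPA disutility is zero (no
usable estimate exists); WPA deaths and treatment costs are modelled.

## Parameters and uncertainty

All inputs live in one flat, validated configuration (YAML) of
`ParameterSpec` entries: value, optional 95% CI and standard error,
distribution family, semantic role (probability, relative effect, cost,
utility, count/rate, fraction) and a provenance flag.  Roles define
admissible domains enforced at load time; structural invariants (untreated
response = 0, age weights summing to 1, admissions ⊆ medically attended
falls) are checked on every set, including each perturbed set built during
sensitivity analysis.

One-way analysis varies each non-structural parameter over its 95% CI where
reported, otherwise ±20%, clipped to the role's domain, and re-evaluates
the full model at both endpoints; parameters are ranked by outcome span.
The tornado outcome is net monetary benefit (NMB = WTP·ΔE − ΔC) for
dominant base cases — the ICER is undefined or explosive near ΔE = 0 — and
the ICER for trade-off comparisons.  Deterministic thresholds (e.g. the
comparator fall risk at which incremental cost crosses zero) are found by
bisection to relative tolerance 1e-6, returning "no crossing" when the
criterion does not change sign over the bracket.

The probabilistic analysis draws every uncertain parameter independently
(2000 draws by default) from a distribution moment-matched to (value, se):
beta for probabilities/fractions/utilities, gamma for costs and rates,
log-normal for relative effects, normal otherwise; the standard error falls
back from the declared value to (CI width)/3.92 to 10% of the mean.  Values
on a support boundary (probability exactly 0 or 1) degrade to a point mass
with a warning rather than failing.  Each parameter owns a counter-based
random stream keyed by (seed, CRC32 of its id), so the draw sequence of one
parameter is invariant to the presence of others; identical seeds give
bitwise-identical analyses.  Draws that assemble into an invalid set (e.g.
a gamma draw of falls-per-faller below 1, expected less than once per
thousand draws at the reference dispersion) are resampled from per-parameter
overflow streams and counted.

## Scenarios

Scenario analyses cover the pure age subgroups and two alternative
responder definitions — wake after sleep onset (WASO ≤60 min) and latency
to persistent sleep (LPS ≤20 min) — each paired with the insomnia
disutility estimated under the same measure.  Scenario overrides may touch
only response rates and the insomnia disutility; everything else is
inherited.  The WPA weighting is recomputed from the scenario's response
rate.  One consequence worth stating: because the response rate moves the
WPA odds ratio, it moves WPA deaths and hence the half-cycle factor on drug
and visit costs — a sub-0.01-JPY effect under the reference set.  The tests
pin the exact invariance of drug/visit/fall/MVC costs with WPA fatality set
to zero, and sub-yen invariance otherwise.

## Reference fixture and what tests do and do not show

Roughly thirty inputs are printed in the published model description and are
embedded verbatim (`provenance: printed`, each with a source string).  The
remaining inputs — baseline event risks, unit event costs, the utility
norm, event disutilities, the zolpidem relative effects, the visit fee, the
WASO/LPS inputs, age weights, the re-fall regression anchor rate and slope
— are not publicly reproduced; the fixture supplies placeholder values of
realistic Japanese magnitude (e.g. the 730-JPY re-examination fee, a 20%
annual faller proportion in older adults), each flagged
`provenance: placeholder` in the shipped manifest CSV.

Under these placeholders the reference evaluation reproduces the published
qualitative pattern — lemborexant dominant over suvorexant and zolpidem IR,
QALY ordering lemborexant > suvorexant > untreated > zolpidem IR, and an
ICER vs untreated insomnia between zero and the WTP threshold — and the
one-way analysis identifies the comparator fall risk as the dominant
uncertainty, as published.  Exact published totals (e.g. QALYs of 0.4220 or
costs of JPY 34 034) depend on the unprinted inputs and are deliberately
not asserted; tests check printed arithmetic exactly and everything else
structurally (partitions, monotonicity, convexity, determinism, oracle
agreement).  Passing tests therefore certify the machinery and the printed
arithmetic, not the unpublished calibration.

`random_parameters(seed)` draws structurally valid sets from wide ranges
(probabilities to 0.5, relative effects 0.25–4, costs over orders of
magnitude) for property-based testing; across seeds it exercises dominant,
dominated and trade-off regimes.

## Numerical choices

- Six months = 0.5 years = 182.625 drug-cost days (365.25/2); visits billed
  as 6 whole months at 1.3 visits/month.
- ICERs are computed from full-precision outputs; rounding (QALYs 4 dp, JPY
  and USD integers, relative effects 2 dp, percentages 1 dp) happens only
  in the reporting layer.  JPY→USD uses half-up rounding at 107 JPY/USD.
- Weak dominance (one margin strict, the other zero) is labelled
  dominant/dominated; both-zero increments are "equal"; ICERs are reported
  only for same-sign trade-offs.
- Composite risks pushed past 1 by a sensitivity perturbation are clipped
  to 1 with a logged warning; negative expected QALYs are floored at 0 with
  a warning.  A probability of exactly 1 entering the hazard conversion
  returns 1 with a warning (no finite hazard).
- Problem sizes: the law-of-large-numbers check runs 20 000 draws on a
  two-parameter linear configuration; grid-scan cross-checks use 1000
  points; the full PSA uses the configured 2000 draws.

## Limitations

Beyond the placeholder calibration: efficacy measured at one month is held
constant for six; no treatment-emergent adverse-event disutilities; no
indirect or caregiver costs; no correlation structure between sampled
parameters; no lifetime extrapolation or efficiency frontier across more
than two strategies (comparisons are pairwise against lemborexant, as
published).
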