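# Methods

## Model structure

The package implements a discrete-time cohort state-transition model for a
two-arm comparison (an active drug vs best supportive care) in an advanced
cancer setting. Three clinical states — progression-free (PFS), progressed
disease (PD), dead — are expanded to five implementation states by splitting
PD into two one-month tunnel states (PD1, PD2) plus PD3+. The tunnels exist
purely to keep a duration-dependent cost Markovian: the first two months
after progression carry a higher cost tier (work-up, palliative
intensification), after which the monthly cost falls back to the supportive
level. Both tunnel states and PD3+ share one death probability and one
utility; death is absorbing.

Assumptions inherited from this structure:

- constant (time-homogeneous) monthly hazards within each state;
- the cohort is an expectation — no individual-level variability beyond the
  parameter uncertainty of the PSA (no microsimulation mode);
- the drug is taken until progression, so its acquisition cost accrues in
  PFS only; after progression both arms pay the same supportive costs.

## Conventions and numerical choices

- **Cycle length** 1 month; **horizon** 120 cycles (10 years, by which the
  cohort is essentially absorbed); **cohort size** 1,000 (display only —
  per-patient results are invariant to it).
- **Accrual**: state membership is read at cycle start and accrues cost and
  utility for the whole cycle; **no half-cycle correction**. This is the
  simplest cohort convention and makes arm cost *exactly* affine in the drug
  price, which the price solver exploits. A half-cycle correction would
  shift absolute costs/QALYs by roughly half a cycle's accrual but barely
  moves the incrementals.
- **Discounting**: cycle *t* (1-based) is discounted by (1+r)^(−t/12),
  r = 0.035/year — i.e. the annual factor applied at fractional-year
  exponents, so cycle 12 is discounted by exactly 1/1.035.
- **Utilities** are annual QALY weights; a monthly cycle contributes
  utility/12.
- **Transition-matrix validation** requires rows to sum to 1 within 1e-9 and
  rejects PFS exit probabilities summing above 1; cohort conservation holds
  to 1e-9 persons over the full horizon (pure linear algebra, no
  renormalisation).

## Parameter uncertainty

Every uncertain input is a tagged parametric distribution:

| input | family | fitting rule |
|---|---|---|
| transition probabilities | beta | pseudo-counts α = p·n, β = (1−p)·n at the per-arm trial size n (451/452 in the bundled fixture) |
| utilities | beta | method of moments from mean and SE: ν = m(1−m)/se² − 1 |
| medical/pharmaceutical costs | gamma (shape, rate) | method of moments: shape = m²/v, rate = m/v |
| drug acquisition price | uniform | fixed €20 administrative spread |

Non-integer pseudo-counts are deliberate: rounding to whole events would
shift the stated point probabilities by ~0.2%. The bundled fixture's cost
gammas have very small coefficients of variation (shape ≈ 1,300–7,200), so
cost uncertainty is modest relative to transition/utility uncertainty.

The PSA draws all parameters independently; utilities are state properties,
so one shared utility draw per iteration feeds both arms, while transitions
and costs are arm-specific. Independent Monte Carlo is exactly equivalent to
a Gibbs scheme here (independent priors, no data-updating), so no burn-in is
used. The engine is vectorised across iterations: it accumulates each
draw's discounted expected months per state in one pass over the horizon,
then takes dot products with the drawn costs and utilities; 50,000
iterations run in ~1 s. 95% intervals are equal-tailed percentile
intervals. Convergence diagnostics report MC standard errors (SD/√n) and
running means on a 1% grid, the tabular analogue of trace plots.

## Value-based price inversion

Arm cost is affine in the monthly drug price p with slope equal to the mean
discounted months in PFS, and the incremental QALYs do not depend on p at
all. The solver therefore runs the PSA at two anchor prices under **common
random numbers** (one seed drives every run; the candidate price only
shifts the uniform price distribution's location, so the underlying
deviates are identical), fits the ΔC(p) line, checks affinity at the
midpoint (relative residual < 1e-6, else bisection via Brent's method), and
solves ΔC(p) = λ·ΔE in closed form. A confirmation run at the solved price
(same seed) verifies |ICER − λ|/λ; under CRN the round trip is exact to
machine precision, so the 1%-tolerance recovery check is a structural
invariant, not a statistical one. A threshold that cannot be reached at any
non-negative price yields a negative solved price, reported with a warning
flag and a confirmation run clamped at zero.

## One-way sensitivity analysis

Each scenario perturbs one parameter group and reports (a) the value-based
price re-solved under the scenario at the base threshold and (b) the ICER
of the scenario model with the price fixed at the base-case solved price —
the only reading under which a pure price cut halves the "new price"
exactly. Perturbation rules preserve each family's uncertainty structure:
utility means shift with SEs preserved; cost means scale at fixed CV (gamma
keeps its shape); survival effects act on the hazard scale (a +10% median
improvement divides the affected monthly hazards by 1.1, i.e.
p′ = 1 − (1−p)^(1/1.1)) and apply to the intervention arm, since they
represent treatment effectiveness. An overall-survival effect scales death
hazards from both PFS and PD (the attribution between them is not
identifiable from state-level inputs), which is flagged in the output.
These rules make the computed table internally anti-monotone: a scenario
whose fixed-price ICER falls below the threshold necessarily re-solves to a
higher price.

## Synthetic study generator

The generator emulates the full derivation chain a real analysis follows:
trial medians → monthly probabilities via the constant-hazard conversion
(risk = 1 − 0.5^(1/median), identically 1 − e^(−ln2/median)); binomially
simulated event counts → beta uncertainty; cost means with a CV → gamma by
moments; utility means/SEs → beta by moments. Default ranges describe a
second-line oncology setting: comparator median PFS 2–4 months,
intervention 4–8, post-progression survival 8–18 months, supportive costs
in the hundreds of euro per month, a four-figure monthly drug price.
Because value-based pricing is only meaningful for an effective drug, the
generator rejects candidate draws whose expected QALY gain is below 0.02 or
whose zero-drug-price ICER exceeds 90% of the lowest configured threshold,
redrawing from the same stream (deterministic per seed).

What it does **not** emulate: censoring and non-constant hazards (real
survival curves are not exponential), correlation between costs and disease
severity, structural uncertainty, or individual patient data. Passing tests
on synthetic studies therefore validate the *pipeline* — conversions,
engine, solver round trip — not the clinical realism of any particular
parameterisation.

## Fidelity to the original analysis of the bundled fixture

The bundled fixture reproduces, verbatim, the published inputs of a
sorafenib-vs-BSC value-based-pricing analysis (monthly probabilities
0.104/0.21, 0.034/0.042, 0.05/0.051; utility betas (153.26, 48.4) and
(91.8, 43.2); cost gammas and the uniform(2880, 2900) price). Running this
implementation on those inputs does **not** reproduce that analysis's
headline outputs, and the discrepancy is not attributable to Monte-Carlo
noise or to the open structural choices (accrual timing, half-cycle, tunnel
timing): the original report's own figures are mutually inconsistent. Its
printed PD death probabilities imply a mean post-progression survival near
20 months, which fixes the comparator arm's discounted cost near €13k —
about 75% above the originally reported €7,336 — while its price/cost rows
imply ~6.4 discounted PFS drug-months and a much *shorter* progressed
phase; and its reported QALY gain (0.1605) closely matches this model's
discounted-to-undiscounted *life-year* gain band (0.153–0.167) rather than
any utility-weighted difference obtainable from its inputs. This
implementation reports its own computed values (e.g. ΔE ≈ 0.126, comparator
cost ≈ €13.3k, ICER at current price ≈ €176k/QALY, value-based price ≈
€843/month at €60k/QALY) and makes no attempt to recover the published
figures by altering the published inputs. The original report also prints
two different current-price ICERs (102,879 in text, 102,616 in its
threshold table); both sit far below this implementation's value.

## Known limitations

- Constant hazards and a three-state clinical structure are strong
  simplifications; no survival-curve fitting is provided.
- No cost-effectiveness acceptability curves or EVPI.
- No microsimulation; all results are cohort expectations.
- The price solver assumes the drug cost enters linearly through PFS
  occupancy; models violating that (dose tapering, post-progression drug
  use) would rely on the bisection path.
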