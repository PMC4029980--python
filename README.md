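# vbprice

Probabilistic Markov cohort cost-utility modelling and **value-based price
inversion** for drug vs supportive-care comparisons, built around a bundled
parameterisation of sorafenib vs best supportive care (BSC) in second-line
metastatic renal cell cancer.

Health-economics analysts usually ask "is this drug cost-effective at its
price?". Value-based pricing inverts the question: *what price makes it
exactly cost-effective?* This package answers both, with full parameter
uncertainty, from a single declarative model configuration.

## The model

A monthly-cycle cohort model over five states: progression-free survival
(PFS), two progressed-disease tunnel months (PD1, PD2 — carrying the higher
early-progression cost tier), PD3+ and Death. A cohort of 1,000 patients
enters in PFS and is propagated for 120 cycles by a row-stochastic matrix
built from three monthly probabilities per arm (PFS→PD, PFS→Death,
PD→Death). Per cycle *t*, each alive state accrues its monthly cost and
utility/12, discounted by (1+r)^(−t/12) with r = 3.5%/year:

- Cost(arm) = Σ_t d(t) · occ(t) · c,  QALY(arm) = Σ_t d(t) · occ(t) · u/12
- ΔC = C_int − C_comp, ΔE = E_int − E_comp, ICER = ΔC/ΔE
- value-based price p\*: the drug price with ICER(p\*) = λ, the
  willingness-to-pay threshold (here 1–3× GDP per capita ≈ 20,000–60,000
  €/QALY)

Uncertainty: probabilities and utilities are beta-distributed (utilities
fitted from mean/SE by moments, probabilities from pseudo-counts at the
trial sample size), costs are gamma (method of moments), the drug price is
uniform with a fixed €20 spread. The PSA draws all parameters independently
(utilities shared across arms) and is fully vectorised — 50,000 iterations
of the 120-cycle model run in about a second.

Because the drug cost accrues only in PFS, arm cost is exactly affine in
the price (slope = discounted expected PFS months), so the solver fits the
incremental-cost line from two anchor PSA runs under common random numbers
and inverts ICER(p) = λ in closed form, with a bisection fallback and a
same-seed confirmation run.

## Worked example

```python
import vbprice as v

cfg = v.load_reference_config()           # bundled sorafenib-vs-BSC fixture
res = v.run_psa(cfg, iterations=50_000, seed=1)   # at the current price
vb  = v.solve_vbp_price(cfg, 60_000, iterations=50_000, seed=1)
```

prints (via `res.summary()` / `vb`):

```text
sorafenib arm: 35521 EUR (29079-43402), 1.274 QALY
bsc arm:       13288 EUR (9357-18822), 1.147 QALY
incremental:   dC=22233 EUR, dE=0.1262 QALY, ICER=176175 EUR/QALY
value-based price at 60,000 EUR/QALY: 843 EUR/month (confirmation ICER 60000, method affine)
```

Read: at its current reference price (~€2,890/month) sorafenib costs an
extra €22,233 per patient for a gain of 0.126 QALYs — about €176,000 per
QALY, far above a 3×-GDP threshold. Holding everything else fixed, the
price at which the ICER lands exactly on €60,000/QALY is ≈ €843/month.
(These are this implementation's estimates from the published model inputs;
see `docs/methods.md` for structural conventions and for a discussion of
discrepancies against the originally reported results.)

The same pipeline is scriptable from the shell:

```bash
vbp solve --wtp 60000 --iterations 50000 --seed 1
vbp table --wtp 20000,40000,60000 --out thresholds.csv
vbp sensitivity --out one_way.csv        # bundled one-way scenario set
vbp synth --seed 7 --out synthetic.yaml  # generate a synthetic study config
```

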