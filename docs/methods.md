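# Methods

## Model

The analysis assumes dichotomous susceptibility: a fraction `p` of the
population can develop the cancer under study during their lifetime; the
remaining `1 - p` cannot. Within the susceptible pool, first presentation
of the cancer at age `t` is governed by an ordinary survival triple — the
conditional hazard `h(t)` (individual cancer presentation rate), survival
`S(t) = exp(-H(t))` (individual cancer resistance rate, with `H` the
cumulative conditional hazard) and density `f(t) = h(t) S(t)`. The
population-level (unconditional) quantities follow from the two-component
mixture:

    S_U(t) = 1 - p + p S(t)
    h_U(t) = p h(t) / (p + (1 - p) exp(H(t)))
    h(t)   = h_U(t) / (1 + (p - 1) exp(H_U(t)))

with `H_U(t)` the cumulative unconditional hazard. `S_U` is floored at the
immune fraction `1 - p`, so `H_U` is bounded by `-ln(1 - p)`; its limit is
the overall cumulative unconditional hazard

    H_UO = -ln(1 - p) ≈ p        (first order for small p).

Estimation proceeds in the opposite direction: the registry yields an
estimate of `h_U` on an age grid; its total gives `H_UO`, hence `p`; and
the small-`p` working estimate of the presentation rate is

    h^(t_i) = h^_U(t_i) / (H^_UO - H^_U(t_i)),

the discrete form of the exact inverse map expanded to first order in `p`.
The relative deviation of the working estimate from the exact inverse is
`~ p S / (2 S_U) <= p/2`, linear in `p` (verified by a log-log slope test in
the acceptance suite).

This is a cure-fraction (mixture cure) structure applied to cancer
*onset* rather than post-diagnosis survival. It deliberately replaces
continuous frailty with a binary susceptibility indicator; no competing
risks, migration or screening effects are modelled.

## Registry model and APC identification

Observed counts per age interval `i` and calendar period `j` are modelled
as

    O[i, j] ~ Poisson( PY[i, j] * exp(mu + a_i + b_j + c_k) ),  k = j - i + n

with person-years `PY` as exposure. The age/period/cohort effect families
are structurally collinear (each family carries a free level, and cohort =
period − age leaves a free linear drift), so the model is identified by
convention, not by data:

- **Anchoring.** `a_{i*} = b_{j*} = c_{k*} = 0` at user-chosen reference
  indices, with `k* = j* - i* + n`. The defaults anchor the 1990–94 period
  (`j* = 4`) and the 70–74 age interval (`i* = 11`), hence `k* = 9`;
  anchoring `j* = 7` (2005–09) gives `k* = 12`.
- **Drift.** The common linear trend is allocated to the age effects by
  constraining the cohort effects to zero linear trend. The constraint sum
  runs over the cohorts supported by at least two grid cells. The two
  extreme anti-diagonal cohorts rest on a single cell each; when such a
  cell draws zero counts its ML effect diverges to −∞, and a trend
  constraint that includes it would push the divergence into every other
  parameter. Restricting the constraint to multi-cell cohorts (a property
  of the grid geometry, not of the data) keeps such divergences local; a
  Monte-Carlo check of period-effect sampling SDs against Wald SEs
  motivated this choice. The convention is recorded in the fitted object's
  `drift_convention` field. Note that an alternative drift allocation
  changes the age-effect slope by a linear term while leaving all fitted
  means (and hence everything downstream of `h_U`) unchanged.

The fit maximizes the Poisson log-likelihood on a null-space
parameterization of the constraints by damped Newton (IRLS): iteration cap
200, score tolerance `1e-8 * sqrt(total counts)` (the score is in count
units; the scaling keeps the rule above the floating-point noise floor of
large registries while leaving parameter error far below 1e-6). The
likelihood is concave on the constraint space; the Newton step uses a
singular-value cutoff so aliased layouts (e.g. single-period tables)
converge to the identified means. The covariance is the inverse observed
information mapped back to the full effect vector. Fitted cell means
reproduce the observed total (intercept-property of Poisson ML) and are
invariant under re-anchoring.

The population hazard rate is the fitted age curve corrected to the
anchored period and cohort chain, `h_U(t_i) = exp(mu + a_i)`, with delta-
method SEs and the full curve covariance retained for downstream
propagation.

The conventional ">15 cases per cell" retention rule is computed and
reported for every table. By default sub-threshold cells still enter the
likelihood with weight 1: Poisson ML handles low counts correctly, and
excluding whole young-age rows would bias `H_UO` low. Setting
`RunConfig.exclude_masked` gives the strict behaviour (weight 0), in which
case a fully masked age row is an error.

## Discretization conventions

- Hazards live on a uniform age grid (default ages 20–99, width Δ = 5,
  n = 16) and are evaluated at interval midpoints `t_i` (72.5 for 70–74).
- Cumulative hazards use the left-cumulative rectangle rule: `H(t_1) = 0`,
  `H(t_i) = Δ Σ_{m<i} h[m]`, `H_UO = Δ Σ_m h[m]`. Evaluating at the left
  edge keeps `H_UO − H_U(t_i)` no smaller than interval `i`'s own mass, so
  the working estimate stays positive through the last interval (where it
  equals `1/Δ` exactly when the pool is exhausted there — a convention
  artifact to keep in mind when reading the oldest interval).
- With midpoint-evaluated hazards the overall sum is a midpoint-rule
  quadrature (O(Δ²)); for a pool-exhausting curve the identity
  `H_UO = −ln(1−p)` holds to well under 2% at Δ = 5 and tightens under
  grid refinement. For curves that do not exhaust the pool within the
  grid, the truncated tail `p·S(t_max)` is the dominant (grid-independent)
  error term.
- `p` enters each formula on its own scale: the working presentation-rate
  estimate uses the first-order `p = H_UO` (that is how it is derived);
  exact mixture identities (forward/inverse maps, resistance curves) use
  `p = 1 − exp(−H_UO)`.
- The exact inverse map is computed in `expm1` form,
  `1 + (p−1)e^{H_U} = (expm1(−H_U) + p)/(1 + expm1(−H_U))`, which avoids
  catastrophic cancellation near pool exhaustion and makes
  forward-then-inverse an identity to ~1e-12 relative.

## Error propagation

The first-order SE formula for the working estimate treats the numerator
and denominator as independent:

    SE²[h^] = (h^_U²/D²) ( SE²[h^_U]/h^_U² + SE²[D]/D² ),  D = H^_UO − H^_U,

with `SE²[D]` the independent-interval tail sum `Δ² Σ_{m≥i} SE²[h_U(t_m)]`.
Both this formula and a complete first-order (delta-method) propagation
through `h_U(t_i) / (Δ Σ_{m≥i} h_U(t_m))` using the full fitted covariance
are implemented. The per-age hazards from one registry fit share the fit
intercept and are strongly positively correlated; Monte-Carlo calibration
on the default synthetic registry (500–1,000 Poisson replicates) shows the
independence form overstates the SE by up to ~1.9× at old ages (the shared
intercept cancels between numerator and denominator) and understates
`SE[H_UO]` ~4×, while the full delta propagation is within ~8% of the
empirical SD at every interval with ≥ 30 expected cases. The pipeline
therefore defaults to the covariance-based propagation
(`se_mode="delta"`); `se_mode="independent"` reproduces the plain formula.

Resistance-rate SEs use the delta method `SE[S] = S · SE[H]` with `SE[H]`
from the independent-interval sum over the conditional-hazard SEs; this is
a first-order substitute and is expected to be conservative in the same
way as the independence formula above.

"Greatly overlapping error bars" between strata is operationalized as a
per-interval z-test on the difference at the 5% level (|d| ≤ 1.96·SE of
the difference) — a standard and stricter criterion than geometric
interval overlap; reports state it explicitly so users can reinterpret.

## Synthetic registry generator

The generator is the forward direction of the model and defines the
conditions under which the pipeline is validated:

- Conditional hazard: Gompertz `h(t) = α exp(βt)` with defaults
  `α = 1e-5` per person-year (extrapolated to age 0) and `β = 0.11` per
  year; a piecewise-constant family is available for closed-form checks.
  `H(t)` is accumulated by trapezoidal integration at 0.01-year steps from
  age 0, and the exact mixture map gives `h_U` at the grid midpoints.
- Susceptible fraction default `p = 0.01`; anchored period/cohort effects
  default to zero and must satisfy the same identification constraints the
  fitter imposes (so recovery is exact, not up-to-reparameterization).
- Expected counts `μ[i,j] = PY[i,j] · h_U(t_i) · exp(b_j + c_k)` with the
  embedded male person-year matrix as the default template; observed
  counts are Poisson draws. Sub-streams for multi-table experiments are
  derived from one master seed via `numpy` `SeedSequence` spawning.

The defaults were chosen once to emulate a large multi-area registry
extract for a moderately common gastrointestinal cancer: the susceptible
pool is nearly exhausted by age 100 (cumulative conditional hazard ≈ 5.4,
so `H_UO` carries essentially the full `−ln(1−p)`; truncation ≈ 0.5%)
while every age row keeps enough expected cases (row totals ≈ 13–2,500)
for stable Poisson ML. What the generator does *not* emulate: secular
trends in coverage, registry reporting delay, age heaping, competing
mortality, or misclassification — passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness of the model against real-data violations.

## Validation experiments (acceptance suite)

All run on one CPU in about a minute total; problem sizes are chosen to
keep the whole suite at desk scale:

1. Cohort-index and grid worked examples (exact).
2. Exact inversion of the mixture maps to 1e-10 relative.
3. `H_UO = −ln(1−p)` at Δ = 5 within 2%, error shrinking at Δ = 1.
4. First-order approximation error linear in `p` (log-log slope ≈ 1,
   R² > 0.95) over `p ∈ {0.001, 0.005, 0.01, 0.05}`.
5. SE calibration of the presentation-rate estimate against 1,000 Poisson
   replicates: within 15% at intervals with ≥ 30 expected cases.
6. APC recovery: noiseless expected counts reproduce the generating
   effects to 1e-6; pooled 95% CI coverage ≥ 90% over 200 replicates.
7. Geographic invariance in silico: region pairs sharing the conditional
   hazard with `p` scaled by 0.7 give concordant presentation rates at
   ≥ 90% of well-populated intervals while the `H_UO` ratio tracks 0.7.
8. Embedded fixture integrity against the printed cells.

## Known limitations

- The drift allocation is a convention; age-effect slopes are only
  meaningful relative to it, and other tools may allocate drift
  differently (fitted means agree regardless).
- Wald CIs for effects supported by very sparse cells (single-cell corner
  cohorts, the oldest age row) can be degenerate when those cells draw
  zero counts; the constraint design keeps the damage local but the
  affected entries are individually uninformative.
- The resistance-rate SE is a first-order substitute; no exact reference
  construction is implemented for it.
- The working presentation-rate estimate at the last age interval is
  pinned near `1/Δ` whenever the pool exhausts within the grid.
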