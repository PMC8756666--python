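# Methods

## Model and assumptions

The package implements the standard irreversible-investment real-options
model specialised to an elderly-care service project (ECSP):

- **Demand** for nursing beds follows a geometric Brownian motion
  `dQ_t = α Q_t dt + σ Q_t dz` under the risk-neutral measure, so
  `E[Q_t] = Q_0 e^{αt}`. Demand units are abstract: the same code serves
  bed counts (the valuation grids) and survey percentage points (the
  calibration series); no unit conversion is attempted and the caller
  must stay consistent.
- **The project** completes instantly at exercise, runs for its whole
  lifetime *T*, and sells every unit of demand at the regulated price
  *P* (the investor is a price taker). The sunk cost is `μ I_t`, with
  the premium coefficient μ ≥ 1 capturing the higher cost of serving
  semi-disabled and disabled clienteles. Discounting is at a constant
  risk-free rate *r*; the rate-of-return shortfall `δ = r − α` must be
  strictly positive, and scenarios with δ ≤ 0 are rejected at
  construction rather than producing infinities (with δ ≤ 0 waiting is
  never costly and the option would never be exercised).
- **Valuation** is the closed form of this model class: the option value
  solves the homogeneous second-order ODE whose power exponents are the
  roots of `½σ²β(β−1) + (r−δ)β − r = 0`; the package computes both roots
  analytically and treats the ODE/boundary-condition structure as
  properties to verify (value matching, smooth pasting, the vanishing
  limit at Q→0), not as equations to re-derive numerically.
- **Subsidy schemes** enter multiplicatively: the construction subsidy
  reduces the effective cost to `I_t − ρN_sS_cs` (rejected as infeasible
  if that is non-positive), the operating subsidy raises the effective
  price to `P + θS_ps`. All scheme quantities reuse the unsubsidized
  closed forms on a transformed scenario, which makes the exact ratio
  identities `Q*_cs/Q* = I'_t/I_t` and `Q*_ps/Q* = P/(P+θS_ps)` hold to
  machine precision by construction.

## Parameters

| symbol | field | default | units | role |
|---|---|---|---|---|
| I_t | `investment_cost` | 60,000,000 | CNY | sunk construction cost |
| P | `price` | 36,000 | CNY/elder-year | regulated service price |
| T | `lifetime` | 30 | years | operating horizon |
| N_s | `scale` | 300 | beds | project capacity |
| S_cs | `construction_subsidy` | 12,000 | CNY/bed (one-time) | scheme 1 amount |
| S_ps | `operating_subsidy` | 4,800 | CNY/elder-year | scheme 2 amount |
| ρ, θ | `rho`, `theta` | 0.90 | — | quality-supervision pass-through in [0,1] |
| μ | `premium` | 1.20 | — | care-intensity cost multiplier (given input) |
| r | `rate` | 0.10 | /year | risk-free rate |
| α | `drift` | 0.005 | /year | demand drift |
| σ | `volatility` | 0.12 | /year | demand volatility |

The defaults are the baseline numerical scenario; α and σ are exactly
what the packaged survey series calibrates to. μ is treated as a given
input (its upstream derivation is not part of the model).

## Survey calibration conventions

Estimation consumes wave-level aggregates only (no microdata,
weighting or attrition handling). Proportions are kept at full
precision from the raw counts; the printed two-decimal columns are a
display layer reproduced with round-half-up (so 0.18534 → 0.19). Two
conventions are implemented verbatim and deliberately **not** corrected:

- **Time scaling σ = k/Δy.** For i.i.d. GBM increments the usual scaling
  would be k/√Δy; the k/Δy convention yields σ̂ ≈ s/√Δy when the true
  per-√year volatility is s. The estimator-consistency tests therefore
  check the estimate against its own analytic expectation under this
  convention — `E[σ̂²] = e^{2αΔy}(e^{s²Δy}−1)/Δy²` — not against s.
- **Divisor n − 2 with n = number of waves.** Eight waves give seven
  relative changes, so the divisor equals the number of changes minus
  one and k² is exactly the unbiased sample variance of the ω_i. That n
  counts waves (not increments) is pinned down by reproducing the
  printed volatility from the printed counts.
- **Scalar Δy = 3.** Actual wave gaps in the packaged series are 2–4
  years; the calibration treats them as evenly spaced 3-year intervals.
  A per-interval mode (`delta_y="actual"`) that divides each ω_i by its
  actual gap is provided as a diagnostic but is not the convention the
  packaged series reproduces.

Relative changes are undefined when a preceding wave's proportion is
zero; such series are rejected.

## Synthetic data

`simulate_gbm` uses exact lognormal stepping
`Q_{t+dt} = Q_t·exp((α−σ²/2)dt + σ√dt·ε)`, which is distribution-exact
at any step size — no Euler bias, no positivity violations — so moment
tests can use coarse steps. σ = 0 is admitted as the degenerate
deterministic case. One integer seed determines a path or panel
exactly; replicate k of a panel ensemble uses seed + k. Synthetic survey
panels sample a single path at the wave spacing and carry their
generating parameters, which is what makes the estimation module
testable end-to-end: the generator emulates the *shape* of the survey
series (8 waves, 3-year spacing, percent units) but not real-survey
features such as sampling noise in the wave proportions, varying wave
gaps, or attrition — passing consistency tests therefore shows the
estimator recovers the parameters of an exactly-GBM world, not that
real survey data is GBM.

## Numerical choices

- β-roots: closed form; verified in tests against an independent
  bracketed root-finder and the polynomial-roots route, with quadratic
  residuals below 1e−9 (relative) on randomized draws.
- Tangency (value matching / smooth pasting): checked with central
  differences at step 1e−6·Q*, slope tolerance 1e−4 relative.
- Required-subsidy curves: the closed-form inversions are clamped at
  zero for demand at or above the unsubsidized trigger (no subsidy is
  needed there); below it, zero pass-through (ρ = 0 or θ = 0) is an
  infeasible policy and raises.
- Printed triggers are integers; reports round half-up and keep the
  full-precision value (e.g. 271.62) internally.
- Default grids: demand 150–300 step 1 for valuations and spillovers,
  50–300 step 1 for required-subsidy curves; both configurable.
- Monte-Carlo problem sizes: 10,000 paths for the expectation check and
  10,000 eight-wave panels for estimator consistency, asserted at three
  Monte-Carlo standard errors with sample-estimated spread; each runs in
  seconds.

## Design choices where the design was open

- **Per-unit subsidy comparison.** The required-subsidy curves of the two
  schemes are in different denominations (CNY per bed one-time vs CNY
  per elder-year recurring). The comparison reports them per-unit, as
  conventionally plotted, and additionally exposes a clearly-labelled
  `total_outlay` view (S_cs·N_s one-time vs S_ps·Q per year) so the unit
  mixing is not mistaken for a like-for-like cost comparison. Replication
  checks use only the per-unit view.
- **Spillover comparison range.** The operating scheme's payoff spillover
  `dV_ps = Q·θS_ps(1−e^{−δT})/δ` is linear in demand while the
  construction scheme's `dV_cs = μρN_sS_cs` is constant, so at small
  demand (below ≈ 91 beds at the defaults) construction dominates
  analytically. The "operating dominates" ordering is asserted on the
  150–300 valuation grid where it holds pointwise; the small-demand
  crossover is a documented property of the formulas, not an error.
- **Scheme orchestration** is a library module plus a thin CLI; the CLI
  adds no logic. The full derivation trace (β₁, δ, discount factor,
  effective cost/price) is attached to every scenario report.

## Known limitations

- Single constant-parameter GBM; no jumps, mean reversion, regime
  switching, or stochastic discounting.
- Pure schemes only: no mixed construction+operating subsidies, no
  government budget constraint or welfare aggregation.
- The calibration inherits the conventions above; users wanting a
  textbook GBM estimate (log-return MLE, k/√Δy scaling) should treat
  the output as the model's convention, not a consistent estimate of
  per-√year volatility.
- Regional cost heterogeneity and microdata-level survey processing are
  out of scope; the packaged series is wave-level aggregates.
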