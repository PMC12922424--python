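# Methods

## Model structure

A budget impact analysis compares two deterministic cost projections over a
short horizon: a *baseline* scenario (the current treatment mix persists) and
a *projected* scenario (market shares shift toward an intervention).  The
model has four stages, each a pure function of the declarative
`ModelSpec`:

1. **Population.** The treated cohort compounds at the net prevalence growth
   rate *g = incidence − dropout* (additive convention).  Counts are rounded
   to whole patients each year — nearest integer, halves away from zero —
   and the *rounded* count seeds the next year's compounding.  For the
   shipped Qatari cohort (base 173, g = 0.05) this yields 173, 182, 191,
   201, 211; the half-away rule is load-bearing (200.55 → 201) and plain
   nearest rounding is equally required (211.05 → 211, not 212).  A
   `rounding_policy: none` escape hatch gives the exact closed form
   `base · (1+g)^t` for analytic work.
2. **Costing.** Each arm carries a per-patient annual cost per calendar
   year.  Costs are stored per (arm, year) rather than as a price plus an
   inflation rule because real schedules drift non-uniformly; a bottom-up
   assembler (`annual_cost_from_components`) builds an annual figure from
   per-cycle drug acquisition (13 cycles/year for 28-day schedules by
   default) plus annual laboratory, imaging, cardiac-monitoring, visit and
   hospitalisation components, and `blended_unit_cost` prices a comparator
   basket at a share-weighted rate.
3. **Engine.** Year by year, arm cost = N · share · unit cost with the
   arm-level population left fractional (shares split budgets, not people —
   this matches how published BIA tables are computed); incremental impact
   ΔC = projected − baseline with savings negative; per-patient impact
   ΔC/N rounded to integer QAR, halves away from zero; cumulative impact is
   the exact undiscounted sum.  No discounting or inflation adjustment is
   applied anywhere, and no field is exposed for it in v1.
4. **Affordability.** Per-patient yearly impacts are classified against a
   threshold T, by default 1.5 × GDP per capita with a 10% tolerance band:
   saving (≤ 0), affordable (≤ T), borderline (≤ 1.1 T), unacceptable.
   The shipped fixtures override the formula with the published effective
   value T = 453,822 QAR, because the stated inputs (1.5 × 302,172 =
   453,258) do not reproduce the figure the source reports; the override
   field exists precisely so a spec can pin the number actually used.

## Scenario fixtures and back-derivation

The two shipped scenarios are reconstructed from their printed result
tables, stored verbatim (integer QAR) in `src/bimpact/data/*.csv` with a
provenance column.  Since every arm-cost cell equals N · share · unit cost,
dividing by (share × N) recovers the underlying per-arm unit cost; the
baseline column divided by N gives the blended current-mix rate.  Two
consequences of this design:

- The baseline blended rate differs in the third decimal from the projected
  comparator arm's derived rate (the source's own columns are not perfectly
  mutually consistent), so `ModelSpec` carries an optional
  `baseline_unit_costs` table; the fixtures populate it, and the engine
  prices each scenario from its own table.
- Recomputed monetary cells agree with the printed ones to ≤ ~1e-6 relative
  deviation (the residue of integer-printed cells), well inside the 1e-4
  consistency gate.  One per-patient cell (scenario 2, 2026) recomputes one
  QAR above its printed value because the back-derived incremental sits on
  the other side of a half-QAR rounding boundary; `fixture_consistency`
  tracks per-patient exactness separately for this reason.

The fixtures follow the share trajectories the result tables use
(20/30/40/50/60% and 30/40/50/65/80%).  The alternative trajectories stated
in the source's scenario descriptions (10/20/35/50/60% and 40/50/60/70/80%)
are shipped as named `MarketShareTrajectory` objects for completeness but
are not what the printed results arise from.

## Sensitivity analysis

Only one-way (deterministic) analysis is provided; probabilistic sensitivity
analysis is deliberately out of scope for this class of model.  Cost axes
multiply selected arms' unit costs by (1 + level) in a configurable scenario
scope — `both` by default, since a price change applies wherever the drug is
bought; `projected_only`/`baseline_only` support asymmetric questions.
Uptake axes shift the intervention share by a fixed number of percentage
points in every year: the published "±10%" uptake variation is a
percentage-point shift, which the year-5 figures confirm exactly
(−4,517,729 × 0.7/0.6 = −5,270,684), whereas a relative ±10% does not.
Perturbation is pure (the input spec is never mutated; a zero-level
perturbation reproduces the base case bit-for-bit), shifts that would push
any share outside [0, 1] fail loudly, and sub-1e-12 share-sum drift is
renormalized silently.

With fixed unit costs and a comparator-only baseline, ΔC(t) =
N(t) · s(t) · (c_int(t) − c_comp(t)) is affine in the uptake share — the
spider series for an uptake axis is a straight line, asserted in tests by
three-point collinearity at 1e-6 relative tolerance.

## Synthetic models

`generate_synthetic_spec` draws structurally valid random models — 2–5 arms,
positive unit costs (default 50k–200k QAR with ±2% yearly drift), a monotone
intervention uptake trajectory, Dirichlet-distributed comparator splits, net
growth in [0, 10%] — together with the expected `BudgetImpactResult`
computed by direct arithmetic in the generator itself, independent of the
engine.  Same seed, same spec and ground truth, bit for bit.  These
synthetics exercise the engine's arithmetic and invariants; they do not
emulate the messiness of real cost data (correlated price changes,
mid-year switching, adverse-event cost shocks), so passing them shows the
accounting is right, not that any particular real-world forecast is.

## Numerical choices

- All arithmetic is double precision; monetary outputs are rounded to
  integer QAR only at the reporting boundary (unit-cost exports keep two
  decimals).
- Half-away-from-zero integer rounding is implemented as
  `floor(x + 0.5)` / `ceil(x − 0.5)`; ties produced by real cost data sit
  far from representation error at the magnitudes involved.
- Currency conversion (QAR → USD at 3.65) truncates toward zero by default,
  matching how the source's USD figures relate to its QAR figures; a
  `nearest` mode is available.
- Share sums are validated to 1e-9; spider levels compare by exact float
  equality because levels are user-supplied constants, not computed values.
- The population property that sequentially rounded counts stay within
  1 + horizon/2 of the closed form holds for horizons up to ~7 years at
  growth rates up to 20% (verified exhaustively over bases 1–5000); over
  longer horizons rounding error compounds geometrically and the bound
  fails, so the test suite asserts it only in the short-horizon regime.

## Limitations

- Arms are opaque cost baskets: the comparator mix is priced at one blended
  rate, with no per-drug decomposition, dose reductions, wastage, or
  adverse-event micro-costing.
- Patients are on treatment for whole years; there is no within-year
  attrition or stratification by age or stage.
- The horizon is capped at 50 years, but the model's no-discounting
  assumption is only defensible over short (≤ ~5-year) budget windows.
- Cost-effectiveness outputs (QALYs, ICERs) are out of scope by design; a
  BIA answers affordability, not value for money.
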