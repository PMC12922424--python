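"""Validate the engine against synthetic models with known answers.

`generate_synthetic_spec` draws a random but structurally valid model and
computes its expected budget impact by direct arithmetic, independently of
the engine.  Agreement to ~1e-9 relative tolerance across seeds is the
package's internal correctness check.
"""

from bimpact import generate_synthetic_spec, run_budget_impact

for seed in (1, 2, 3):
    spec, truth = generate_synthetic_spec(seed=seed, n_arms=3, horizon=5)
    result = run_budget_impact(spec)
    worst = max(
        abs(r.incremental - t.incremental) / max(1.0, abs(t.incremental))
        for r, t in zip(result.rows, truth.rows)
    )
    print(
        f"seed {seed}: base cohort {spec.population.base_count}, "
        f"cumulative {round(result.cumulative):,} QAR, "
        f"max relative deviation from analytic ground truth {worst:.2e}"
    )
print("\nDeviations at machine precision mean the engine computes exactly "
      "N(t) x share x unit cost summed over arms and years.")
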