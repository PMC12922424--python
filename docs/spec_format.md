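# Model specification format (schema version 1)

A model is one YAML document (JSON, being a YAML subset, also parses).
`load_model_spec` validates the schema and every cross-field invariant and
raises naming the offending field and year; `validate_model_spec` returns
the violation list instead.  `ModelSpec.to_yaml()` /
`ModelSpec.model_dump_json()` round-trip losslessly.

```yaml
schema_version: 1

population:
  base_year: 2024            # first modelled calendar year
  base_count: 173            # patients in the base year (> 0, integer)
  incidence_rate: 0.10       # fraction/year, in [0, 1]
  dropout_rate: 0.05         # fraction/year, in [0, 1]
  horizon_years: 5           # 1..50
  rounding_policy: nearest_half_away_from_zero   # or: none

arms:                        # 1+ arms; arm_id unique
  - {arm_id: abma,         label: ABMA,                 role: intervention}
  - {arm_id: std_care_mix, label: PLBO/RIBO/Other Tx,   role: comparator_mix}

unit_costs:                  # QAR/patient/year, strictly positive;
  entries:                   # must cover every (arm, year) with share > 0
    abma:         {2024: 144226.85, 2025: 143955.1, ...}
    std_care_mix: {2024: 179911.92, ...}

baseline_unit_costs:         # optional; prices the baseline scenario
  entries:                   # (falls back to unit_costs when absent)
    std_care_mix: {2024: 179911.92, ...}

baseline:                    # shares per year sum to 1 (tol 1e-9);
  scenario_name: current_mix # years must equal the population horizon
  shares:
    2024: {std_care_mix: 1.0}
    # ...
projected:
  scenario_name: abma_uptake
  shares:
    2024: {abma: 0.20, std_care_mix: 0.80}
    # ...

threshold:
  gdp_per_capita: 302172     # QAR
  multiplier: 1.5            # effective T = multiplier x gdp_per_capita
  override_value: 453822     # optional; wins verbatim when present
  tolerance_fraction: 0.10   # borderline band above T

currency:                    # optional block, defaults shown
  reporting_currency: QAR
  usd_per_unit_rate: 3.65    # QAR per USD
  conversion_rounding: truncate_toward_zero   # or: nearest
```

Sensitivity axes files (for `bimpact sensitivity`) are a YAML list:

```yaml
- axis_id: uptake
  target: uptake_trajectory            # or: arm_unit_cost
  perturbation_kind: additive_percentage_points   # or: multiplicative_factor
  levels: [-0.10, 0.10]
  # arm_selector: [abma]               # default: intervention arms (uptake)
  #                                    # or all arms (costs)
  # scenario_scope: both               # projected_only | baseline_only | both
```
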