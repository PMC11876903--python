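"""Time-horizon and cohort-size scenarios.

Re-runs the paired comparison at horizons from 5 to 30 years and several
cohort sizes.  Per-patient differences should be roughly stable: the
intervention effect is per-patient, so scale only reduces Monte Carlo noise.
"""

from dataclasses import replace

from hccsim import SimulationConfig, default_params, scenario_grid

params, unprinted, config = default_params()

df = scenario_grid([5, 10, 20, 30], [10_000], params, unprinted, config, seed=3)
print("horizon scenarios (10,000 patients):")
print(df[["horizon_years", "delta_cost", "delta_qaly",
          "delta_cost_per_patient", "verdict"]].to_string(index=False))

df2 = scenario_grid([10], [5_000, 20_000, 50_000], params, unprinted, config, seed=3)
print("\ncohort-size scenarios (10-year horizon):")
print(df2[["n_patients", "delta_cost_per_patient",
           "delta_qaly_per_patient"]].to_string(index=False))
print("\nper-patient savings and QALY gains are scale-stable; totals grow "
      "linearly with cohort size.")
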