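"""Time-to-endpoint survival analysis of a simulated xenograft study.

Simulates four arms (vehicle, each single agent, the combination) of 10
animals with exponential tumor growth and twice-weekly caliper
measurements, derives each animal's fractional time to the 2000 mm^3
endpoint by log-linear regression, and compares arms by log-rank test.
"""

from synergykit import (SimulationConfig, run_survival,
                        simulate_tumor_growth_study)

config = SimulationConfig(seed=5, volume_sigma_log10=0.05)
volumes, fates, truth = simulate_tumor_growth_study(config)

report = run_survival(volumes, fates)
print(report.medians.to_string(index=False))
print()
print(report.logrank.to_string(index=False))
print()
print("Group growth rates are calibrated so the noise-free medians sit at "
      "14 / 17 / 17.6 / 33.7 days; survivors past day 34 are censored. "
      "Small log-rank p-values mean the arms' event-time distributions "
      "differ beyond chance.")
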