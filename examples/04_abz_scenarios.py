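"""Sweep the agricultural-buffer-zone fraction and watch diversity respond.

Runs the scenario grid (0% ... 100% of the candidate cells converted, a few
repetitions each) and prints how persistence, Shannon diversity and
quasi-extinction risk move along the gradient — the experiment at the heart
of the package.
"""

import numpy as np

from bitz import (
    ScenarioSpec,
    SimulationConfig,
    SyntheticLandscapeConfig,
    default_community,
    generate_synthetic_landscape,
    run_scenarios,
)
from bitz.metrics import landscape_qe_threshold, quasi_extinction_risk, shannon

ls = generate_synthetic_landscape(
    SyntheticLandscapeConfig(n_rows=50, n_cols=50, mean_patch_area_cells=80.0, seed=11)
)
community = default_community(28, seed=1)
config = SimulationConfig(repetitions=3, base_seed=7, store_final_state=False)
spec = ScenarioSpec(abz_fractions=(0.0, 0.25, 0.5, 1.0), landscapes=[("demo", ls)])

results = run_scenarios(spec, community, config)
threshold = landscape_qe_threshold(ls)

print(f"quasi-extinction threshold: {threshold:.0f} individuals "
      f"(10,000 per 9 km^2, scaled to {ls.area_m2 / 1e6:.1f} km^2)")
print("fraction  persisting%  shannon  mean QE risk")
for fraction in spec.abz_fractions:
    run = results.runs[("demo", fraction)]
    finals = run.series[:, -1, :]
    persisting = np.mean([(f > 0).sum() for f in finals]) / community.size * 100
    diversity = np.mean([shannon(f) if f.sum() > 0 else 0.0 for f in finals])
    risk = quasi_extinction_risk(run.series, threshold, (40, 50)).mean()
    print(f"{fraction:8.2f}  {persisting:10.1f}  {diversity:7.3f}  {risk:12.2f}")
# more buffer zones -> more types persist and risks fall; Shannon responds
# more slowly because abundances stay uneven.
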