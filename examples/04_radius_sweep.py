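"""Sweep the displacement magnitude r and find the error-minimizing value.

The displacement magnitude is a fixed input of the fit (co-estimating it
with the diffusion rate is unstable), so in practice one fits a grid of
candidate values.  On data generated at r = 6.68 the branch-length error
traces a U-shape whose minimum sits near the true value.
"""

import numpy as np

from sdtrace import (
    ModelConfig,
    SimConfig,
    fit,
    r_sweep_report,
    simulate_locations,
    simulate_sequences,
    simulate_topology,
)

R_GRID = [0.0, 1.0, 3.0, 5.0, 7.0, 10.0]
N_TREES = 4

true_trees, fits_by_r = [], {r: [] for r in R_GRID}
for seed in range(N_TREES):
    sim = SimConfig(seed=seed)
    tree = simulate_topology(sim.n_leaves, sim.tau_end, seed=seed,
                             time_resolution=sim.time_resolution)
    loc = simulate_locations(tree, sim.sd_params(), seed=seed)
    mat = simulate_sequences(tree, sim.pmm_params(), sim.alphabets(),
                             seed=seed)
    topo = tree.copy()
    for v in topo.parent:
        topo.branch_length[v] = None
    true_trees.append(tree)
    for r in R_GRID:
        fits_by_r[r].append(fit(
            topo, mat, loc,
            ModelConfig(modality="S+L", r=r, tau_end=sim.tau_end,
                        restarts=2, seed=seed)))

report = r_sweep_report(fits_by_r, true_trees, truth_sigma=1.5)
print(f"{'r':>5}  {'sigma bias':>10}  {'mean MAPE':>9}")
for row in report["per_r"]:
    print(f"{row['r']:5.1f}  {row['mean_sigma_bias']:10.3f}  "
          f"{row['mean_mape']:9.3f}")
print(f"\nerror-minimizing r: {report['argmin_r']} "
      f"(data generated at r = 6.68)")
# r=0 (pure Brownian) inflates sigma-hat because the displacement variance
# must be absorbed by diffusion; the branch-length error is smallest for r
# near the generating value.
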