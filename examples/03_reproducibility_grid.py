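"""Robustness of the group result to window size and sliding step.

Reruns the full group analysis for every window/step combination of the
protocol grid ({50, 64, 100} s windows x {2, 4} s steps) on the same cohort
and quantifies agreement: Pearson correlation of group t-maps and Dice
overlap of surviving-cluster vertex sets against the 64 s / 4 s default.
"""

from surfstab.pipeline import RunConfig
from surfstab.reproducibility import (ParameterGrid, dice_overlap,
                                      map_agreement, run_grid)
from surfstab.synthetic import simulate_cohort

cohort = simulate_cohort(n_per_group=15, seed=0)
grid = ParameterGrid(window_s=(50.0, 64.0, 100.0), step_s=(2.0, 4.0),
                     fwhm_mm=(None,))
entries = run_grid(cohort, grid, RunConfig(seed=0, fwhm_mm=None))

ref_key = (64.0, 4.0, None)
ref = entries[ref_key]
print(f"{'window':>7} {'step':>5} {'clusters':>9} {'t-map r':>8} {'Dice':>6}")
for key, entry in entries.items():
    r = map_agreement(ref.tmap, entry.tmap, cohort.mask)
    d = dice_overlap(ref.surviving_vertices, entry.surviving_vertices)
    mark = "  (reference)" if key == ref_key else ""
    print(f"{key[0]:7.0f} {key[1]:5.0f} {len(entry.surviving):9d} "
          f"{r:8.3f} {d:6.3f}{mark}")

print("\nHigh t-map correlations and Dice near 1 mean the case-control "
      "difference does not depend on the sliding-window parameters.")
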