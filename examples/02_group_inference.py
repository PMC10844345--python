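"""Full case-control analysis on a synthetic cohort with a known effect.

Simulates 15 patients and 15 controls; patients carry 0.6 extra modulation
amplitude in one parcel (lower expected stability there).  The pipeline runs
motion QC, nuisance regression, band-pass, stability, Z-scoring, a
vertex-wise group GLM (mean framewise displacement as covariate), cluster
formation (|t| at two-sided p < 0.001, area > 20 mm^2), permutation cluster
p-values (499 shuffles) and BH-FDR, then correlates surviving-cluster
stability with the visual-field covariate in patients.
"""

import numpy as np

from surfstab.pipeline import RunConfig, end_to_end
from surfstab.synthetic import simulate_cohort

cohort = simulate_cohort(n_per_group=15, seed=0)
print(f"simulated {len(cohort.subjects)} subjects; ground-truth effect "
      f"parcel(s): {cohort.truth.effect_parcels}")

# smoothing off: a 6 mm kernel is below this coarse demo mesh's resolution
result = end_to_end(cohort, RunConfig(seed=0, fwhm_mm=None))

print("\ncluster table (one row per suprathreshold cluster):")
print(result.cluster_table.to_string(index=False))

effect = set(np.flatnonzero(
    cohort.atlas.labels == cohort.truth.effect_parcels[0]).tolist())
for i, c in enumerate(result.surviving, 1):
    overlap = len(effect & set(c.vertices.tolist()))
    print(f"surviving cluster {i}: sign {c.sign:+d}, q = {c.q:.4f}, "
          f"{overlap}/{len(effect)} effect-parcel vertices covered")

print("\nstability vs visual-field mean deviation (patients):")
print(result.correlations.to_string(index=False))
print("\nA negative-sign surviving cluster over the effect parcel means the "
      "injected loss of stability was recovered; q is the BH-FDR-adjusted "
      "permutation cluster p.")
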