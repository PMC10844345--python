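"""Compute one subject's functional-stability map on a synthetic cortex.

Builds a 162-vertex spherical surface with 12 parcels, simulates a BOLD-like
series in which parcel 2's connectivity switches between network states, and
computes the per-vertex Kendall's-W stability map (64 s windows, 4 s steps,
parcel-mean targets).  Stable (stationary) parcels score high W; the
state-switching parcel scores low.
"""

import numpy as np

from surfstab import WindowSpec, stability_map, zscore_map
from surfstab.synthetic import (default_atlas, default_config, default_mesh,
                                simulate_subject_bold)

mesh = default_mesh()
atlas = default_atlas(mesh)
config = default_config().with_amplitude(2, 0.8)   # parcel 2 switches states
mask = np.ones(mesh.n_vertices, dtype=bool)

bold = simulate_subject_bold(mesh, atlas, config, n_volumes=180, tr_s=2.0,
                             seed=7)
smap = stability_map(bold, mask, atlas, WindowSpec(window_s=64, step_s=4),
                     mode="vertex_by_atlas")

print(f"windows: {smap.provenance['n_windows']}  "
      f"(window {smap.provenance['window_s']} s, step "
      f"{smap.provenance['step_s']} s)")
for parcel in atlas.parcels:
    w = np.nanmean(smap.values[atlas.labels == parcel])
    tag = " <- state-switching" if parcel == 2 else ""
    print(f"parcel {parcel:2d}: mean W = {w:.3f}{tag}")

z = zscore_map(smap, mask)
print(f"\nZ-scored map: mask mean {z.values[mask].mean():+.2e}, "
      f"SD {z.values[mask].std(ddof=1):.3f}")
print("Low W = the vertex's windowed connectivity profile keeps reordering; "
      "high W = a temporally stable architecture.")
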