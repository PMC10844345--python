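"""Surface smoothing with a calibrated full-width-at-half-maximum.

Volume-space Gaussian kernels do not exist on a triangulated cortex, so the
smoother is iterative graph heat diffusion whose step size and iteration
count are auto-calibrated per mesh: the geodesic FWHM of the operator's
impulse response is driven to the requested width.  This demo measures the
realised FWHM for the protocol kernels (6, 8, 10 mm) on a fine spherical
mesh and shows the variance reduction on a noise field.
"""

import numpy as np
from scipy.sparse.csgraph import dijkstra

from surfstab.surface import (_edge_length_graph, _profile_fwhm, adjacency,
                              build_icosphere, smooth_field)

mesh = build_icosphere(3, 13.0)          # 642 vertices, ~2 mm edges
mask = np.ones(mesh.n_vertices, dtype=bool)
deg = np.asarray(adjacency(mesh).sum(axis=1)).ravel()
src = int(np.flatnonzero(deg == 6)[0])   # typical six-neighbour vertex

impulse = np.zeros(mesh.n_vertices)
impulse[src] = 1.0
dist = dijkstra(_edge_length_graph(mesh), indices=src)

rng = np.random.default_rng(0)
noise = rng.standard_normal(mesh.n_vertices)

print(f"{'nominal mm':>11} {'measured mm':>12} {'noise var ratio':>16}")
for fwhm in (6.0, 8.0, 10.0):
    response = smooth_field(mesh, impulse, mask, fwhm)
    measured = _profile_fwhm(response, dist, 2.0)
    smoothed = smooth_field(mesh, noise, mask, fwhm)
    print(f"{fwhm:11.1f} {measured:12.2f} {smoothed.var() / noise.var():16.3f}")

print("\nThe measured impulse-response FWHM tracks the nominal kernel, and "
      "wider kernels suppress more high-frequency noise, as a Gaussian "
      "filter should.")
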