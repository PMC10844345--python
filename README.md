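# surfstab

Surface-based analysis of the *stability* of dynamic brain functional
architecture from resting-state fMRI, with a fully synthetic cortical cohort
generator for end-to-end validation.

## The problem and the statistic

Static functional connectivity (FC) summarises a whole scan with one
correlation per region pair, discarding how the connectivity pattern evolves.
A complementary question is how *consistent* each cortical location's
connectivity profile is over time. Given a vertex *v* on a cortical surface
mesh and a BOLD series, the analysis:

1. slides a window (default 64 s, step 4 s) along the series;
2. within each window computes the Pearson correlation between *v*'s signal
   and each target — every other vertex in the cortex mask
   (`vertex_by_vertex`) or each parcel-mean series of an atlas
   (`vertex_by_atlas`), giving one dynamic FC map per window;
3. quantifies the concordance of those windowed FC maps with Kendall's
   coefficient of concordance, treating the *k* windows as judges ranking the
   *n* targets:

   W = (12 ΣᵢRᵢ² − 3k²n(n+1)²) / (k²n(n²−1) − k ΣⱼTⱼ),

   with Rᵢ the rank sum of target *i* across windows and Tⱼ = Σ(t³−t) the
   per-window tie correction. W ∈ [0, 1]; a high value means the vertex keeps
   the same connectivity ordering over time (a temporally stable functional
   architecture), a low value means its FC profile keeps reordering.

Repeating this for all masked vertices yields a per-subject stability map,
which is Z-scored within the mask and optionally smoothed on the mesh with an
FWHM-calibrated graph-diffusion kernel. Group inference is a vertex-wise GLM
(two-sample contrast with nuisance covariates such as mean framewise
displacement), cluster formation on the mesh (|t| thresholded at two-sided
p < 0.001, clusters kept if area > 20 mm²), cluster p-values from group-label
permutation of maximal cluster extent, and Benjamini–Hochberg FDR across
clusters. A reproducibility module reruns everything over a grid of window
sizes (50/64/100 s), steps (2/4 s) and smoothing kernels (6/8/10 mm) and
quantifies agreement (t-map correlation, Dice overlap of surviving clusters).

Because no public dataset accompanies this design, the package ships a
first-class synthetic cohort generator: parcel-level latent signals whose
inter-parcel correlation switches between connectivity states, vertex noise,
AR(1) temporal structure, random-walk motion traces with framewise
displacement, and clinical covariates with a controlled rank correlation to a
designated parcel's modulation — all reproducible bit-for-bit from one master
seed.

## Worked example

`examples/02_group_inference.py` simulates 15 patients and 15 controls on a
162-vertex spherical cortex with 12 parcels (170 analysed volumes at TR 2 s);
patients carry 0.6 extra modulation amplitude in parcel 2, i.e. their parcel-2
connectivity re-routes between network states more of the time:

```
$ python examples/02_group_inference.py
simulated 30 subjects; ground-truth effect parcel(s): (2,)

cluster table (one row per suprathreshold cluster):
 location hemisphere  size_mm2  n_vertices  peak_x  peak_y  peak_z  peak_t     sign networks     p     q
parcel-02     single  9887.139          13  80.902    50.0  30.902 -6.8517 decrease   visual 0.002 0.002
surviving cluster 1: sign -1, q = 0.0020, 13/13 effect-parcel vertices covered
```

The single surviving cluster is a *decrease* in stability that covers all 13
vertices of the effect parcel: the injected loss of stability is recovered,
with permutation cluster p = 0.002 surviving FDR. The script also prints the
Spearman correlation between surviving-cluster stability and the simulated
visual-field covariate in patients.

Other examples: `01_stability_map.py` (single-subject map; the
state-switching parcel scores W ≈ 0.38 against ≈ 0.55–0.75 for stationary
parcels), `03_reproducibility_grid.py` (window/step sweep; Dice ≥ 0.87
against the default setting), `04_smoothing_calibration.py` (measured
impulse-response FWHM 6.00/8.07/10.01 mm for nominal 6/8/10 mm kernels).

A thin CLI wraps the same library calls:

```bash
surfstab simulate --n-per-group 15 --seed 0 --out cohort/
surfstab run --bold sub-001.func.gii --atlas atlas.label.gii --out stab.func.gii
surfstab group --n-per-group 15 --seed 0 --out results/
surfstab grid --windows 50,64,100 --steps 2,4 --out grid/
```

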