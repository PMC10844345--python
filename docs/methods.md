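# Methods

This note documents the models, numerical choices and limitations behind
`surfstab`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## The stability statistic

For a seed vertex, the windowed FC maps form a k × n matrix (k windows,
n targets). Functional stability is the tie-corrected Kendall coefficient of
concordance W of that matrix, with windows as judges and targets as items.
Properties the implementation guarantees (and the suite verifies):

* **Rank invariance.** W depends only on the within-window ordering of the
  targets, so any strictly increasing transform of the correlations —
  including Fisher's z — leaves W unchanged, exactly. This also settles the
  question of whether correlations should be Fisher-transformed before
  computing W: it is a no-op.
* **Bounds and invariances.** W ∈ [0, 1] (clamped against rounding at the
  1e-15 level); permuting targets or windows does not change W.
* **Ties.** Average ranks with the standard per-judge correction
  Tⱼ = Σ(t³ − t). Continuous correlations rarely tie, but degenerate inputs
  must be exact.
* **Undefined cases.** A target whose series is flat within any window has
  undefined correlations there; that target is dropped from all windows'
  rankings for that seed so the judge/item grid stays rectangular. If every
  judge ties all items, W is undefined: NaN with a warning, never a fake 0
  or 1.
* **Oracle equivalence.** The vectorised batch implementation matches a
  brute-force per-judge rank implementation to < 1e-12 on 500 random stacks,
  and the full vertex-by-vertex map on a 162-vertex sphere matches a naive
  O(V²·windows) reference to < 1e-10.

**Target sets.** `vertex_by_vertex` uses all other masked vertices.
`vertex_by_atlas` uses parcel-mean series; the seed's own parcel mean is
recomputed *without* the seed (`seed_policy="exclude"`, default), because a
target containing the seed contributes a near-constant high correlation that
compresses rank variance. The inclusive variant is available as
`seed_policy="include"`. Singleton parcels have no leave-one-out mean; that
target is dropped for its own vertex.

## Sliding windows and preprocessing

Windows are rectangular (unweighted Pearson within the window), full-length
only: count = floor((T − w)/s) + 1 starting at volume 0. Window and step must
be integer multiples of the TR; 170 volumes at TR 2 s with a 64 s window and
4 s step give 70 windows of 32 volumes.

Subject-level preprocessing mirrors standard practice and its defaults are
the protocol's: discard the first 10 volumes; regress the 24-parameter
motion expansion (6 rigid-body parameters, their one-volume lags, both sets
squared) plus a linear trend, with an intercept always included; band-pass
0.01–0.1 Hz by an FFT mask (DC always removed when the low edge is
positive). Regression and filtering are applied sequentially, not jointly
re-orthogonalised — a known, documented simplification. Motion QC excludes a
subject when any |translation| > 2.5 mm or |rotation| > 2.5° (strict
inequality: exactly 2.5 passes). Framewise displacement is the Power form —
sum of absolute backward differences with rotations converted to arc length
on a 50 mm sphere.

## Standardisation and surface smoothing

Stability maps are Z-scored over the cortex mask using the sample (n−1)
standard deviation; for two hemispheres a pooled variant shares one mean/SD
across both masks. The protocol order is Z-score, then smooth; the reverse
order is available (`RunConfig.smooth_before_zscore`) since the source
protocol's wording leaves it ambiguous.

A volumetric Gaussian kernel has no meaning on a triangulated sheet, so
smoothing is iterative graph heat diffusion restricted to the mask:
f ← f − λ L f with L the combinatorial Laplacian of the masked subgraph.
Choices and consequences:

* λ ≤ 0.5/max-degree keeps every step a convex combination with a dominant
  self-weight, so smoothed values never leave [min, max] of the input and
  the impulse peak stays at its source.
* L is symmetric with zero row/column sums on the masked subgraph, so the
  masked mean is preserved *exactly* and nothing bleeds across the mask
  boundary; unmasked vertices pass through untouched.
* The kernel width is specified as the geodesic FWHM of the impulse
  response. Per (mesh, mask, FWHM) the iteration count is estimated from the
  √n growth law and λ is then bisected until the measured FWHM is within 1%
  of nominal; the calibration is cached. FWHM is measured by binning the
  response by geodesic distance (Dijkstra over edge lengths, bins of half
  the local edge length, bin centres at mean distance) and interpolating the
  first half-maximum crossing. Calibration uses a modal-degree source vertex;
  icosphere poles (degree 5) have a slightly narrower response, within the
  15% contract.
* If the requested FWHM is below the mesh resolution (roughly one edge
  length), no diffusion operator can realise it; the function warns and
  returns the closest (near-identity) smoothing rather than silently
  over-smoothing. For this reason the desk-scale cohort analyses (162-vertex
  sphere, ~30 mm edges) run with smoothing disabled, while the FWHM contract
  is validated on a finer 642-vertex mesh with ~2 mm edges.

## The synthetic cohort

The generator is parcel-level: each of K parcels carries one latent signal;
the latents' instantaneous correlation matrix C(t) varies over time;
vertex signal = own-parcel latent + independent Gaussian noise (SD 0.3),
with AR(1) temporal structure (φ = 0.3) applied to the innovations.

**Coupling model.** The default C(t) comes from a two-factor loading model:
parcel p has loadings L_p on two latent network factors, C = L Lᵀ with unit
diagonal. Odd parcels load 0.85…0.60 on factor 1 (0.15 on the other), even
parcels symmetrically on factor 2, so every parcel has a fully ordered
connectivity profile over the others. A *modulated* parcel interpolates its
loading vector toward the factor-swapped version by s_p(t) = a_p·m_p(t),
where a_p ∈ [0, 1] is its amplitude and m_p(t) a piecewise 0/1 regime wave
(dwell 64 s, random phase; a sinusoidal form is available). Modulation
therefore *re-routes* the parcel's connectivity between networks. This is
deliberate: Kendall's W is rank-based, and a modulation that merely scales
correlations up and down hardly reorders the targets and produces almost no
stability contrast; state re-routing is both what the statistic is sensitive
to and the standard picture of dynamic connectivity states. The factor form
guarantees positive semi-definiteness at every interpolation point. An
explicit edge-list coupling (with a numeric PSD check that names the
offending volume) is retained for custom graphs.

**Case-control design.** Patients receive +0.6 amplitude in the designated
effect parcel (parcel 2). Every subject gets an individual amplitude
U(0.2, 0.8) in a covariate parcel (parcel 5), and the patients'
visual-field mean deviation (dB, clipped to [−32, 1.7]) is drawn with a
target Spearman correlation (−0.5 by default) to that amplitude via the
bivariate-normal rank-correlation inversion. Ages, sexes and motion traces
round out the subject table; controls have no visual-field value, so
clinical correlations use patients only. All per-subject seeds derive from
one master seed; cohorts are bit-for-bit reproducible.

**What the generator does not emulate.** Hemodynamic response shapes,
scanner drift/spike artifacts, spatial noise correlations beyond parcel
membership, registration error, and real cortical geometry. Passing tests
therefore demonstrate the *statistical machinery* — sensitivity of W to
connectivity-state switching, calibration of the cluster inference,
robustness across analysis settings — not performance on real scanner data.

## Group inference

Per vertex, stability is regressed on [intercept, group, covariates] by
ordinary least squares (mean framewise displacement included by default);
the group t equals the classical pooled two-sample t when no covariates are
present (verified to 1e-10). |t| is thresholded at the two-sided p < 0.001
critical value; positive and negative excursions are clustered separately by
connected components on the mesh adjacency; clusters survive only if their
barycentric area exceeds 20 mm² (strict inequality).

Cluster p-values come from group-label permutation: labels are shuffled
(covariates stay with their subjects), the GLM re-fit, and the maximal
suprathreshold cluster area over the whole |t| map recorded; a cluster's
p is (1 + #{null max ≥ area}) / (1 + n_perm), with n_perm = 499 by default.
The null maximum is taken over *both* signs: a per-sign null would run two
simultaneous max-statistic families and double the run-level error of the
two-sided test to ≈ 0.10; the global maximum keeps it at the nominal level
(measured 5/120 = 0.042 null cohorts with ≥ 1 surviving cluster). BH-FDR is
then applied across clusters, against q = 0.05, or q = 0.025 per hemisphere
when the Bonferroni split is enabled. A vertex-wise-FDR mode is deliberately
not offered as an equivalent — how the original cluster q-values were
produced is not derivable from the protocol, and the permutation route is
the assumption-light, testable choice.

Demographics: Mann–Whitney U for age, Pearson chi-square without continuity
correction for sex (the correction is a switch; an empty cell triggers it
with a warning), Wilcoxon signed-rank for paired inter-eye visual-field
differences (undefined, with a warning, when all differences vanish). The
chi-square choice reproduces the published p = 0.933 from the published
41/29 vs 26/19 table; the accompanying printed statistic 0.674 is
inconsistent with those counts (it duplicates the p-value column) and is
documented rather than targeted. Spearman correlations use rank-then-Pearson
with the t-approximation for p, switching to exact permutation for n ≤ 9.

## Reproducibility protocol

`run_grid` reruns preprocessing once and the stability → GLM → cluster →
permutation chain per setting of {50, 64, 100} s × {2, 4} s × kernel,
with identical seeds, caching per-setting subject maps by a content hash.
Agreement is reported as the Pearson correlation of group t-maps over the
mask and the Dice overlap of surviving-cluster vertex sets; on the default
effect cohort every window/step setting reaches Dice ≥ 0.87 against the
64 s / 4 s reference (the acceptance suite asserts ≥ 0.5, the convention
adopted for "reproducible" since the source protocol defines it only
visually).

## Problem sizes and determinism

The validation suite runs at desk scale by design: 162-vertex icospheres
with 12 parcels and 15 + 15 subjects for cohort-level checks (the
vertex-by-vertex oracle also at 162 vertices), and a 642-vertex mesh for
smoothing calibration. fsaverage5-resolution inputs (10,242 vertices per
hemisphere) are supported by the same code paths; vertex-by-vertex mode at
that scale holds one V × V correlation matrix per window batch in memory,
which is the practical ceiling, while vertex-by-atlas mode scales linearly.
All randomness — simulation, permutation — flows through explicit seeds;
results are invariant to rerun and to the execution order of the
embarrassingly parallel vertex loops (which are implemented as vectorised
batches, not threads).

## Known limitations

* Nuisance regression and band-pass are sequential, not a joint projection.
* The permutation null assumes exchangeability of subjects under the group
  labelling; covariate imbalance between groups is re-fit but not
  re-randomised (no Freedman–Lane scheme).
* The FWHM calibration targets isotropic meshes; on strongly anisotropic
  cortical meshes the realised kernel varies locally within the stated 15%
  envelope only approximately.
* Cluster "location" naming is a coverage lookup against whatever atlas the
  user supplies; no bundled brain atlas.
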