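# Methods

`airwaykit` automates bronchial parameter extraction from CT-like volumes: a
lumen segmentation (assumed given, e.g. from a deep-learning segmenter) is
refined and the airway wall segmented by a coupled two-surface optimal-surface
graph cut; the lumen is decomposed into branches by front propagation; lumen
and wall radii are measured every 0.5 mm along branch centrelines and
aggregated into LA, WA, WAP, SRWA, Pi and Pi10; repeat-scan agreement is
quantified by R² and Bland–Altman limits of agreement. A synthetic scanner
supplies phantoms and airway trees with exact ground truth.

## Coupled-surface graph cut

Columns are cast from every vertex of a smoothed marching-cubes isosurface of
the initial lumen mask, along the outward vertex normal, spanning
`[-l_in, +l_out]` mm in steps of `step_mm`. Each of the two surfaces (inner =
refined lumen, outer = outer wall boundary) selects exactly one sample per
column. The energy is

```
E = Σ_v [ c_in(v, k_in(v)) + c_out(v, k_out(v)) ]
  + p · Σ_(u,v) [ |k_in(u)-k_in(v)| + |k_out(u)-k_out(v)| ]
  + q · Σ_v max(0, (k_out(v) - k_in(v)) - s_pref)
```

subject to `|k(u)-k(v)| ≤ delta` per neighbour pair and surface, and
`k_out - k_in ≥ s_min`. The global minimum is found by the standard
boundary-of-closed-set reduction to a minimum s-t cut (one node chain per
column per surface; infinite intra-column arcs; equal-level arcs of capacity
`p` for the smoothness penalty; shifted infinite arcs for `delta`; inter-chain
arcs for `s_min`, `s_pref`, `q`). The minimal source side of the cut is taken,
which breaks ties toward smaller sample indices. Unit tests assert exact
energy equality with exhaustive enumeration on small random instances.

Costs reward intensity edges: `c_in = -w_in·g' - w2_in·g''·δ` favours
dark-to-bright transitions (air → wall) and `c_out = +w_out·g' - w2_out·g''·δ`
bright-to-dark transitions (wall → parenchyma), with `g'` the first derivative
of the trilinearly interpolated intensity along the column. The
second-derivative weights shift the detected edge sub-voxel-wise along the
profile; they are the knob that counters the systematic inward bias of the
first-derivative response on small, blurred lumens.

Numerical details that matter:

- **Max-flow capacities.** The scipy max-flow backend stores capacities in 32
  bits; float costs are scaled into a fixed integer budget (2^28) with
  infinite arcs at 2^30. With integer costs and `cost_scale=1` the solve is
  exact.
- **Medial-axis column truncation.** Walking inward from the surface, samples
  past the maximum of the initial mask's interior distance transform are
  discarded. Without this, columns in thin structures cross the centreline
  and the opposite wall becomes a competing globally-optimal edge.
- **Sub-sample refinement.** After the cut, each surface is refined by
  fitting a parabola through the unary cost at the optimum ±1 sample
  (clamped to half a step). This removes the sample-quantisation floor
  (±δ/2 per surface, which alone is ±5 % diameter on a 3 mm lumen at
  δ = 0.3 mm).
- **PSF sharpening.** An optional 3D unsharp filter
  `v + α(v - G_σ v)` (α = `sharpen_alpha`, σ = `sharpen_sigma_mm`,
  default 0.42 mm ≈ the scanner PSF combined with voxel-sampling blur)
  partially deconvolves the point-spread function before column sampling.
  For walls thinner than ~2σ the opposing edges interfere under blur and the
  apparent wall expands ~0.1–0.2 mm on each side; sharpening restores thin
  walls while leaving well-separated edges unchanged, which no global edge
  weight can do.
- **Surface rasterisation.** Solved surfaces are rasterised by even–odd
  parity counting of triangle crossings along z through every voxel centre
  (exact centre-inside test for the closed displaced mesh); wall = interior
  of outer minus interior of inner, with conflicts resolved in favour of the
  lumen.

Column geometry defaults: `l_in` 3 mm, `l_out` 5 mm, δ 0.3 mm for general
use; the phantom-tuning experiment fixes δ = 0.2 mm so quantisation stays
well below the sub-voxel accuracy target on 3 mm lumens.

## Phantom-based tuning (TPE)

The energy weights depend on protocol and resolution, so they are tuned on a
tube phantom with known dimensions. The default phantom holds 8 straight
tubes (lumen 3–6 mm, wall 0.5–1.5 mm) in foam, rasterised with analytic
partial-volume anti-aliasing (3× supersampling) at 0.6 × 0.6 × 0.7 mm
spacing, blurred with a 0.8 mm-FWHM Gaussian PSF and degraded with 25 HU
Gaussian noise — the contrast and noise class of a low-dose (120 kVp/20 mAs)
screening protocol. Tube centres carry a fixed sub-voxel offset so the
geometry is incommensurate with the voxel grid (aligned centres digitise
with a systematic rim deficit).

The objective is the mean over tubes of
`(|d_lum - d_lum,GT|/d_lum,GT + |d_tot - d_tot,GT|/d_tot,GT)/2`, with the
initial lumen mask taken as the ground truth eroded by one voxel (a
reproducible stand-in for an imperfect upstream segmentation) and diameters
re-measured from the segmented masks by perpendicular cross-sections along
the central half of each tube. Failed segmentations contribute a large
sentinel value instead of raising, so the optimiser can continue.

The optimiser is a from-scratch Tree-structured Parzen Estimator:
`n_startup = 10` uniform trials (log-uniform where flagged), then the history
is split at the `ceil(γ·n)`-th best value (γ = 0.25) into good/bad sets, each
modelled per dimension as a mixture of truncated normal kernels centred at
the observed values with bandwidth `range/√(set size)`; 24 candidates drawn
from the good density are ranked by the good/bad log-density ratio and the
argmax is evaluated. Integer-valued dimensions are relaxed to continuous and
rounded at evaluation. Everything is deterministic given the seed.

The tuned dimensions are the derivative weights, the smoothness constraint
and penalty, the separation penalty and preferred separation, the
second-derivative weights and the sharpening strength; bounds bracket the
regimes where each term is active at this contrast (see
`default_param_space`). 40 trials complete in a couple of minutes on one CPU
because per-tube meshes, columns and distance transforms are cached across
trials.

## Front-propagation tree extraction

Geodesic distance from a cranial trachea seed (26-connected voxel graph,
physical edge lengths) is binned into shells one max-spacing wide. Connected
components within each shell (26-connectivity) are tracked across shells;
a component splitting into two or more children that each persist at least
2 shells commits a bifurcation; one-shell splits are surface noise and are
absorbed. Centreline points are shell-component centroids, lightly smoothed
(3-point moving average) and snapped back to in-mask voxels. Weibel
generations: trachea 0, +1 at every branch point (trifurcation children all
parent+1). Terminal branches strictly shorter than 2 mm are removed in a
single pass; parents are never merged with surviving siblings, so generation
indices are preserved as measured. Every reachable lumen voxel is assigned
to exactly one branch.

## Measurement

Branch centrelines are resampled by arc length every 0.5 mm on a smoothed
(window-5, endpoint-anchored) polyline; samples within one step of a branch
point are dropped (sections at bifurcations are not tubular). At each sample
a plane perpendicular to the tangent is resampled at 0.25 mm from the lumen
and wall masks (bilinear); the connected region containing the centre gives
the areas, made partial-volume aware by adding the interpolated mass in a
one-pixel fringe around the thresholded region. Radii are area-equivalent:
`r = √(A/π)`. Per-section areas are averaged per branch — areas, not radii,
so the estimate is unbiased under varying calibre: `LA = mean(π r_in²)`,
`WA = mean(π r_out² − π r_in²)`, `WAP = 100·WA/(WA+LA)`, `SRWA = √WA`,
`Pi = mean(2π r_in)`. Pi10 is the OLS prediction of SRWA at Pi = 10 mm over
branches of generations 1–6 (trachea excluded). Scan summaries carry
unweighted per-generation branch means, TAC (count of measured branches),
Pi10 and TLV (an input scalar; lung segmentation is out of scope).

Segmentation scoring: Dice overlap; centreline completeness = % of reference
centreline points (0.5 mm resampling) inside the prediction; centreline
leakage = % of the prediction's own extracted centreline outside the
reference.

## Synthetic data — what it does and does not emulate

The generator produces: tube phantoms (above); recursive symmetric
bifurcating trees (child diameter = parent × ratio, default 0.75; length =
3 × diameter; half-angle 35°; branching planes rotated 90° per generation;
junctions rounded by a sphere of the parent radius; wall thickness =
0.35 × lumen radius), with optional angle/length jitter; repeat-scan pairs
(same geometry scaled by `inflation^(1/3)` with independent noise, TLV proxy
= lumen volume); and summary-level paired cohorts for the agreement
statistics, with per-generation population means echoing a general screening
population and per-scan measurement noise of known SD.

Cohort noise is moment-matched by default: noise vectors are centred,
decorrelated between the two scans and rescaled to the nominal sample SD, so
a simulated cohort realises the specified noise level exactly at finite n
(the Bland–Altman check against `1.96·√2·σ_g` is then a test of the
statistics, not of Monte-Carlo luck). Inspiration drift is off by default
(inspiration-matched cohorts); the TLV exclusion rule is exercised by
passing a non-zero drift.

Not modelled: helical-CT physics (beam hardening, dose, kernel ringing),
cartilage and vessels, anatomical asymmetry of the real bronchial tree,
bronchoconstriction, disease. Passing tests therefore demonstrate
correctness of the algorithms and sub-voxel behaviour under an idealised but
non-trivial image-formation model — not clinical performance on patient
scans.

## Agreement analysis

Participants whose TLV differs by more than 15 % between scans are excluded;
the relative difference uses the mean of the two TLVs (symmetric, no
ordering artefact). Differences are scan2 − scan1. Per (parameter,
generation): R² = squared Pearson correlation (the usual reading of the
coefficient of determination for scan–rescan scatter), MD = mean difference,
LoA = 1.96 × sample SD of the differences (large-sample multiplier, no
small-sample t correction), LoA% = 100 × LoA / mean of the pairwise means.
Participants missing a generation in either scan are dropped pairwise for
that row; rows with fewer than 3 contributors are omitted rather than
reported as zero. Pi10 gets a single overall row.

## Known limitations

- Columns are straight rays along smoothed normals, not flow lines; in
  strongly curved or branching regions neighbouring columns can cross.
- The thinnest-wall configuration (0.5 mm wall on a 3 mm lumen under a
  0.8 mm PSF) remains the dominant error contributor even after sharpening;
  its inner edge is only partly recoverable at this resolution.
- Front propagation assumes a tree (no loops) and a single connected lumen;
  components disconnected from the seed are ignored.
- The TLV proxy for synthetic repeat pairs is airway lumen volume, a stand-in
  for lung volume with the same scaling behaviour, not a lung-field model.
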