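# Methods

This note documents the models, estimators and numerical choices behind
`organgeo`, and what the synthetic-data tests do and do not demonstrate
about real imaging data.

## Centreline representation

A centreline is an ordered polyline in µm, anterior end first (the first
SWC root / first CSV row is taken as anterior; traces made in voxel
space can be converted with a voxel-size multiplier). Arclength is the
cumulative chord length; this underestimates the true arclength of the
underlying smooth curve by O(κ²·h²) per segment, negligible at the
sampling densities used (≥500 points per organ). Anatomical landmarks
(`loop_start`, `loop_end`, `R3`) are manual picks made on image stacks,
so they are snapped to the nearest centreline point within a default
30 µm radius (≈10 microCT voxels); a pick farther away is an error, not
silently accepted. Region subsetting re-parameterizes from s = 0, and
regional lengths are additive by construction.

## Curvature and torsion

Around each point the curve is fitted, coordinate-wise and by unweighted
least squares, to a cubic in (s − s*) over the neighbourhood
{|s − s*| < δ}, δ = 0.05·L. Derivatives are read off the coefficients
and combined by the Frenet–Serret relations κ = |x″| and
τ = ((x′×x″)·x‴)/κ². Numerical behaviour worth knowing:

* The cubic-fit estimate of κ carries a truncation bias of order
  (δκ)²/28 (the quartic term of the curve leaks into the quadratic
  coefficient). At δκ ≈ 0.2 (a one-turn unit helix) this is <1%; at
  δκ ≈ 1 it reaches ~10%. Estimates are therefore validated against
  closed forms on circles and helices at the <1% regime, and the
  synthetic generator defaults keep loop arcs in the few-percent regime.
* Endpoint neighbourhoods are truncated, not dropped, so profiles cover
  the full organ; the first and last ~δ of the profile are the least
  reliable.
* Torsion divides by κ²; where κ < 10⁻⁶ µm⁻¹ the sample is flagged
  undefined rather than set to 0 (a straight run has no meaningful
  torsion). Undefined gaps are interpolated over before smoothing and
  re-flagged afterwards.
* Smoothing is a 4th-order Butterworth filter with normalized cutoff 0.3
  (fraction of Nyquist) applied forward and backward (zero phase).
  Constants pass exactly; a sinusoid at twice the cutoff is attenuated
  >90%, one at a tenth of the cutoff <5%. Only this qualitative response
  is relied on anywhere.

Normalized curvature κ̃ = L·κ and L·τ are the scale-free shape
descriptors; both are invariant to rigid motion and uniform scaling, and
τ (not κ) flips sign under reflection.

Tube radius is the minimum distance from each centreline point to the
mesh **vertices** (not point-to-triangle), matching the vertex-based
convention used throughout the proximity analyses; the bias is about
half a mesh edge length, so tolerances in tests are set to twice the
mean edge length. Tilt uses the leading eigenvector of the 3×3 point
covariance of each curve; the angle takes the absolute dot product
(eigenvectors have no preferred sign) and lives in [0°, 90°]. An
isotropic point cloud (degenerate leading eigenvalue) is an error.

## Procrustes shape statistics

Curves become k×3 pseudolandmark configurations (k = 1000 whole gut,
500 loop region) by equal-arclength resampling. GPA centres each
configuration, scales it to unit centroid size, and rotates it to the
iteratively re-estimated consensus; rotations are proper (det +1) —
reflections are disallowed because anatomy has fixed chirality. The
unit-size convention (rather than a fitted Procrustes scale) was chosen
so that aligned coordinates keep an interpretable norm; the alignment
converges to mean-shape changes <1e-8.

The ANOVA treats the n×3k aligned coordinates as the response. For each
term, the type III (marginal) Procrustes SS is RSS(model without the
term) − RSS(full model), computed via orthonormal column-space bases;
continuous covariates are mean-centred before interactions are formed,
and rank-deficient designs are rejected with the aliased terms named.
F is the mean-square ratio against the full-model residual. RRPP
p-values: the reduced model's residuals are permuted, added back to the
reduced-model fits, the statistic recomputed, and the observed value
included in the reference distribution — so p ≥ 1/iterations (0.001 at
the conventional 1,000), and permuted statistics exactly equal to the
observed count toward the rank (conservative). One generator is seeded
per call and the permutation indices are retained for reproducibility.
Under a true null the resulting p-values are uniform on {1/N, …, 1},
verified by simulation (type-I error 0.05 ± 0.02 at α = 0.05).

Pairwise group tests compare least-squares mean shapes (covariates of
the null model held at their means, which is exact because covariate
columns are centred) under RRPP of the null-model residuals
(`shape ~ batch` or `shape ~ 1`); groups with fewer than two specimens
are excluded with a warning.

## Elastic registration and the curvature distance

Profiles are re-expressed on relative arclength s/L ∈ [0, 1] (κ̃ is
already dimensionless) and resampled to a 101-point grid. Registration
minimizes the square-root-slope misalignment
∫(q₁(t) − q₂(γ(t))√γ′(t))² dt, where q = sign(f′)√|f′|, by dynamic
programming over monotone lattice paths with slopes between 1/5 and 5.
Values are min–max normalized first (the optimal warp is invariant to
affine value scaling; this also keeps the SRSF away from float noise).
Tie-breaks: the diagonal step is preferred, so identical — and constant —
inputs return the identity warp.

The distance evaluates the registered difference on 200 equally spaced
s₁ points and takes the root mean square. Two guards shape its
behaviour: (i) SRSF optimality is in the Fisher–Rao metric, not L², so
if the warp fails to reduce the value-space RMS the identity warp is
used — registration therefore never increases the distance; (ii) the
one-directional formula is asymmetric, so matrix entries average the two
registration directions, giving a symmetric matrix fit for MDS.
Relative distances divide by the maximum over all pairs in the analysis.

MDS is metric least-squares: classical scaling provides the initial
configuration (with deterministic eigenvector signs) and SMACOF stress
majorization refines it; on exactly Euclidean inputs the embedding
reproduces the distances to ~1e-15 and Kruskal stress-1 ≈ 0. Group
scatter uses Gaussian ellipsoids with radii √(λᵢ·χ²₃(0.95)). The group
location test deliberately does **not** pick the most powerful test
post hoc (minimum-p selection across a battery inflates type-I error);
instead a fixed decision table applies: Shapiro–Wilk normality per
coordinate per group → Hotelling's T² (the multivariate two-sample t
family); otherwise Mann–Whitney U on scores along the first principal
axis of the pooled, label-blind point cloud (the projection is
exchangeable under the null, keeping the test calibrated). The selected
test's name is always reported with its p.

## Proximity

All interorgan distances are exact nearest-vertex queries (k-d tree,
identical to brute force — verified, not approximate). Centreline-
referenced profiles resample the curve to 100 equally spaced points,
link each to its 20 nearest gut-mesh vertices, and assign the minimum of
those vertices' distances to the target organ. Mesh decimation is the
caller's responsibility; a warning fires above 10⁵ vertices. Contact
calling uses a configurable threshold, default 5 µm — adjacency in real
data is meaningful below ~10 µm, and no universal criterion exists, so
the threshold is always reported alongside frequencies.

## Intensity profiles and the autoregressive null

Traces are position–value series with an R3 anchor. Alignment maps
positions piecewise-linearly (0→0, anchor→0.5, 1→1) and pools values
into 40 equal-width bins (left-closed, final bin closed), reporting per-
bin mean and sd. Min–max normalization maps each profile onto [0, 1];
Pearson correlations are invariant to this affine choice. All-pairs
correlation registers each intensity curve onto the curvature curve (one
direction, matching the asymmetric pairing of the analysis) and
evaluates Pearson r on the 200-point registered grid. The null fits an
AR(p) process per real trace (conditional least squares, default p = 1 —
higher orders are configurable), simulates surrogate traces with
matched innovation variance and a stationarity burn-in, and repeats the
identical correlation procedure. Surrogates preserve autocorrelation but
not anatomical peak placement, so a genuine shared regional signal
shifts the observed histogram right of the null.

## Synthetic cohort generator

The generator is the package's ground truth, not a renderer of real
anatomy. A centreline is integrated from a tangent-rotation program at
1,500 equal arclength steps: an anterior run with a gentle sinusoidal
in-plane wiggle (26% of L), a transition arc (4%), a serpentine loop
region (50%) of circular arcs with exactly the prescribed curvature
amplitude — a leading and trailing half-arc flank an odd number of full
arcs so the region's principal axis is exactly its progression axis,
which is tilted by `loop_tilt_deg` against the body axis — another
transition (4%), and a 45°-pitch terminal helix making
`hindgut_coil_turns` turns (16%). Landmarks sit at the loop-region
boundaries and at 50% of arclength (R3). Positional noise is smooth
(white noise convolved with a Gaussian kernel of ~2% of the curve, then
scaled to `noise_sd`), emulating tracing wobble rather than per-point
jitter. Tube meshes place 16-gon cross-sections in parallel-transported
frames with conical end caps pushed out by one radius (watertight, and
no cap vertex closer to the curve than the wall). Neighbour-organ pairs
(icospheres oriented so a vertex lies on the common axis; subdivided
boxes) realize an exact prescribed surface gap. Intensity traces are a
Gaussian bump (width 8% of length) at `intensity_peak_pos` over a 0.2
baseline plus AR(p) noise drawn from seed-fixed normals, so the zero-
noise trace is the analytic mean and the noise path is seed-reproducible
in isolation.

Default dimorphisms are illustrative, not published effect sizes (none
are printed in a usable form): female guts are generated ~16% longer
(6,500 vs 5,600 µm, matching the few-mm scale of the adult gut at
2.5–3 µm microCT voxels), with ~1.4× loop curvature amplitude
(0.0022 vs 0.0016 µm⁻¹), half the loop tilt (10° vs 20°) and ~1.25× tube
radius (50 vs 40 µm). Per-specimen jitter is 5% lognormal on length,
curvature amplitude and radius and 2° on tilt; gonad and crop volumes
are lognormal with a latent size factor shared with length, giving
correlated but non-degenerate covariates for the ANOVA formula.

What passing tests show: the estimators recover known geometry
(curvature to a few %, radius to the mesh-resolution bias, orderings of
group means, exact organ gaps), the permutation machinery is calibrated,
and the full pipeline separates the groups it should. What they do not
show: robustness to segmentation artefacts, branching ambiguities or
tracing errors in real microCT data, nor the biological effect sizes —
the generated tilt, for example, is recovered with strong attenuation
(the whole-organ principal axis is itself dragged toward the loop axis),
so only orderings, not absolute tilt values, are meaningful.

A note on measured tilt: because the loop region contributes half of all
centreline points, the whole-gut covariance axis rotates toward the loop
axis and the measured angle is roughly a quarter of the nominal
generator tilt. This is a property of the covariance-eigenvector
definition itself, shared by any data with the same region proportions.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes chosen
to exercise every code path with comfortable statistical margins:
cohorts of 8–10 specimens per sex, 100–500 pseudolandmarks, 101-point
registration grids, 1,000 RRPP iterations where the p-floor matters and
200 where only calibration is measured (500 null replicates). Larger
sizes change runtimes, not conclusions.

## Known limitations

* SWC input must be a single unbranched path; branched traces are
  rejected rather than pruned.
* Vertex-based distances inherit mesh resolution; heavily decimated
  meshes bias radius and proximity upward by ~half an edge length.
* The location test battery omits the paired-sample variants (specimens
  here are unpaired by design).
* The elastic warp is computed on a fixed 101-point grid; warps with
  slopes outside [1/5, 5] are not representable.
* AR-null order defaults to 1; strongly oscillatory traces may need a
  higher order, at the caller's discretion.
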