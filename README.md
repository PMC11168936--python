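# organgeo

Quantitative 3D morphometrics for tubular organs, built around the
*Drosophila* adult gut: the intestine is a single tube traced from the
proventriculus to the ampulla, and its shape — how long it is, how
sharply its midgut loops bend, how those loops tilt against the body
axis, how wide the tube is, and which neighbouring organs it touches —
is consistent within a sex and differs between sexes. `organgeo` turns
traced centrelines, segmented surface meshes and along-the-gut
fluorescence traces into those numbers, with permutation statistics for
group comparisons. It is aimed at anyone analysing microCT or confocal
segmentations of tubular organs (gut, trachea, vasculature) who needs
reproducible shape statistics rather than per-image measurements.

## What it computes

**Centreline differential geometry.** A traced centreline (SWC or CSV,
µm) is parameterized by arclength *s* ∈ [0, L]. Around every point the
curve is fitted to a cubic in (*s* − *s**) within a neighbourhood of
half-width δ = 0.05·L, and the Frenet–Serret relations give

κ(s*) = |x″(s*)|,  τ(s*) = (x′ × x″)·x‴ / κ²,

smoothed with a zero-phase low-pass filter (normalized cutoff 0.3).
Multiplying by L yields the scale-invariant normalized curvature
κ̃ = L·κ (a circle has κ̃ = 2π at any size). Tube radius is the minimum
centreline-to-mesh-vertex distance along *s*; loop tilt is the angle
between the leading covariance eigenvectors of the loop region and the
whole gut, φ = arccos(|V_g·V_m|/(|V_g||V_m|)).

**Procrustes shape statistics.** Centrelines are resampled to k equally
spaced pseudolandmarks (1000 whole gut, 500 loop region), aligned by
generalized Procrustes analysis (unit centroid size, optimal rotation,
no reflections), and analysed by PCA and a Procrustes type III ANOVA
whose p-values come from randomizing reduced-model residuals (RRPP).
With 1,000 iterations the smallest attainable p is 0.001.

**Elastic curvature comparison.** Two guts' κ̃ profiles are registered
by a monotone warp γ minimizing the Fisher–Rao (square-root-slope)
misalignment; their distance is the discretized root-mean-square
difference on 200 points of *s₁*:
dist(κ̃₁, κ̃₂) = √((1/200) Σₙ [κ̃₁(sₙ) − κ̃₂(γ(sₙ))]²).
Relative distances feed a metric MDS that gives each gut 3D coordinates
(µ₁, µ₂, µ₃); groups are summarized by 95% Gaussian ellipsoids and
compared with a location test.

**Interorgan proximity.** Nearest-vertex distances between organ meshes,
profiles of the distance to a neighbour organ along 100 equally spaced
centreline points (each linked to its 20 nearest gut-mesh vertices), and
cohort contact frequencies at a stated threshold.

**Intensity profiles.** Traces of expression (e.g. the FGF-like ligand
*branchless* in gut muscle) vs. position are anchored at the R3 midgut
landmark (mapped to 50% of length), pooled into 40 bins, min–max
normalized, and correlated all-against-all with curvature profiles after
elastic registration; an autoregressive null — surrogate traces
simulated from AR processes fitted to the real ones — calibrates the
correlation histogram.

**Synthetic cohorts.** `organgeo.synthetic` generates ground-truthed
sex-dimorphic cohorts (centrelines whose loop arcs have closed-form
curvature, tube and neighbour-organ meshes at exact separations, AR-noise
intensity traces), so every estimator in the package is testable without
any imaging data.

## Worked example

```python
import numpy as np, pandas as pd
from organgeo.synthetic import CohortSpec, generate_cohort
from organgeo.centreline import parameterize, subset_by_landmarks, resample_equal
from organgeo.diffgeo import curvature_torsion, normalize_by_length, tilt_angle
from organgeo.morphometrics import gpa_align, procrustes_anova_rrpp

cohort = generate_cohort(CohortSpec(n_per_group=8, seed=42))
rows, configs = [], []
for c, meta in cohort:
    p = parameterize(c)
    sub = subset_by_landmarks(p, "loop_start", "loop_end")
    kappa, tau = curvature_torsion(p)
    kn = normalize_by_length(kappa, p.L)
    loop = (kappa.s > 0.32 * p.L) & (kappa.s < 0.78 * p.L)
    rows.append((meta["sex"], p.L, float(np.mean(kn.values[loop])), tilt_angle(p, sub)))
    configs.append(resample_equal(sub, 500))

df = pd.DataFrame(rows, columns=["sex", "gut_length_um", "loop_norm_curvature", "tilt_deg"])
print(df.groupby("sex").mean().round(2))

aligned = gpa_align(configs, metadata=cohort.metadata)
table = procrustes_anova_rrpp(aligned, ["sex", "batch"], iterations=1000, seed=42)
print(table.table.round(3))
```

prints

```
        gut_length_um  loop_norm_curvature  tilt_deg
sex
female        6586.95                10.16      2.65
male          5630.26                 6.24      4.80
           df     SS     R2        F      Z      p
term
sex         1  0.017  0.961  354.240  3.371  0.001
batch       1  0.000  0.004    1.513  0.853  0.220
Residuals  13  0.001  0.035      NaN    NaN    NaN
Total      15  0.018  1.000      NaN    NaN    NaN
```

The simulated females are longer, have higher normalized loop curvature
and are less tilted than males (the generator's ground truth), and the
sex term of the loop-shape ANOVA hits the 0.001 permutation floor —
batch, a nuisance factor, does not. The same analyses run end to end
from a shell:

```sh
organgeo run-all --out results_run --seed 7
```

which writes per-stage CSV/JSON artifacts plus a `manifest.json` with
checksums; identical configuration and seed reproduce identical files.

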