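"""Synthetic sex-dimorphic cohorts with known geometric ground truth.

Generates the three kinds of input the analysis pipeline consumes —
centrelines, tube/organ meshes and intensity traces — from explicit
parameters, so every downstream estimator can be checked against the
quantity it is supposed to recover.

A synthetic gut centreline has three regions mirroring fly gut anatomy:
an anterior run with gentle bending, a midgut-loop region built from
circular arcs of prescribed curvature amplitude whose progression axis is
tilted against the main body axis, and a hindgut terminal coil. Curves
are integrated in a Bishop (rotation-minimizing) frame from a curvature
program, so the loop arcs have closed-form curvature for oracle tests.
Sexes differ in total length, loop curvature amplitude, loop tilt and
tube radius; the dimorphism directions (female: longer, higher loop
curvature, less tilted, wider tube) follow the qualitative biology, with
illustrative effect sizes. Intensity traces are a smooth regional bump
(the R3-centred expression domain) plus stationary AR(p) noise. All
outputs are deterministic in (parameters, seed); units are µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from organgeo.centreline import Centreline, ParamCurve, parameterize, resampled_curve
from organgeo.diffgeo import ScalarProfile
from organgeo.proximity import SurfaceMesh

__all__ = [
    "Cohort",
    "CohortSpec",
    "GeneratorParams",
    "default_female_params",
    "default_male_params",
    "generate_centreline",
    "generate_cohort",
    "generate_intensity_trace",
    "generate_organ_pair",
    "generate_tube_mesh",
]

#: Arclength fractions of the curve segments. The two short transitions
#: carry the inflections where the gut turns into and out of the loop
#: region; anatomically they belong to the anterior midgut and hindgut.
SEGMENT_FRACTIONS = {"anterior": 0.26, "trans1": 0.04, "loops": 0.50,
                     "trans2": 0.04, "hindgut": 0.16}


def _ar_is_stationary(coeffs) -> bool:
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    if coeffs.size == 0:
        return True
    p = len(coeffs)
    companion = np.zeros((p, p))
    companion[0] = coeffs
    if p > 1:
        companion[1:, :-1] = np.eye(p - 1)
    return bool(np.all(np.abs(np.linalg.eigvals(companion)) < 1.0))


@dataclass
class GeneratorParams:
    """Ground-truth geometry and trace parameters for one group.

    total_length µm; loop_curvature_amp 1/µm (the curvature of every loop
    arc); loop_tilt_deg degrees between the loop-progression axis and the
    main body axis; tube_radius_mean µm; noise_sd µm of smooth positional
    tracing noise; intensity_peak_pos fraction of gut length (R3 centre);
    ar_coeffs/ar_noise_sd define the stationary AR noise on traces.
    """

    total_length: float = 6000.0
    loop_count: int = 3
    loop_curvature_amp: float = 0.002
    loop_tilt_deg: float = 15.0
    hindgut_coil_turns: float = 2.0
    tube_radius_mean: float = 45.0
    noise_sd: float = 2.0
    intensity_peak_pos: float = 0.5
    ar_coeffs: tuple = (0.9,)
    ar_noise_sd: float = 0.05
    n_points: int = 1500

    def validate(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        if self.loop_count < 1:
            raise ValueError("loop_count must be ≥ 1")
        if self.loop_curvature_amp <= 0:
            raise ValueError("loop_curvature_amp must be positive")
        if not 0 <= self.loop_tilt_deg <= 90:
            raise ValueError("loop_tilt_deg must lie in [0, 90]")
        if self.tube_radius_mean <= 0:
            raise ValueError("tube_radius_mean must be positive")
        if self.noise_sd < 0 or self.ar_noise_sd < 0:
            raise ValueError("noise standard deviations must be ≥ 0")
        if not 0.0 <= self.intensity_peak_pos <= 1.0:
            raise ValueError("intensity_peak_pos must lie in [0, 1]")
        if not _ar_is_stationary(self.ar_coeffs):
            raise ValueError("AR coefficients are non-stationary "
                             "(companion eigenvalue on/outside the unit circle)")


def default_female_params() -> GeneratorParams:
    """Illustrative female geometry: longer, curvier loops, flatter, wider."""
    return GeneratorParams(total_length=6500.0, loop_curvature_amp=0.0022,
                           loop_tilt_deg=10.0, tube_radius_mean=50.0)


def default_male_params() -> GeneratorParams:
    return GeneratorParams(total_length=5600.0, loop_curvature_amp=0.0016,
                           loop_tilt_deg=20.0, tube_radius_mean=40.0)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    n = np.linalg.norm(axis)
    if n == 0 or angle == 0:
        return np.eye(3)
    a = axis / n
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _heading_plan(params: GeneratorParams, s: np.ndarray):
    """Per-step rotation (axis, rate) of the tangent at each arclength sample.

    The tangent T(s) is rotated about a prescribed axis at a prescribed
    rate (= unsigned curvature) in each segment:

    * anterior: gentle sinusoidal in-plane wiggle (axis ẑ);
    * trans1: constant-rate geodesic turn from x̂ to the serpentine entry
      tangent;
    * loops: serpentine of circular arcs — rotation about the tilted
      plane's normal at constant rate ``loop_curvature_amp`` with the
      sign alternating every arc, so |κ| is exactly the amplitude and the
      net progression runs along the tilted axis u = (cos φ_t, 0, sin φ_t);
    * trans2: turn from the serpentine exit tangent to the helix entry;
    * hindgut: terminal coil — rotation about x̂ at the rate that makes
      ``hindgut_coil_turns`` turns of a 45°-pitch helix.
    """
    L = params.total_length
    seg = {k: v * L for k, v in SEGMENT_FRACTIONS.items()}
    tilt = np.radians(params.loop_tilt_deg)
    u = np.array([np.cos(tilt), 0.0, np.sin(tilt)])     # loop progression axis
    v = np.array([0.0, 1.0, 0.0])                       # serpentine lateral axis
    n_t = np.cross(u, v)                                # tilted-plane normal
    # symmetric serpentine: half-arcs at both ends flank loop_count full
    # arcs, so the serpentine enters and leaves along u and (for odd
    # loop_count) its lateral bulges form a palindrome, putting its
    # principal axis exactly on u
    arc_len = seg["loops"] / (params.loop_count + 1)
    t_loop_in = u
    t_loop_out = u

    # helix entry tangent (45° pitch about x̂)
    if params.hindgut_coil_turns > 0:
        t_helix_in = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
        nu = 2.0 * np.pi * params.hindgut_coil_turns / seg["hindgut"]
    else:
        t_helix_in = np.array([1.0, 0.0, 0.0])
        nu = 0.0

    def geodesic(a, b, length):
        """Axis and rate rotating unit vector a onto b over the length."""
        c = np.cross(a, b)
        sc = np.linalg.norm(c)
        ang = np.arctan2(sc, float(np.dot(a, b)))
        axis = c / sc if sc > 1e-12 else np.array([0.0, 0.0, 1.0])
        return axis, ang / length

    ax1, rate1 = geodesic(np.array([1.0, 0.0, 0.0]), t_loop_in, seg["trans1"])
    ax2, rate2 = geodesic(t_loop_out, t_helix_in, seg["trans2"])

    b0 = seg["anterior"]
    b1 = b0 + seg["trans1"]
    b2 = b1 + seg["loops"]
    b3 = b2 + seg["trans2"]

    axes = np.zeros((len(s), 3))
    rates = np.zeros(len(s))
    ant = s < b0
    axes[ant] = [0.0, 0.0, 1.0]
    rates[ant] = (1.2 / b0) * np.cos(2 * np.pi * s[ant] / b0)
    tr1 = (s >= b0) & (s < b1)
    axes[tr1] = ax1
    rates[tr1] = rate1
    loop = (s >= b1) & (s < b2)
    # sign program: leading half-arc (−), alternating full arcs (+,−,…),
    # trailing half-arc returning the heading to u
    sl = s[loop] - b1
    half = arc_len / 2.0
    signs = np.empty(sl.shape)
    lead = sl < half
    signs[lead] = -1.0
    trail = sl >= seg["loops"] - half
    full = ~lead & ~trail
    arc_idx = np.floor((sl[full] - half) / arc_len).astype(int)
    signs[full] = np.where(arc_idx % 2 == 0, 1.0, -1.0)
    signs[trail] = 1.0 if params.loop_count % 2 == 0 else -1.0
    axes[loop] = n_t
    rates[loop] = params.loop_curvature_amp * signs
    tr2 = (s >= b2) & (s < b3)
    axes[tr2] = ax2
    rates[tr2] = rate2
    hind = s >= b3
    axes[hind] = [1.0, 0.0, 0.0]
    rates[hind] = nu
    return axes, rates, (b1, b2)


def generate_centreline(params: GeneratorParams, seed: int = 0) -> Centreline:
    """Generate one synthetic gut centreline by tangent integration.

    The tangent is advanced with the exact per-step rotation (Rodrigues)
    prescribed by :func:`_heading_plan`, and positions by the tangent
    midpoint rule, so the loop arcs carry closed-form curvature.
    Landmarks ``loop_start``, ``loop_end`` and ``R3`` (at 50% of
    arclength) are attached. Positional noise is smooth (white noise
    convolved with a Gaussian kernel, rescaled to ``noise_sd``), emulating
    tracing wobble rather than sample-to-sample jitter.
    """
    params.validate()
    n = params.n_points
    L = params.total_length
    s = np.linspace(0.0, L, n)
    h = s[1] - s[0]
    axes, rates, (s_loop_start, s_loop_end) = _heading_plan(params, s)

    T = np.array([1.0, 0.0, 0.0])
    pts = np.empty((n, 3))
    pts[0] = 0.0
    for i in range(n - 1):
        R = _rodrigues(axes[i], rates[i] * h)
        T_new = R @ T
        pts[i + 1] = pts[i] + h * 0.5 * (T + T_new)
        T = T_new

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(n, 3))
        width = max(int(0.02 * n), 3)
        kern = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
        kern /= kern.sum()
        sm = np.column_stack([np.convolve(raw[:, j], kern, mode="same")
                              for j in range(3)])
        sd = sm.std()
        if sd > 0:
            pts = pts + sm * (params.noise_sd / sd)

    landmarks = {
        "loop_start": pts[np.searchsorted(s, s_loop_start)].copy(),
        "loop_end": pts[min(np.searchsorted(s, s_loop_end), n - 1)].copy(),
        "R3": pts[np.searchsorted(s, 0.5 * L)].copy(),
    }
    return Centreline(points=pts, specimen_id=f"sim_{seed}", landmarks=landmarks)


@dataclass
class CohortSpec:
    """A two-group (female/male) cohort recipe; seed fixes everything."""

    n_per_group: int = 10
    group_params: dict = field(default_factory=lambda: {
        "female": default_female_params(), "male": default_male_params()})
    batch_labels: list = field(default_factory=lambda: ["batch1", "batch2"])
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be ≥ 1")
        for p in self.group_params.values():
            p.validate()


@dataclass
class Cohort:
    """Generated centrelines plus a metadata table keyed by specimen_id."""

    centrelines: list
    metadata: pd.DataFrame

    def __iter__(self):
        for c, (_, row) in zip(self.centrelines, self.metadata.iterrows()):
            yield c, row

    def __len__(self) -> int:
        return len(self.centrelines)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a sex-dimorphic cohort with covariates.

    Per specimen, geometry parameters get mild lognormal jitter (5% on
    length, curvature amplitude and radius; 2° on tilt) so groups have
    within-group variance. Gonad and crop volumes are drawn lognormal
    with sex-specific means and share a latent factor with gut length, so
    covariates correlate with size without asserting real effect sizes.
    """
    spec.validate()
    batches = list(spec.batch_labels)
    if not batches:
        warnings.warn("empty batch list; assuming a single batch")
        batches = ["batch1"]
    rng = np.random.default_rng(spec.seed)
    centrelines = []
    rows = []
    idx = 0
    for sex, base in spec.group_params.items():
        for j in range(spec.n_per_group):
            z = rng.normal()  # latent size factor shared by length & volumes
            p = replace(
                base,
                total_length=base.total_length * np.exp(0.05 * z),
                loop_curvature_amp=base.loop_curvature_amp
                * np.exp(0.05 * rng.normal()),
                loop_tilt_deg=float(np.clip(
                    base.loop_tilt_deg + 2.0 * rng.normal(), 0.0, 90.0)),
                tube_radius_mean=base.tube_radius_mean
                * np.exp(0.05 * rng.normal()),
            )
            child_seed = int(rng.integers(0, 2**31 - 1))
            c = generate_centreline(p, seed=child_seed)
            c.specimen_id = f"{sex}_{j}"
            c.sex = sex
            c.batch = batches[idx % len(batches)]
            centrelines.append(c)
            gonad = np.exp((0.5 if sex == "female" else 0.0)
                           + 0.3 * z + 0.2 * rng.normal())
            crop = np.exp(0.2 * z + 0.2 * rng.normal())
            rows.append({"specimen_id": c.specimen_id, "sex": sex,
                         "batch": c.batch, "gonad_volume": gonad * 1e7,
                         "crop_volume": crop * 1e7,
                         "gut_length": p.total_length,
                         "true_curvature_amp": p.loop_curvature_amp,
                         "true_tilt_deg": p.loop_tilt_deg,
                         "true_radius": p.tube_radius_mean,
                         "generator_seed": child_seed})
            idx += 1
    return Cohort(centrelines=centrelines, metadata=pd.DataFrame(rows))


def generate_tube_mesh(c: Centreline | ParamCurve, radius, *,
                       n_rings: int = 200, n_sides: int = 16) -> SurfaceMesh:
    """Watertight triangular tube around a centreline.

    Cross-section circles of the local radius are placed in
    parallel-transported (rotation-minimizing) frames at ``n_rings``
    equally spaced arclength stations and capped with end fans. ``radius``
    is a constant, an array per ring, or a radius :class:`ScalarProfile`.
    Warns when the tube radius exceeds half the local radius of curvature
    (the tube would self-intersect).
    """
    p = c if isinstance(c, ParamCurve) else parameterize(c)
    if p.L <= 0:
        raise ValueError("zero-length centreline")
    curve = resampled_curve(p, n_rings)
    if isinstance(radius, ScalarProfile):
        r = radius.interp(np.linspace(radius.s[0], radius.s[-1], n_rings))
    else:
        r = np.broadcast_to(np.asarray(radius, dtype=float), (n_rings,)).copy()
    if np.any(r <= 0):
        raise ValueError("radius must be positive everywhere")

    pts = curve.points
    tang = np.gradient(pts, curve.s, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    # local curvature from tangent turning, for the self-intersection check
    dT = np.gradient(tang, curve.s, axis=0)
    kappa = np.linalg.norm(dT, axis=1)
    tight = kappa * r > 0.5
    if tight.any():
        warnings.warn(f"tube radius exceeds half the local curvature radius at "
                      f"{int(tight.sum())} rings; the tube may self-intersect")

    # parallel transport an initial normal along the curve
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tang[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    N = np.empty_like(pts)
    N[0] = ref - np.dot(ref, tang[0]) * tang[0]
    N[0] /= np.linalg.norm(N[0])
    for i in range(1, n_rings):
        v = np.cross(tang[i - 1], tang[i])
        sv = np.linalg.norm(v)
        if sv < 1e-12:
            N[i] = N[i - 1]
        else:
            ang = np.arctan2(sv, np.dot(tang[i - 1], tang[i]))
            N[i] = _rodrigues(v, ang) @ N[i - 1]
        N[i] -= np.dot(N[i], tang[i]) * tang[i]
        N[i] /= np.linalg.norm(N[i])
    B = np.cross(tang, N)

    theta = 2 * np.pi * np.arange(n_sides) / n_sides
    verts = (pts[:, None, :]
             + r[:, None, None] * (np.cos(theta)[None, :, None] * N[:, None, :]
                                   + np.sin(theta)[None, :, None] * B[:, None, :]))
    verts = verts.reshape(-1, 3)
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_sides):
            a = i * n_sides + j
            b = i * n_sides + (j + 1) % n_sides
            cc = (i + 1) * n_sides + j
            d = (i + 1) * n_sides + (j + 1) % n_sides
            faces.append([a, b, d])
            faces.append([a, d, cc])
    # conical caps with apexes pushed out by one radius, so no cap vertex
    # sits nearer the centreline than the tube wall
    start_cap = len(verts)
    verts = np.vstack([verts, pts[0] - r[0] * tang[0], pts[-1] + r[-1] * tang[-1]])
    end_cap = start_cap + 1
    for j in range(n_sides):
        faces.append([start_cap, (j + 1) % n_sides, j])
        base = (n_rings - 1) * n_sides
        faces.append([end_cap, base + j, base + (j + 1) % n_sides])
    sid = getattr(c, "specimen_id", "")
    return SurfaceMesh(vertices=verts, faces=np.array(faces), organ_name="gut",
                       specimen_id=sid)


def generate_intensity_trace(length_points: int, params: GeneratorParams,
                             seed: int = 0) -> ScalarProfile:
    """Intensity vs. position: a smooth R3-centred bump plus AR(p) noise.

    The deterministic mean is a Gaussian bump (width 8% of gut length)
    at ``intensity_peak_pos`` over a 0.2 baseline. The noise path is
    always drawn with the same normals for a given seed and scaled by
    ``ar_noise_sd``, so ``ar_noise_sd=0`` returns the mean exactly and
    trace(sd) − trace(0) is the pure (scaled) AR path.
    """
    params.validate()
    if length_points < 2:
        raise ValueError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, length_points)
    mean = 0.2 + np.exp(-0.5 * ((t - params.intensity_peak_pos) / 0.08) ** 2)
    rng = np.random.default_rng(seed)
    coeffs = np.atleast_1d(np.asarray(params.ar_coeffs, dtype=float))
    from scipy.signal import lfilter

    burn = 200
    eps = rng.normal(size=length_points + burn)
    noise = lfilter([1.0], np.concatenate([[1.0], -coeffs]), eps)[burn:]
    values = mean + params.ar_noise_sd * noise
    return ScalarProfile(s=t, values=values, kind="intensity",
                         specimen_id=f"trace_{seed}",
                         anchor=params.intensity_peak_pos)


def generate_organ_pair(gap: float, shape: str = "sphere", seed: int = 0, *,
                        radius: float = 10.0, subdivisions: int = 2
                        ) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Two meshes whose true minimal surface separation equals ``gap`` (µm).

    Spheres are oriented so one vertex of each lies exactly on the common
    axis, making the minimum vertex distance exactly ``gap``; boxes face
    each other with flat sides, likewise exact. The seed only randomizes
    the rotation about the common axis (which preserves the gap).
    """
    if gap < 0:
        raise ValueError("gap must be ≥ 0")
    rng = np.random.default_rng(seed)
    if shape == "sphere":
        base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        v = np.asarray(base.vertices)
        # rotate so vertex 0 points along +x
        u = v[0] / np.linalg.norm(v[0])
        axis = np.cross(u, [1.0, 0.0, 0.0])
        ang = np.arccos(np.clip(u[0], -1, 1))
        R = _rodrigues(axis, ang) if np.linalg.norm(axis) > 1e-12 else np.eye(3)
        v1 = v @ R.T
        spin = _rodrigues(np.array([1.0, 0.0, 0.0]), rng.uniform(0, 2 * np.pi))
        v1 = v1 @ spin.T
        centre_dist = 2 * radius + gap
        v2 = -v1 + np.array([centre_dist, 0.0, 0.0])
        f = np.asarray(base.faces)
        m1 = SurfaceMesh(vertices=v1, faces=f, organ_name="organX")
        m2 = SurfaceMesh(vertices=v2, faces=f[:, ::-1], organ_name="organY")
        return m1, m2
    if shape == "box":
        ext = 2 * radius
        base = trimesh.creation.box(extents=(ext, ext, ext)).subdivide()
        v = np.asarray(base.vertices)
        f = np.asarray(base.faces)
        v1 = v.copy()
        v2 = v + np.array([ext + gap, 0.0, 0.0])
        return (SurfaceMesh(vertices=v1, faces=f, organ_name="organX"),
                SurfaceMesh(vertices=v2, faces=f, organ_name="organY"))
    raise ValueError(f"unknown organ shape {shape!r}")
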