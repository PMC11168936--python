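"""Local differential geometry of arclength-parameterized centrelines.

Curvature κ(s) and torsion τ(s) are estimated by fitting the curve in a
sliding arclength neighbourhood of half-width δ = 0.05·L to a cubic
(third-degree Taylor expansion of position), reading the derivatives off
the fitted coefficients, and applying the Frenet–Serret relations for an
(approximately) arclength-parameterized curve:

    κ(s*) = |x″(s*)|,     τ(s*) = (x′(s*) × x″(s*)) · x‴(s*) / κ(s*)²

Both profiles are then smoothed with a zero-phase low-pass filter
(normalized cutoff 0.3). Curvature and torsion carry units 1/µm; the
scale-invariant descriptors are the length-normalized κ̃ = L·κ and L·τ.
The module also measures tube radius (centreline-to-mesh distance) and the
tilt of a sub-region's principal axis against the whole organ's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

from organgeo.centreline import ParamCurve

#: Curvature below this (1/µm) makes the torsion quotient unreliable;
#: τ is flagged undefined there rather than reported as 0.
KAPPA_EPS = 1e-6


@dataclass
class ScalarProfile:
    """A scalar function sampled along arclength.

    ``kind`` is one of ``curvature`` (1/µm), ``torsion`` (1/µm),
    ``normalized_curvature``/``normalized_torsion`` (dimensionless),
    ``radius`` (µm) or ``intensity`` (arbitrary units). ``undefined`` marks
    samples where the quantity could not be evaluated (e.g. torsion at
    vanishing curvature).
    """

    s: np.ndarray
    values: np.ndarray
    kind: str = "intensity"
    specimen_id: str = ""
    anchor: float | None = None  # R3 anchor as a fraction of length, for traces
    undefined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.s.shape != self.values.shape:
            raise ValueError("s and values must have the same shape")
        if len(self.s) > 1 and np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)
        else:
            self.undefined = np.asarray(self.undefined, dtype=bool)

    def __len__(self) -> int:
        return len(self.s)

    @property
    def domain_length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def on_unit_domain(self) -> "ScalarProfile":
        """Re-express samples on relative arclength s/L ∈ [0, 1]."""
        span = self.domain_length
        if span <= 0:
            raise ValueError("degenerate profile domain")
        return replace(self, s=(self.s - self.s[0]) / span)

    def interp(self, s_query: np.ndarray) -> np.ndarray:
        """Linear interpolation of values, interpolating over undefined samples."""
        good = ~self.undefined
        if good.sum() < 2:
            raise ValueError("too few defined samples to interpolate")
        return np.interp(np.asarray(s_query, dtype=float),
                         self.s[good], self.values[good])


@dataclass
class LocalFit:
    """Derivatives of position w.r.t. arclength from one local cubic fit."""

    s_star: float
    d1: np.ndarray  # x′(s*)
    d2: np.ndarray  # x″(s*)
    d3: np.ndarray  # x‴(s*)
    n_neighbors: int


def local_cubic_fit(p: ParamCurve, s_star: float, delta: float) -> LocalFit:
    """Unweighted least-squares cubic fit of x(s) around s*.

    The neighbourhood is {points with |s − s*| < δ}; neighbourhoods at the
    curve ends are simply truncated. Each coordinate is fitted by a cubic
    in (s − s*); the derivatives are 1×, 2×, 6× the linear, quadratic and
    cubic coefficients.
    """
    mask = np.abs(p.s - s_star) < delta
    n = int(mask.sum())
    if n < 4:
        raise ValueError(
            f"only {n} points within δ={delta:g} of s*={s_star:g}; "
            "resample the curve more densely or increase δ")
    ds = p.s[mask] - s_star
    # Vandermonde [1, ds, ds², ds³]; one lstsq solves all 3 coordinates.
    A = np.vander(ds, 4, increasing=True)
    coef, *_ = np.linalg.lstsq(A, p.points[mask], rcond=None)
    return LocalFit(s_star=float(s_star), d1=coef[1], d2=2.0 * coef[2],
                    d3=6.0 * coef[3], n_neighbors=n)


def _raw_curvature_torsion(p: ParamCurve, delta: float):
    n = len(p)
    kappa = np.empty(n)
    tau = np.full(n, np.nan)
    undef = np.zeros(n, dtype=bool)
    # Shared Vandermonde machinery, re-sliced per point: neighbourhood
    # bounds move monotonically so two pointers suffice.
    lo = 0
    hi = 0
    for i, s_star in enumerate(p.s):
        while lo < n and p.s[lo] <= s_star - delta:
            lo += 1
        if hi < lo:
            hi = lo
        while hi < n and p.s[hi] < s_star + delta:
            hi += 1
        if hi - lo < 4:
            raise ValueError(
                f"only {hi - lo} points within δ={delta:g} of s*={s_star:g}; "
                "resample the curve more densely or increase δ")
        ds = p.s[lo:hi] - s_star
        A = np.vander(ds, 4, increasing=True)
        coef, *_ = np.linalg.lstsq(A, p.points[lo:hi], rcond=None)
        d1, d2, d3 = coef[1], 2.0 * coef[2], 6.0 * coef[3]
        k = float(np.linalg.norm(d2))
        kappa[i] = k
        if k < KAPPA_EPS:
            undef[i] = True
        else:
            tau[i] = float(np.dot(np.cross(d1, d2), d3) / k**2)
    return kappa, tau, undef


def curvature_torsion(p: ParamCurve, delta_frac: float = 0.05, *,
                      cutoff: float = 0.3) -> tuple[ScalarProfile, ScalarProfile]:
    """Curvature and torsion profiles along the whole curve.

    Evaluates the local cubic fit at every curve point with neighbourhood
    half-width δ = delta_frac·L, applies the Frenet–Serret formulas, and
    low-pass filters both profiles (zero phase, normalized cutoff 0.3).
    Where κ < κ_eps the torsion is recorded undefined, not zero.
    """
    if not 0 < delta_frac < 0.5:
        raise ValueError("delta_frac must lie in (0, 0.5)")
    if len(p) < 4:
        raise ValueError("need at least 4 points")
    delta = delta_frac * p.L
    kappa, tau, undef = _raw_curvature_torsion(p, delta)
    kap = ScalarProfile(s=p.s, values=kappa, kind="curvature",
                        specimen_id=p.specimen_id)
    kap = smooth_profile(kap, cutoff)
    kap.values = np.maximum(kap.values, 0.0)  # κ ≥ 0 by definition
    if undef.all():
        tau_prof = ScalarProfile(s=p.s, values=tau, kind="torsion",
                                 specimen_id=p.specimen_id, undefined=undef)
    else:
        tau_filled = tau.copy()
        if undef.any():  # interpolate over undefined gaps before filtering
            good = ~undef
            tau_filled[undef] = np.interp(p.s[undef], p.s[good], tau[good])
        tau_prof = ScalarProfile(s=p.s, values=tau_filled, kind="torsion",
                                 specimen_id=p.specimen_id)
        tau_prof = smooth_profile(tau_prof, cutoff)
        tau_prof.undefined = undef
        tau_prof.values[undef] = np.nan
    return kap, tau_prof


def smooth_profile(f: ScalarProfile, cutoff: float = 0.3) -> ScalarProfile:
    """Zero-phase low-pass filtering of a profile.

    A 4th-order Butterworth filter with the given normalized cutoff
    (fraction of the Nyquist frequency) is applied forward and backward
    (``filtfilt``), so constants pass unchanged and no phase lag is
    introduced. Samples are resampled to a uniform grid internally if the
    arclength spacing is uneven, and mapped back by interpolation.
    """
    n = len(f)
    order = 4
    if n <= 3 * (order + 1):
        warnings.warn("profile shorter than filter warm-up; returned unfiltered")
        return replace(f, values=f.values.copy())
    ds = np.diff(f.s)
    uniform = np.allclose(ds, ds[0], rtol=1e-6)
    if uniform:
        y = f.values
    else:
        grid = np.linspace(f.s[0], f.s[-1], n)
        y = np.interp(grid, f.s, f.values)
    b, a = signal.butter(order, cutoff)
    y_s = signal.filtfilt(b, a, y, padtype="even")
    if not uniform:
        y_s = np.interp(f.s, grid, y_s)
    return replace(f, values=y_s)


def normalize_by_length(f: ScalarProfile, L: float) -> ScalarProfile:
    """Scale-invariant normalized curvature/torsion: values × L.

    Doubling the organ without changing its shape halves κ and τ; the
    products κ̃ = L·κ and L·τ depend only on shape.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if f.kind not in ("curvature", "torsion"):
        raise ValueError(f"cannot length-normalize a {f.kind!r} profile")
    return replace(f, values=f.values * L, kind=f"normalized_{f.kind}")


def radius_profile(p: ParamCurve, mesh, cutoff: float = 0.3) -> ScalarProfile:
    """Tube radius along the centreline.

    Radius at each centreline point is its minimum distance to the gut
    mesh vertices (the unsmoothed segmentation mesh), smoothed with the
    standard cutoff-0.3 low-pass. Vertex (not point-to-triangle) distances
    are used throughout the package; the bias is about half an edge length.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if len(verts) == 0:
        raise ValueError("empty mesh")
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    outside = np.any((p.points < lo) | (p.points > hi), axis=1)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} centreline points lie outside "
                      "the mesh bounding box")
    d, _ = cKDTree(verts).query(p.points)
    prof = ScalarProfile(s=p.s, values=d, kind="radius", specimen_id=p.specimen_id)
    return smooth_profile(prof, cutoff)


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the 3×3 covariance of a point cloud."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    C = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 1e-10:
        raise ValueError("degenerate leading eigenvalue: point cloud has no "
                         "unique principal axis")
    return evecs[:, -1]


def tilt_angle(whole: ParamCurve, subregion: ParamCurve) -> float:
    """Tilt (degrees) of a sub-region against the whole organ.

    Both curves are summarized by the largest eigendirection of their
    point-cloud covariance (V_g for the whole gut, V_m for the midgut
    loops); the tilt is φ = arccos(|V_g·V_m| / (|V_g||V_m|)), in [0°, 90°].
    The absolute value resolves the eigenvector sign ambiguity.
    """
    vg = principal_axis(whole.points)
    vm = principal_axis(subregion.points)
    c = abs(float(np.dot(vg, vm))) / (np.linalg.norm(vg) * np.linalg.norm(vm))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def profiles_to_frame(profiles: list[ScalarProfile]):
    """Export profiles as a tidy table (specimen_id, s, s/L, kind, value, flag)."""
    import pandas as pd

    rows = []
    for f in profiles:
        span = f.domain_length or 1.0
        for si, vi, ui in zip(f.s, f.values, f.undefined):
            rows.append({"specimen_id": f.specimen_id, "s": si,
                         "s_over_L": (si - f.s[0]) / span, "kind": f.kind,
                         "value": vi, "undefined_flag": bool(ui)})
    return pd.DataFrame(rows)
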