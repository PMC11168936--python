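"""Elastic comparison of curvature profiles across specimens.

Two centrelines are compared through their normalized-curvature functions
κ̃(s). First the functions are registered: a boundary-anchored monotone
warp s₂ = γ(s₁) is found that minimizes the Fisher–Rao misalignment,
computed in square-root-slope (SRSF) representation

    q(t) = sign(f′(t))·√|f′(t)|,   cost = ∫ [q₁(t) − q₂(γ(t))·√γ′(t)]² dt

by dynamic programming over monotone lattice paths. The curvature distance
is then the root-mean-square difference of the registered functions on a
200-point grid in s₁:

    dist(κ̃₁, κ̃₂) = sqrt( (1/200) Σₙ [κ̃₁(sₙ) − κ̃₂(γ(sₙ))]² )

Relative distances (divided by the cohort maximum) feed a metric MDS that
assigns each specimen 3D coordinates (µ₁, µ₂, µ₃); group scatter is
summarized by 95% Gaussian ellipsoids and group location differences are
tested with a conservative two-branch battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import smacof

from organgeo.diffgeo import ScalarProfile

__all__ = [
    "DistanceMatrix",
    "MdsEmbedding",
    "Warping",
    "curvature_distance",
    "distance_matrix",
    "elastic_register",
    "group_ellipsoid",
    "location_test",
    "mds_embed",
]

#: Monotone lattice steps (Δi, Δj) allowed in the warping path; coprime
#: pairs up to 5 give slopes between 1/5 and 5. The diagonal step comes
#: first so that cost ties resolve toward the identity warp.
_STEPS = [(1, 1)] + sorted(
    {(p, q) for p in range(1, 6) for q in range(1, 6)
     if gcd(p, q) == 1 and (p, q) != (1, 1)},
    key=lambda pq: abs(pq[0] - pq[1]))

_DEFAULT_GRID = 101


@dataclass
class Warping:
    """Boundary-anchored monotone map s₂ = γ(s₁) on a discrete grid.

    ``grid`` and ``gamma`` live on normalized arclength [0, 1];
    ``L1``/``L2`` restore physical units.
    """

    grid: np.ndarray
    gamma: np.ndarray
    L1: float = 1.0
    L2: float = 1.0

    def __call__(self, s1: np.ndarray) -> np.ndarray:
        """Evaluate γ at physical arclengths on the first curve."""
        t = np.asarray(s1, dtype=float) / self.L1
        return np.interp(t, self.grid, self.gamma) * self.L2

    @property
    def is_identity(self) -> bool:
        step = self.grid[1] - self.grid[0]
        return bool(np.max(np.abs(self.gamma - self.grid)) < step)


def _srsf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    d = np.gradient(values, grid)
    return np.sign(d) * np.sqrt(np.abs(d))


def _resample(f: ScalarProfile, n: int) -> tuple[np.ndarray, np.ndarray]:
    fu = f.on_unit_domain()
    grid = np.linspace(0.0, 1.0, n)
    return grid, fu.interp(grid)


def _dp_warp(q1: np.ndarray, q2: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Optimal warp node path by dynamic programming; returns γ on the grid."""
    n = len(grid)
    dt = grid[1] - grid[0]
    INF = np.inf
    E = np.full((n, n), INF)
    E[0, 0] = 0.0
    step_p = np.zeros((n, n), dtype=np.int8)
    step_q = np.zeros((n, n), dtype=np.int8)

    # Precompute the cost of each allowed step ending at every node (i, j):
    # trapezoid integral of (q1(t) - sqrt(slope) q2(gamma(t)))^2 over the
    # p subintervals the step spans.
    costs = {}
    for (p, q) in _STEPS:
        if p >= n or q >= n:
            continue
        slope = q / p
        w = np.full(p + 1, dt)
        w[0] = w[-1] = dt / 2.0
        C = np.zeros((n - p, n - q))
        i_idx = np.arange(p, n)
        j_idx = np.arange(q, n)
        for m in range(p + 1):
            a = q1[i_idx - p + m]
            # fractional index of gamma at the m-th sample: j - q + q*m/p
            g = j_idx - q + slope * m
            fl = np.floor(g).astype(int)
            fr = g - fl
            fl_next = np.minimum(fl + 1, n - 1)
            b = (1.0 - fr) * q2[fl] + fr * q2[fl_next]
            C += w[m] * (a[:, None] - np.sqrt(slope) * b[None, :]) ** 2
        costs[(p, q)] = C

    for i in range(1, n):
        for (p, q) in _STEPS:
            if p > i or (p, q) not in costs:
                continue
            prev = E[i - p, : n - q]
            cand = prev + costs[(p, q)][i - p, :]
            row = E[i, q:]
            better = cand < row
            if better.any():
                row[better] = cand[better]
                step_p[i, q:][better] = p
                step_q[i, q:][better] = q

    # backtrack from (n-1, n-1)
    path_i, path_j = [n - 1], [n - 1]
    i, j = n - 1, n - 1
    while i > 0:
        p, q = int(step_p[i, j]), int(step_q[i, j])
        if p == 0:  # unreachable corner: fall back to identity
            return grid.copy()
        i, j = i - p, j - q
        path_i.append(i)
        path_j.append(j)
    path_i.reverse()
    path_j.reverse()
    return np.interp(grid, grid[path_i], grid[path_j])


def elastic_register(f1: ScalarProfile, f2: ScalarProfile, *,
                     n_grid: int = _DEFAULT_GRID) -> Warping:
    """Fisher–Rao optimal warping of f2's domain onto f1's.

    Both profiles are re-expressed on relative arclength so organs of
    different lengths are comparable; the SRSF dynamic program finds the
    monotone, boundary-anchored γ. Identical (and constant) inputs return
    the identity warp.
    """
    if len(f1) < 10 or len(f2) < 10:
        raise ValueError("profiles need at least 10 samples for registration")
    grid, v1 = _resample(f1, n_grid)
    _, v2 = _resample(f2, n_grid)
    if not (np.isfinite(v1).all() and np.isfinite(v2).all()):
        raise ValueError("profiles must be finite everywhere")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        # a constant profile makes every warp optimal; tie-break: identity
        return Warping(grid=grid, gamma=grid.copy(),
                       L1=f1.domain_length, L2=f2.domain_length)
    # the optimal warp is invariant to affine value scaling; normalizing
    # keeps the SRSF well away from float noise
    v1 = (v1 - v1.min()) / np.ptp(v1)
    v2 = (v2 - v2.min()) / np.ptp(v2)
    q1 = _srsf(v1, grid)
    q2 = _srsf(v2, grid)
    gamma = _dp_warp(q1, q2, grid)
    return Warping(grid=grid, gamma=gamma,
                   L1=f1.domain_length, L2=f2.domain_length)


def registered_difference(k1: ScalarProfile, k2: ScalarProfile,
                          warp: Warping, n_grid: int = 200) -> np.ndarray:
    """κ̃₁(sₙ) − κ̃₂(γ(sₙ)) on n_grid equally spaced s₁ points."""
    sn = np.linspace(0.0, 1.0, n_grid)
    k1u = k1.on_unit_domain()
    k2u = k2.on_unit_domain()
    g = np.interp(sn, warp.grid, warp.gamma)
    return k1u.interp(sn) - k2u.interp(g)


def curvature_distance(k1: ScalarProfile, k2: ScalarProfile, *,
                       n_grid: int = 200, symmetric: bool = False,
                       reg_grid: int = _DEFAULT_GRID) -> float:
    """RMS distance between normalized-curvature profiles after registration.

    Registers k2 onto k1 and evaluates the discretized distance on
    ``n_grid`` equally spaced s₁ points. If the elastic warp does not
    reduce the value-space RMS below the unwarped one (SRSF optimality is
    in the Fisher–Rao metric, not L2), the identity warp is used, so
    registration never increases the distance. ``symmetric=True`` averages
    the two registration directions (required when the values feed MDS).
    """
    frac_undef = max(np.mean(k1.undefined), np.mean(k2.undefined))
    if frac_undef > 0.05:
        raise ValueError("more than 5% of samples undefined; cannot interpolate")
    if symmetric:
        d12 = curvature_distance(k1, k2, n_grid=n_grid, reg_grid=reg_grid)
        d21 = curvature_distance(k2, k1, n_grid=n_grid, reg_grid=reg_grid)
        return 0.5 * (d12 + d21)
    warp = elastic_register(k1, k2, n_grid=reg_grid)
    diff = registered_difference(k1, k2, warp, n_grid)
    d = float(np.sqrt(np.mean(diff**2)))
    ident = Warping(grid=warp.grid, gamma=warp.grid.copy())
    diff0 = registered_difference(k1, k2, ident, n_grid)
    d0 = float(np.sqrt(np.mean(diff0**2)))
    return min(d, d0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise profile distances, optionally relative to the max."""

    values: np.ndarray
    ids: list[str]
    relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(profiles: list[ScalarProfile], *, relative: bool = False,
                    n_grid: int = 200, reg_grid: int = _DEFAULT_GRID) -> DistanceMatrix:
    """All-pairs symmetrized curvature distances for a cohort.

    With ``relative=True`` the distances are divided by the maximum over
    all pairs in the analysis, so the largest entry is 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = curvature_distance(
                    profiles[i], profiles[j], n_grid=n_grid,
                    symmetric=True, reg_grid=reg_grid)
            except ValueError as exc:
                ids = (profiles[i].specimen_id, profiles[j].specimen_id)
                raise ValueError(f"distance failed for pair {ids}: {exc}") from exc
    if relative:
        m = D.max()
        if m > 0:
            D = D / m
    ids = [f.specimen_id or f"profile_{i}" for i, f in enumerate(profiles)]
    return DistanceMatrix(values=D, ids=ids, relative=relative)


@dataclass
class MdsEmbedding:
    """Per-specimen MDS coordinates (µ₁, µ₂, µ₃) and the Kruskal stress-1."""

    coords: np.ndarray
    ids: list[str]
    stress: float

    def to_frame(self, groups=None) -> pd.DataFrame:
        df = pd.DataFrame(self.coords,
                          columns=[f"mu{i+1}" for i in range(self.coords.shape[1])])
        df.insert(0, "id", self.ids)
        if groups is not None:
            df["group"] = list(groups)
        return df


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    X = evecs[:, order] * np.sqrt(lam)
    # deterministic sign: largest-magnitude coordinate positive
    for j in range(X.shape[1]):
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] *= -1
    return X


def mds_embed(d: DistanceMatrix, dim: int = 3, seed: int | None = None) -> MdsEmbedding:
    """Metric least-squares MDS of a distance matrix.

    Classical scaling provides the initial coordinates; SMACOF stress
    majorization refines them (stress is non-increasing by construction).
    For distance matrices that are exactly Euclidean in ``dim`` dimensions
    the embedding reproduces the inputs and the stress is ≈ 0. The
    reported stress is Kruskal's stress-1.
    """
    if d.n <= dim:
        raise ValueError(f"need more than {dim} items to embed in {dim}D")
    D = d.values
    init = _classical_scaling(D, dim)
    coords, _ = smacof(D, metric=True, n_components=dim, init=init, n_init=1,
                       max_iter=300, eps=1e-9,
                       random_state=None if seed is None else int(seed) % (2**31),
                       normalized_stress=False)
    demb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    denom = float((D**2).sum())
    stress1 = float(np.sqrt(((demb - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MdsEmbedding(coords=coords, ids=list(d.ids), stress=stress1)


@dataclass
class Ellipsoid:
    """Gaussian confidence ellipsoid: centre, principal axes, radii."""

    centre: np.ndarray
    axes: np.ndarray    # rows are unit principal directions
    radii: np.ndarray
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(points) - self.centre) @ self.axes.T
        return (np.sum((x / self.radii) ** 2, axis=1) <= 1.0)

    def to_dict(self) -> dict:
        return {"centre": self.centre.tolist(), "axes": self.axes.tolist(),
                "radii": self.radii.tolist(), "level": self.level}


def group_ellipsoid(coords: np.ndarray, level: float = 0.95) -> Ellipsoid:
    """Fit a Gaussian to points and return the given-level ellipsoid.

    Radii are √(λᵢ · χ²_d(level)) along the covariance eigendirections, so
    for a large Gaussian sample about ``level`` of points fall inside.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points to fit an ellipsoid")
    centre = pts.mean(axis=0)
    C = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    if evals.min() <= 1e-12 * max(evals.max(), 1.0):
        raise ValueError("singular covariance; reduce the embedding dimension")
    q = stats.chi2.ppf(level, df=pts.shape[1])
    return Ellipsoid(centre=centre, axes=evecs.T, radii=np.sqrt(evals * q),
                     level=level)


def location_test(groupA: np.ndarray, groupB: np.ndarray, *,
                  normality_alpha: float = 0.05) -> tuple[float, str]:
    """Two-sample location test on MDS coordinates.

    A fixed decision table (rather than min-p over a battery, which would
    inflate type-I error): if every coordinate of both groups passes a
    Shapiro–Wilk normality check, Hotelling's T² (the multivariate
    two-sample t-test) is used; otherwise a Mann–Whitney U test on scores
    along the first principal axis of the pooled, label-blind point cloud
    (so the projection is exchangeable under the null). Returns (p, name).
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must have equal dimensionality")
    if len(A) < 3 or len(B) < 3:
        raise ValueError("need at least 3 points per group")
    normal = True
    for G in (A, B):
        for j in range(G.shape[1]):
            col = G[:, j]
            if np.ptp(col) == 0:
                continue
            if stats.shapiro(col).pvalue < normality_alpha:
                normal = False
    d = A.shape[1]
    if normal:
        p = _hotelling_t2_p(A, B)
        if p is not None:
            return p, "hotelling_t2"
    pooled = np.vstack([A, B])
    centred = pooled - pooled.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    axis = Vt[0]
    sa, sb = A @ axis, B @ axis
    if np.ptp(np.concatenate([sa, sb])) == 0:
        return 1.0, "mann_whitney_u"
    res = stats.mannwhitneyu(sa, sb, alternative="two-sided")
    return float(res.pvalue), "mann_whitney_u"


def _hotelling_t2_p(A: np.ndarray, B: np.ndarray) -> float | None:
    n1, n2 = len(A), len(B)
    d = A.shape[1]
    df2 = n1 + n2 - d - 1
    if df2 <= 0:
        return None
    diff = A.mean(axis=0) - B.mean(axis=0)
    S = (((n1 - 1) * np.cov(A.T, ddof=1) + (n2 - 1) * np.cov(B.T, ddof=1))
         / (n1 + n2 - 2))
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        return None
    t2 = (n1 * n2) / (n1 + n2) * float(diff @ sol)
    F = t2 * df2 / ((n1 + n2 - 2) * d)
    return float(stats.f.sf(F, d, df2))
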