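"""Centreline containers and I/O.

A centreline is the ordered 3D polyline traced through the middle of a
tubular organ (here, the fly gut from proventriculus to ampulla), in µm.
This module reads traces (SWC from neurite tracing, or plain x,y,z CSV),
parameterizes them by arclength, subsets them between anatomical landmarks
(anterior midgut / midgut loops / hindgut boundaries), and resamples them
into the equally spaced pseudolandmark configurations that the shape
statistics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default snap radius (µm) for mapping an off-curve landmark pick onto the
#: nearest centreline point; manual picks are made on image stacks so they
#: rarely lie exactly on the trace.
DEFAULT_SNAP_RADIUS = 30.0

#: Refuse pathologically large pseudolandmark counts.
MAX_PSEUDOLANDMARKS = 100_000


@dataclass
class Centreline:
    """Ordered, unbranched 3D polyline with specimen metadata.

    Parameters
    ----------
    points
        (n, 3) float array of x, y, z in µm, ordered anterior → posterior.
    specimen_id
        Free-text identifier.
    sex, batch
        Optional categorical metadata used by the cohort statistics.
    landmarks
        Optional named 3D points (``loop_start``, ``loop_end``, ``R3``)
        delimiting gut regions; they need not lie exactly on the polyline.
    """

    points: np.ndarray
    specimen_id: str = ""
    sex: str | None = None
    batch: str | None = None
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 4:
            raise ValueError("a centreline needs at least 4 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive centreline points must be distinct")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class ParamCurve:
    """A centreline with its arclength coordinate.

    ``s[i]`` is the cumulative length of the segments leading up to point i,
    starting from the anterior end, so ``s[0] = 0`` and ``s[-1] = L``.
    """

    points: np.ndarray
    s: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    specimen_id: str = ""

    @property
    def L(self) -> float:
        """Total arclength (µm)."""
        return float(self.s[-1])

    def __len__(self) -> int:
        return len(self.points)

    def position_at(self, s_query: np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arbitrary arclengths."""
        s_query = np.atleast_1d(np.asarray(s_query, dtype=float))
        out = np.empty((len(s_query), 3))
        for j in range(3):
            out[:, j] = np.interp(s_query, self.s, self.points[:, j])
        return out


class LandmarkConfiguration(np.ndarray):
    """k×3 matrix of equally spaced pseudolandmarks (anterior → posterior).

    A thin ndarray subclass: rows are the k points; behaves as a plain
    array in all numerical code.
    """

    def __new__(cls, points: np.ndarray) -> "LandmarkConfiguration":
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("a landmark configuration must be k×3")
        return arr.view(cls)

    @property
    def k(self) -> int:
        return self.shape[0]


def read_centreline(path, format: str | None = None, *, specimen_id: str = "",
                    voxel_size: float = 1.0) -> Centreline:
    """Read a centreline from an SWC or 3-column CSV file.

    SWC files must encode a single unbranched path (one root, each node the
    parent of at most one other node); the radius column is ignored, radii
    come from meshes. ``voxel_size`` multiplies coordinates for traces
    stored in voxel units (default: coordinates already in µm).
    """
    path = str(path)
    if format is None:
        format = "swc" if path.lower().endswith(".swc") else "csv"
    if format not in ("swc", "csv"):
        raise ValueError(f"unknown centreline format {format!r}")
    if format == "swc":
        pts = _read_swc(path)
    else:
        pts = _read_csv(path)
    return Centreline(points=pts * float(voxel_size),
                      specimen_id=specimen_id or path)


def _read_swc(path: str) -> np.ndarray:
    nodes: dict[int, tuple[np.ndarray, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 7:
                raise ValueError(f"{path}:{lineno}: SWC rows need 7 columns")
            try:
                idx = int(cols[0])
                xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])])
                parent = int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric SWC field") from exc
            nodes[idx] = (xyz, parent)
    if not nodes:
        raise ValueError(f"{path}: empty SWC file")
    children: dict[int, list[int]] = {}
    roots = []
    for idx, (_, parent) in nodes.items():
        if parent == -1:
            roots.append(idx)
        else:
            children.setdefault(parent, []).append(idx)
    if len(roots) != 1:
        raise ValueError(f"{path}: expected exactly one SWC root, found {len(roots)}")
    for parent, kids in children.items():
        if len(kids) > 1:
            raise ValueError(
                f"{path}: SWC tree branches at node {parent}; centrelines must be unbranched")
    order = [roots[0]]
    while order[-1] in children:
        order.append(children[order[-1]][0])
    if len(order) != len(nodes):
        raise ValueError(f"{path}: SWC file contains disconnected nodes")
    return np.array([nodes[i][0] for i in order])


def _read_csv(path: str) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    if {"x", "y", "z"}.issubset(df.columns):
        df = df[["x", "y", "z"]]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
    else:
        raise ValueError(f"{path}: need 3 coordinate columns")
    bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric coordinates at data row {row + 1}")
    return df.to_numpy(dtype=float)


def write_centreline(c: Centreline, path, format: str | None = None, *,
                     seed: int | None = None) -> None:
    """Write a centreline as SWC (unbranched chain) or CSV (x,y,z header)."""
    path = str(path)
    if format is None:
        format = "swc" if path.lower().endswith(".swc") else "csv"
    if format == "swc":
        with open(path, "w") as fh:
            fh.write(f"# organgeo centreline {c.specimen_id} (units µm)\n")
            for i, p in enumerate(c.points, start=1):
                parent = -1 if i == 1 else i - 1
                fh.write(f"{i} 0 {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} 1.0 {parent}\n")
    elif format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# organgeo centreline {c.specimen_id} (units µm)")
            if seed is not None:
                fh.write(f" seed={seed}")
            fh.write("\nx,y,z\n")
            for p in c.points:
                fh.write(f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
    else:
        raise ValueError(f"unknown centreline format {format!r}")


def parameterize(c: Centreline) -> ParamCurve:
    """Assign the arclength coordinate s to every centreline point.

    ``s[i]`` sums the lengths of the line segments leading up to point i
    from the anterior end. Duplicate consecutive points (which a
    ``Centreline`` cannot hold but raw arrays passed in tests may) are
    collapsed with a warning.
    """
    pts = np.asarray(c.points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        warnings.warn("collapsing duplicate consecutive points")
        keep = np.concatenate([[True], seg > 0.0])
        pts = pts[keep]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return ParamCurve(points=pts, s=s, landmarks=dict(c.landmarks),
                      specimen_id=c.specimen_id)


def _snap_landmark(p: ParamCurve, name: str, snap_radius: float) -> int:
    if name not in p.landmarks:
        raise KeyError(f"landmark {name!r} not present on {p.specimen_id or 'curve'}")
    lm = p.landmarks[name]
    d = np.linalg.norm(p.points - lm, axis=1)
    i = int(np.argmin(d))
    if d[i] > snap_radius:
        raise ValueError(
            f"landmark {name!r} is {d[i]:.1f} µm from the centreline "
            f"(snap radius {snap_radius:g} µm)")
    return i


def subset_by_landmarks(p: ParamCurve, from_lm: str, to_lm: str, *,
                        snap_radius: float = DEFAULT_SNAP_RADIUS) -> ParamCurve:
    """Contiguous sub-curve between two named landmarks, re-parameterized.

    Each landmark is snapped to the nearest centreline point (it must lie
    within ``snap_radius``); ``from_lm`` must be anterior of ``to_lm``.
    The returned curve starts again at s = 0.
    """
    i0 = _snap_landmark(p, from_lm, snap_radius)
    i1 = _snap_landmark(p, to_lm, snap_radius)
    if i1 <= i0:
        raise ValueError(
            f"landmark {to_lm!r} is not posterior of {from_lm!r} on the curve")
    pts = p.points[i0:i1 + 1]
    s = p.s[i0:i1 + 1] - p.s[i0]
    return ParamCurve(points=pts, s=s, landmarks=dict(p.landmarks),
                      specimen_id=p.specimen_id)


def resample_equal(p: ParamCurve, k: int) -> LandmarkConfiguration:
    """k equally spaced pseudolandmarks along the curve.

    Point j sits at arclength j·L/(k−1), linearly interpolated on the
    polyline segments; the first and last pseudolandmarks coincide with the
    curve endpoints. Whole guts conventionally use k = 1000, loop-region
    subsets k = 500.
    """
    if k < 2:
        raise ValueError("need at least 2 pseudolandmarks")
    if k > MAX_PSEUDOLANDMARKS:
        raise ValueError(f"k={k} exceeds the configured maximum {MAX_PSEUDOLANDMARKS}")
    s_new = np.linspace(0.0, p.L, k)
    return LandmarkConfiguration(p.position_at(s_new))


def resampled_curve(p: ParamCurve, k: int) -> ParamCurve:
    """Like :func:`resample_equal` but returned as a ParamCurve."""
    cfg = resample_equal(p, k)
    seg = np.linalg.norm(np.diff(cfg, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return ParamCurve(points=np.asarray(cfg), s=s, landmarks=dict(p.landmarks),
                      specimen_id=p.specimen_id)


def curve_length(p: ParamCurve) -> float:
    """Total centreline length L (µm); the gut-length measurement."""
    return p.L


def cohort_table(curves: list[Centreline]) -> pd.DataFrame:
    """Serialize a cohort of centrelines to one tidy table keyed by specimen."""
    rows = []
    for c in curves:
        for i, pnt in enumerate(c.points):
            rows.append({"specimen_id": c.specimen_id, "sex": c.sex,
                         "batch": c.batch, "point_index": i,
                         "x": pnt[0], "y": pnt[1], "z": pnt[2]})
    return pd.DataFrame(rows)


def shift_landmarks(c: Centreline, **landmarks: np.ndarray) -> Centreline:
    """Return a copy with (re)placed named landmarks."""
    lm = dict(c.landmarks)
    lm.update({k: np.asarray(v, dtype=float) for k, v in landmarks.items()})
    return replace(c, landmarks=lm)
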