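"""Interorgan proximity from triangular surface meshes.

Adjacency between segmented organs is quantified on the mesh vertices:
for every vertex of organ X the Euclidean distance to its nearest vertex
of organ Y (an exact nearest-neighbour query, identical to brute force).
For gut-referenced plots the centreline is resampled to 100 equally
spaced points; each point is linked to its nearest 20 gut-mesh vertices
and inherits the minimum of their distances to the other organ. Contacts
are called when a specimen's minimum profile distance falls below a
threshold (default 5 µm, configurable — always report it with results),
and cohort contact frequency is the fraction of specimens in contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from organgeo.centreline import ParamCurve, resampled_curve

__all__ = [
    "ProximityProfile",
    "SurfaceMesh",
    "centreline_proximity",
    "contact_call",
    "min_vertex_distances",
    "read_mesh",
    "write_mesh",
]

#: Above this vertex count a warning suggests decimating the mesh first.
VERTEX_WARN = 100_000

#: Default contact-calling threshold (µm).
DEFAULT_CONTACT_THRESHOLD = 5.0


@dataclass
class SurfaceMesh:
    """Triangular surface mesh of a segmented organ (coordinates in µm)."""

    vertices: np.ndarray
    faces: np.ndarray
    organ_name: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if len(self.vertices) < 4:
            raise ValueError("a mesh needs at least 4 vertices")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if len(self.vertices) > VERTEX_WARN:
            warnings.warn(f"mesh has {len(self.vertices)} vertices; "
                          "consider decimating before proximity analysis")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def read_mesh(path, organ_name: str = "", specimen_id: str = "") -> SurfaceMesh:
    """Read a Wavefront OBJ mesh (v/f records), validating face indices."""
    path = str(path)
    n_v = 0
    faces = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0] not in ("v", "f"):
                continue
            if tok[0] == "v":
                n_v += 1
            else:
                try:
                    idx = [int(t.split("/")[0]) for t in tok[1:]]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed face record") from exc
                if any(i < 1 or i > n_v for i in idx):
                    # forward references are legal OBJ but our writers never
                    # produce them; validated again after full load below
                    faces.append((lineno, idx))
                else:
                    faces.append((lineno, idx))
    if not faces:
        raise ValueError(f"{path}: no faces found (not a surface mesh)")
    for lineno, idx in faces:
        if any(i < 1 or i > n_v for i in idx):
            raise ValueError(f"{path}:{lineno}: face index out of range")
    mesh = trimesh.load(path, file_type="obj", process=False)
    if isinstance(mesh, trimesh.Scene):
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    degen = mesh.area_faces <= 0 if len(mesh.faces) else np.array([])
    faces_arr = np.asarray(mesh.faces)
    if degen.any():
        faces_arr = faces_arr[~degen]
    return SurfaceMesh(vertices=np.asarray(mesh.vertices), faces=faces_arr,
                       organ_name=organ_name, specimen_id=specimen_id)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write v/f-only Wavefront OBJ."""
    with open(str(path), "w") as fh:
        fh.write(f"# organgeo mesh {mesh.organ_name} {mesh.specimen_id} (units µm)\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")


def min_vertex_distances(organX: SurfaceMesh, organY: SurfaceMesh) -> np.ndarray:
    """For each vertex of X, the distance to its nearest vertex of Y.

    A k-d tree performs the query; nearest neighbours are exact, so the
    result equals the brute-force all-pairs minimum.
    """
    if organX.n_vertices == 0 or organY.n_vertices == 0:
        raise ValueError("empty mesh")
    d, _ = cKDTree(organY.vertices).query(organX.vertices)
    return d


@dataclass
class ProximityProfile:
    """Distance to a target organ referenced to centreline position."""

    positions: np.ndarray   # fraction along the (sub)curve, 0..1
    distances: np.ndarray   # µm
    organ_name: str = ""
    specimen_id: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def min_distance(self) -> float:
        return float(self.distances.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"specimen_id": self.specimen_id,
                             "organ": self.organ_name,
                             "point_index": np.arange(1, len(self) + 1),
                             "position_fraction": self.positions,
                             "distance": self.distances})


def centreline_proximity(gut_curve: ParamCurve, gut_mesh: SurfaceMesh,
                         organ: SurfaceMesh, *, n_points: int = 100,
                         k_nearest: int = 20) -> ProximityProfile:
    """Distance from another organ to the gut, referenced to the centreline.

    The centreline is replotted as ``n_points`` equally spaced points;
    each is linked to its ``k_nearest`` gut-mesh vertices, and the minimum
    of those vertices' distances to the other organ is assigned to the
    point. Restrict to the loop region by subsetting the curve first.
    """
    if k_nearest > gut_mesh.n_vertices:
        warnings.warn(f"k_nearest={k_nearest} exceeds gut mesh vertex count "
                      f"{gut_mesh.n_vertices}; clipped")
        k_nearest = gut_mesh.n_vertices
    curve = resampled_curve(gut_curve, n_points)
    vert_to_organ = min_vertex_distances(gut_mesh, organ)
    _, nn = cKDTree(gut_mesh.vertices).query(curve.points, k=k_nearest)
    nn = np.atleast_2d(nn)
    if nn.ndim == 1:
        nn = nn[:, None]
    dist = vert_to_organ[nn].min(axis=1)
    return ProximityProfile(positions=np.linspace(0.0, 1.0, n_points),
                            distances=dist, organ_name=organ.organ_name,
                            specimen_id=gut_curve.specimen_id)


def contact_call(profiles: list[ProximityProfile],
                 threshold: float = DEFAULT_CONTACT_THRESHOLD) -> pd.DataFrame:
    """Per-specimen contact flags and the cohort contact frequency.

    A specimen is "in contact" when its minimum profile distance is below
    ``threshold`` (µm). Returns a table with one row per specimen plus the
    frequency in ``.attrs`` (also recoverable as ``contact.mean()``).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not profiles:
        raise ValueError("empty cohort")
    rows = [{"specimen_id": p.specimen_id, "organ": p.organ_name,
             "min_distance": p.min_distance,
             "contact": p.min_distance < threshold} for p in profiles]
    df = pd.DataFrame(rows)
    df.attrs["threshold"] = threshold
    df.attrs["n_contacts"] = int(df["contact"].sum())
    df.attrs["frequency"] = float(df["contact"].mean())
    return df


def heatmap_table(organX: SurfaceMesh, organY: SurfaceMesh) -> pd.DataFrame:
    """Per-vertex min distances of X to Y, the mesh-heatmap convention."""
    d = min_vertex_distances(organX, organY)
    return pd.DataFrame({"vertex_id": np.arange(len(d)), "distance": d})
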