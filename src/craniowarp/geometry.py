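"""Core geometric types and queries.

All coordinates are millimetres throughout the package.  Landmarks are
stored independently of meshes: a landmark placed on an iso-surface is not
assumed to coincide with any mesh vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

# Controlled vocabularies -------------------------------------------------

ROLES = ("skin", "bone_moving", "bone_static", "craniometric", "reference")
#: roles counted as bone landmarks
BONE_ROLES = ("bone_moving", "bone_static", "craniometric", "reference")
REGIONS = (
    "forehead",
    "brow",
    "ocular",
    "nasal",
    "maxillary",
    "zygomatic",
    "mandibular",
    "calvarium_skull_base",
    "none",
)
STAGES = ("pre", "post", "predicted")
SURFACE_CLASSES = ("skin", "bone")


def _check_choice(value: str, allowed: Sequence[str], what: str) -> str:
    if value not in allowed:
        raise InputError(f"unknown {what} {value!r}; expected one of {allowed}")
    return value


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (N, 3) array of points, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point with a role and a facial region."""

    name: str
    position: np.ndarray
    role: str
    region: str = "none"

    def __post_init__(self):
        if not self.name:
            raise InputError("landmark name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise InputError(f"landmark {self.name!r}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise InputError(f"landmark {self.name!r}: non-finite position")
        object.__setattr__(self, "position", pos)
        _check_choice(self.role, ROLES, "role")
        _check_choice(self.region, REGIONS, "region")


class LandmarkSet:
    """Ordered, named landmarks for one patient and stage.

    Two sets are *correspondable* iff their name sequences are identical;
    every cohort-level operation requires correspondable sets.
    """

    def __init__(
        self,
        names: Sequence[str],
        positions,
        roles: Sequence[str],
        regions: Sequence[str] | None = None,
        patient_id: str = "",
        stage: str = "pre",
    ):
        self.names = list(names)
        self.positions = _as_points(positions).copy()
        self.roles = list(roles)
        self.regions = list(regions) if regions is not None else ["none"] * len(self.names)
        self.patient_id = patient_id
        self.stage = _check_choice(stage, STAGES, "stage")
        n = len(self.names)
        if not (len(self.positions) == len(self.roles) == len(self.regions) == n):
            raise InputError("names, positions, roles and regions must have equal length")
        if len(set(self.names)) != n:
            dupes = sorted({x for x in self.names if self.names.count(x) > 1})
            raise InputError(f"duplicate landmark names: {dupes}")
        for r in self.roles:
            _check_choice(r, ROLES, "role")
        for r in self.regions:
            _check_choice(r, REGIONS, "region")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("non-finite landmark position")
        self._index = {name: i for i, name in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterable[Landmark]:
        for i, name in enumerate(self.names):
            yield Landmark(name, self.positions[i], self.roles[i], self.regions[i])

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InputError(f"landmark {name!r} not present") from None

    def position_of(self, name: str) -> np.ndarray:
        return self.positions[self.index_of(name)]

    def correspondable(self, other: "LandmarkSet") -> bool:
        return self.names == other.names

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        idx = [self.index_of(n) for n in names]
        return LandmarkSet(
            [self.names[i] for i in idx],
            self.positions[idx],
            [self.roles[i] for i in idx],
            [self.regions[i] for i in idx],
            self.patient_id,
            self.stage,
        )

    def subset_by_role(self, *roles: str) -> "LandmarkSet":
        for r in roles:
            _check_choice(r, ROLES, "role")
        names = [n for n, r in zip(self.names, self.roles) if r in roles]
        return self.subset(names)

    def with_positions(self, positions, stage: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            self.names,
            positions,
            self.roles,
            self.regions,
            self.patient_id,
            stage if stage is not None else self.stage,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": self.names,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "role": self.roles,
                "region": self.regions,
            }
        )


class SurfaceMesh:
    """A triangulated skin or bone iso-surface (vertices in mm)."""

    def __init__(self, vertices, faces, surface_class: str = "bone", stage: str = "pre"):
        self.vertices = _as_points(vertices).copy()
        faces = np.asarray(faces, dtype=np.int64)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise InputError(f"faces must be an (M, 3) index array, got shape {faces.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise InputError("non-finite mesh vertex")
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.vertices)):
            raise InputError("face index out of range")
        self.faces = faces.copy()
        self.surface_class = _check_choice(surface_class, SURFACE_CLASSES, "surface class")
        self.stage = _check_choice(stage, STAGES, "stage")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def drop_degenerate_faces(self, min_area: float = 1e-12) -> "SurfaceMesh":
        keep = self.triangle_areas() > min_area
        return SurfaceMesh(self.vertices, self.faces[keep], self.surface_class, self.stage)

    def with_vertices(self, vertices, stage: str | None = None) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices, self.faces, self.surface_class, stage if stage is not None else self.stage
        )

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InputError("rotation must be 3x3 and translation a 3-vector")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise InputError("non-finite transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise InputError("rotation matrix is not orthonormal (within 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InputError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        return apply_rigid(self, points)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )


@dataclass
class PatientDataset:
    """One patient's pre/post skin and bone surfaces plus combined landmarks."""

    patient_id: str
    pre_skin: SurfaceMesh
    pre_bone: SurfaceMesh
    pre_landmarks: LandmarkSet
    post_skin: SurfaceMesh | None = None
    post_bone: SurfaceMesh | None = None
    post_landmarks: LandmarkSet | None = None
    cohort_label: str = "monobloc_older"
    alignment: dict | None = None

    def __post_init__(self):
        if self.post_landmarks is not None and not self.pre_landmarks.correspondable(
            self.post_landmarks
        ):
            raise InputError(
                f"patient {self.patient_id}: pre and post landmark sets are not correspondable"
            )

    @property
    def is_aligned(self) -> bool:
        return self.alignment is not None


# Operations ---------------------------------------------------------------


def apply_rigid(transform: RigidTransform, points) -> np.ndarray:
    """Apply a rigid transform to one point or an (N, 3) stack of points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = _as_points(pts)
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
        raise InputError(f"non-finite input point at index {bad}")
    out = pts @ transform.rotation.T + transform.translation
    return out[0] if single else out


def closest_points_on_triangles(points, tri_a, tri_b, tri_c) -> np.ndarray:
    """Closest point on each triangle (a, b, c) from each query point.

    Vectorised Voronoi-region classification (Ericson, *Real-Time Collision
    Detection*).  Broadcasts queries (Q, 3) against triangles (F, 3) and
    returns a (Q, F, 3) array.
    """
    p = np.asarray(points, dtype=float)[:, None, :]  # (Q,1,3)
    a = np.asarray(tri_a, dtype=float)[None, :, :]  # (1,F,3)
    b = np.asarray(tri_b, dtype=float)[None, :, :]
    c = np.asarray(tri_c, dtype=float)[None, :, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ac, ap)[0], ap)

    bp = p - b
    d3 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ac, bp)[0], bp)

    cp = p - c
    d5 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("qfk,qfk->qf", np.broadcast_arrays(ac, cp)[0], cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = va + vb + vc
    # interior barycentric coordinates; guard zero-area triangles
    safe = np.where(np.abs(denom) > 0, denom, 1.0)
    v = vb / safe
    w = vc / safe
    result = a + v[..., None] * ab + w[..., None] * ac

    # edge AC region
    wc = d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    result = np.where(on_ac[..., None], a + wc[..., None] * ac, result)

    # edge BC region
    wbc = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) + (d5 - d6), 1.0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    result = np.where(on_bc[..., None], b + wbc[..., None] * (c - b), result)

    # edge AB region
    vab = d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    result = np.where(on_ab[..., None], a + vab[..., None] * ab, result)

    # vertex regions
    at_a = (d1 <= 0) & (d2 <= 0)
    at_b = (d3 >= 0) & (d4 <= d3)
    at_c = (d6 >= 0) & (d5 <= d6)
    result = np.where(at_c[..., None], np.broadcast_to(c, result.shape), result)
    result = np.where(at_b[..., None], np.broadcast_to(b, result.shape), result)
    result = np.where(at_a[..., None], np.broadcast_to(a, result.shape), result)
    return result


def closest_points_on_mesh(points, mesh: SurfaceMesh, chunk: int = 256):
    """Closest surface points for a stack of queries.

    Exact per-triangle scan, chunked over queries to bound memory.  Ties
    between equidistant faces resolve to the lowest face index.  Returns
    (closest_points (Q, 3), face_indices (Q,), distances (Q,)).
    """
    if mesh.n_faces == 0:
        raise InputError("mesh has no faces")
    pts = _as_points(points)
    if not np.all(np.isfinite(pts)):
        raise InputError("non-finite query point")
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]

    out_pts = np.empty_like(pts)
    out_face = np.empty(len(pts), dtype=np.int64)
    out_dist = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        q = pts[start : start + chunk]
        cand = closest_points_on_triangles(q, a, b, c)  # (q,F,3)
        d2 = np.einsum("qfk,qfk->qf", cand - q[:, None, :], cand - q[:, None, :])
        best = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
        rows = np.arange(len(q))
        out_pts[start : start + chunk] = cand[rows, best]
        out_face[start : start + chunk] = best
        out_dist[start : start + chunk] = np.sqrt(d2[rows, best])
    return out_pts, out_face, out_dist


def closest_point_on_mesh(query, mesh: SurfaceMesh):
    """Closest point on a triangle mesh to a single query point.

    Returns (point, face_index, distance).
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (3,):
        raise InputError("query must be a single 3-vector")
    pts, faces, dists = closest_points_on_mesh(q[None, :], mesh)
    return pts[0], int(faces[0]), float(dists[0])
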