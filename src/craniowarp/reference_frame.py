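"""Standardised skull-base reference frame.

The frame is built from seven landmarks in unoperated anatomy: the lateral
and posterior points of both lateral semicircular canals, both glenoid
fossae, and the crista galli.  The horizontal is the best-fit plane of the
six vestibular/glenoid points; the six points are projected onto that
plane, the line through the two lateral canal points is brought onto the
x-axis with the midpoint at the origin, the plane is rotated flat onto
x-y, and a final rotation about z places the crista galli on the anterior
y-z plane (x = 0, y > 0).  +z is superior; the normal sign is chosen so
the crista galli (or a caller-supplied superior hint) ends with z >= 0.

Because the final z-rotation follows the x-axis alignment, the canal line
is only approximately on the x-axis afterwards; the guaranteed
postconditions are (a) the projected canal midpoint is at the origin,
(b) the best-fit plane coincides with x-y, (c) crista galli has x = 0 and
y > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, NumericalError
from .geometry import LandmarkSet, PatientDataset, RigidTransform, _as_points
from .landmarks import REFERENCE_NAMES


@dataclass(frozen=True)
class FramePlane:
    """A least-squares plane through scattered points."""

    centroid: np.ndarray
    unit_normal: np.ndarray
    rms_residual: float


@dataclass(frozen=True)
class ReferenceLandmarks:
    """The 7 reference-frame landmark positions, in table order."""

    positions: np.ndarray  # (7, 3)

    def __post_init__(self):
        pos = _as_points(self.positions)
        if pos.shape != (7, 3):
            raise InputError(f"expected 7 reference landmarks, got {pos.shape[0]}")
        if np.linalg.norm(pos[0] - pos[1]) < 1e-9:
            raise InputError("lateral canal landmarks 1 and 2 coincide")
        object.__setattr__(self, "positions", pos)

    @staticmethod
    def from_landmark_set(lms: LandmarkSet) -> "ReferenceLandmarks":
        missing = [n for n in REFERENCE_NAMES if n not in lms.names]
        if missing:
            raise InputError(f"missing reference landmark(s): {missing}")
        return ReferenceLandmarks(
            np.stack([lms.position_of(n) for n in REFERENCE_NAMES])
        )

    @property
    def crista_galli(self) -> np.ndarray:
        return self.positions[6]

    @property
    def plane_points(self) -> np.ndarray:
        """Landmarks 1-6 (vestibular + glenoid), used for the best-fit plane."""
        return self.positions[:6]


def best_fit_plane(points) -> FramePlane:
    """Total-least-squares plane through >= 3 non-collinear points.

    The normal is the smallest-singular-value direction of the centred
    points; its sign is fixed deterministically (largest-magnitude
    component positive).
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise InputError(f"need at least 3 points to fit a plane, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise NumericalError("points are collinear or coincident: plane is not defined")
    normal = vt[2]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return FramePlane(centroid=centroid, unit_normal=normal, rms_residual=rms)


def _project_to_plane(points: np.ndarray, plane: FramePlane) -> np.ndarray:
    offsets = (points - plane.centroid) @ plane.unit_normal
    return points - offsets[:, None] * plane.unit_normal


def compute_reference_transform(
    ref: ReferenceLandmarks,
    superior_hint=None,
    flip_z: bool = False,
) -> RigidTransform:
    """Rigid transform taking a patient into the standard skull-base frame.

    ``superior_hint`` may supply points (e.g. other bone landmarks) whose
    centroid defines the superior side of the horizontal plane; by default
    the crista galli is used.  ``flip_z`` forces the opposite choice.
    """
    plane = best_fit_plane(ref.plane_points)
    proj = _project_to_plane(ref.plane_points, plane)

    # canal line (landmark 1 -> right, landmark 2 -> left) maps onto +x
    u = proj[0] - proj[1]
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise NumericalError("projected canal landmarks coincide; frame undefined")
    u = u / nu

    n = plane.unit_normal
    # superior side: crista galli (or hint centroid) must end up with z >= 0
    hint = (
        np.atleast_2d(np.asarray(superior_hint, dtype=float)).mean(axis=0)
        if superior_hint is not None
        else ref.crista_galli
    )
    if (hint - plane.centroid) @ n < 0:
        n = -n
    if flip_z:
        n = -n
    # re-orthogonalise u against n (u is in-plane already; guard roundoff)
    u = u - (u @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)  # +y completes the right-handed frame

    R1 = np.stack([u, v, n])  # rows: maps u->x, v->y, n->z
    midpoint = 0.5 * (proj[0] + proj[1])
    t1 = -R1 @ midpoint

    # final rotation about z: crista galli onto the anterior y-z half-plane
    cg = R1 @ ref.crista_galli + t1
    r = np.hypot(cg[0], cg[1])
    if r < 1e-9:
        raise NumericalError("crista galli lies on the vertical axis; z-rotation undefined")
    ca, sa = cg[1] / r, cg[0] / r  # rotate by (pi/2 - atan2(y, x))
    Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(Rz @ R1, Rz @ t1)


def _transform_landmarks(lms: LandmarkSet, T: RigidTransform) -> LandmarkSet:
    return lms.with_positions(T.apply(lms.positions))


def align_dataset(
    ds: PatientDataset, flip_z: bool = False
) -> PatientDataset:
    """Align a patient dataset into the standard skull-base frame.

    Pre- and post-operative stages are aligned independently, each from its
    own reference landmarks; since the frame landmarks lie in unoperated
    anatomy the two stages land in a common frame, and the residual
    discrepancy at static (unoperated) landmarks is reported in the
    returned dataset's ``alignment`` record.
    """
    pre_ref = ReferenceLandmarks.from_landmark_set(ds.pre_landmarks)
    pre_hint = ds.pre_landmarks.subset_by_role("bone_static").positions
    T_pre = compute_reference_transform(
        pre_ref, superior_hint=pre_hint if len(pre_hint) else None, flip_z=flip_z
    )

    info: dict = {
        "pre_transform": T_pre,
        "post_transform": None,
        "static_rms_mm": None,
    }
    new = PatientDataset(
        patient_id=ds.patient_id,
        pre_skin=ds.pre_skin.with_vertices(T_pre.apply(ds.pre_skin.vertices)),
        pre_bone=ds.pre_bone.with_vertices(T_pre.apply(ds.pre_bone.vertices)),
        pre_landmarks=_transform_landmarks(ds.pre_landmarks, T_pre),
        cohort_label=ds.cohort_label,
    )
    if ds.post_landmarks is not None:
        post_ref = ReferenceLandmarks.from_landmark_set(ds.post_landmarks)
        post_hint = ds.post_landmarks.subset_by_role("bone_static").positions
        T_post = compute_reference_transform(
            post_ref, superior_hint=post_hint if len(post_hint) else None, flip_z=flip_z
        )
        new.post_landmarks = _transform_landmarks(ds.post_landmarks, T_post)
        if ds.post_skin is not None:
            new.post_skin = ds.post_skin.with_vertices(T_post.apply(ds.post_skin.vertices))
        if ds.post_bone is not None:
            new.post_bone = ds.post_bone.with_vertices(T_post.apply(ds.post_bone.vertices))
        info["post_transform"] = T_post
        pre_static = new.pre_landmarks.subset_by_role("bone_static", "reference").positions
        post_static = new.post_landmarks.subset_by_role("bone_static", "reference").positions
        info["static_rms_mm"] = float(
            np.sqrt(np.mean(np.sum((pre_static - post_static) ** 2, axis=1)))
        )
    new.alignment = info
    return new
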