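"""Synthetic head-like cohorts with a known ground-truth surgical field.

Clinical CT iso-surfaces cannot be redistributed, so every pipeline stage
is exercised on stylised but structurally faithful stand-ins: a bone
surface built as a deformed superellipsoid-like radial function with a
facial protrusion, a skin surface offset outward by a smoothly varying
soft-tissue thickness, the full packaged landmark schema (78 skin, 78
facial-bone with the 36 craniometric subset, 7 calvarial constraints, 7
skull-base reference landmarks), and an analytic "surgical" displacement
field advancing the mid-face and forehead with a Gaussian falloff that
vanishes at the skull base.

Landmark positions are exact evaluations of the analytic shape functions —
no mesh-snapping error — and every output is a deterministic function of
the seeds.  The per-patient variation emulates the syndromic phenotypes
the normalisation must remove: tall (turricephalic) and antero-posteriorly
short (brachycephalic) heads, asymmetry, and variable mid-face retrusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .geometry import LandmarkSet, PatientDataset, RigidTransform, SurfaceMesh
from . import landmarks as lmdict
from .landmarks import DEFAULT_DICTIONARY, REFERENCE_SCALE

# Head geometry -----------------------------------------------------------


@dataclass(frozen=True)
class HeadParams:
    """Shape parameters of one synthetic head.

    ``scale`` is the overall head scale in mm (canonical 75); the
    turricephaly factor stretches the vertical axis (> 1 = taller), the
    brachycephaly factor multiplies the antero-posterior axis (< 1 =
    shorter head); asymmetry amplitude is in mm at the canonical scale;
    mid-face retrusion depth (mm) flattens the facial protrusion.
    """

    scale: float = REFERENCE_SCALE
    turricephaly: float = 1.0
    brachycephaly: float = 1.0
    asymmetry_mm: float = 0.0
    retrusion_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.scale <= 0:
            raise InputError("scale must be positive")
        if not (0.5 <= self.turricephaly <= 2.0 and 0.5 <= self.brachycephaly <= 2.0):
            raise InputError("cephalic factors must lie in [0.5, 2.0]")
        if self.asymmetry_mm < 0:
            raise InputError("asymmetry amplitude must be non-negative")


def _asymmetry_coeffs(seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
    return rng.normal(size=4)


def _bone_radius(dirs: np.ndarray, p: HeadParams) -> np.ndarray:
    """Radial bone-surface function (mm) along unit directions (N, 3)."""
    u = dirs
    ax, ay, az = 0.78, 0.92 * p.brachycephaly, 1.0 * p.turricephaly
    r_ell = 1.0 / np.sqrt((u[:, 0] / ax) ** 2 + (u[:, 1] / ay) ** 2 + (u[:, 2] / az) ** 2)

    # facial protrusion: smooth bump toward the anterior-inferior face axis,
    # flattened by mid-face retrusion
    f0 = np.array([0.0, 0.94, -0.34])
    f0 /= np.linalg.norm(f0)
    c = u @ f0
    amp = max(0.22 - p.retrusion_mm / REFERENCE_SCALE, 0.0)
    bump = amp * np.exp(-(1.0 - c) / 0.10)

    # narrow nasal ridge
    n0 = np.array([0.0, 0.97, -0.24])
    n0 /= np.linalg.norm(n0)
    nose = 0.05 * np.exp(-(1.0 - u @ n0) / 0.02)

    r = r_ell * (1.0 + bump + nose)

    if p.asymmetry_mm > 0:
        c0, c1, c2, c3 = _asymmetry_coeffs(p.seed)
        s = u[:, 0] * (c0 + c1 * u[:, 1] + c2 * u[:, 2] + c3 * u[:, 0] ** 2)
        r = r + (p.asymmetry_mm / REFERENCE_SCALE) * 0.5 * s
    return p.scale * r


def _skin_thickness(dirs: np.ndarray, p: HeadParams) -> np.ndarray:
    """Soft-tissue thickness (mm): thicker over the cheeks, thinner over
    the forehead and calvarium."""
    u = dirs
    t = np.full(len(u), 5.0)
    for sx in (1.0, -1.0):
        ch = np.array([0.55 * sx, 0.72, -0.42])
        ch /= np.linalg.norm(ch)
        t = t + 5.0 * np.exp(-(1.0 - u @ ch) / 0.06)
    up = u[:, 2]
    t = t - 2.0 * np.clip(up, 0.0, 1.0)  # thin scalp
    return np.clip(t, 2.0, None) * (p.scale / REFERENCE_SCALE)


def _reference_positions(p: HeadParams) -> np.ndarray:
    """Interior skull-base reference landmarks: canonical coordinates under
    the head's anisotropic scaling (asymmetry spares the skull base, as the
    frame construction assumes)."""
    canon = np.array([lmdict._REFERENCE_CANONICAL[n] for n in lmdict.REFERENCE_NAMES])
    S = np.array([1.0, p.brachycephaly, p.turricephaly]) * (p.scale / REFERENCE_SCALE)
    return canon * S


def _unit_sphere_mesh(subdivisions: int):
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(m.vertices), np.asarray(m.faces)


def generate_head(params: HeadParams, mesh_subdivisions: int = 3):
    """Generate one head: (skin mesh, bone mesh, pre-op landmark set).

    Landmark positions come from the same analytic radial functions as the
    mesh vertices, evaluated at the dictionary's canonical directions.
    """
    verts_u, faces = _unit_sphere_mesh(mesh_subdivisions)
    bone_r = _bone_radius(verts_u, params)
    bone = SurfaceMesh(verts_u * bone_r[:, None], faces, "bone", "pre")
    skin_r = bone_r + _skin_thickness(verts_u, params)
    skin = SurfaceMesh(verts_u * skin_r[:, None], faces, "skin", "pre")

    names, roles, regions, positions = [], [], [], []
    surf_specs = [s for s in DEFAULT_DICTIONARY if s.surface != "interior"]
    dirs = np.array([s.direction for s in surf_specs])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    base_r = _bone_radius(dirs, params)
    thick = _skin_thickness(dirs, params)
    for i, s in enumerate(surf_specs):
        r = base_r[i] + (thick[i] if s.surface == "skin" else 0.0)
        names.append(s.name)
        roles.append(s.role)
        regions.append(s.region)
        positions.append(dirs[i] * r)
    ref_pos = _reference_positions(params)
    for j, n in enumerate(lmdict.REFERENCE_NAMES):
        spec = lmdict.spec_for(n)
        names.append(n)
        roles.append(spec.role)
        regions.append(spec.region)
        positions.append(ref_pos[j])

    lms = LandmarkSet(names, np.array(positions), roles, regions, stage="pre")
    return skin, bone, lms


# Surgical field ----------------------------------------------------------


@dataclass(frozen=True)
class SurgeryParams:
    """Parameters of the analytic distraction field (mm, canonical frame).

    Defaults emulate a typical monobloc advancement: 15 mm forward at the
    mid-face apex with 5 mm of vertical descent, decaying with a 32 mm
    Gaussian falloff so the skull base is essentially unmoved.  The
    bipartition flag adds para-midline divergence of the anterior maxilla
    and medialisation of the orbits.  Placement noise (sigma, mm) perturbs
    landmark placements only — surfaces are transported noise-free.
    """

    advancement: tuple = (0.0, 15.0, 0.0)
    descent_mm: float = 5.0
    falloff_mm: float = 32.0
    bipartition: bool = False
    divergence_mm: float = 4.0
    medialisation_mm: float = 3.0
    noise_sigma_mm: float = 1.0
    mandible_autorotation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.falloff_mm <= 0:
            raise InputError("falloff length-scale must be positive")
        if self.noise_sigma_mm < 0:
            raise InputError("placement noise sigma must be non-negative")


class SurgicalField:
    """Analytic ground-truth displacement field, queryable anywhere.

    Every term is multiplied by a smooth skull-base gate that is exactly
    zero on an ellipsoidal neighbourhood of the vestibular, glenoid and
    crista galli anatomy, mirroring the surgical reality that the skull
    base is untouched by the osteotomy.
    """

    #: mid-face apex, orbital centres and anterior maxilla centre in the
    #: canonical frame at the reference scale
    APEX = np.array([0.0, 82.0, -18.0])
    MAXILLA = np.array([0.0, 72.0, -32.0])
    ORBIT_R = np.array([24.0, 64.0, 10.0])
    CONDYLE = np.array([0.0, 10.0, -25.0])
    #: centre and semi-axes of the protected skull-base ellipsoid (mm)
    BASE_CENTRE = np.array([0.0, 18.0, 2.0])
    BASE_SEMI_AXES = np.array([55.0, 45.0, 30.0])

    def __init__(self, params: SurgeryParams):
        self.params = params

    def base_gate(self, x: np.ndarray) -> np.ndarray:
        """0 inside the protected skull base, smoothstep to 1 outside."""
        m = np.sqrt(np.sum(((x - self.BASE_CENTRE) / self.BASE_SEMI_AXES) ** 2, axis=1))
        t = np.clip((m - 1.0) / 0.6, 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)

    def __call__(self, points) -> np.ndarray:
        x = np.asarray(points, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        p = self.params

        adv = np.asarray(p.advancement, dtype=float) + np.array([0.0, 0.0, -p.descent_mm])
        w = np.exp(-np.sum((x - self.APEX) ** 2, axis=1) / p.falloff_mm**2)
        d = w[:, None] * adv

        if p.bipartition:
            lateral = np.tanh(x[:, 0] / 15.0)
            wm = np.exp(-np.sum((x - self.MAXILLA) ** 2, axis=1) / 25.0**2)
            d[:, 0] += p.divergence_mm * lateral * wm
            orb_l = self.ORBIT_R * np.array([-1.0, 1.0, 1.0])
            wo = np.exp(-np.sum((x - self.ORBIT_R) ** 2, axis=1) / 18.0**2) + np.exp(
                -np.sum((x - orb_l) ** 2, axis=1) / 18.0**2
            )
            d[:, 0] -= p.medialisation_mm * lateral * wo

        if p.mandible_autorotation and p.descent_mm > 0:
            # rigid rotation about the trans-condylar (x) axis, blended in
            # smoothly over the mandibular region
            angle = -0.008 * p.descent_mm  # radians per mm of descent
            ca, sa = np.cos(angle), np.sin(angle)
            rel = x - self.CONDYLE
            rot = rel.copy()
            rot[:, 1] = ca * rel[:, 1] - sa * rel[:, 2]
            rot[:, 2] = sa * rel[:, 1] + ca * rel[:, 2]
            mand = np.array([0.0, 40.0, -45.0])
            wman = np.exp(-np.sum((x - mand) ** 2, axis=1) / 35.0**2)
            d += wman[:, None] * (rot - rel)

        d *= self.base_gate(x)[:, None]
        return d[0] if single else d


def simulate_surgery(skin: SurfaceMesh, bone: SurfaceMesh, lms: LandmarkSet, params: SurgeryParams):
    """Apply the analytic field: post-op (skin, bone, landmarks) + the field.

    Surfaces are transported noise-free; Gaussian placement noise (sigma)
    perturbs the post-operative landmark positions only, emulating manual
    landmarking error.
    """
    fld = SurgicalField(params)
    post_skin = skin.with_vertices(skin.vertices + fld(skin.vertices), stage="post")
    post_bone = bone.with_vertices(bone.vertices + fld(bone.vertices), stage="post")
    pos = lms.positions + fld(lms.positions)
    if params.noise_sigma_mm > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x51]))
        pos = pos + rng.normal(scale=params.noise_sigma_mm, size=pos.shape)
    post_lms = lms.with_positions(pos, stage="post")
    return post_skin, post_bone, post_lms, fld


# Cohorts -----------------------------------------------------------------


@dataclass(frozen=True)
class CohortVariation:
    """Uniform sampling ranges for the per-patient head parameters."""

    scale: tuple = (68.0, 84.0)
    turricephaly: tuple = (0.95, 1.25)
    brachycephaly: tuple = (0.80, 1.00)
    asymmetry_mm: tuple = (0.0, 3.0)
    retrusion_mm: tuple = (4.0, 10.0)

    @staticmethod
    def none(base: HeadParams = HeadParams()) -> "CohortVariation":
        return CohortVariation(
            scale=(base.scale, base.scale),
            turricephaly=(base.turricephaly, base.turricephaly),
            brachycephaly=(base.brachycephaly, base.brachycephaly),
            asymmetry_mm=(base.asymmetry_mm, base.asymmetry_mm),
            retrusion_mm=(base.retrusion_mm, base.retrusion_mm),
        )


def _random_rigid(rng: np.random.Generator, max_angle_deg: float, max_shift_mm: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    return RigidTransform(R, t)


def random_rigid_transform(seed: int, max_angle_deg: float = 180.0, max_shift_mm: float = 50.0):
    """A seeded random proper rigid transform (test and fixture helper)."""
    return _random_rigid(np.random.default_rng(seed), max_angle_deg, max_shift_mm)


def generate_patient(
    patient_id: str,
    head_params: HeadParams,
    surgery: SurgeryParams,
    cohort_label: str = "monobloc_older",
    pose_angle_deg: float = 15.0,
    pose_shift_mm: float = 25.0,
    pose_seed: int = 0,
    mesh_subdivisions: int = 2,
) -> PatientDataset:
    """One patient dataset: head + simulated surgery + random scanner pose.

    Pre and post stages receive independent random rigid poses (as two CT
    acquisitions would), so the alignment stage is genuinely exercised.
    """
    skin, bone, lms = generate_head(head_params, mesh_subdivisions)
    post_skin, post_bone, post_lms, _ = simulate_surgery(skin, bone, lms, surgery)

    rng = np.random.default_rng(np.random.SeedSequence([pose_seed, 0x90]))
    T_pre = _random_rigid(rng, pose_angle_deg, pose_shift_mm)
    T_post = _random_rigid(rng, pose_angle_deg, pose_shift_mm)

    def move(mesh, T, stage):
        return mesh.with_vertices(T.apply(mesh.vertices), stage=stage)

    lms_pre = lms.with_positions(T_pre.apply(lms.positions))
    lms_pre.patient_id = patient_id
    lms_post = post_lms.with_positions(T_post.apply(post_lms.positions))
    lms_post.patient_id = patient_id
    return PatientDataset(
        patient_id=patient_id,
        pre_skin=move(skin, T_pre, "pre"),
        pre_bone=move(bone, T_pre, "pre"),
        pre_landmarks=lms_pre,
        post_skin=move(post_skin, T_post, "post"),
        post_bone=move(post_bone, T_post, "post"),
        post_landmarks=lms_post,
        cohort_label=cohort_label,
    )


def generate_cohort(
    n: int,
    variation: CohortVariation = CohortVariation(),
    surgery: SurgeryParams = SurgeryParams(),
    seed: int = 0,
    cohort_label: str = "monobloc_older",
    pose_angle_deg: float = 15.0,
    pose_shift_mm: float = 25.0,
    mesh_subdivisions: int = 2,
) -> list[PatientDataset]:
    """A cohort of n patients sharing one ground-truth surgical field.

    Each patient is generated from a seed derived from (seed, patient
    index), so cohorts are reproducible and order-independent per id.
    """
    if n < 2:
        raise InputError("a cohort needs at least 2 patients")
    patients = []
    for i in range(n):
        child = np.random.default_rng(np.random.SeedSequence([seed, i]))
        hp = HeadParams(
            scale=child.uniform(*variation.scale),
            turricephaly=child.uniform(*variation.turricephaly),
            brachycephaly=child.uniform(*variation.brachycephaly),
            asymmetry_mm=child.uniform(*variation.asymmetry_mm),
            retrusion_mm=child.uniform(*variation.retrusion_mm),
            seed=int(child.integers(0, 2**31 - 1)),
        )
        surg_i = replace(surgery, seed=int(child.integers(0, 2**31 - 1)))
        patients.append(
            generate_patient(
                patient_id=f"p{i:03d}",
                head_params=hp,
                surgery=surg_i,
                cohort_label=cohort_label,
                pose_angle_deg=pose_angle_deg,
                pose_shift_mm=pose_shift_mm,
                pose_seed=int(child.integers(0, 2**31 - 1)),
                mesh_subdivisions=mesh_subdivisions,
            )
        )
    return patients
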