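"""File formats.

Meshes: OBJ, PLY (ascii and binary little-endian) and STL via trimesh.
Landmarks: CSV with header ``name,x,y,z,role,region`` or an equivalent JSON
schema.  All coordinates are millimetres; files that declare any other unit
are rejected rather than converted.  Patient datasets live in one directory
per patient::

    <patient_id>/
        meta.json            {"patient_id": ..., "cohort_label": ...}
        pre_skin.ply  pre_bone.ply  pre_landmarks.csv
        post_skin.ply post_bone.ply post_landmarks.csv   (optional)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import LandmarkSet, PatientDataset, RigidTransform, SurfaceMesh

MESH_EXTENSIONS = (".obj", ".ply", ".stl")
LANDMARK_COLUMNS = ["name", "x", "y", "z", "role", "region"]


def load_mesh(path, surface_class: str = "bone", stage: str = "pre") -> SurfaceMesh:
    """Load a triangle mesh; degenerate (zero-area) faces are dropped."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise InputError(f"unsupported mesh format {path.suffix!r}; expected {MESH_EXTENSIONS}")
    if not path.exists():
        raise InputError(f"mesh file not found: {path}")
    tm = trimesh.load(str(path), process=False, force="mesh")
    units = getattr(tm, "units", None)
    if units not in (None, "mm", "millimeters", "millimetres"):
        raise InputError(f"mesh {path} declares units {units!r}; only mm is supported")
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), surface_class, stage)
    return mesh.drop_degenerate_faces()


def save_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise InputError(f"unsupported mesh format {path.suffix!r}; expected {MESH_EXTENSIONS}")
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        tm.export(str(path), encoding="ascii")
    else:
        tm.export(str(path))


def load_landmarks(path, patient_id: str = "", stage: str = "pre") -> LandmarkSet:
    """Read a landmark file (CSV with the standard header, or JSON)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        units = payload.get("units", "mm")
        if units != "mm":
            raise InputError(f"landmark file {path} declares units {units!r}; only mm is supported")
        rows = payload["landmarks"]
        return LandmarkSet(
            names=[r["name"] for r in rows],
            positions=np.array([r["position"] for r in rows], dtype=float),
            roles=[r["role"] for r in rows],
            regions=[r.get("region", "none") for r in rows],
            patient_id=payload.get("patient_id", patient_id),
            stage=payload.get("stage", stage),
        )
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"landmark CSV {path} is missing column(s) {missing}")
    return LandmarkSet(
        names=df["name"].tolist(),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        roles=df["role"].tolist(),
        regions=df["region"].fillna("none").tolist(),
        patient_id=patient_id,
        stage=stage,
    )


def save_landmarks(lms: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "patient_id": lms.patient_id,
            "stage": lms.stage,
            "units": "mm",
            "landmarks": [
                {
                    "name": n,
                    "position": [float(v) for v in p],
                    "role": r,
                    "region": g,
                }
                for n, p, r, g in zip(lms.names, lms.positions, lms.roles, lms.regions)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        lms.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def save_transform(transform: RigidTransform, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "rotation_row_major": transform.rotation.ravel().tolist(),
                "translation": transform.translation.tolist(),
            }
        )
    )


def load_transform(path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(
        np.asarray(d["rotation_row_major"], dtype=float).reshape(3, 3),
        np.asarray(d["translation"], dtype=float),
    )


def save_patient(ds: PatientDataset, directory) -> Path:
    d = Path(directory) / ds.patient_id
    d.mkdir(parents=True, exist_ok=True)
    (d / "meta.json").write_text(
        json.dumps({"patient_id": ds.patient_id, "cohort_label": ds.cohort_label})
    )
    save_mesh(ds.pre_skin, d / "pre_skin.ply")
    save_mesh(ds.pre_bone, d / "pre_bone.ply")
    save_landmarks(ds.pre_landmarks, d / "pre_landmarks.csv")
    if ds.post_landmarks is not None:
        save_landmarks(ds.post_landmarks, d / "post_landmarks.csv")
    if ds.post_skin is not None:
        save_mesh(ds.post_skin, d / "post_skin.ply")
    if ds.post_bone is not None:
        save_mesh(ds.post_bone, d / "post_bone.ply")
    return d


def load_patient(directory) -> PatientDataset:
    d = Path(directory)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise InputError(f"not a patient directory (no meta.json): {d}")
    meta = json.loads(meta_path.read_text())
    pid = meta["patient_id"]
    kwargs = {}
    if (d / "post_landmarks.csv").exists():
        kwargs["post_landmarks"] = load_landmarks(d / "post_landmarks.csv", pid, "post")
    if (d / "post_skin.ply").exists():
        kwargs["post_skin"] = load_mesh(d / "post_skin.ply", "skin", "post")
    if (d / "post_bone.ply").exists():
        kwargs["post_bone"] = load_mesh(d / "post_bone.ply", "bone", "post")
    return PatientDataset(
        patient_id=pid,
        pre_skin=load_mesh(d / "pre_skin.ply", "skin", "pre"),
        pre_bone=load_mesh(d / "pre_bone.ply", "bone", "pre"),
        pre_landmarks=load_landmarks(d / "pre_landmarks.csv", pid, "pre"),
        cohort_label=meta.get("cohort_label", "monobloc_older"),
        **kwargs,
    )


def load_cohort(directory) -> list:
    root = Path(directory)
    if not root.is_dir():
        raise InputError(f"cohort directory not found: {root}")
    patients = []
    for sub in sorted(root.iterdir()):
        if sub.is_dir() and (sub / "meta.json").exists():
            patients.append(load_patient(sub))
    if not patients:
        raise InputError(f"no patient directories found under {root}")
    return patients
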