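"""Per-patient post-operative prediction.

The composite map is sequential: forward normalisation (individual toward
cohort average), then the cohort surgical warp, then the exact reverse
normalisation restoring the individual's shape-size.  Landmarks and mesh
vertices travel through the identical composite field.  Leave-one-out
integrity is machine-enforced: predicting a patient who contributed to the
surgical model raises unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .geometry import LandmarkSet, PatientDataset, SurfaceMesh
from .cohort import NormalisationModel, SurgicalModel
from .rbf import RBFWarp

__version__ = "0.1.0"


def compose_fields(warps):
    """Sequential composition of warps: the output of warp k feeds warp k+1.

    Returns a callable mapping an (M, 3) point stack to warped positions.
    """
    warps = list(warps)
    if not warps:
        raise InputError("compose_fields requires at least one warp")

    def composite(points):
        out = np.asarray(points, dtype=float)
        for w in warps:
            out = w(out)
        return out

    return composite


@dataclass(frozen=True)
class Prediction:
    """A predicted post-operative dataset with full provenance."""

    patient_id: str
    skin: SurfaceMesh
    bone: SurfaceMesh
    landmarks: LandmarkSet
    provenance: dict


def predict(
    patient: PatientDataset,
    surgical: SurgicalModel,
    norm: NormalisationModel,
    allow_leakage: bool = False,
) -> Prediction:
    """Predict the patient's post-operative skin, bone and landmarks."""
    if not patient.is_aligned:
        raise InputError(f"patient {patient.patient_id!r} must be aligned before prediction")
    if norm.patient_id != patient.patient_id:
        raise InputError(
            f"normalisation model is for patient {norm.patient_id!r}, "
            f"not {patient.patient_id!r}"
        )
    if patient.patient_id in surgical.stats.contributing_ids and not allow_leakage:
        raise InputError(
            f"data leakage: patient {patient.patient_id!r} contributed to the "
            "surgical model; rebuild the model excluding them or pass allow_leakage=True"
        )

    composite = compose_fields([norm.forward, surgical.warp, norm.reverse])

    provenance = {
        "patient_id": patient.patient_id,
        "cohort_label": surgical.cohort_label,
        "surgical_contributing_ids": list(surgical.stats.contributing_ids),
        "basis_id": surgical.warp.basis_id,
        "smoothing_alpha": surgical.warp.smoothing_alpha,
        "normalisation_alpha": norm.forward.smoothing_alpha,
        "allow_leakage": allow_leakage,
        "package_version": __version__,
    }
    return Prediction(
        patient_id=patient.patient_id,
        skin=patient.pre_skin.with_vertices(
            composite(patient.pre_skin.vertices), stage="predicted"
        ),
        bone=patient.pre_bone.with_vertices(
            composite(patient.pre_bone.vertices), stage="predicted"
        ),
        landmarks=patient.pre_landmarks.with_positions(
            composite(patient.pre_landmarks.positions), stage="predicted"
        ),
        provenance=provenance,
    )
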