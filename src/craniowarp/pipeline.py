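"""End-to-end leave-one-out pipeline orchestration.

For every patient in a cohort directory: align all datasets into the
skull-base frame, build the surgical model and the cohort craniometric
statistics from the other n-1 patients, fit the patient's normalisation,
predict, and (when actual post-operative surfaces are present) evaluate
the prediction with a signed-distance map.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as cwio
from .cohort import build_normalisation, build_surgical_model, craniometric_cohort_stats
from .config import RunConfig
from .errors import CranioWarpError
from .evaluation import signed_distance_map
from .prediction import predict
from .reference_frame import align_dataset

log = logging.getLogger("craniowarp")

__version__ = "0.1.0"


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a per-patient report dictionary.

    Stage failures are re-raised with the stage name and patient id
    attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    config.save(out_root / "run_config.yaml")
    provenance_base = {
        "config_hash": config.content_hash(),
        "package_version": __version__,
    }

    stage = "load"
    patient_id = None
    try:
        cohort = cwio.load_cohort(config.cohort_dir)
        stage = "align"
        aligned = []
        for ds in cohort:
            patient_id = ds.patient_id
            a = align_dataset(ds, flip_z=config.flip_z)
            log.info(
                "aligned %s: %d landmarks, static pre/post RMS %.3f mm",
                ds.patient_id,
                len(a.pre_landmarks),
                a.alignment["static_rms_mm"] if a.alignment["static_rms_mm"] else 0.0,
            )
            aligned.append(a)

        excluded = set(config.exclusions)
        report = {"patients": {}, **provenance_base}
        for ds in aligned:
            patient_id = ds.patient_id
            if ds.patient_id in excluded:
                log.info("skipping excluded patient %s", ds.patient_id)
                continue
            stage = "build-model"
            model = build_surgical_model(
                aligned,
                exclude_patient_ids=(ds.patient_id, *excluded),
                basis_id=config.basis_id,
                smoothing_alpha=config.smoothing_alpha,
                variance_estimator=config.variance_estimator,
            )
            stage = "build-norm"
            names, mean, var = craniometric_cohort_stats(
                aligned,
                exclude_patient_ids=(ds.patient_id, *excluded),
                variance_estimator=config.variance_estimator,
            )
            norm = build_normalisation(
                ds,
                mean,
                var,
                craniometric_names=names,
                basis_id=config.basis_id,
                smoothing_alpha=config.smoothing_alpha,
            )
            stage = "predict"
            pred = predict(ds, model, norm)

            pdir = out_root / ds.patient_id
            pdir.mkdir(exist_ok=True)
            cwio.save_mesh(pred.skin, pdir / "predicted_skin.ply")
            cwio.save_mesh(pred.bone, pdir / "predicted_bone.ply")
            cwio.save_landmarks(pred.landmarks, pdir / "predicted_landmarks.csv")
            (pdir / "provenance.json").write_text(
                json.dumps({**provenance_base, **pred.provenance}, indent=1)
            )

            entry = {
                "n_contributing": model.stats.n_contributing,
                "static_rms_mm": ds.alignment["static_rms_mm"],
            }
            if ds.post_skin is not None:
                stage = "evaluate"
                sd = signed_distance_map(pred.skin, ds.post_skin)
                entry["skin_signed_distance"] = sd.summary
                np.savetxt(
                    pdir / "skin_signed_distance_mm.txt",
                    sd.signed_distances,
                    header="signed_distance_mm",
                    comments="",
                    fmt="%.6g",
                )
            if ds.post_landmarks is not None:
                err = np.linalg.norm(
                    pred.landmarks.positions - ds.post_landmarks.positions, axis=1
                )
                entry["landmark_rms_mm"] = float(np.sqrt(np.mean(err**2)))
            report["patients"][ds.patient_id] = entry
            log.info("predicted %s (n-1 = %d)", ds.patient_id, model.stats.n_contributing)

        (out_root / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except CranioWarpError as exc:
        raise type(exc)(
            f"stage {stage!r}" + (f", patient {patient_id!r}" if patient_id else "") + f": {exc}"
        ) from exc
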