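"""Cohort-average surgical models and per-patient shape-size normalisation.

A surgical model averages pre->post landmark change vectors over a cohort,
leaving out the patient the model will be applied to, and fits the
variance-weighted RBF to the averaged vectors at the averaged pre-operative
landmarks.  Static (calvarial / skull-base) landmarks contribute near-zero
change vectors that anchor the warp in unoperated anatomy.

The normalisation model moves an individual's 36 craniometric landmarks
toward the cohort average before surgery simulation, and its reverse warp
(an exact, unsmoothed interpolant) restores the individual's shape-size
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .geometry import LandmarkSet, PatientDataset
from .rbf import RBFWarp, WeightedSamples, fit_weighted_rbf

VARIANCE_ESTIMATORS = ("mean", "sample")


def _variance(contributions: np.ndarray, estimator: str) -> np.ndarray:
    """Scalar per-landmark variance from (K, N, 3) contributions.

    ``mean`` (default): trace of the sample covariance divided by the
    contribution count — the variance of the averaged landmark, which is
    what the warp is asked to honour.  ``sample``: the raw trace.
    """
    if estimator not in VARIANCE_ESTIMATORS:
        raise InputError(f"unknown variance estimator {estimator!r}")
    k = contributions.shape[0]
    if k < 2:
        return np.zeros(contributions.shape[1])
    trace = contributions.var(axis=0, ddof=1).sum(axis=1)
    return trace / k if estimator == "mean" else trace


def _check_correspondable(sets: list[LandmarkSet], what: str) -> list[str]:
    names = sets[0].names
    for s in sets[1:]:
        if s.names != names:
            extra = sorted(set(s.names) ^ set(names))
            raise InputError(
                f"{what}: landmark sets are not correspondable "
                f"(patient {s.patient_id!r}; differing names {extra[:10]})"
            )
    return names


@dataclass(frozen=True)
class CohortStats:
    """Per-landmark cohort averages for one surgical group."""

    landmark_names: tuple
    mean_pre_positions: np.ndarray
    mean_change_vectors: np.ndarray
    variances: np.ndarray
    contributing_ids: tuple

    @property
    def n_contributing(self) -> int:
        return len(self.contributing_ids)

    def to_dict(self) -> dict:
        return {
            "landmark_names": list(self.landmark_names),
            "mean_pre_positions": self.mean_pre_positions.tolist(),
            "mean_change_vectors": self.mean_change_vectors.tolist(),
            "variances": self.variances.tolist(),
            "contributing_ids": list(self.contributing_ids),
        }

    @staticmethod
    def from_dict(d: dict) -> "CohortStats":
        return CohortStats(
            landmark_names=tuple(d["landmark_names"]),
            mean_pre_positions=np.asarray(d["mean_pre_positions"], dtype=float),
            mean_change_vectors=np.asarray(d["mean_change_vectors"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            contributing_ids=tuple(d["contributing_ids"]),
        )


@dataclass(frozen=True)
class SurgicalModel:
    """Cohort-average surgical warp with its provenance statistics."""

    cohort_label: str
    stats: CohortStats
    warp: RBFWarp

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "stats": self.stats.to_dict(),
            "warp": self.warp.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "SurgicalModel":
        return SurgicalModel(
            cohort_label=d["cohort_label"],
            stats=CohortStats.from_dict(d["stats"]),
            warp=RBFWarp.from_dict(d["warp"]),
        )


@dataclass(frozen=True)
class NormalisationModel:
    """Forward (toward cohort average) and exact reverse craniometric warps."""

    patient_id: str
    craniometric_names: tuple
    individual_positions: np.ndarray
    forward: RBFWarp
    reverse: RBFWarp

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "craniometric_names": list(self.craniometric_names),
            "individual_positions": self.individual_positions.tolist(),
            "forward": self.forward.to_dict(),
            "reverse": self.reverse.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "NormalisationModel":
        return NormalisationModel(
            patient_id=d["patient_id"],
            craniometric_names=tuple(d["craniometric_names"]),
            individual_positions=np.asarray(d["individual_positions"], dtype=float),
            forward=RBFWarp.from_dict(d["forward"]),
            reverse=RBFWarp.from_dict(d["reverse"]),
        )


def _require_aligned(cohort: list[PatientDataset], what: str) -> None:
    for ds in cohort:
        if not ds.is_aligned:
            raise InputError(f"{what}: patient {ds.patient_id!r} is not aligned")


def build_surgical_model(
    cohort: list[PatientDataset],
    exclude_patient_ids=(),
    cohort_label: str | None = None,
    basis_id: str = "biharmonic_r",
    smoothing_alpha: float = 1.0,
    variance_estimator: str = "mean",
) -> SurgicalModel:
    """Average the cohort's change vectors (excluding the target patient)
    and fit the surgical warp."""
    if isinstance(exclude_patient_ids, str):
        exclude_patient_ids = (exclude_patient_ids,)
    excluded = set(exclude_patient_ids)
    contributing = [ds for ds in cohort if ds.patient_id not in excluded]
    if len(contributing) < 1:
        raise InputError(
            f"need at least 1 contributing dataset, got {len(contributing)} "
            f"after excluding {sorted(excluded)}"
        )
    _require_aligned(contributing, "build_surgical_model")
    for ds in contributing:
        if ds.post_landmarks is None:
            raise InputError(f"patient {ds.patient_id!r} has no post-operative landmarks")
    # deterministic, order-independent averaging
    contributing = sorted(contributing, key=lambda d: d.patient_id)
    names = _check_correspondable(
        [ds.pre_landmarks for ds in contributing]
        + [ds.post_landmarks for ds in contributing],
        "build_surgical_model",
    )
    pre = np.stack([ds.pre_landmarks.positions for ds in contributing])
    post = np.stack([ds.post_landmarks.positions for ds in contributing])
    change = post - pre

    stats = CohortStats(
        landmark_names=tuple(names),
        mean_pre_positions=pre.mean(axis=0),
        mean_change_vectors=change.mean(axis=0),
        variances=_variance(change, variance_estimator),
        contributing_ids=tuple(ds.patient_id for ds in contributing),
    )
    warp = fit_weighted_rbf(
        WeightedSamples(stats.mean_pre_positions, stats.mean_change_vectors, stats.variances),
        basis_id=basis_id,
        smoothing_alpha=smoothing_alpha,
    )
    label = cohort_label if cohort_label is not None else contributing[0].cohort_label
    return SurgicalModel(cohort_label=label, stats=stats, warp=warp)


def craniometric_cohort_stats(
    cohort: list[PatientDataset],
    exclude_patient_ids=(),
    variance_estimator: str = "mean",
):
    """Cohort mean and scalar variance of the pre-operative craniometric
    landmarks.  Returns (names, mean_positions (36, 3), variances (36,))."""
    if isinstance(exclude_patient_ids, str):
        exclude_patient_ids = (exclude_patient_ids,)
    excluded = set(exclude_patient_ids)
    contributing = sorted(
        (ds for ds in cohort if ds.patient_id not in excluded),
        key=lambda d: d.patient_id,
    )
    if len(contributing) < 2:
        raise InputError(f"need at least 2 datasets, got {len(contributing)}")
    _require_aligned(contributing, "craniometric_cohort_stats")
    sets = [ds.pre_landmarks.subset_by_role("craniometric") for ds in contributing]
    names = _check_correspondable(sets, "craniometric_cohort_stats")
    pos = np.stack([s.positions for s in sets])
    return tuple(names), pos.mean(axis=0), _variance(pos, variance_estimator)


def build_normalisation(
    patient: PatientDataset,
    craniometric_mean: np.ndarray,
    craniometric_variances: np.ndarray,
    craniometric_names=None,
    basis_id: str = "biharmonic_r",
    smoothing_alpha: float = 1.0,
) -> NormalisationModel:
    """Fit the forward normalisation warp (individual -> cohort average) and
    its exact reverse.

    The forward warp is weighted by the cohort craniometric variances; the
    reverse warp is fitted at the forward-warped positions with zero
    smoothing, so forward-then-reverse restores every craniometric landmark
    exactly.
    """
    if not patient.is_aligned:
        raise InputError(f"patient {patient.patient_id!r} is not aligned")
    cranio = patient.pre_landmarks.subset_by_role("craniometric")
    if craniometric_names is not None:
        missing = [n for n in craniometric_names if n not in cranio.names]
        if missing:
            raise InputError(
                f"patient {patient.patient_id!r} missing craniometric landmark(s): {missing}"
            )
        cranio = cranio.subset(list(craniometric_names))
    mean = np.asarray(craniometric_mean, dtype=float)
    var = np.asarray(craniometric_variances, dtype=float)
    if mean.shape != cranio.positions.shape or var.shape != (len(cranio),):
        raise InputError("cohort craniometric statistics do not match the patient's landmarks")

    forward = fit_weighted_rbf(
        WeightedSamples(cranio.positions, mean - cranio.positions, var),
        basis_id=basis_id,
        smoothing_alpha=smoothing_alpha,
    )
    fwd_pos = forward(cranio.positions)
    reverse = fit_weighted_rbf(
        WeightedSamples(fwd_pos, cranio.positions - fwd_pos, np.zeros(len(cranio))),
        basis_id=basis_id,
        smoothing_alpha=0.0,
    )
    return NormalisationModel(
        patient_id=patient.patient_id,
        craniometric_names=tuple(cranio.names),
        individual_positions=cranio.positions.copy(),
        forward=forward,
        reverse=reverse,
    )
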