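"""Cohort averaging, leave-one-out bookkeeping and normalisation warps."""

import numpy as np
import pytest

import craniowarp as cw
from craniowarp.errors import InputError
from craniowarp.rbf import warp_residuals


class TestSurgicalModel:
    def test_identical_cohort_gives_exact_vectors_and_zero_variance(self, noiseless_cohort5):
        model = cw.build_surgical_model(noiseless_cohort5, exclude_patient_ids="p000")
        ds = noiseless_cohort5[1]
        change = ds.post_landmarks.positions - ds.pre_landmarks.positions
        np.testing.assert_allclose(model.stats.mean_change_vectors, change, atol=1e-9)
        np.testing.assert_allclose(model.stats.variances, 0.0, atol=1e-12)
        assert model.stats.n_contributing == 4
        assert "p000" not in model.stats.contributing_ids

    def test_cohort_of_two_equals_the_other_patient(self, noiseless_cohort5):
        pair = noiseless_cohort5[:2]
        model = cw.build_surgical_model(pair, exclude_patient_ids="p000")
        other = pair[1]
        np.testing.assert_allclose(
            model.stats.mean_change_vectors,
            other.post_landmarks.positions - other.pre_landmarks.positions,
            atol=1e-12,
        )
        assert model.stats.contributing_ids == ("p001",)

    def test_mean_vectors_converge_to_true_field(self):
        # 20 noisy but shape-identical patients around one known field
        surgery = cw.SurgeryParams(noise_sigma_mm=1.0)
        cohort = [
            cw.align_dataset(ds)
            for ds in cw.generate_cohort(
                20, variation=cw.CohortVariation.none(), surgery=surgery, seed=5
            )
        ]
        model = cw.build_surgical_model(cohort, exclude_patient_ids="p000")
        assert model.stats.n_contributing == 19
        truth_field = cw.SurgicalField(surgery)
        truth = truth_field(model.stats.mean_pre_positions)
        err = model.stats.mean_change_vectors - truth
        # placement noise (sigma = 1 mm) also perturbs the reference
        # landmarks, and the frame alignment amplifies it at distant
        # landmarks by roughly the lever arm / canal spread (factor ~2)
        sigma_eff = 2.0
        assert np.abs(err).mean() <= 3.0 * 1.0 / np.sqrt(19)
        assert np.sqrt(np.mean(err**2)) <= 3.0 * sigma_eff / np.sqrt(19)

    def test_model_invariant_to_cohort_order(self, noiseless_cohort5):
        fwd = cw.build_surgical_model(noiseless_cohort5, exclude_patient_ids="p002")
        rev = cw.build_surgical_model(noiseless_cohort5[::-1], exclude_patient_ids="p002")
        np.testing.assert_array_equal(
            fwd.stats.mean_change_vectors, rev.stats.mean_change_vectors
        )
        assert fwd.stats.contributing_ids == rev.stats.contributing_ids

    def test_zero_variance_model_interpolates_mean_vectors(self, noiseless_cohort5):
        model = cw.build_surgical_model(noiseless_cohort5, exclude_patient_ids="p000")
        from craniowarp.rbf import WeightedSamples

        res = warp_residuals(
            model.warp,
            WeightedSamples(
                model.stats.mean_pre_positions,
                model.stats.mean_change_vectors,
                model.stats.variances,
            ),
        )
        assert np.linalg.norm(res, axis=1).max() <= 1e-8

    def test_static_centres_included(self, noiseless_cohort5):
        model = cw.build_surgical_model(noiseless_cohort5, exclude_patient_ids="p000")
        roles = dict(zip(noiseless_cohort5[0].pre_landmarks.names, noiseless_cohort5[0].pre_landmarks.roles))
        assert any(roles[n] == "bone_static" for n in model.stats.landmark_names)
        assert any(roles[n] == "reference" for n in model.stats.landmark_names)

    def test_no_contributors_rejected(self, noiseless_cohort5):
        with pytest.raises(InputError, match="at least 1"):
            cw.build_surgical_model(
                noiseless_cohort5[:2], exclude_patient_ids=("p000", "p001")
            )

    def test_name_mismatch_rejected(self, noiseless_cohort5):
        broken = noiseless_cohort5[1]
        renamed = cw.LandmarkSet(
            ["odd_name"] + broken.pre_landmarks.names[1:],
            broken.pre_landmarks.positions,
            broken.pre_landmarks.roles,
            broken.pre_landmarks.regions,
            broken.patient_id,
            "pre",
        )
        bad = cw.PatientDataset(
            "bad",
            broken.pre_skin,
            broken.pre_bone,
            renamed,
            post_landmarks=renamed.with_positions(renamed.positions, stage="post"),
            alignment={},
        )
        with pytest.raises(InputError, match="odd_name"):
            cw.build_surgical_model([noiseless_cohort5[0], bad])


class TestCraniometricStats:
    def test_identical_patients_have_zero_variance(self, noiseless_cohort5):
        names, mean, var = cw.craniometric_cohort_stats(noiseless_cohort5)
        assert len(names) == 36
        np.testing.assert_allclose(var, 0.0, atol=1e-12)

    def test_two_patient_offset_variance_matches_hand_computation(self, noiseless_cohort5):
        # offset one landmark by +/- d along x: sample var (ddof=1) of {+d,-d}
        # is 2 d^2; the variance-of-the-mean estimator divides by K=2 -> d^2
        d = 1.5
        a, b = noiseless_cohort5[0], noiseless_cohort5[1]
        pa = a.pre_landmarks.positions.copy()
        pb = b.pre_landmarks.positions.copy()
        idx = a.pre_landmarks.roles.index("craniometric")
        pa[idx, 0] += d
        pb[idx, 0] -= d
        mod = [
            cw.PatientDataset(
                ds.patient_id, ds.pre_skin, ds.pre_bone,
                ds.pre_landmarks.with_positions(p), alignment={},
            )
            for ds, p in ((a, pa), (b, pb))
        ]
        names, mean, var = cw.craniometric_cohort_stats(mod)
        k = names.index(a.pre_landmarks.names[idx])
        assert var[k] == pytest.approx(d**2, rel=1e-12)
        np.testing.assert_allclose(
            mean[k], 0.5 * (pa[idx] + pb[idx]), atol=1e-12
        )
        _, _, var_sample = cw.craniometric_cohort_stats(mod, variance_estimator="sample")
        assert var_sample[k] == pytest.approx(2 * d**2, rel=1e-12)

    def test_gaussian_cohort_variance_estimate(self, noiseless_cohort5):
        rng = np.random.default_rng(33)
        sigma = 2.0
        base = noiseless_cohort5[0]
        cohort = []
        for i in range(40):
            jitter = rng.normal(scale=sigma, size=base.pre_landmarks.positions.shape)
            cohort.append(
                cw.PatientDataset(
                    f"g{i:02d}", base.pre_skin, base.pre_bone,
                    base.pre_landmarks.with_positions(base.pre_landmarks.positions + jitter),
                    alignment={},
                )
            )
        _, _, var = cw.craniometric_cohort_stats(cohort, variance_estimator="sample")
        # E[trace of covariance] = 3 sigma^2; Monte-Carlo tolerance at n=40
        assert var.mean() == pytest.approx(3 * sigma**2, rel=0.15)


class TestNormalisation:
    def test_patient_at_cohort_mean_gives_zero_warps(self, noiseless_cohort5):
        ds = noiseless_cohort5[0]
        names, mean, var = cw.craniometric_cohort_stats(
            noiseless_cohort5, exclude_patient_ids=ds.patient_id
        )
        norm = cw.build_normalisation(ds, mean, var, craniometric_names=names)
        pts = np.random.default_rng(1).normal(scale=60.0, size=(20, 3))
        np.testing.assert_allclose(norm.forward.displacement(pts), 0.0, atol=1e-8)
        np.testing.assert_allclose(norm.reverse.displacement(pts), 0.0, atol=1e-8)

    def test_scaled_patient_lands_on_cohort_mean(self, noiseless_cohort5):
        ds = noiseless_cohort5[0]
        names, mean, _ = cw.craniometric_cohort_stats(
            noiseless_cohort5, exclude_patient_ids=ds.patient_id
        )
        scaled = cw.PatientDataset(
            ds.patient_id,
            ds.pre_skin,
            ds.pre_bone,
            ds.pre_landmarks.with_positions(ds.pre_landmarks.positions * 1.2),
            alignment={},
        )
        norm = cw.build_normalisation(
            scaled, mean, np.zeros(len(names)), craniometric_names=names
        )
        cranio = scaled.pre_landmarks.subset_by_role("craniometric")
        np.testing.assert_allclose(norm.forward(cranio.positions), mean, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forward_then_reverse_restores_craniometric_landmarks(self, seed, varied_cohort10):
        ds = varied_cohort10[seed]
        names, mean, var = cw.craniometric_cohort_stats(
            varied_cohort10, exclude_patient_ids=ds.patient_id
        )
        norm = cw.build_normalisation(ds, mean, var, craniometric_names=names)
        cranio = ds.pre_landmarks.subset_by_role("craniometric")
        round_trip = norm.reverse(norm.forward(cranio.positions))
        err = np.linalg.norm(round_trip - cranio.positions, axis=1)
        assert err.max() <= 1e-6

    def test_missing_craniometric_landmark_named(self, noiseless_cohort5):
        ds = noiseless_cohort5[0]
        names, mean, var = cw.craniometric_cohort_stats(
            noiseless_cohort5, exclude_patient_ids=ds.patient_id
        )
        keep = [n for n in ds.pre_landmarks.names if n != "nasion_bone"]
        reduced = cw.PatientDataset(
            ds.patient_id,
            ds.pre_skin,
            ds.pre_bone,
            ds.pre_landmarks.subset(keep),
            alignment={},
        )
        with pytest.raises(InputError, match="nasion_bone"):
            cw.build_normalisation(reduced, mean, var, craniometric_names=names)
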