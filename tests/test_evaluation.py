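"""Signed-distance maps, region summaries, reliability and colour export."""

import numpy as np
import pytest
import trimesh

import craniowarp as cw
from craniowarp.errors import InputError
from craniowarp.evaluation import RELIABILITY_BANDS, band_for_sd, colour_for_values


def sphere_mesh(radius, subdivisions=3, stage="post", cls="skin"):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return cw.SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces), cls, stage)


class TestSignedDistance:
    def test_mesh_against_itself_is_zero(self, default_head):
        skin, _, _ = default_head
        sd = cw.signed_distance_map(skin, skin)
        assert np.abs(sd.signed_distances).max() <= 1e-9
        assert sd.signed

    def test_concentric_spheres_give_radius_difference(self):
        pred = sphere_mesh(50.0, subdivisions=4, stage="predicted")
        actual = sphere_mesh(48.0, subdivisions=4)
        assert actual.n_faces >= 5000
        sd = cw.signed_distance_map(pred, actual)
        assert np.abs(sd.signed_distances - 2.0).max() <= 0.05
        assert sd.summary["mean"] == pytest.approx(2.0, abs=0.05)

    def test_inward_offset_is_negative(self):
        actual = sphere_mesh(50.0, subdivisions=3)
        pred = cw.SurfaceMesh(
            actual.vertices * (49.0 / 50.0), actual.faces, "skin", "predicted"
        )
        sd = cw.signed_distance_map(pred, actual)
        assert np.all(sd.signed_distances < 0)
        assert sd.summary["mean"] == pytest.approx(-1.0, abs=0.05)

    def test_swapping_meshes_flips_sign(self):
        a = sphere_mesh(50.0)
        b = sphere_mesh(48.0)
        ab = cw.signed_distance_map(a, b)
        ba = cw.signed_distance_map(b, a)
        assert ab.summary["mean"] == pytest.approx(2.0, abs=0.05)
        assert ba.summary["mean"] == pytest.approx(-2.0, abs=0.05)

    def test_magnitude_equals_unsigned_closest_point(self, default_head):
        skin, bone, _ = default_head
        small = cw.SurfaceMesh(bone.vertices, bone.faces, "bone", "post")
        sd = cw.signed_distance_map(skin, small)
        from craniowarp.geometry import closest_points_on_mesh

        _, _, dist = closest_points_on_mesh(skin.vertices, small)
        np.testing.assert_allclose(np.abs(sd.signed_distances), dist, atol=1e-12)

    def test_inconsistent_winding_falls_back_to_unsigned(self):
        actual = sphere_mesh(20.0, subdivisions=1)
        faces = actual.faces.copy()
        faces[0] = faces[0][::-1]
        flipped = cw.SurfaceMesh(actual.vertices, faces, "skin", "post")
        pred = sphere_mesh(22.0, subdivisions=1, stage="predicted")
        with pytest.warns(UserWarning, match="unsigned"):
            sd = cw.signed_distance_map(pred, flipped)
        assert not sd.signed
        assert np.all(sd.signed_distances >= 0)


class TestRegionSummary:
    def test_uniform_map_gives_uniform_region_means(self):
        mesh = sphere_mesh(10.0, subdivisions=1, stage="predicted")
        sd = cw.signed_distance_map(mesh, mesh)
        sd.signed_distances[:] = 2.0
        labels = ["maxillary"] * (mesh.n_vertices // 2) + ["forehead"] * (
            mesh.n_vertices - mesh.n_vertices // 2
        )
        out = cw.region_summary(sd, labels)
        assert out["maxillary"]["mean"] == pytest.approx(2.0)
        assert out["forehead"]["mean"] == pytest.approx(2.0)

    def test_region_means_match_groupby_oracle(self):
        import pandas as pd

        mesh = sphere_mesh(10.0, subdivisions=2, stage="predicted")
        sd = cw.signed_distance_map(mesh, mesh)
        rng = np.random.default_rng(5)
        sd.signed_distances[:] = rng.normal(size=mesh.n_vertices)
        regions = list(rng.choice(["maxillary", "nasal", "none"], size=mesh.n_vertices))
        out = cw.region_summary(sd, regions)
        oracle = pd.Series(sd.signed_distances).groupby(pd.Series(regions)).mean()
        for region, stats in out.items():
            assert stats["mean"] == pytest.approx(oracle[region], rel=1e-12)

    def test_unknown_region_rejected(self):
        mesh = sphere_mesh(10.0, subdivisions=1, stage="predicted")
        sd = cw.signed_distance_map(mesh, mesh)
        with pytest.raises(InputError, match="nowhere"):
            cw.region_summary(sd, ["nowhere"] * mesh.n_vertices)


class TestReliability:
    def make_repeats(self, offsets):
        base = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        sets = []
        for off in offsets:
            sets.append(
                cw.LandmarkSet(
                    ["a", "b"], base + np.asarray(off), ["skin", "skin"], stage="pre"
                )
            )
        return sets

    def test_identical_repeats_give_zero_sd_high_band(self):
        rep = cw.landmark_reliability(self.make_repeats([(0, 0, 0)] * 3))
        np.testing.assert_array_equal(rep.sd, 0.0)
        assert rep.bands == ("high", "high")

    def test_two_repeats_half_mm_apart(self):
        rep = cw.landmark_reliability(
            self.make_repeats([(0.5, 0, 0), (-0.5, 0, 0)])
        )
        np.testing.assert_allclose(rep.sd, 0.5)
        assert rep.bands == ("high", "high")

    def test_band_edges_are_half_open(self):
        assert band_for_sd(0.999999) == "high"
        assert band_for_sd(1.0) == "accurate"
        assert band_for_sd(2.0) == "less_accurate"
        assert band_for_sd(2.999) == "less_accurate"
        assert band_for_sd(3.0) == "out_of_band"

    def test_isotropic_jitter_sd_matches_estimator(self):
        # 10 repeats, sigma = 1 per axis: E[SD^2] = 3 sigma^2 (K-1)/K
        rng = np.random.default_rng(8)
        base = rng.normal(scale=30.0, size=(50, 3))
        sets = [
            cw.LandmarkSet(
                [f"m{i}" for i in range(50)],
                base + rng.normal(scale=1.0, size=base.shape),
                ["skin"] * 50,
            )
            for _ in range(10)
        ]
        rep = cw.landmark_reliability(sets)
        expected = np.sqrt(3.0 * (9 / 10))
        assert rep.sd.mean() == pytest.approx(expected, rel=0.05)
        assert rep.n_repeats == 10

    def test_sd_invariant_under_joint_rigid_motion(self):
        from craniowarp.synthetic import random_rigid_transform

        rng = np.random.default_rng(9)
        base = rng.normal(scale=20.0, size=(10, 3))
        sets = [
            cw.LandmarkSet(
                [f"m{i}" for i in range(10)],
                base + rng.normal(scale=0.8, size=base.shape),
                ["skin"] * 10,
            )
            for _ in range(5)
        ]
        rep = cw.landmark_reliability(sets)
        T = random_rigid_transform(4)
        moved = [s.with_positions(T.apply(s.positions)) for s in sets]
        rep2 = cw.landmark_reliability(moved)
        np.testing.assert_allclose(rep2.sd, rep.sd, atol=1e-9)

    def test_single_repeat_rejected(self):
        with pytest.raises(InputError, match="at least 2"):
            cw.landmark_reliability(self.make_repeats([(0, 0, 0)]))


class TestColourMap:
    def test_zero_map_is_uniformly_green(self):
        colours = colour_for_values(np.zeros(10), -3.0, 3.0)
        assert np.all(colours[:, 1] > colours[:, 0])
        assert np.all(colours[:, 1] > colours[:, 2])
        assert len(np.unique(colours, axis=0)) == 1

    def test_limit_value_gets_extreme_colour(self):
        colours = colour_for_values(np.array([-3.0, 0.0, 3.0, 10.0]), -3.0, 3.0)
        np.testing.assert_array_equal(colours[2], colours[3])  # clipped
        assert colours[2][0] > 200  # hot red at +limit

    def test_monotone_values_monotone_channels(self):
        values = np.linspace(-3, 3, 20)
        colours = colour_for_values(values, -3.0, 3.0).astype(int)
        red = colours[:, 0]
        blue = colours[:, 2]
        assert all(a <= b for a, b in zip(red, red[1:]))
        assert all(a >= b for a, b in zip(blue, blue[1:]))

    def test_export_writes_ply_and_sidecar(self, tmp_path):
        mesh = sphere_mesh(10.0, subdivisions=1, stage="predicted")
        sd = cw.signed_distance_map(mesh, mesh)
        ply = tmp_path / "map.ply"
        side = tmp_path / "map.txt"
        tm, colours = cw.export_colour_map(sd, mesh, -2.0, 2.0, ply_path=ply, scalar_path=side)
        assert ply.exists() and side.exists()
        reloaded = trimesh.load(str(ply), process=False)
        assert np.asarray(reloaded.visual.vertex_colors).shape[0] == mesh.n_vertices
        scalars = np.loadtxt(side, skiprows=1)
        np.testing.assert_allclose(scalars, sd.signed_distances, atol=1e-9)

    def test_bad_limits_rejected(self):
        with pytest.raises(InputError, match="limits"):
            colour_for_values(np.zeros(3), 2.0, -2.0)
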