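"""Centerline extraction, wall-thickness regression and beam meshing."""

import numpy as np
import pytest

from veinfem import veins
from veinfem.image import LabelImage

from conftest import make_cylinder_mask


class TestCenterlines:
    @pytest.mark.parametrize("radius", [0.33, 1.0, 2.0, 3.0, 4.0])
    def test_cylinder_length_and_radius_recovery(self, radius):
        """Analytic tube: length within 5%, mean radius within half a voxel."""
        img = make_cylinder_mask(radius, 20.0)
        tree = veins.extract_centerlines(img, min_diameter=0.33, min_node_distance=1.0)
        assert len(tree.paths) == 1
        assert abs(tree.total_length() - 20.0) <= 0.05 * 20.0
        assert abs(tree.node_radii.mean() - radius) <= 0.165

    def test_tilted_cylinder_recovery(self):
        tilt = 0.3
        img = make_cylinder_mask(1.0, 20.0, tilt=tilt)
        true_len = 20.0 * np.sqrt(1 + tilt**2)
        tree = veins.extract_centerlines(img, 0.33, 1.0)
        assert abs(tree.total_length() - true_len) <= 0.05 * true_len

    def test_thin_arm_pruned_from_junction(self):
        """A Y-arm below the 0.33 mm minimum diameter is dropped."""
        vs = 0.33
        n = 40
        ax = [np.arange(n) * vs for _ in range(3)]
        x, y, z = np.meshgrid(*ax, indexing="ij")
        c = (n // 2) * vs
        trunk = (((x - c) ** 2 + (y - c) ** 2) <= 1.0**2) & (z >= 2 * vs) & (z <= 10.0)
        # thin side arm, diameter 0.2 mm (radius 0.1 < voxel/2 rasterises to
        # a 1-voxel-wide line): attach at the trunk midpoint along +x
        arm = np.zeros_like(trunk)
        j = n // 2
        k = int(5.0 / vs)
        arm[n // 2: n // 2 + 12, j, k] = True
        img = LabelImage((trunk | arm).astype(np.int32), np.diag([vs, vs, vs, 1.0]),
                         {1: "vein"})
        tree = veins.extract_centerlines(img, min_diameter=0.33, min_node_distance=1.0)
        # recovered geometry stays within the trunk: no node reaches the arm tip
        assert tree.node_positions[:, 0].max() < (n // 2 + 8) * vs

    def test_min_node_spacing_contract(self):
        img = make_cylinder_mask(1.0, 25.0)
        tree = veins.extract_centerlines(img, 0.33, min_node_distance=1.0)
        e = tree.edges
        gaps = np.linalg.norm(
            tree.node_positions[e[:, 1]] - tree.node_positions[e[:, 0]], axis=1
        )
        assert gaps.min() >= 1.0

    def test_empty_mask_warns_and_returns_empty_tree(self):
        img = LabelImage(np.zeros((5, 5, 5), dtype=np.int32), np.eye(4), {1: "vein"})
        with pytest.warns(UserWarning, match="empty"):
            tree = veins.extract_centerlines(img)
        assert tree.n_nodes == 0 and tree.paths == []


class TestWallThickness:
    def test_printed_regression_value(self):
        assert veins.wall_thickness(1.0) == pytest.approx(0.1143)

    def test_intercept_limit(self):
        # h(d) -> 0.0411 as d -> 0 (the annulus guard fires well before)
        assert veins.WALL_THICKNESS_INTERCEPT == 0.0411

    def test_monotone_in_diameter(self):
        d = np.linspace(0.2, 6.0, 50)
        h = np.array([veins.wall_thickness(x) for x in d])
        assert np.all(np.diff(h) > 0)

    def test_nonpositive_and_degenerate_diameters_rejected(self):
        with pytest.raises(ValueError):
            veins.wall_thickness(0.0)
        with pytest.raises(ValueError, match="annulus"):
            veins.wall_thickness(0.05)  # 2h >= d below ~0.096 mm


class TestThicknessRegression:
    def test_exact_points_recover_printed_coefficients(self):
        d = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0])
        h = 0.0732 * d + 0.0411
        slope, intercept, r2, p = veins.fit_thickness_regression(np.c_[d, h])
        assert slope == pytest.approx(0.0732, abs=1e-12)
        assert intercept == pytest.approx(0.0411, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-6

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            veins.fit_thickness_regression(np.array([[1.0, 0.1], [2.0, 0.2]]))
        with pytest.raises(ValueError, match="degenerate"):
            veins.fit_thickness_regression(np.array([[1.0, 0.1]] * 5))

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        d = rng.uniform(0.5, 5.0, 20)
        h = 0.07 * d + 0.04 + rng.normal(0, 0.01, 20)
        slope, intercept, _, _ = veins.fit_thickness_regression(np.c_[d, h])
        # independent normal-equations solve
        a_mat = np.c_[d, np.ones_like(d)]
        beta = np.linalg.solve(a_mat.T @ a_mat, a_mat.T @ h)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)

    def test_round_trip_through_wall_thickness(self):
        """Points generated by the packaged formula refit to it exactly."""
        d = np.linspace(0.2, 5.0, 9)
        pairs = np.c_[d, [veins.wall_thickness(x) for x in d]]
        slope, intercept, r2, _ = veins.fit_thickness_regression(pairs)
        assert (slope, intercept) == pytest.approx(
            (veins.WALL_THICKNESS_SLOPE, veins.WALL_THICKNESS_INTERCEPT), abs=1e-12
        )
        assert r2 == pytest.approx(1.0)


class TestElasticModulus:
    def test_linear_curve_gives_packaged_constant(self):
        eps = np.linspace(0, 0.3, 50)
        curve = veins.StressStrainCurve(eps, veins.VEIN_ELASTIC_MODULUS_MPA * eps)
        assert veins.elastic_modulus_from_curve(curve, (0.05, 0.25)) == pytest.approx(3.63)

    def test_toe_region_excluded_by_caller_region(self):
        eps = np.linspace(0, 0.4, 81)
        stress = np.where(eps < 0.2, 0.1 * eps, 0.1 * 0.2 + 4.0 * (eps - 0.2))
        curve = veins.StressStrainCurve(eps, stress)
        assert veins.elastic_modulus_from_curve(curve, (0.25, 0.4)) == pytest.approx(4.0)

    def test_automatic_linear_window_skips_toe(self):
        eps = np.linspace(0, 0.4, 81)
        stress = np.where(eps < 0.2, 0.1 * eps, 0.1 * 0.2 + 4.0 * (eps - 0.2))
        curve = veins.StressStrainCurve(eps, stress)
        assert veins.elastic_modulus_from_curve(curve) == pytest.approx(4.0, rel=1e-6)

    def test_secant_matches_two_point_arithmetic(self, rng):
        eps = np.linspace(0, 0.3, 61)
        stress = 3.0 * eps + rng.normal(0, 0.01, eps.size)
        curve = veins.StressStrainCurve(eps, stress)
        a, b = 0.1, 0.25
        sa = np.interp(a, eps, stress)
        sb = np.interp(b, eps, stress)
        assert veins.elastic_modulus_from_curve(curve, (a, b)) == pytest.approx(
            (sb - sa) / (b - a)
        )

    def test_zero_width_region_rejected(self):
        curve = veins.StressStrainCurve([0, 0.1, 0.2], [0, 0.1, 0.2])
        with pytest.raises(ValueError):
            veins.elastic_modulus_from_curve(curve, (0.1, 0.1))


class TestBeamMesh:
    def test_single_segment(self):
        tree = veins.VesselTree(np.array([[0, 0, 0], [0, 0, 2.0]]),
                                np.array([0.5, 0.5]), [[0, 1]])
        beam = veins.build_beam_mesh(tree)
        assert beam.elements.shape == (1, 2)
        assert len(beam.sections) == 1
        assert beam.couple_to_solid

    def test_element_count_rule(self):
        """Paths of 5 and 3 nodes sharing a junction give 4 + 2 beams."""
        pos = np.zeros((7, 3))
        pos[:, 2] = [0, 1, 2, 3, 4, 5, 6]
        tree = veins.VesselTree(pos, np.full(7, 0.6), [[0, 1, 2, 3, 4], [4, 5, 6]])
        beam = veins.build_beam_mesh(tree)
        assert beam.elements.shape[0] == 6

    def test_tube_phantom_sections(self):
        img = make_cylinder_mask(1.0, 20.0)
        tree = veins.extract_centerlines(img, 0.33, 1.0)
        beam = veins.build_beam_mesh(tree)
        for sec in beam.sections:
            assert sec.outer_diameter_mm == pytest.approx(2.0, abs=0.35)
            assert sec.wall_thickness_mm == pytest.approx(
                veins.wall_thickness(sec.outer_diameter_mm)
            )
            assert sec.e_mpa == veins.VEIN_ELASTIC_MODULUS_MPA

    def test_beam_length_matches_tree_length(self):
        img = make_cylinder_mask(1.5, 24.0)
        tree = veins.extract_centerlines(img, 0.33, 1.0)
        beam = veins.build_beam_mesh(tree)
        seg = tree.node_positions[beam.elements[:, 1]] - tree.node_positions[beam.elements[:, 0]]
        assert np.linalg.norm(seg, axis=1).sum() == pytest.approx(tree.total_length())

    def test_annulus_violation_propagates(self):
        tree = veins.VesselTree(np.array([[0, 0, 0], [0, 0, 2.0]]),
                                np.array([0.04, 0.04]), [[0, 1]])
        with pytest.raises(ValueError, match="annulus"):
            veins.build_beam_mesh(tree)
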