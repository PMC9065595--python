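"""Phantom generators: determinism, ground truth and consumer contracts."""

import numpy as np
import pytest

from veinfem import phantoms, strain, veins
from veinfem.image import adjacent_pairs_6, role_ids


class TestHeadPhantom:
    def test_csf_layer_guarantee(self):
        for seed in (0, 3, 11):
            img = phantoms.head_phantom(phantoms.HeadPhantomSpec(seed=seed))
            roles = role_ids(img.label_table)
            assert adjacent_pairs_6(img.voxels, roles["brain"], roles["skull"]) == 0

    def test_unnested_shells_rejected(self):
        spec = phantoms.HeadPhantomSpec(csf_semi=(68.0, 53.0, 59.0))  # equals grey
        with pytest.raises(ValueError, match="nested"):
            phantoms.head_phantom(spec)

    def test_determinism(self):
        a = phantoms.head_phantom(phantoms.HeadPhantomSpec(seed=5))
        b = phantoms.head_phantom(phantoms.HeadPhantomSpec(seed=5))
        assert np.array_equal(a.voxels, b.voxels)

    def test_shell_volumes_match_analytic_ellipsoids(self):
        """Cumulative voxel volumes track 4/3 pi abc within voxelisation error."""
        spec = phantoms.HeadPhantomSpec(seed=0, jitter=0.0)
        img = phantoms.head_phantom(spec)
        counts = img.counts()
        vox_vol = spec.voxel_size_mm**3

        def ellipsoid(semi):
            a, b, c = semi
            return 4.0 / 3.0 * np.pi * a * b * c

        # shells strictly outside the carve planes are pure voxelisations
        cumulative = {
            "scalp": sum(counts.values()),
            "skull": sum(v for k, v in counts.items() if k >= 2),
            "csf": sum(v for k, v in counts.items() if k >= 3),
        }
        for name, nvox in cumulative.items():
            expect = ellipsoid(getattr(spec, f"{name}_semi"))
            assert abs(nvox * vox_vol - expect) / expect < 0.05
        # the brain volume equals the grey ellipsoid minus the two 1-voxel
        # carve planes (analytic ellipse cross-sections)
        a, b, c = spec.grey_semi
        brain = sum(v for k, v in counts.items() if k >= 4) * vox_vol
        vs = spec.voxel_size_mm
        tent_frac = 0.45
        area_tent = np.pi * a * b * (1 - tent_frac**2)
        t = tent_frac
        area_sag_above = b * c * (np.arccos(-t) - (-t) * np.sqrt(1 - t * t))
        expect = ellipsoid(spec.grey_semi) - vs * (area_tent + area_sag_above)
        assert abs(brain - expect) / expect < 0.05


class TestVesselPhantom:
    def test_determinism(self):
        t1, m1 = phantoms.vessel_phantom(phantoms.VesselPhantomSpec(seed=3))
        t2, m2 = phantoms.vessel_phantom(phantoms.VesselPhantomSpec(seed=3))
        assert np.array_equal(m1.voxels, m2.voxels)
        assert t1.total_length_mm == t2.total_length_mm

    def test_subvoxel_radius_rejected(self):
        with pytest.raises(ValueError, match="half a voxel"):
            phantoms.vessel_phantom(phantoms.VesselPhantomSpec(radius_mm=(0.1, 0.2)))

    def test_centerline_recovery_against_ground_truth(self):
        truth, mask = phantoms.vessel_phantom(phantoms.VesselPhantomSpec(seed=1))
        tree = veins.extract_centerlines(mask, 0.33, 1.0)
        rec = tree.total_length()
        assert abs(rec - truth.total_length_mm) <= 0.05 * truth.total_length_mm
        # every recovered node sits inside some true tube (radius + 1 voxel)
        from scipy.spatial import cKDTree

        best = np.full(tree.n_nodes, np.inf)
        bestr = np.zeros(tree.n_nodes)
        for poly, r in zip(truth.polylines, truth.radii):
            d, _ = cKDTree(poly).query(tree.node_positions)
            upd = d < best
            best[upd] = d[upd]
            bestr[upd] = r
        assert np.all(best <= bestr + 0.34)
        assert np.abs(tree.node_radii - bestr).mean() <= 0.165


class TestMotionGenerator:
    def _beam(self, rng):
        nodes = rng.uniform(5, 20, (20, 3))
        elems = np.array([[i, i + 1] for i in range(19)])
        return nodes, elems

    @pytest.mark.parametrize("peak,duration", [(20.0, 30.0), (40.0, 60.0)])
    def test_rigid_pulse_reaches_peak_velocity(self, rng, peak, duration):
        """Quadrature of the generated pulse hits the preset within 1%."""
        nodes, elems = self._beam(rng)
        spec = phantoms.MotionSpec(mode="rigid", peak_velocity_rad_s=peak,
                                   duration_ms=duration)
        traj, _ = phantoms.motion_generator(spec, nodes, elems)
        center = nodes.mean(axis=0)
        v0 = nodes[0] - center
        ang = []
        for i in range(traj.times_ms.size):
            vi = traj.positions[i, 0] - center
            cos = np.clip(
                (v0[:2] @ vi[:2]) / (np.linalg.norm(v0[:2]) * np.linalg.norm(vi[:2])),
                -1, 1,
            )
            ang.append(np.arccos(cos))
        omega = np.gradient(np.unwrap(np.asarray(ang)), traj.dt_ms * 1e-3)
        assert omega.max() == pytest.approx(peak, rel=0.01)

    def test_rigid_motion_has_zero_strain_truth_and_measurement(self, rng):
        nodes, elems = self._beam(rng)
        traj, truth = phantoms.motion_generator(phantoms.MotionSpec(mode="rigid"), nodes, elems)
        assert np.all(truth == 0)
        hist = strain.axial_strain_history(traj)
        assert np.abs(hist.strain).max() < 1e-9

    def test_affine_stretch_closed_form(self):
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        elems = np.array([[0, 1], [0, 2]])
        spec = phantoms.MotionSpec(mode="affine", affine_matrix=np.diag([1.1, 1.0, 1.0]))
        traj, truth = phantoms.motion_generator(spec, nodes, elems)
        assert truth[-1, 0] == pytest.approx(0.1)
        assert truth[-1, 1] == pytest.approx(0.0)
        hist = strain.axial_strain_history(traj)
        assert np.allclose(hist.strain, truth, atol=1e-12)

    def test_smooth_field_strain_matches_endpoint_oracle(self, rng):
        nodes, elems = self._beam(rng)
        spec = phantoms.MotionSpec(mode="smooth-field", seed=4, n_bumps=2)
        traj, truth = phantoms.motion_generator(spec, nodes, elems)
        assert truth is None
        hist = strain.axial_strain_history(traj)
        # independent endpoint-distance computation
        p = traj.positions
        for t in (0, 10, -1):
            for e, (i, j) in enumerate(elems):
                l0 = np.linalg.norm(p[0, j] - p[0, i])
                lt = np.linalg.norm(p[t, j] - p[t, i])
                assert hist.strain[t, e] == pytest.approx(lt / l0 - 1, abs=1e-12)

    def test_unknown_mode_rejected(self, rng):
        nodes, elems = self._beam(rng)
        with pytest.raises(ValueError, match="mode"):
            phantoms.motion_generator(phantoms.MotionSpec(mode="wiggle"), nodes, elems)


class TestMicrobleeds:
    def _map_and_atlas(self, rng):
        data = np.zeros((12, 12, 12))
        data[2:10, 2:10, 2:10] = rng.uniform(0.01, 0.05, (8, 8, 8))
        data[3, 4, 5] = 0.9  # unique global peak in tract 1
        vmap = strain.VoxelMap(data, np.eye(4))
        atlas = phantoms.tract_atlas_phantom((12, 12, 12), np.eye(4), blocks=(2, 1, 1))
        return vmap, atlas

    def test_cluster_centred_on_peak_voxel(self, rng):
        vmap, atlas = self._map_and_atlas(rng)
        mask = phantoms.plant_microbleeds(vmap, atlas)
        assert mask[3, 4, 5]

    def test_random_tract_rule_is_seeded(self, rng):
        vmap, atlas = self._map_and_atlas(rng)
        a = phantoms.plant_microbleeds(vmap, atlas, rule="random-tract", seed=9)
        b = phantoms.plant_microbleeds(vmap, atlas, rule="random-tract", seed=9)
        assert np.array_equal(a, b)

    def test_downstream_classification_flags_exactly_one_tract(self, rng):
        from veinfem import roistats

        vmap, atlas = self._map_and_atlas(rng)
        mask = phantoms.plant_microbleeds(vmap, atlas)
        _, groups = roistats.prepare_atlas(atlas, mask)
        assert sum(groups.values()) == 1

    def test_all_zero_map_rejected(self, rng):
        _, atlas = self._map_and_atlas(rng)
        zero = strain.VoxelMap(np.zeros((12, 12, 12)), np.eye(4))
        with pytest.raises(ValueError, match="zero"):
            phantoms.plant_microbleeds(zero, atlas)


class TestCoraPairs:
    def test_zero_perturbation_scores_one(self):
        from veinfem import cora

        pair, pert = phantoms.cora_pair(phantoms.CoraPairSpec())
        assert pert == {"shift_ms": 0.0, "gain": 1.0, "noise_sigma": 0.0}
        assert cora.cora_score(pair, "giordano").total == 1.0

    def test_gain_hits_size_not_phase(self):
        from veinfem import cora

        pair, _ = phantoms.cora_pair(phantoms.CoraPairSpec(gain=2.0))
        s = cora.cora_score(pair, "giordano")
        assert s.size < 1.0 and s.phase == 1.0

    def test_determinism_with_noise(self):
        a, _ = phantoms.cora_pair(phantoms.CoraPairSpec(seed=3, noise_sigma=0.05))
        b, _ = phantoms.cora_pair(phantoms.CoraPairSpec(seed=3, noise_sigma=0.05))
        assert np.array_equal(a.test, b.test)
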