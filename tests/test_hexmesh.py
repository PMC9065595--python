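"""Voxel-to-hex meshing, CSF layer, smoothing, quality and positioning."""

import numpy as np
import pytest

from veinfem import hexmesh as hx
from veinfem import phantoms
from veinfem.image import LabelImage, adjacent_pairs_6, role_ids


def test_structured_grid_counts():
    """A 2x2x2 block of unit voxels meshes into 8 bricks on 27 shared nodes."""
    img = LabelImage(np.ones((2, 2, 2), dtype=np.int32), np.eye(4), {1: "white matter"})
    mesh = hx.build_hex_mesh(img)
    assert mesh.solid_elems.shape == (8, 8)
    assert mesh.node_coords.shape == (27, 3)
    # nodes shared: 8 elements x 8 corners = 64 references but only 27 nodes
    assert np.unique(mesh.solid_elems).size == 27


def test_empty_and_invalid_images_rejected():
    with pytest.raises(ValueError):
        hx.build_hex_mesh(LabelImage(np.zeros((3, 3, 3), dtype=np.int32), np.eye(4)))
    with pytest.raises(ValueError):
        LabelImage(np.ones((2, 2, 2), dtype=np.int32), np.diag([0.0, 1, 1, 1]))


def test_lone_voxel_reassigned_to_enclosing_part():
    vox = np.full((3, 3, 3), 2, dtype=np.int32)
    vox[1, 1, 1] = 5
    img = LabelImage(vox, np.eye(4), {2: "white matter", 5: "grey matter"})
    mesh = hx.build_hex_mesh(img)
    assert mesh.part_counts() == {2: 27}


def test_lone_voxel_with_mixed_neighbours_kept():
    vox = np.full((3, 3, 3), 2, dtype=np.int32)
    vox[1, 1, 1] = 5
    vox[0, 1, 1] = 7  # mixed shell: not "inside another part"
    img = LabelImage(vox, np.eye(4), {2: "a", 5: "b", 7: "c"})
    mesh = hx.build_hex_mesh(img)
    assert mesh.part_counts()[5] == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_voxel_element_bijection_on_phantoms(seed):
    """Per-part hex counts equal per-label voxel counts (histogram oracle)."""
    img = phantoms.head_phantom(phantoms.HeadPhantomSpec(seed=seed))
    mesh = hx.build_hex_mesh(img)
    assert mesh.part_counts() == img.counts()


def test_csf_layer_insertion_and_idempotence():
    vox = np.zeros((6, 5, 5), dtype=np.int32)
    vox[1, :, :] = 2   # skull slab
    vox[2, :, :] = 4   # brain touching skull
    vox[3, :, :] = 3   # csf behind
    vox[4, :, :] = 4
    img = LabelImage(vox, np.eye(4), {2: "skull", 3: "csf", 4: "grey matter"})
    out = hx.ensure_csf_layer(img, 2)
    assert adjacent_pairs_6(out.voxels, {4}, {2}) == 0
    # a CSF voxel now sits where brain touched skull
    assert np.all(out.voxels[2] == 3)
    # idempotence away from the gap: the second slab of brain is untouched
    assert np.all(out.voxels[4] == 4)
    again = hx.ensure_csf_layer(out, 2)
    assert np.array_equal(again.voxels, out.voxels)


def test_csf_layer_requires_labels():
    img = LabelImage(np.ones((3, 3, 3), dtype=np.int32), np.eye(4), {1: "grey matter"})
    with pytest.raises(ValueError):
        hx.ensure_csf_layer(img)


def test_csf_layer_phantom_brute_force_scan():
    """Exhaustive 6-adjacency scan finds no brain-skull contact."""
    img = phantoms.head_phantom(phantoms.HeadPhantomSpec(seed=7))
    out = hx.ensure_csf_layer(img, 2)
    roles = role_ids(out.label_table)
    brain = np.isin(out.voxels, sorted(roles["brain"]))
    skull = np.isin(out.voxels, sorted(roles["skull"]))
    bad = 0
    idx = np.argwhere(brain)
    for i, j, k in idx:
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < skull.shape[0] and 0 <= b < skull.shape[1] and 0 <= c < skull.shape[2]:
                bad += skull[a, b, c]
    assert bad == 0


class TestSmoothing:
    def _sphere(self, n=24, radius=8.0):
        ax = np.arange(n)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = (n - 1) / 2
        sph = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= radius**2
        return LabelImage(sph.astype(np.int32), np.eye(4), {1: "grey matter"}), c, radius

    def test_zero_iterations_is_identity(self):
        img, _, _ = self._sphere()
        mesh = hx.build_hex_mesh(img)
        out = hx.smooth_mesh(mesh, img, hx.MeshConfig(smooth_iterations=0))
        assert np.array_equal(out.node_coords, mesh.node_coords)

    def test_sphere_surface_rms_decreases(self):
        img, c, radius = self._sphere()
        mesh = hx.build_hex_mesh(img)
        out = hx.smooth_mesh(mesh, img, hx.MeshConfig(smooth_iterations=10))
        movable = hx._movable_nodes(mesh, img)

        def rms(m):
            r = np.linalg.norm(m.node_coords[movable] - c, axis=1)
            return np.sqrt(np.mean((r - radius) ** 2))

        assert rms(out) < rms(mesh)

    def test_quality_gate_enforced_and_topology_unchanged(self):
        img, _, _ = self._sphere()
        mesh = hx.build_hex_mesh(img)
        cfg = hx.MeshConfig(smooth_iterations=10, jac_min=0.25)
        out = hx.smooth_mesh(mesh, img, cfg)
        report = hx.mesh_quality(out)
        assert report.min_jacobian >= cfg.jac_min
        assert np.array_equal(out.solid_elems, mesh.solid_elems)
        assert np.array_equal(out.solid_parts, mesh.solid_parts)

    def test_invalid_gate_rejected(self):
        img, _, _ = self._sphere(n=6, radius=2.0)
        mesh = hx.build_hex_mesh(img)
        with pytest.raises(ValueError):
            hx.smooth_mesh(mesh, img, hx.MeshConfig(jac_min=1.5))


class TestQuality:
    def test_unit_cube_metrics(self):
        img = LabelImage(np.ones((1, 1, 1), dtype=np.int32), np.eye(4), {1: "csf"})
        mesh = hx.build_hex_mesh(img)
        rep = hx.mesh_quality(mesh)
        assert rep.scaled_jacobian[0] == pytest.approx(1.0)
        assert rep.aspect_ratio[0] == pytest.approx(1.0)
        assert rep.char_length_mm[0] == pytest.approx(1.0)

    def test_stretched_cube_aspect_ratio(self):
        img = LabelImage(np.ones((1, 1, 1), dtype=np.int32),
                         np.diag([2.0, 1.0, 1.0, 1.0]), {1: "csf"})
        mesh = hx.build_hex_mesh(img)
        rep = hx.mesh_quality(mesh)
        assert rep.aspect_ratio[0] == pytest.approx(2.0)

    def test_stable_timestep_matches_wave_speed_formula(self):
        """dt = L/c with c = sqrt(E(1-nu)/((1+nu)(1-2nu)rho)), L = 1 mm."""
        img = LabelImage(np.ones((1, 1, 1), dtype=np.int32), np.eye(4), {1: "csf"})
        mesh = hx.build_hex_mesh(img)
        mat = hx.Material(e_mpa=1.0, nu=0.3, rho_kg_m3=1000.0)
        rep = hx.mesh_quality(mesh, {1: mat})
        c = np.sqrt(1e6 * 0.7 / (1.3 * 0.4 * 1000.0))
        assert rep.dt_s[0] == pytest.approx(1e-3 / c, rel=1e-12)

    def test_nonpositive_material_rejected(self):
        with pytest.raises(ValueError):
            hx.Material(e_mpa=-1.0, nu=0.3, rho_kg_m3=1000.0).wave_speed()

    def test_forbidden_adjacency_reported(self):
        vox = np.zeros((2, 1, 1), dtype=np.int32)
        vox[0] = 1
        vox[1] = 2
        img = LabelImage(vox, np.eye(4), {1: "white matter", 2: "csf"})
        mesh = hx.build_hex_mesh(img)
        rep = hx.mesh_quality(mesh)
        assert len(rep.adjacency_violations) == 1


class TestMembranes:
    def test_falx_on_midplane_and_dura_face_count(self, small_head):
        mesh = hx.build_hex_mesh(small_head)
        out = hx.add_membranes(mesh, small_head)
        names = {v: k for k, v in out.part_names.items()}
        falx = out.shell_elems[out.shell_parts == names["falx"]]
        assert falx.size > 0
        xs = out.node_coords[falx.ravel(), 0]
        assert np.unique(xs).size == 1  # all falx nodes on one plane
        # dura count equals skull/inner interface faces (inner box surface)
        dura = out.shell_elems[out.shell_parts == names["dura"]]
        assert dura.shape[0] == 6 * 8 * 8  # the 8^3 inner box surface

    def test_shell_nodes_subset_of_solid_nodes(self, small_head):
        mesh = hx.build_hex_mesh(small_head)
        out = hx.add_membranes(mesh, small_head)
        assert set(out.shell_elems.ravel()) <= set(out.solid_elems.ravel())

    def test_missing_hemispheres_warns_and_skips_falx(self):
        vox = np.zeros((4, 4, 4), dtype=np.int32)
        vox[1:3, 1:3, 1:3] = 4
        img = LabelImage(vox, np.eye(4), {4: "grey matter"})
        mesh = hx.build_hex_mesh(img)
        with pytest.warns(UserWarning, match="falx"):
            out = hx.add_membranes(mesh, img)
        assert "falx" not in out.part_names.values()


class TestPositionAndScale:
    landmarks = {
        "porion_left": np.array([2.0, 3.0, 1.0]),
        "porion_right": np.array([2.0, 0.0, 1.0]),
        "orbitale": np.array([3.5, 1.5, 1.0]),
    }

    def _mesh(self):
        img = LabelImage(np.ones((4, 4, 4), dtype=np.int32), np.eye(4), {1: "white matter"})
        return hx.build_hex_mesh(img)

    def test_in_plane_landmarks_identity(self):
        mesh = self._mesh()
        out = hx.position_and_scale(mesh, self.landmarks)
        assert np.allclose(out.node_coords, mesh.node_coords, atol=1e-12)
        assert out.frankfort_aligned

    def test_rotation_round_trip(self):
        """Rotating mesh+landmarks about the mid-porion point is undone."""
        mesh = self._mesh()
        ref = hx.position_and_scale(mesh, self.landmarks)
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        origin = 0.5 * (self.landmarks["porion_left"] + self.landmarks["porion_right"])
        rotated = mesh.copy()
        rotated.node_coords = (mesh.node_coords - origin) @ rot.T + origin
        lm = {k: rot @ (v - origin) + origin for k, v in self.landmarks.items()}
        rec = hx.position_and_scale(rotated, lm)
        assert np.allclose(rec.node_coords, ref.node_coords, atol=1e-9)

    def test_anisotropic_scaling_linearity(self):
        mesh = self._mesh()
        base = hx.position_and_scale(mesh, self.landmarks)
        dims = base.node_coords.max(axis=0) - base.node_coords.min(axis=0)
        target = dims * np.array([2.0, 1.0, 1.0])
        out = hx.position_and_scale(mesh, self.landmarks, head_dims=target)
        new_dims = out.node_coords.max(axis=0) - out.node_coords.min(axis=0)
        assert np.allclose(new_dims, target)
        # cg offset from the occipital condyle doubles along x only
        oc = 0.5 * (self.landmarks["porion_left"] + self.landmarks["porion_right"])
        assert (out.cg - oc)[0] == pytest.approx(2 * (base.cg - oc)[0])
        assert np.allclose((out.cg - oc)[1:], (base.cg - oc)[1:])

    def test_collinear_landmarks_rejected(self):
        mesh = self._mesh()
        lm = dict(self.landmarks, orbitale=np.array([2.0, 1.5, 1.0]))
        with pytest.raises(ValueError, match="collinear"):
            hx.position_and_scale(mesh, lm)
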