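"""Voxel-based hexahedral meshing of segmented head images.

Each non-background voxel becomes one 8-node brick element; nodes sit on
voxel corners and are shared between neighbouring voxels.  Jagged tissue
surfaces and interfaces are relaxed by quality-gated Taubin smoothing,
membranes (dura, falx, tentorium) are added as shell elements re-using
solid nodes, and the mesh can be rotated to the Frankfort plane and
scaled to subject head dimensions with an anthropometric centre of
gravity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import LabelImage, role_ids

__all__ = [
    "MeshConfig",
    "Material",
    "HexMesh",
    "QualityReport",
    "build_hex_mesh",
    "ensure_csf_layer",
    "smooth_mesh",
    "mesh_quality",
    "add_membranes",
    "position_and_scale",
    "scaled_jacobian",
    "aspect_ratio",
]

# VTK/solver hexahedron corner ordering on the unit voxel: bottom face
# counter-clockwise, then top face.
_HEX_OFFSETS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ]
)

# Edge-vector triads per corner, ordered so det > 0 on a right-handed brick.
_CORNER_TRIADS = (
    (1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
    (5, 0, 7), (4, 6, 1), (5, 7, 2), (6, 4, 3),
)

_HEX_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
)

_HEX_FACES = (
    (0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
    (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7),
)

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class MeshConfig:
    """Tunable meshing parameters.

    lone_max
        Maximum size (voxels) of a 6-connected island fully enclosed by a
        single other part that gets reassigned to that part.
    jac_min
        Scaled-Jacobian floor enforced while smoothing, in (0, 1].
    dt_min
        Stable-time-step floor (s) enforced while smoothing; 0 disables
        the gate (it needs a material assignment to be meaningful).
    smooth_iterations
        Number of Taubin lambda/mu smoothing passes.
    """

    lone_max: int = 1
    jac_min: float = 0.2
    dt_min: float = 0.0
    smooth_iterations: int = 10
    taubin_lambda: float = 0.5
    taubin_mu: float = -0.53
    dura_thickness_mm: float = 1.0
    membrane_thickness_mm: float = 0.5
    falx_corridor_vox: float = 2.0


@dataclass
class Material:
    """Linear-elastic material for time-step estimates.

    E in MPa, density in kg/m^3.
    """

    e_mpa: float
    nu: float
    rho_kg_m3: float

    def wave_speed(self) -> float:
        """Dilatational wave speed in m/s."""
        if self.e_mpa <= 0 or self.rho_kg_m3 <= 0:
            raise ValueError("modulus and density must be positive")
        e_pa = self.e_mpa * 1e6
        return float(
            np.sqrt(e_pa * (1 - self.nu) / ((1 + self.nu) * (1 - 2 * self.nu) * self.rho_kg_m3))
        )


@dataclass
class HexMesh:
    """Nodes (mm) plus solid / shell / beam elements with part labels."""

    node_coords: np.ndarray  # (N, 3) mm
    solid_elems: np.ndarray  # (E, 8) node row indices
    solid_parts: np.ndarray  # (E,) label ids
    shell_elems: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=np.int64))
    shell_parts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    shell_thickness: np.ndarray = field(default_factory=lambda: np.empty(0))
    beam_elems: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    beam_sections: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    part_names: dict[int, str] = field(default_factory=dict)
    cg: np.ndarray | None = None
    frankfort_aligned: bool = False
    # voxel bookkeeping kept so membranes can reuse corner node ids
    _corner_origin: np.ndarray | None = None
    _corner_strides: tuple[int, int, int] | None = None
    _corner_lookup: np.ndarray | None = None

    def copy(self) -> "HexMesh":
        return replace(
            self,
            node_coords=self.node_coords.copy(),
            solid_elems=self.solid_elems.copy(),
            solid_parts=self.solid_parts.copy(),
            shell_elems=self.shell_elems.copy(),
            shell_parts=self.shell_parts.copy(),
            shell_thickness=self.shell_thickness.copy(),
            beam_elems=self.beam_elems.copy(),
            beam_sections=self.beam_sections.copy(),
            part_names=dict(self.part_names),
            cg=None if self.cg is None else self.cg.copy(),
        )

    def part_counts(self) -> dict[int, int]:
        ids, n = np.unique(self.solid_parts, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, n)}


@dataclass
class QualityReport:
    """Per-element quality metrics and forbidden part adjacencies."""

    scaled_jacobian: np.ndarray
    aspect_ratio: np.ndarray
    char_length_mm: np.ndarray
    dt_s: np.ndarray
    adjacency_violations: list[tuple[int, int, int, int]]

    @property
    def min_jacobian(self) -> float:
        return float(self.scaled_jacobian.min())

    @property
    def min_dt(self) -> float:
        finite = self.dt_s[np.isfinite(self.dt_s)]
        return float(finite.min()) if finite.size else float("inf")


# ---------------------------------------------------------------------------
# element geometry kernels (vectorised over elements)
# ---------------------------------------------------------------------------

def _corner_dets(coords: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Jacobian determinant at each of the 8 corners of each element."""
    x = coords[elems]  # (E, 8, 3)
    dets = np.empty((elems.shape[0], 8))
    for c, (a, b, d) in enumerate(_CORNER_TRIADS):
        ea = x[:, a] - x[:, c]
        eb = x[:, b] - x[:, c]
        ec = x[:, d] - x[:, c]
        dets[:, c] = np.einsum("ij,ij->i", np.cross(ea, eb), ec)
    return dets


def scaled_jacobian(coords: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Min/max corner-determinant ratio per element (1 for a perfect brick)."""
    dets = _corner_dets(coords, elems)
    dmax = dets.max(axis=1)
    dmin = dets.min(axis=1)
    out = np.where(dmax > 0, dmin / np.where(dmax > 0, dmax, 1.0), -1.0)
    return out


def aspect_ratio(coords: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Max/min edge-length ratio per element (>= 1)."""
    x = coords[elems]
    lengths = np.stack(
        [np.linalg.norm(x[:, b] - x[:, a], axis=1) for a, b in _HEX_EDGES], axis=1
    )
    return lengths.max(axis=1) / lengths.min(axis=1)


def _char_length(coords: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Characteristic length: volume / largest face area (mm)."""
    vol = _corner_dets(coords, elems).mean(axis=1)
    x = coords[elems]
    areas = []
    for f in _HEX_FACES:
        d1 = x[:, f[2]] - x[:, f[0]]
        d2 = x[:, f[3]] - x[:, f[1]]
        areas.append(0.5 * np.linalg.norm(np.cross(d1, d2), axis=1))
    amax = np.stack(areas, axis=1).max(axis=1)
    return np.abs(vol) / amax


# ---------------------------------------------------------------------------
# lone voxels
# ---------------------------------------------------------------------------

def remove_lone_voxels(labels: LabelImage, lone_max: int = 1) -> LabelImage:
    """Reassign small 6-connected islands enclosed by a single other part.

    An island of label A of size <= ``lone_max`` whose entire 6-neighbour
    shell carries one label B != A (background does not count as a part)
    is relabelled to B.
    """
    vox = labels.voxels.copy()
    for lid in np.unique(vox):
        if lid == 0:
            continue
        comp, ncomp = ndimage.label(vox == lid, structure=_SIX_CONN)
        if ncomp <= 1:
            # a single component is the part itself, not an island
            pass
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, ncomp + 1))
        for ci in np.flatnonzero(sizes <= lone_max):
            mask = comp == (ci + 1)
            idx = np.argwhere(mask)
            if idx.min() == 0 or np.any(idx.max(axis=0) == np.array(vox.shape) - 1):
                continue  # touches the image border: not enclosed
            shell = ndimage.binary_dilation(mask, structure=_SIX_CONN) & ~mask
            neigh = np.unique(vox[shell])
            neigh = neigh[(neigh != 0) & (neigh != lid)]
            if neigh.size == 1 and not np.any(vox[shell] == 0):
                vox[mask] = neigh[0]
    return LabelImage(vox, labels.affine, dict(labels.label_table))


# ---------------------------------------------------------------------------
# build
# ---------------------------------------------------------------------------

def build_hex_mesh(labels: LabelImage, config: MeshConfig | None = None) -> HexMesh:
    """One hexahedral element per non-background voxel, corner-shared nodes."""
    config = config or MeshConfig()
    if labels.voxels.size == 0:
        raise ValueError("empty label image")
    labels = remove_lone_voxels(labels, config.lone_max)
    mask = labels.voxels > 0
    if not mask.any():
        raise ValueError("label image has no non-background voxels")

    nx, ny, nz = labels.shape
    corner_shape = (nx + 1, ny + 1, nz + 1)
    used = np.zeros(corner_shape, dtype=bool)
    vox_idx = np.argwhere(mask)  # (E, 3)
    for off in _HEX_OFFSETS:
        c = vox_idx + off
        used[c[:, 0], c[:, 1], c[:, 2]] = True

    node_id = np.full(corner_shape, -1, dtype=np.int64)
    node_id[used] = np.arange(int(used.sum()))
    corner_ijk = np.argwhere(used).astype(float)
    # corner (ci,cj,ck) sits at voxel coordinate (ci-0.5, cj-0.5, ck-0.5)
    node_coords = labels.world_from_voxel(corner_ijk - 0.5)

    elems = np.empty((vox_idx.shape[0], 8), dtype=np.int64)
    for k, off in enumerate(_HEX_OFFSETS):
        c = vox_idx + off
        elems[:, k] = node_id[c[:, 0], c[:, 1], c[:, 2]]
    parts = labels.voxels[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]].astype(np.int64)

    return HexMesh(
        node_coords=np.atleast_2d(node_coords),
        solid_elems=elems,
        solid_parts=parts,
        part_names=dict(labels.label_table),
        _corner_lookup=node_id,
    )


# ---------------------------------------------------------------------------
# CSF layer
# ---------------------------------------------------------------------------

def ensure_csf_layer(labels: LabelImage, n_dilations: int = 2) -> LabelImage:
    """Dilate the CSF label into the brain-skull corridor.

    Repeats ``n_dilations`` passes converting brain/background voxels that
    sit in the brain-skull gap (adjacent to both CSF and skull) to CSF,
    then enforces the invariant that no brain voxel is left 6-adjacent to
    a skull voxel.
    """
    roles = role_ids(labels.label_table)
    for need in ("csf", "brain", "skull"):
        if not roles[need]:
            raise ValueError(f"label table lacks a {need!r} label")
    csf_id = min(roles["csf"])
    vox = labels.voxels.copy()
    brain = sorted(roles["brain"])
    skull = sorted(roles["skull"])
    for _ in range(n_dilations):
        near_csf = ndimage.binary_dilation(vox == csf_id, structure=_SIX_CONN)
        near_skull = ndimage.binary_dilation(np.isin(vox, skull), structure=_SIX_CONN)
        candidates = (np.isin(vox, brain) | (vox == 0)) & near_csf & near_skull
        vox[candidates] = csf_id
    # guarantee the layer even where CSF could not reach in n passes
    near_skull = ndimage.binary_dilation(np.isin(vox, skull), structure=_SIX_CONN)
    leftover = np.isin(vox, brain) & near_skull
    vox[leftover] = csf_id
    return LabelImage(vox, labels.affine, dict(labels.label_table))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _movable_nodes(mesh: HexMesh, labels: LabelImage) -> np.ndarray:
    """Surface / interface nodes: corner whose incident voxels disagree."""
    vox = labels.voxels
    nx, ny, nz = vox.shape
    padded = np.zeros((nx + 2, ny + 2, nz + 2), dtype=vox.dtype)
    padded[1:-1, 1:-1, 1:-1] = vox
    lookup = mesh._corner_lookup
    if lookup is None:
        raise ValueError("mesh lacks voxel bookkeeping; build it with build_hex_mesh")
    movable = np.zeros(mesh.node_coords.shape[0], dtype=bool)
    corner = np.argwhere(lookup >= 0)
    ids = lookup[corner[:, 0], corner[:, 1], corner[:, 2]]
    # the 8 voxels incident to corner (ci,cj,ck) are padded[ci:ci+2, ...]
    stacks = np.stack(
        [
            padded[corner[:, 0] + di, corner[:, 1] + dj, corner[:, 2] + dk]
            for di in (0, 1)
            for dj in (0, 1)
            for dk in (0, 1)
        ],
        axis=1,
    )
    disagree = np.any(stacks != stacks[:, :1], axis=1)
    movable[ids] = disagree
    return movable


def _edge_adjacency(mesh: HexMesh):
    from scipy import sparse

    n = mesh.node_coords.shape[0]
    rows, cols = [], []
    for a, b in _HEX_EDGES:
        rows.append(mesh.solid_elems[:, a])
        cols.append(mesh.solid_elems[:, b])
    r = np.concatenate(rows + cols)
    c = np.concatenate(cols + rows)
    adj = sparse.coo_matrix((np.ones_like(r, dtype=float), (r, c)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    adj.sum_duplicates()
    adj = sparse.csr_matrix((np.ones_like(adj.data), adj.indices, adj.indptr), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return adj, deg


def smooth_mesh(
    mesh: HexMesh,
    labels: LabelImage,
    config: MeshConfig | None = None,
    materials: dict[int, Material] | None = None,
) -> HexMesh:
    """Quality-gated Taubin smoothing of surface/interface nodes.

    Node updates that would drop an incident element's scaled Jacobian
    below ``config.jac_min`` (or its stable time step below
    ``config.dt_min`` when materials are given) are rejected.  Topology
    is never changed.
    """
    config = config or MeshConfig()
    if not (0 < config.jac_min <= 1):
        raise ValueError("jac_min must lie in (0, 1]")
    out = mesh.copy()
    if config.smooth_iterations <= 0:
        return out
    movable = _movable_nodes(mesh, labels)
    if not movable.any():
        return out
    adj, deg = _edge_adjacency(mesh)
    elems = out.solid_elems
    node_elem_count = np.bincount(elems.ravel(), minlength=out.node_coords.shape[0])

    wave = None
    if materials is not None and config.dt_min > 0:
        wave = np.full(elems.shape[0], np.nan)
        for pid, mat in materials.items():
            wave[out.solid_parts == pid] = mat.wave_speed()

    coords = out.node_coords
    for _ in range(config.smooth_iterations):
        for factor in (config.taubin_lambda, config.taubin_mu):
            target = adj @ coords / deg[:, None]
            proposed = coords.copy()
            proposed[movable] += factor * (target[movable] - coords[movable])
            accept = movable.copy()
            for _sweep in range(4):
                jac = scaled_jacobian(proposed, elems)
                bad = jac < config.jac_min
                if wave is not None:
                    lc = _char_length(proposed, elems)
                    dt = lc * 1e-3 / wave
                    bad |= np.nan_to_num(dt, nan=np.inf) < config.dt_min
                if not bad.any():
                    break
                bad_nodes = np.unique(elems[bad])
                bad_nodes = bad_nodes[accept[bad_nodes]]
                if bad_nodes.size == 0:
                    break
                proposed[bad_nodes] = coords[bad_nodes]
                accept[bad_nodes] = False
            else:
                # final safety: revert everything still failing
                jac = scaled_jacobian(proposed, elems)
                bad = jac < config.jac_min
                if bad.any():
                    proposed[np.unique(elems[bad])] = coords[np.unique(elems[bad])]
            coords = proposed
    out.node_coords = coords
    return out


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def _face_pairs(elems: np.ndarray) -> np.ndarray:
    """Pairs of element indices sharing a quad face; (P, 2) array."""
    e = elems.shape[0]
    faces = np.empty((e * 6, 4), dtype=np.int64)
    owner = np.empty(e * 6, dtype=np.int64)
    for fi, f in enumerate(_HEX_FACES):
        faces[fi * e:(fi + 1) * e] = np.sort(elems[:, f], axis=1)
        owner[fi * e:(fi + 1) * e] = np.arange(e)
    order = np.lexsort(faces.T[::-1])
    faces = faces[order]
    owner = owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    idx = np.flatnonzero(same)
    return np.stack([owner[idx], owner[idx + 1]], axis=1)


def mesh_quality(mesh: HexMesh, materials: dict[int, Material] | None = None) -> QualityReport:
    """Scaled Jacobian, aspect ratio, characteristic length and stable dt.

    ``dt = L_char / c`` with c the dilatational wave speed of each
    element's material (NaN where no material is assigned).  Also reports
    face-sharing element pairs between parts that must not touch (white
    matter against CSF, grey matter against skull).
    """
    coords, elems = mesh.node_coords, mesh.solid_elems
    jac = scaled_jacobian(coords, elems)
    asp = aspect_ratio(coords, elems)
    lc = _char_length(coords, elems)
    dt = np.full(elems.shape[0], np.nan)
    if materials:
        for pid, mat in materials.items():
            sel = mesh.solid_parts == pid
            if sel.any():
                dt[sel] = lc[sel] * 1e-3 / mat.wave_speed()

    roles = role_ids(mesh.part_names)
    forbidden = [
        (roles["white"], roles["csf"]),
        (roles["grey"], roles["skull"]),
    ]
    violations: list[tuple[int, int, int, int]] = []
    if any(a and b for a, b in forbidden):
        pairs = _face_pairs(elems)
        pa = mesh.solid_parts[pairs[:, 0]]
        pb = mesh.solid_parts[pairs[:, 1]]
        for ids_a, ids_b in forbidden:
            if not (ids_a and ids_b):
                continue
            hit = (np.isin(pa, sorted(ids_a)) & np.isin(pb, sorted(ids_b))) | (
                np.isin(pb, sorted(ids_a)) & np.isin(pa, sorted(ids_b))
            )
            for i, j in pairs[hit]:
                violations.append((int(i), int(j), int(mesh.solid_parts[i]), int(mesh.solid_parts[j])))
    return QualityReport(jac, asp, lc, dt, violations)


# ---------------------------------------------------------------------------
# membranes
# ---------------------------------------------------------------------------

def _face_nodes_between(lookup: np.ndarray, v: np.ndarray, axis: int) -> np.ndarray:
    """Node ids of the quad face between voxel v and its +axis neighbour."""
    # face lies at corner plane v[axis] + 1
    base = v.copy()
    base[:, axis] += 1
    others = [a for a in range(3) if a != axis]
    quads = np.empty((v.shape[0], 4), dtype=np.int64)
    offs = [(0, 0), (1, 0), (1, 1), (0, 1)]
    for k, (da, db) in enumerate(offs):
        c = base.copy()
        c[:, others[0]] += da
        c[:, others[1]] += db
        quads[:, k] = lookup[c[:, 0], c[:, 1], c[:, 2]]
    return quads


def _axis_pairs(shape, axis):
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    return tuple(sl_lo), tuple(sl_hi)


def add_membranes(mesh: HexMesh, labels: LabelImage, config: MeshConfig | None = None) -> HexMesh:
    """Emit dura / falx / tentorium shells re-using solid node ids.

    * dura: one shell per face between a skull element and a CSF or brain
      element (the inner skull surface),
    * falx: shells on the surface where the distance transforms of the
      left and right hemisphere labels cross, inside the inter-hemispheric
      corridor,
    * tentorium: likewise for cerebrum vs cerebellum.
    """
    config = config or MeshConfig()
    out = mesh.copy()
    lookup = mesh._corner_lookup
    if lookup is None:
        raise ValueError("mesh lacks voxel bookkeeping; build it with build_hex_mesh")
    vox = labels.voxels
    roles = role_ids(labels.label_table)

    new_shells: list[np.ndarray] = []
    new_parts: list[np.ndarray] = []
    new_thick: list[np.ndarray] = []
    next_pid = max([0, *mesh.part_names.keys(), *np.unique(mesh.solid_parts).tolist()]) + 1

    def emit(quads: np.ndarray, pid: int, thickness: float) -> None:
        ok = np.all(quads >= 0, axis=1)
        quads = quads[ok]
        if quads.size:
            new_shells.append(quads)
            new_parts.append(np.full(quads.shape[0], pid, dtype=np.int64))
            new_thick.append(np.full(quads.shape[0], thickness))

    # --- dura ---------------------------------------------------------
    if roles["skull"]:
        skull = np.isin(vox, sorted(roles["skull"]))
        inner = np.isin(vox, sorted(roles["csf"] | roles["brain"]))
        dura_pid = next_pid
        next_pid += 1
        out.part_names[dura_pid] = "dura"
        for axis in range(3):
            lo, hi = _axis_pairs(vox.shape, axis)
            for a, b in ((skull, inner), (inner, skull)):
                sel = a[lo] & b[hi]
                v = np.argwhere(sel)
                if v.size:
                    emit(_face_nodes_between(lookup, v, axis), dura_pid, config.dura_thickness_mm)

    # --- falx / tentorium --------------------------------------------
    def midsurface(ids_a: set[int], ids_b: set[int], pid: int, name: str) -> None:
        out.part_names[pid] = name
        da = ndimage.distance_transform_edt(~np.isin(vox, sorted(ids_a)))
        db = ndimage.distance_transform_edt(~np.isin(vox, sorted(ids_b)))
        dd = da - db
        corridor = np.minimum(da, db) <= config.falx_corridor_vox
        neither = ~np.isin(vox, sorted(ids_a | ids_b))
        ok = corridor & neither
        for axis in range(3):
            lo, hi = _axis_pairs(vox.shape, axis)
            both_ok = ok[lo] & ok[hi]
            # strict sign change, or a zero voxel paired with its positive
            # neighbour (deterministic tie-break for odd gaps)
            cross = ((dd[lo] < 0) & (dd[hi] > 0)) | ((dd[lo] > 0) & (dd[hi] < 0))
            tie = ((dd[lo] == 0) & (dd[hi] > 0)) | ((dd[hi] == 0) & (dd[lo] > 0))
            v = np.argwhere(both_ok & (cross | tie))
            if v.size:
                emit(_face_nodes_between(lookup, v, axis), pid, config.membrane_thickness_mm)

    if roles["left"] and roles["right"]:
        midsurface(roles["left"] & roles["brain"], roles["right"] & roles["brain"],
                   next_pid, "falx")
        next_pid += 1
    else:
        warnings.warn("hemisphere labels missing; falx skipped", stacklevel=2)
    if roles["cerebellum"] and roles["cerebrum"]:
        midsurface(roles["cerebrum"], roles["cerebellum"], next_pid, "tentorium")
        next_pid += 1

    if new_shells:
        out.shell_elems = np.concatenate([out.shell_elems, *new_shells])
        out.shell_parts = np.concatenate([out.shell_parts, *new_parts])
        out.shell_thickness = np.concatenate([out.shell_thickness, *new_thick])
    return out


# ---------------------------------------------------------------------------
# positioning
# ---------------------------------------------------------------------------

#: Centre-of-gravity offsets from the occipital condyle as fractions of
#: (head length, head width, head height); anthropometric constants
#: (configurable per subject population).
CG_FRACTIONS = np.array([0.0872, 0.0, 0.1555])


def position_and_scale(
    mesh: HexMesh,
    landmarks: dict[str, np.ndarray],
    head_dims: np.ndarray | None = None,
    cg_constants: np.ndarray | None = None,
) -> HexMesh:
    """Rotate to the Frankfort plane, scale to head dims, set the CG.

    ``landmarks`` must contain world-mm positions for ``porion_left``,
    ``porion_right`` and ``orbitale`` (optionally ``occipital_condyle``).
    The rigid rotation brings the landmark plane horizontal with the
    inter-porion line along +y; anisotropic scale factors
    ``head_dims / mesh bounding-box extents`` are applied about the
    mid-porion point; the CG is set from the occipital-condyle offset
    scaled by the head dimensions.
    """
    for k in ("porion_left", "porion_right", "orbitale"):
        if k not in landmarks:
            raise ValueError(f"missing landmark {k!r}")
    pl = np.asarray(landmarks["porion_left"], dtype=float)
    pr = np.asarray(landmarks["porion_right"], dtype=float)
    orb = np.asarray(landmarks["orbitale"], dtype=float)
    n = np.cross(pl - orb, pr - orb)
    if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(pl - orb), 1.0):
        raise ValueError("collinear landmarks: Frankfort plane undefined")
    y = pl - pr
    y = y / np.linalg.norm(y)
    n = n / np.linalg.norm(n)
    if n[2] < 0:
        n = -n
    n = n - (n @ y) * y  # orthogonalise (porion line lies in the plane)
    n = n / np.linalg.norm(n)
    x = np.cross(y, n)
    rot = np.stack([x, y, n])  # world -> aligned
    origin = 0.5 * (pl + pr)

    out = mesh.copy()
    coords = (out.node_coords - origin) @ rot.T + origin

    if head_dims is not None:
        head_dims = np.asarray(head_dims, dtype=float)
        extent = coords.max(axis=0) - coords.min(axis=0)
        factors = head_dims / extent
        coords = (coords - origin) * factors + origin
    else:
        head_dims = coords.max(axis=0) - coords.min(axis=0)

    out.node_coords = coords
    oc = landmarks.get("occipital_condyle")
    if oc is not None:
        oc = (np.asarray(oc, dtype=float) - origin) @ rot.T + origin
        if "factors" in locals():
            oc = (oc - origin) * factors + origin
    else:
        oc = origin
    frac = CG_FRACTIONS if cg_constants is None else np.asarray(cg_constants, dtype=float)
    out.cg = oc + frac * head_dims
    out.frankfort_aligned = True
    return out
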