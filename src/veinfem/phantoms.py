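"""Seeded phantom generators with analytic ground truth.

Every input the toolkit consumes can be generated here without any
download: nested-ellipsoid head label images, tubular branching vessel
masks with known centerlines and radii, rigid / affine / smooth-field
motion with analytically known axial strain, block tract atlases,
microbleed masks co-located with high-strain voxels, and perturbed
curve pairs for CORA fixtures.  A fixed seed reproduces every output
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cora import CurvePair
from .image import LabelImage, adjacent_pairs_6, role_ids
from .strain import Trajectory, VoxelMap
from .veins import VesselTree

__all__ = [
    "HEAD_LABELS",
    "HeadPhantomSpec",
    "VesselPhantomSpec",
    "MotionSpec",
    "CoraPairSpec",
    "head_phantom",
    "vessel_phantom",
    "motion_generator",
    "tract_atlas_phantom",
    "plant_microbleeds",
    "cora_pair",
]

#: Canonical label table used by the head phantom.
HEAD_LABELS: dict[int, str] = {
    1: "scalp",
    2: "skull",
    3: "csf",
    4: "grey matter left hemisphere",
    5: "grey matter right hemisphere",
    6: "white matter left hemisphere",
    7: "white matter right hemisphere",
    8: "cerebellum",
}


# ---------------------------------------------------------------------------
# head phantom
# ---------------------------------------------------------------------------

@dataclass
class HeadPhantomSpec:
    """Nested-ellipsoid head at roughly anatomical proportions.

    Semi-axes (mm) of the tissue shells from outside in; 3 mm voxels on
    a 64^3 grid cover a ~190 mm head.  ``jitter`` scales a seeded random
    perturbation of the semi-axes so different seeds give different but
    valid geometries.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.0
    scalp_semi: tuple[float, float, float] = (90.0, 75.0, 81.0)
    skull_semi: tuple[float, float, float] = (83.0, 68.0, 74.0)
    csf_semi: tuple[float, float, float] = (76.0, 61.0, 67.0)
    grey_semi: tuple[float, float, float] = (68.0, 53.0, 59.0)
    white_semi: tuple[float, float, float] = (52.0, 38.0, 44.0)
    jitter: float = 0.02


def _ellipsoid(coords, center, semi) -> np.ndarray:
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi))
    return q <= 1.0


def head_phantom(spec: HeadPhantomSpec | None = None) -> LabelImage:
    """Nested-shell head label image with hemisphere/cerebellum sublabels.

    Guarantees at least one CSF voxel between brain and skull (the
    shells are built with a >= 2-voxel CSF layer, then the invariant is
    enforced explicitly).  Raises if the requested shells are not
    strictly nested by at least one voxel.
    """
    spec = spec or HeadPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_mm
    semis = {}
    for name in ("scalp", "skull", "csf", "grey", "white"):
        base = np.asarray(getattr(spec, f"{name}_semi"), dtype=float)
        semis[name] = base * (1.0 + spec.jitter * rng.uniform(-1, 1, size=3))
    order = ["scalp", "skull", "csf", "grey", "white"]
    for outer, inner in zip(order, order[1:]):
        if np.any(semis[inner] >= semis[outer] - vs):
            raise ValueError(
                f"shells not nested: {inner} semi-axes must be at least one "
                f"voxel inside {outer}"
            )

    shape = spec.shape
    center = (np.asarray(shape, dtype=float) - 1) / 2 + rng.uniform(-0.5, 0.5, size=3)
    affine = np.diag([vs, vs, vs, 1.0])
    coords = np.meshgrid(*[np.arange(n) * vs for n in shape], indexing="ij")
    center_mm = center * vs

    vox = np.zeros(shape, dtype=np.int16)
    vox[_ellipsoid(coords, center_mm, semis["scalp"])] = 1
    vox[_ellipsoid(coords, center_mm, semis["skull"])] = 2
    vox[_ellipsoid(coords, center_mm, semis["csf"])] = 3
    grey = _ellipsoid(coords, center_mm, semis["grey"])
    white = _ellipsoid(coords, center_mm, semis["white"])
    vox[grey] = 4
    vox[white] = 6

    # tentorium corridor: one axial CSF plane separates cerebellum below
    brain = (vox == 4) | (vox == 6)
    kz = int(round(center[2] - 0.45 * semis["grey"][2] / vs))
    below = np.zeros(shape, dtype=bool)
    below[:, :, :kz] = True
    plane = np.zeros(shape, dtype=bool)
    if 0 <= kz < shape[2]:
        plane[:, :, kz] = True
    vox[brain & below] = 8
    vox[brain & plane] = 3

    # falx corridor: one sagittal CSF plane splits the cerebrum
    ki = int(round(center[0]))
    cerebrum = (vox == 4) | (vox == 6)
    sag = np.zeros(shape, dtype=bool)
    sag[ki, :, :] = True
    right = np.zeros(shape, dtype=bool)
    right[ki + 1:, :, :] = True
    vox[cerebrum & sag] = 3
    vox[(vox == 4) & right] = 5
    vox[(vox == 6) & right] = 7

    img = LabelImage(vox.astype(np.int32), affine, dict(HEAD_LABELS))
    # enforce the CSF-layer invariant
    roles = role_ids(img.label_table)
    if adjacent_pairs_6(img.voxels, roles["brain"], roles["skull"]):
        from .hexmesh import ensure_csf_layer

        img = ensure_csf_layer(img, n_dilations=0)
    return img


def analytic_shell_volumes(spec: HeadPhantomSpec) -> dict[str, float]:
    """Ideal ellipsoid volumes (mm^3) per shell for the *unjittered* spec."""
    out = {}
    for name in ("scalp", "skull", "csf", "grey", "white"):
        a, b, c = getattr(spec, f"{name}_semi")
        out[name] = 4.0 / 3.0 * np.pi * a * b * c
    return out


# ---------------------------------------------------------------------------
# vessel phantom
# ---------------------------------------------------------------------------

@dataclass
class VesselPhantomSpec:
    """Random branching tube tree rasterised at QSM-like resolution."""

    seed: int = 0
    shape: tuple[int, int, int] = (90, 90, 90)
    voxel_size_mm: float = 0.33
    n_branch_levels: int = 2
    trunk_length_mm: tuple[float, float] = (10.0, 14.0)
    branch_length_mm: tuple[float, float] = (6.0, 9.0)
    radius_mm: tuple[float, float] = (0.6, 1.1)
    tortuosity: float = 0.12  # rad of direction jitter per step
    branch_angle_deg: float = 32.0
    n_trees: int = 1  # independent trunks spread over the grid


@dataclass
class VesselTruth:
    """Analytic ground truth for a rasterised vessel phantom."""

    polylines: list[np.ndarray]  # world mm, one per segment chain
    radii: list[float]  # constant radius per polyline
    total_length_mm: float


def _unit(v):
    return v / np.linalg.norm(v)


def _rot_towards(d, rng, angle):
    """Rotate direction d by `angle` about a random perpendicular axis."""
    perp = np.cross(d, rng.normal(size=3))
    n = np.linalg.norm(perp)
    if n < 1e-9:
        perp = np.cross(d, [1.0, 0.0, 0.0])
        n = np.linalg.norm(perp)
    perp = perp / n
    return _unit(d * np.cos(angle) + np.cross(perp, d) * np.sin(angle))


def vessel_phantom(spec: VesselPhantomSpec | None = None) -> tuple[VesselTruth, LabelImage]:
    """Random binary branching tree of tube segments plus its mask.

    Returns the analytic truth (polylines, radii, total length) and the
    rasterised binary mask.  Radii below half a voxel raise; branches
    that would escape the grid are clipped with a warning.
    """
    import warnings

    spec = spec or VesselPhantomSpec()
    if spec.radius_mm[0] < spec.voxel_size_mm / 2:
        raise ValueError("radii must be at least half a voxel")
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_mm
    extent = np.asarray(spec.shape) * vs
    margin = spec.radius_mm[1] + 2 * vs

    polylines: list[np.ndarray] = []
    radii: list[float] = []
    clipped = False

    def grow(start: np.ndarray, direction: np.ndarray, level: int) -> None:
        nonlocal clipped
        from scipy.spatial import cKDTree

        lo, hi = (spec.trunk_length_mm if level == 0 else spec.branch_length_mm)
        length = rng.uniform(lo, hi)
        radius = rng.uniform(*spec.radius_mm) * (0.8**level)
        radius = max(radius, vs * 0.75)
        step = vs
        pts = [start.copy()]
        d = direction.copy()
        travelled = 0.0
        # keep new growth away from previously laid tubes so distinct
        # branches never merge in the rasterised mask
        laid = [(cKDTree(p), r) for p, r in zip(polylines, radii)]
        clearance = 2.0 * spec.radius_mm[1] + 2 * vs
        while travelled < length:
            d = _rot_towards(d, rng, rng.normal(0.0, spec.tortuosity) * step / 4)
            nxt = pts[-1] + d * step
            if np.any(nxt < margin) or np.any(nxt > extent - margin):
                clipped = True
                break
            if travelled > clearance and any(
                kd.query(nxt)[0] < radius + r + 2 * vs for kd, r in laid
            ):
                clipped = True
                break
            pts.append(nxt)
            travelled += step
        if travelled < 4.5:
            # a stub shorter than a few radii is not a resolvable branch;
            # drop it from both the mask and the ground truth
            return
        poly = np.asarray(pts)
        polylines.append(poly)
        radii.append(radius)
        if travelled < length - step:
            return  # clipped: do not branch into the wall
        if level + 1 <= spec.n_branch_levels:
            ang = np.deg2rad(spec.branch_angle_deg)
            for sign in (1.0, -1.0):
                child_dir = _rot_towards(d, rng, sign * ang)
                grow(poly[-1].copy(), child_dir, level + 1)

    if spec.n_trees == 1:
        anchors = [np.array([0.5, 0.5])]
    else:
        anchors = [
            np.array([0.32, 0.32]), np.array([0.68, 0.32]),
            np.array([0.32, 0.68]), np.array([0.68, 0.68]),
        ][: spec.n_trees]
    for anchor in anchors:
        start = extent / 2 + rng.uniform(-2, 2, size=3)
        start[:2] = anchor * extent[:2] + rng.uniform(-1.5, 1.5, size=2)
        start[2] = margin + 1.0
        grow(start, _unit(np.array([0.1, 0.1, 1.0]) + 0.2 * rng.normal(size=3)), 0)
    if clipped:
        warnings.warn("vessel tree clipped at the grid boundary", stacklevel=2)

    mask = np.zeros(spec.shape, dtype=bool)
    grid_axes = [np.arange(n) * vs for n in spec.shape]
    for poly, r in zip(polylines, radii):
        pad = r + vs
        lo = np.maximum(((poly.min(axis=0) - pad) / vs).astype(int), 0)
        hi = np.minimum(((poly.max(axis=0) + pad) / vs).astype(int) + 2, spec.shape)
        sub = np.meshgrid(*[np.arange(l, h) * vs for l, h in zip(lo, hi)], indexing="ij")
        pts = np.stack([s.ravel() for s in sub], axis=1)
        dmin = np.full(pts.shape[0], np.inf)
        for a, b in zip(poly[:-1], poly[1:]):
            ab = b - a
            denom = float(ab @ ab)
            tpar = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
            closest = a + np.outer(tpar, ab)
            dmin = np.minimum(dmin, np.linalg.norm(pts - closest, axis=1))
        hit = (dmin <= r).reshape(tuple(hi - lo))
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= hit

    total = sum(float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()) for p in polylines)
    truth = VesselTruth(polylines=polylines, radii=radii, total_length_mm=total)
    img = LabelImage(mask.astype(np.int32), np.diag([vs, vs, vs, 1.0]), {1: "vein"})
    return truth, img


# ---------------------------------------------------------------------------
# motion generator
# ---------------------------------------------------------------------------

@dataclass
class MotionSpec:
    """Time-varying deformation applied to beam nodes.

    Modes: ``rigid`` integrates a half-sine rotational acceleration
    pulse (peak velocity / duration presets 20 or 40 rad/s x 30 or
    60 ms) into a strain-free rigid rotation; ``affine`` applies a
    ramped linear map with closed-form axial strain; ``smooth-field``
    superposes localised Gaussian displacement bumps.
    """

    mode: str = "rigid"
    seed: int = 0
    peak_velocity_rad_s: float = 20.0
    duration_ms: float = 30.0
    dt_ms: float = 0.5
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    affine_matrix: np.ndarray | None = None  # target F for mode="affine"
    bump_amplitude_mm: float = 2.0
    bump_sigma_mm: float = 5.0
    n_bumps: int = 1
    bump_centers: np.ndarray | None = None  # (K, 3) mm; random if None
    bump_radial: bool = False  # radial expansion (stretch-dominated) bumps
    background_affine: np.ndarray | None = None  # global F under the bumps


def _axis_angle_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    a = _unit(np.asarray(axis, dtype=float))
    kx = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def half_sine_velocity(t_ms: np.ndarray, peak_rad_s: float, duration_ms: float) -> np.ndarray:
    """Angular velocity (rad/s) from a half-sine acceleration pulse.

    alpha(t) = A sin(pi t / tau) on [0, tau]; the integral reaches the
    peak velocity exactly at t = tau and stays there.
    """
    tau = duration_ms * 1e-3
    t = np.asarray(t_ms, dtype=float) * 1e-3
    amp = np.pi * peak_rad_s / (2 * tau)
    omega = amp * tau / np.pi * (1 - np.cos(np.pi * np.clip(t, 0, tau) / tau))
    omega[t >= tau] = peak_rad_s
    return omega


def motion_generator(
    spec: MotionSpec,
    nodes: np.ndarray,
    elements: np.ndarray,
) -> tuple[Trajectory, np.ndarray | None]:
    """Animate beam nodes and return (Trajectory, analytic strain or None).

    The analytic per-element strain (T, E) is exact for ``rigid``
    (identically zero) and ``affine`` (closed form from the applied
    linear map); for ``smooth-field`` it is None and tests derive truth
    from the deformed endpoint positions directly.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    elements = np.asarray(elements, dtype=np.int64).reshape(-1, 2)
    n_steps = int(round(spec.duration_ms / spec.dt_ms)) + 1
    times = np.arange(n_steps) * spec.dt_ms
    center = nodes.mean(axis=0)
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "rigid":
        tau = spec.duration_ms * 1e-3
        t = times * 1e-3
        amp = np.pi * spec.peak_velocity_rad_s / (2 * tau)
        # theta(t) = integral of omega = (A tau / pi) (t - (tau/pi) sin(pi t/tau))
        theta = amp * tau / np.pi * (t - tau / np.pi * np.sin(np.pi * np.clip(t, 0, tau) / tau))
        positions = np.empty((n_steps, nodes.shape[0], 3))
        for i, th in enumerate(theta):
            rot = _axis_angle_matrix(np.asarray(spec.axis), float(th))
            positions[i] = (nodes - center) @ rot.T + center
        truth = np.zeros((n_steps, elements.shape[0]))
    elif spec.mode == "affine":
        target = np.asarray(
            spec.affine_matrix if spec.affine_matrix is not None else np.diag([1.1, 1.0, 1.0]),
            dtype=float,
        )
        ramp = times / times[-1] if times[-1] > 0 else np.ones_like(times)
        positions = np.empty((n_steps, nodes.shape[0], 3))
        truth = np.empty((n_steps, elements.shape[0]))
        u0 = nodes[elements[:, 1]] - nodes[elements[:, 0]]
        l0 = np.linalg.norm(u0, axis=1)
        for i, s in enumerate(ramp):
            f_mat = np.eye(3) + s * (target - np.eye(3))
            positions[i] = (nodes - center) @ f_mat.T + center
            truth[i] = np.linalg.norm(u0 @ f_mat.T, axis=1) / l0 - 1.0
    elif spec.mode == "smooth-field":
        if spec.bump_centers is not None:
            centers = np.atleast_2d(np.asarray(spec.bump_centers, dtype=float))
        else:
            lo, hi = nodes.min(axis=0), nodes.max(axis=0)
            centers = rng.uniform(lo, hi, size=(spec.n_bumps, 3))
        dirs = rng.normal(size=(centers.shape[0], 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ramp = np.sin(np.pi * times / times[-1]) ** 2 if times[-1] > 0 else np.ones_like(times)
        sig2 = spec.bump_sigma_mm**2
        disp = np.zeros_like(nodes)
        for c, d in zip(centers, dirs):
            w = np.exp(-np.sum((nodes - c) ** 2, axis=1) / (2 * sig2))
            if spec.bump_radial:
                # localized radial expansion: stretches elements of every
                # orientation around the centre instead of shearing them
                disp += spec.bump_amplitude_mm * w[:, None] * (nodes - c) / spec.bump_sigma_mm
            else:
                disp += spec.bump_amplitude_mm * w[:, None] * d
        if spec.background_affine is not None:
            f_bg = np.asarray(spec.background_affine, dtype=float)
            disp = disp + (nodes - center) @ (f_bg - np.eye(3)).T
        positions = nodes[None] + ramp[:, None, None] * disp[None]
        truth = None
    else:
        raise ValueError(f"unknown motion mode {spec.mode!r}")

    traj = Trajectory(times_ms=times, positions=positions, elements=elements)
    return traj, truth


# ---------------------------------------------------------------------------
# tract atlas phantom + microbleeds
# ---------------------------------------------------------------------------

def tract_atlas_phantom(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    blocks: tuple[int, int, int] = (2, 2, 1),
    gap_vox: int = 1,
) -> LabelImage:
    """Partition the grid into labelled blocks standing in for tracts.

    ``gap_vox`` background voxels separate adjacent blocks so modal
    dilation has something to fill.
    """
    vox = np.zeros(shape, dtype=np.int32)
    edges = [np.linspace(0, n, b + 1).astype(int) for n, b in zip(shape, blocks)]
    table: dict[int, str] = {}
    lid = 0
    for ix in range(blocks[0]):
        for iy in range(blocks[1]):
            for iz in range(blocks[2]):
                lid += 1
                sl = tuple(
                    slice(e[i] + (gap_vox if e[i] > 0 else 0), e[i + 1])
                    for e, i in zip(edges, (ix, iy, iz))
                )
                vox[sl] = lid
                table[lid] = f"tract {lid}"
    return LabelImage(vox, np.asarray(affine, dtype=float), table)


def plant_microbleeds(
    strain_map: VoxelMap,
    atlas: LabelImage,
    rule: str = "top-strain-tract",
    seed: int = 0,
    cluster_radius_vox: int = 1,
) -> np.ndarray:
    """Place a small microbleed cluster guided by the strain map.

    ``top-strain-tract`` centres the cluster on the peak-strain voxel of
    the tract with the highest 95th-percentile strain;
    ``random-tract`` picks the tract with a seeded RNG instead.  The
    cluster is intersected with the chosen tract so exactly one tract
    carries the microbleed.  An all-zero map raises.
    """
    data = strain_map.data
    if not np.any(data > 0):
        raise ValueError("all-zero strain map: nowhere to plant a microbleed")
    if data.shape != atlas.shape:
        raise ValueError("strain map and atlas geometry differ")
    ids = [int(i) for i in np.unique(atlas.voxels) if i != 0]
    scored = []
    for lid in ids:
        vals = data[(atlas.voxels == lid) & (data > 0)]
        if vals.size:
            scored.append((lid, float(np.percentile(vals, 95))))
    if not scored:
        raise ValueError("no positive strain inside any tract")
    if rule == "top-strain-tract":
        target = max(scored, key=lambda kv: kv[1])[0]
    elif rule == "random-tract":
        rng = np.random.default_rng(seed)
        target = int(rng.choice([lid for lid, _ in scored]))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    inside = (atlas.voxels == target) & (data > 0)
    masked = np.where(inside, data, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), data.shape)
    mask = np.zeros(data.shape, dtype=bool)
    r = cluster_radius_vox
    sl = tuple(slice(max(0, p - r), min(n, p + r + 1)) for p, n in zip(peak, data.shape))
    mask[sl] = True
    mask &= atlas.voxels == target
    return mask


# ---------------------------------------------------------------------------
# CORA fixtures
# ---------------------------------------------------------------------------

@dataclass
class CoraPairSpec:
    """Reference curve plus a recorded perturbation of its copy."""

    seed: int = 0
    duration_ms: float = 60.0
    dt_ms: float = 0.1
    shift_ms: float = 0.0
    gain: float = 1.0
    noise_sigma: float = 0.0
    waveform: str = "half-sine"  # or "damped-sine"


def cora_pair(spec: CoraPairSpec | None = None) -> tuple[CurvePair, dict]:
    """Reference = base waveform; test = shifted/scaled/noisy copy."""
    spec = spec or CoraPairSpec()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_ms + spec.dt_ms / 2, spec.dt_ms)
    if spec.waveform == "half-sine":
        base = np.sin(np.pi * t / spec.duration_ms)
    elif spec.waveform == "damped-sine":
        base = np.sin(2 * np.pi * t / (spec.duration_ms / 3)) * np.exp(-t / spec.duration_ms)
    else:
        raise ValueError(f"unknown waveform {spec.waveform!r}")

    def wave(tq):
        return np.interp(tq, t, base, left=0.0, right=0.0)

    test = spec.gain * wave(t - spec.shift_ms)
    if spec.noise_sigma > 0:
        test = test + rng.normal(0.0, spec.noise_sigma, size=t.size)
    pair = CurvePair(t, base, test)
    perturbation = {"shift_ms": spec.shift_ms, "gain": spec.gain,
                    "noise_sigma": spec.noise_sigma}
    return pair, perturbation
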