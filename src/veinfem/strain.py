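"""Axial strain / strain-rate post-processing of beam trajectories.

The solver records vein beam node coordinates every 0.5 ms.  From the
inter-node distance L(t) of each 2-node element we compute engineering
axial strain eps(t) = (L(t) - L0) / L0 and its time derivative by
central finite differences, take per-element peaks over time, scatter
the peaks into a voxel grid aligned with the model's T1 image (max on
collision), and smooth the sparse map with a max-dilation then a
mean-of-nonzero dilation over a spherical 5 mm footprint (the
fslmaths dilF-then-dilM semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Trajectory",
    "StrainHistory",
    "VoxelMap",
    "axial_strain_history",
    "peak_fields",
    "voxelize_peaks",
    "smooth_map",
    "spherical_footprint",
]


@dataclass
class Trajectory:
    """Beam node positions on a uniform time base.

    positions: (T, N, 3) mm; times: (T,) ms; elements: (E, 2) node row
    indices.
    """

    times_ms: np.ndarray
    positions: np.ndarray
    elements: np.ndarray
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 2)
        if self.times_ms.ndim != 1 or self.times_ms.size < 2:
            raise ValueError("need at least 2 time samples")
        steps = np.diff(self.times_ms)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time base must be uniform")
        if self.positions.shape[0] != self.times_ms.size or self.positions.ndim != 3:
            raise ValueError("positions must be (T, N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.node_ids is None:
            self.node_ids = np.arange(self.positions.shape[1])

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass
class StrainHistory:
    """Per-element axial strain (dimensionless) and strain rate (1/s)."""

    times_ms: np.ndarray
    strain: np.ndarray  # (T, E)
    strain_rate: np.ndarray  # (T, E)

    @property
    def peak_strain(self) -> np.ndarray:
        return self.strain.max(axis=0)

    @property
    def peak_strain_rate(self) -> np.ndarray:
        return self.strain_rate.max(axis=0)


@dataclass
class VoxelMap:
    """3-D value grid aligned to a reference image geometry."""

    data: np.ndarray
    affine: np.ndarray
    fill_rule: str = "max"
    provenance: dict = field(default_factory=dict)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


def axial_strain_history(traj: Trajectory) -> StrainHistory:
    """Engineering axial strain and central-difference strain rate.

    eps(t) = (L(t) - L0) / L0 with L the inter-node distance;
    eps-dot on the stored time base (central differences, one-sided at
    the ends), reported in 1/s.
    """
    p = traj.positions
    e = traj.elements
    seg = p[:, e[:, 1], :] - p[:, e[:, 0], :]  # (T, E, 3)
    lengths = np.linalg.norm(seg, axis=2)
    l0 = lengths[0]
    zero = np.flatnonzero(l0 <= 0)
    if zero.size:
        raise ValueError(f"zero initial length in element(s) {zero.tolist()}")
    eps = lengths / l0 - 1.0
    dt_s = traj.dt_ms * 1e-3
    rate = np.gradient(eps, dt_s, axis=0)
    return StrainHistory(traj.times_ms.copy(), eps, rate)


def peak_fields(hist: StrainHistory) -> tuple[np.ndarray, np.ndarray]:
    """Per-element maxima of strain and strain rate over the history."""
    if hist.strain.size == 0:
        raise ValueError("empty strain history")
    return hist.strain.max(axis=0), hist.strain_rate.max(axis=0)


def voxelize_peaks(
    peaks: np.ndarray,
    traj: Trajectory,
    ref_shape: tuple[int, int, int],
    ref_affine: np.ndarray,
) -> VoxelMap:
    """Scatter per-element peaks into the voxel containing each element's
    undeformed (t0) midpoint; collisions keep the maximum.

    World -> voxel by inverse affine then floor (deterministic on
    boundaries); midpoints outside the grid are warned about, dropped
    and counted in the provenance.
    """
    peaks = np.asarray(peaks, dtype=float)
    e = traj.elements
    mid = 0.5 * (traj.positions[0, e[:, 0]] + traj.positions[0, e[:, 1]])
    inv = np.linalg.inv(np.asarray(ref_affine, dtype=float))
    vox = mid @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(vox).astype(int)
    shape = np.asarray(ref_shape, dtype=int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} element midpoint(s) outside the grid dropped",
                      stacklevel=2)
    data = np.zeros(tuple(shape))
    np.maximum.at(data, tuple(idx[inside].T), peaks[inside])
    return VoxelMap(
        data,
        np.asarray(ref_affine, dtype=float),
        fill_rule="max",
        provenance={"dropped_outside": n_out, "n_elements": int(e.shape[0])},
    )


def spherical_footprint(kernel_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Boolean sphere of radius kernel_mm on the voxel grid (centre included)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    r_vox = np.maximum(np.floor(kernel_mm / voxel_size).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, voxel_size))
    return dist2 <= kernel_mm**2 + 1e-9


def smooth_map(vmap: VoxelMap, kernel_mm: float = 5.0,
               voxel_size: np.ndarray | None = None) -> VoxelMap:
    """Max dilation then mean-of-nonzero dilation over a spherical footprint.

    Pass 1 replaces each voxel with the maximum over the footprint
    (dilF); pass 2 replaces each voxel with the mean of the non-zero
    pass-1 values over the footprint, zero if none (dilM).  A kernel
    smaller than one voxel is an identity with a warning.
    """
    if kernel_mm <= 0:
        raise ValueError("kernel must be positive")
    if voxel_size is None:
        voxel_size = np.linalg.norm(np.asarray(vmap.affine)[:3, :3], axis=0)
    if kernel_mm < float(np.min(voxel_size)):
        warnings.warn("kernel smaller than one voxel: returning input unchanged",
                      stacklevel=2)
        return VoxelMap(vmap.data.copy(), vmap.affine.copy(), vmap.fill_rule,
                        {**vmap.provenance, "smoothing": "identity"})
    fp = spherical_footprint(kernel_mm, voxel_size)
    pass1 = ndimage.maximum_filter(vmap.data, footprint=fp, mode="constant", cval=0.0)
    w = fp.astype(float)
    sums = ndimage.correlate(pass1, w, mode="constant", cval=0.0)
    counts = ndimage.correlate((pass1 > 0).astype(float), w, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), 0.0)
    return VoxelMap(out, vmap.affine.copy(), vmap.fill_rule,
                    {**vmap.provenance, "smoothing": f"dilF+dilM sphere {kernel_mm} mm"})
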