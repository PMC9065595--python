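"""Voxel label images.

A :class:`LabelImage` is the common currency of the toolkit: a 3-D integer
grid of tissue / ROI labels together with a NIfTI-style voxel-to-world
affine (world units mm, voxel centres at integer voxel coordinates,
0-based indices).  Label id 0 is reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelImage", "role_ids", "adjacent_pairs_6"]


@dataclass
class LabelImage:
    """3-D integer label grid with voxel-to-world geometry.

    Parameters
    ----------
    voxels
        3-D array of non-negative integer labels; 0 is background.
    affine
        4x4 voxel-to-world map (mm).  ``world = affine @ (i, j, k, 1)``.
    label_table
        Mapping of label id -> part name (e.g. ``{2: "skull"}``).
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer array")
        if self.voxels.min(initial=0) < 0:
            raise ValueError("label ids must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    # ---- geometry ---------------------------------------------------
    def world_from_voxel(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel coordinates to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    def voxel_from_world(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to continuous voxel coordinates."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    # ---- label bookkeeping ------------------------------------------
    def ids_matching(self, *substrings: str) -> set[int]:
        """Label ids whose part name contains any of ``substrings``."""
        subs = tuple(s.lower() for s in substrings)
        return {
            lid
            for lid, name in self.label_table.items()
            if any(s in name.lower() for s in subs)
        }

    def counts(self) -> dict[int, int]:
        """Voxel count per non-background label id."""
        ids, n = np.unique(self.voxels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, n) if i != 0}

    def copy(self) -> "LabelImage":
        return LabelImage(self.voxels.copy(), self.affine.copy(), dict(self.label_table))

    # ---- I/O --------------------------------------------------------
    @classmethod
    def from_nifti(cls, path, label_table: dict[int, str] | None = None) -> "LabelImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls(np.rint(data).astype(np.int32), np.asarray(img.affine), label_table or {})

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.voxels.astype(np.int16), self.affine), str(path))


def role_ids(label_table: dict[int, str]) -> dict[str, set[int]]:
    """Group label ids into anatomical roles by part-name keywords.

    Roles: ``scalp``, ``skull``, ``csf``, ``brain`` (grey/white matter,
    hemispheres, brain stem, cerebellum), ``left``, ``right``,
    ``cerebellum``, ``cerebrum``, ``grey``, ``white``.
    """
    roles: dict[str, set[int]] = {k: set() for k in (
        "scalp", "skull", "csf", "brain", "left", "right",
        "cerebellum", "cerebrum", "grey", "white")}
    for lid, raw in label_table.items():
        name = raw.lower()
        if "scalp" in name or "skin" in name:
            roles["scalp"].add(lid)
        if "skull" in name:
            roles["skull"].add(lid)
        if "csf" in name or "cerebrospinal" in name:
            roles["csf"].add(lid)
        brainish = any(s in name for s in (
            "grey", "gray", "white", "brain stem", "brainstem",
            "hemisphere", "cerebellum", "cerebrum"))
        if brainish:
            roles["brain"].add(lid)
            if "cerebellum" in name:
                roles["cerebellum"].add(lid)
            else:
                roles["cerebrum"].add(lid)
        if "left" in name:
            roles["left"].add(lid)
        if "right" in name:
            roles["right"].add(lid)
        if "grey" in name or "gray" in name:
            roles["grey"].add(lid)
        if "white" in name:
            roles["white"].add(lid)
    return roles


def adjacent_pairs_6(voxels: np.ndarray, ids_a: set[int], ids_b: set[int]) -> int:
    """Count 6-adjacent voxel pairs with one label in ``ids_a``, other in ``ids_b``."""
    a = np.isin(voxels, sorted(ids_a))
    b = np.isin(voxels, sorted(ids_b))
    n = 0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        n += int(np.sum(a[lo] & b[hi]) + np.sum(b[lo] & a[hi]))
    return n
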