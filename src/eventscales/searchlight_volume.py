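"""Spherical searchlights over a voxel grid: generation, filters, aggregation, NIfTI I/O.

A searchlight is the set of in-mask voxels within a closed Euclidean ball
(radius in voxel units; anisotropic voxel sizes are ignored, appropriate for
isotropic acquisitions) around a center on a stride-spaced lattice.  Statistics
computed per searchlight are projected back to voxel space by averaging, at
each voxel, the values of all searchlights containing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SearchlightSet",
    "generate_searchlights",
    "participant_validity_filter",
    "voxel_aggregate",
    "extract_searchlight_data",
    "load_nifti",
    "save_voxel_map",
]


@dataclass
class SearchlightSet:
    """Searchlight centers and member voxels on a 3-D grid (0-based coordinates)."""

    centers: np.ndarray  # (N, 3) int
    members: list  # per searchlight, (m_i,) flat voxel indices into mask_shape
    radius: float
    stride: int
    mask_shape: tuple

    def __len__(self) -> int:
        return len(self.members)

    def to_json(self) -> str:
        return json.dumps(
            {
                "radius": self.radius,
                "stride": self.stride,
                "mask_shape": list(self.mask_shape),
                "centers": self.centers.tolist(),
                "members": [m.tolist() for m in self.members],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SearchlightSet":
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"], dtype=int),
            members=[np.asarray(m, dtype=int) for m in d["members"]],
            radius=d["radius"],
            stride=d["stride"],
            mask_shape=tuple(d["mask_shape"]),
        )


def _ball_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with dx^2 + dy^2 + dz^2 <= radius^2."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def generate_searchlights(
    mask: np.ndarray,
    radius: float = 5.0,
    stride: int = 5,
    min_voxels: int = 20,
    offset=(0, 0, 0),
) -> SearchlightSet:
    """Spherical searchlights on a stride-spaced lattice over a binary mask.

    Centers start at ``offset`` (default the grid origin) and step by
    ``stride`` along each axis; membership is every in-mask voxel within
    Euclidean distance ``radius`` (voxel units) of the center; searchlights
    with fewer than ``min_voxels`` members are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3-D binary volume")
    offsets = _ball_offsets(radius)
    shape = mask.shape
    centers, members = [], []
    axes = [np.arange(offset[i], shape[i], stride) for i in range(3)]
    for cx in axes[0]:
        for cy in axes[1]:
            for cz in axes[2]:
                pts = offsets + np.array([cx, cy, cz])
                ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
                pts = pts[ok]
                inside = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
                pts = pts[inside]
                if pts.shape[0] >= min_voxels:
                    centers.append((cx, cy, cz))
                    members.append(
                        np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), shape)
                    )
    if not centers:
        raise ValueError(
            "no searchlight met min_voxels; lower min_voxels/stride or enlarge the mask"
        )
    return SearchlightSet(
        centers=np.asarray(centers, dtype=int),
        members=members,
        radius=float(radius),
        stride=int(stride),
        mask_shape=shape,
    )


def participant_validity_filter(
    validity: np.ndarray,
    searchlights: SearchlightSet,
    min_participants: int = 15,
) -> np.ndarray:
    """Indices of searchlights with enough participants having valid data.

    ``validity`` is boolean, (n_participants, n_voxels_flat) or
    (n_participants, n_viewings, n_voxels_flat).  A participant counts as
    valid for a searchlight iff every member voxel is valid (on every viewing
    when the viewing axis is present); the searchlight is retained iff at
    least ``min_participants`` participants are valid.
    """
    v = np.asarray(validity, dtype=bool)
    if v.ndim == 3:
        v = v.all(axis=1)
    keep = []
    for i, mem in enumerate(searchlights.members):
        n_valid = v[:, mem].all(axis=1).sum()
        if n_valid >= min_participants:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def voxel_aggregate(values, searchlights: SearchlightSet) -> np.ndarray:
    """Project per-searchlight scalars to a voxel map by averaging over coverage.

    Each voxel's value is the mean over all searchlights containing it;
    voxels covered by no searchlight are NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(searchlights):
        raise ValueError("need one value per searchlight")
    shape = searchlights.mask_shape
    total = np.zeros(int(np.prod(shape)))
    count = np.zeros(int(np.prod(shape)))
    for val, mem in zip(values, searchlights.members):
        total[mem] += val
        count[mem] += 1
    out = np.full(total.shape, np.nan)
    covered = count > 0
    out[covered] = total[covered] / count[covered]
    return out.reshape(shape)


def extract_searchlight_data(volume4d: np.ndarray, searchlights: SearchlightSet):
    """Per-searchlight voxel x time matrices from a 4-D (x, y, z, t) volume."""
    vol = np.asarray(volume4d)
    flat = vol.reshape(-1, vol.shape[-1])
    return [flat[mem] for mem in searchlights.members]


def load_nifti(path):
    """(data, affine) from a .nii/.nii.gz volume."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_voxel_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a voxel map as NIfTI, carrying the input affine through unchanged."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
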