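"""Volume reorientation, sub-volume extraction along the tendon axis, and
the cross-sectional-area procedure used to quantify shrinkage.

Convention: (z, y, x) axis order, 0-based voxel indices, z is the tendon
axis after reorientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ComputationError, ValidationError
from .volume import SubVolume, VolumeStack

#: Minimum largest/second principal-eigenvalue ratio for a defined axis.
MIN_ANISOTROPY = 1.5


@dataclass
class AreaProfile:
    """Per-block cross-sectional areas over the central tendon region."""

    areas_mm2: np.ndarray  # one entry per slice block
    block_slices: int
    z_starts: np.ndarray  # first slice index of each block (parent volume)
    mean_mm2: float
    sd_mm2: float


def _foreground_mask(volume: VolumeStack) -> np.ndarray:
    data = volume.data
    if not data.max() > data.min():
        raise ComputationError("constant volume: no foreground")
    thr = threshold_otsu(data, nbins=256)
    return data > thr


def _principal_axes(mask: np.ndarray):
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] < 2:
        raise ComputationError("foreground too small for axis estimation")
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return centroid, evals[::-1], evecs[:, ::-1]


def reorient(volume: VolumeStack) -> VolumeStack:
    """Rotate the volume so the dominant elongated axis is parallel to z.

    The foreground (voxels above the whole-volume Otsu threshold) must have
    one dominant principal axis (largest/second eigenvalue ratio >= 1.5);
    the rotation aligning that axis with z is applied by trilinear
    resampling about the volume center and recorded in the metadata.
    """
    mask = _foreground_mask(volume)
    centroid, evals, evecs = _principal_axes(mask)
    if evals[1] <= 0 or evals[0] / evals[1] < MIN_ANISOTROPY:
        raise ComputationError(
            "axis undefined: foreground is isotropic (eigenvalue ratio "
            f"{evals[0] / max(evals[1], 1e-300):.2f} < {MIN_ANISOTROPY})"
        )
    axis = evecs[:, 0]
    if axis[0] < 0:
        axis = -axis  # keep the +z hemisphere

    z_hat = np.array([1.0, 0.0, 0.0])  # (z, y, x) order
    v = np.cross(axis, z_hat)
    s, c = np.linalg.norm(v), float(np.dot(axis, z_hat))
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)  # Rodrigues

    center = (np.array(volume.shape) - 1) / 2.0
    # affine_transform maps output coords through the matrix: x_in = R^T x_out
    # rotates the volume content by R.
    data = ndimage.affine_transform(
        volume.data,
        rot.T,
        offset=center - rot.T @ center,
        order=1,
        mode="nearest",
    )
    meta = dict(volume.metadata)
    meta["reorient"] = {
        "rotation_matrix": rot.tolist(),
        "eigenvalue_ratio": float(evals[0] / evals[1]),
    }
    return VolumeStack(data, volume.voxel_size, meta)


def extract_subvolumes(
    volume: VolumeStack,
    count: int,
    size: int,
    stride: int,
    content_label: str = "fibers",
) -> list[SubVolume]:
    """Cut ``count`` cubic sub-volumes at regular z offsets along the axis.

    Sub-volumes are ``size`` voxels on edge, spaced ``stride`` voxels apart
    in z (disjoint when stride >= size, matching the repeated-measurement
    protocol of three repeats per sample), and centered in x, y on the
    foreground centroid. The whole span is centered in z.
    """
    if count < 1 or size < 1 or stride < 1:
        raise ValidationError("count, size and stride must be >= 1")
    nz, ny, nx = volume.shape
    span = (count - 1) * stride + size
    if span > nz:
        max_count = max(0, (nz - size) // stride + 1) if size <= nz else 0
        raise ValidationError(
            f"{count} sub-volumes of {size} voxels at stride {stride} need "
            f"{span} slices but only {nz} exist; maximum feasible count is "
            f"{max_count}"
        )
    if size > ny or size > nx:
        raise ValidationError(
            f"sub-volume edge {size} exceeds the in-plane extent ({ny}, {nx})"
        )
    mask = _foreground_mask(volume)
    _, cy, cx = ndimage.center_of_mass(mask)
    y0 = int(np.clip(round(cy - size / 2), 0, ny - size))
    x0 = int(np.clip(round(cx - size / 2), 0, nx - size))
    z_first = (nz - span) // 2
    subs = []
    for k in range(count):
        z0 = z_first + k * stride
        subs.append(
            SubVolume(
                data=volume.data[z0:z0 + size, y0:y0 + size, x0:x0 + size],
                voxel_size=volume.voxel_size,
                content_label=content_label,  # type: ignore[arg-type]
                origin=(z0, y0, x0),
            )
        )
    return subs


def cross_section_area(
    volume: VolumeStack, block: int = 100, central_extent_um: float = 500.0
) -> AreaProfile:
    """Cross-sectional area of the tendon over its central region.

    The tissue outline is not separable from the background on single
    slices, so contrast is first enhanced by a maximum-intensity projection
    over every ``block`` slices within the central z-window of
    ``central_extent_um``. Each block MIP is binarized (Otsu), holes are
    filled, the largest connected component kept, and its pixel count
    converted to mm². Blocks are non-overlapping, anchored at the window
    start; remainder slices are dropped.
    """
    if block < 1:
        raise ValidationError(f"block must be >= 1 slice, got {block}")
    nz = volume.shape[0]
    vs = volume.voxel_size
    window = min(nz, int(round(central_extent_um / vs)))
    if window < block:
        raise ValidationError(
            f"central extent {central_extent_um} µm spans {window} slices, "
            f"fewer than one block of {block}"
        )
    z0 = (nz - window) // 2
    n_blocks = window // block
    areas = np.empty(n_blocks)
    z_starts = np.empty(n_blocks, dtype=int)
    for b in range(n_blocks):
        zs = z0 + b * block
        mip = volume.data[zs:zs + block].max(axis=0)
        if not mip.max() > mip.min():
            raise ComputationError(f"empty foreground in block {b}: uniform MIP")
        binary = mip > threshold_otsu(mip, nbins=256)
        if not binary.any():
            raise ComputationError(f"empty foreground after binarization in block {b}")
        filled = ndimage.binary_fill_holes(binary)
        labels, n_lab = ndimage.label(filled)
        largest = np.argmax(ndimage.sum_labels(filled, labels, range(1, n_lab + 1))) + 1
        n_pix = int(np.count_nonzero(labels == largest))
        areas[b] = n_pix * (vs * 1e-3) ** 2  # µm² -> mm²
        z_starts[b] = zs
    return AreaProfile(
        areas_mm2=areas,
        block_slices=block,
        z_starts=z_starts,
        mean_mm2=float(areas.mean()),
        sd_mm2=float(areas.std(ddof=1)) if n_blocks > 1 else 0.0,
    )
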