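"""Synthetic tendon phantoms: parallel collagen fibers in matrix, fat-cell
spheres, and controlled degradation (blur, noise, ring artifacts).

The generator emulates the two structural motifs that drive the quality
analysis: tightly packed bright cylinders running along the tendon axis
(collagen fibers, hexagonally packed, optionally crimped) in a darker
non-collagenous matrix, and bright spheres with sharp borders (fat cells).
Every generator is a pure function of its spec and seed: identical inputs
give bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import VolumeStack


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic tendon generator.

    All geometric fields are in µm; gray levels are abstract floats with
    ``fiber_level > matrix_level`` (fibers image brighter than the
    inter-fiber matrix). ``psf_sigma`` models detector/scintillator blur,
    ``noise_sigma`` additive Gaussian noise, ``ring_amplitude`` a radial
    sinusoidal bias emulating ring artifacts.
    """

    shape: tuple[int, int, int] = (64, 64, 64)  # (nz, ny, nx) voxels
    voxel_size: float = 1.63  # µm
    fiber_radius: float = 8.0  # µm
    fiber_gap: float = 3.0  # µm of matrix rim between adjacent fibers
    fiber_level: float = 1.0
    matrix_level: float = 0.0
    crimp_amplitude: float = 0.0  # µm, sinusoidal centerline displacement
    crimp_period: float = 100.0  # µm
    sphere_radius_range: tuple[float, float] = (8.0, 20.0)  # µm (fat cells)
    sphere_count: int = 8
    psf_sigma: float = 0.0  # µm
    noise_sigma: float = 0.0  # gray units
    ring_amplitude: float = 0.0  # gray units
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValidationError(f"shape must be 3D with every dim >= 16, got {shape}")
        self.shape = shape
        for name in ("voxel_size", "fiber_radius", "crimp_period"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("fiber_gap", "crimp_amplitude", "psf_sigma",
                     "noise_sigma", "ring_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.fiber_level > self.matrix_level:
            raise ValidationError(
                "fiber_level must exceed matrix_level "
                f"({self.fiber_level} <= {self.matrix_level})"
            )
        lo, hi = self.sphere_radius_range
        if not (0 < lo <= hi):
            raise ValidationError(
                f"sphere_radius_range must be 0 < lo <= hi, got {(lo, hi)}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(d["shape"])
        d["sphere_radius_range"] = list(d["sphere_radius_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "sphere_radius_range" in d:
            d["sphere_radius_range"] = tuple(d["sphere_radius_range"])
        return cls(**d)


def _hex_lattice_distance(y: np.ndarray, x: np.ndarray, pitch: float) -> np.ndarray:
    """Distance from each (y, x) point (in µm) to the nearest center of a
    hexagonal lattice with center spacing ``pitch``.

    Rows are spaced pitch·√3/2 apart in y; odd rows are shifted pitch/2 in x.
    Vectorized by folding coordinates onto the candidate rows adjacent to
    each point.
    """
    dy = pitch * np.sqrt(3.0) / 2.0
    j0 = np.floor(y / dy).astype(int)
    best = np.full(np.broadcast(y, x).shape, np.inf)
    for j in (j0, j0 + 1):
        x_off = np.where(j % 2 == 0, 0.0, pitch / 2.0)
        cx = x_off + pitch * np.round((x - x_off) / pitch)
        cy = j * dy
        d = np.hypot(x - cx, y - cy)
        best = np.minimum(best, d)
    return best


def make_fiber_phantom(spec: PhantomSpec) -> VolumeStack:
    """Generate parallel fibers on a hexagonal lattice, axes along z.

    Cylinders of radius ``fiber_radius`` with center spacing
    ``2·fiber_radius + fiber_gap`` (densest packing of the "tightly packed"
    fiber bundle); if ``crimp_amplitude > 0`` the centerlines are displaced
    sinusoidally in x with period ``crimp_period``. No degradation is
    applied; voxels are exactly ``fiber_level`` inside and ``matrix_level``
    outside.
    """
    nz, ny, nx = spec.shape
    pitch = 2.0 * spec.fiber_radius + spec.fiber_gap
    fov_x = nx * spec.voxel_size
    fov_y = ny * spec.voxel_size
    if pitch > fov_x:
        raise ValidationError(
            f"fiber spacing {pitch:g} µm exceeds the x field of view "
            f"{fov_x:g} µm: no fiber fits in x"
        )
    if pitch * np.sqrt(3.0) / 2.0 > fov_y:
        raise ValidationError(
            f"fiber row spacing {pitch * np.sqrt(3.0) / 2.0:g} µm exceeds the "
            f"y field of view {fov_y:g} µm: no fiber fits in y"
        )

    # Voxel-center physical coordinates.
    yy = (np.arange(ny)[:, None] + 0.5) * spec.voxel_size
    xx = (np.arange(nx)[None, :] + 0.5) * spec.voxel_size

    vol = np.empty(spec.shape, dtype=float)
    if spec.crimp_amplitude == 0:
        dist = _hex_lattice_distance(yy, xx, pitch)
        sl = np.where(dist <= spec.fiber_radius, spec.fiber_level, spec.matrix_level)
        vol[:] = sl[None, :, :]
    else:
        for iz in range(nz):
            z_um = (iz + 0.5) * spec.voxel_size
            dx = spec.crimp_amplitude * np.sin(2.0 * np.pi * z_um / spec.crimp_period)
            dist = _hex_lattice_distance(yy, xx - dx, pitch)
            vol[iz] = np.where(
                dist <= spec.fiber_radius, spec.fiber_level, spec.matrix_level
            )

    meta = {
        "generator": "fiber",
        "lattice": "hexagonal",
        "pitch_um": pitch,
        "spec": spec.to_dict(),
    }
    return VolumeStack(vol, spec.voxel_size, meta)


def make_fat_cell_phantom(spec: PhantomSpec) -> VolumeStack:
    """Generate non-overlapping bright spheres (fat cells) on a dark matrix.

    Radii are drawn uniformly from ``sphere_radius_range`` and centers by
    rejection sampling so that spheres lie fully inside the volume and do
    not overlap. Deterministic under ``spec.seed``.
    """
    if spec.sphere_count < 1:
        raise ValidationError(f"sphere_count must be >= 1, got {spec.sphere_count}")
    nz, ny, nx = spec.shape
    vs = spec.voxel_size
    rng = np.random.default_rng(spec.seed)

    placed: list[tuple[float, float, float, float]] = []  # (z, y, x, r) in µm
    extent = np.array([nz, ny, nx], dtype=float) * vs
    max_attempts = 10_000
    attempts = 0
    while len(placed) < spec.sphere_count:
        if attempts >= max_attempts:
            raise ValidationError(
                f"could not place {spec.sphere_count} non-overlapping spheres "
                f"in {max_attempts} attempts; placed {len(placed)}"
            )
        attempts += 1
        r = rng.uniform(*spec.sphere_radius_range)
        if np.any(extent < 2 * r):
            continue  # sphere larger than the volume in some direction
        c = rng.uniform(r, extent - r)
        if all(np.linalg.norm(c - np.array(p[:3])) > r + p[3] for p in placed):
            placed.append((c[0], c[1], c[2], r))

    vol = np.full(spec.shape, spec.matrix_level, dtype=float)
    for cz, cy, cx, r in placed:
        # Local bounding box in voxel indices.
        lo = np.maximum(np.floor((np.array([cz, cy, cx]) - r) / vs).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.array([cz, cy, cx]) + r) / vs).astype(int) + 1,
            np.array(spec.shape),
        )
        zz = (np.arange(lo[0], hi[0])[:, None, None] + 0.5) * vs - cz
        yy = (np.arange(lo[1], hi[1])[None, :, None] + 0.5) * vs - cy
        xx = (np.arange(lo[2], hi[2])[None, None, :] + 0.5) * vs - cx
        inside = zz**2 + yy**2 + xx**2 <= r**2
        sub = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = spec.fiber_level

    meta = {
        "generator": "fat_cells",
        "spheres": [list(p) for p in placed],
        "spec": spec.to_dict(),
    }
    return VolumeStack(vol, vs, meta)


def degrade(
    volume: VolumeStack,
    psf_sigma: float,
    noise_sigma: float,
    ring_amplitude: float,
    seed: int = 0,
) -> VolumeStack:
    """Apply instrument-like degradation: blur, then noise, then rings.

    Order is fixed: (1) 3D Gaussian blur of ``psf_sigma`` µm (converted to
    voxels, reflective boundaries so edge slices stay usable); (2) additive
    zero-mean Gaussian noise of SD ``noise_sigma`` gray units; (3) a
    concentric-ring bias field ``ring_amplitude · sin(r)`` with ``r`` the
    in-plane distance (voxels) from the volume center axis, identical for
    every slice — the simplest structure that defeats naive thresholding.
    """
    for name, v in (("psf_sigma", psf_sigma), ("noise_sigma", noise_sigma),
                    ("ring_amplitude", ring_amplitude)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")

    data = np.asarray(volume.data, dtype=float)
    if psf_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=psf_sigma / volume.voxel_size, mode="reflect"
        )
    else:
        data = data.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    if ring_amplitude > 0:
        _, ny, nx = data.shape
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        rr = np.hypot(
            np.arange(ny)[:, None] - cy, np.arange(nx)[None, :] - cx
        )
        data += ring_amplitude * np.sin(rr)

    meta = dict(volume.metadata)
    meta["degrade"] = {
        "psf_sigma_um": psf_sigma,
        "noise_sigma": noise_sigma,
        "ring_amplitude": ring_amplitude,
        "seed": seed,
        "order": "blur->noise->rings",
    }
    return VolumeStack(data, volume.voxel_size, meta)


def make_cylinder_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    radius_um: float,
    inside_level: float = 1.0,
    outside_level: float = 0.0,
    tilt_deg: float = 0.0,
) -> VolumeStack:
    """A single solid cylinder along z — the whole-tendon stand-in used for
    reorientation and cross-sectional-area checks.

    ``tilt_deg`` tips the cylinder axis in the xz-plane; the cross-section
    stays the circle of ``radius_um`` in each slice (small-angle shear
    model), which keeps the per-slice area analytic.
    """
    if radius_um <= 0:
        raise ValidationError(f"radius_um must be > 0, got {radius_um}")
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy = (np.arange(ny)[:, None] - cy) * voxel_size
    slope = np.tan(np.deg2rad(tilt_deg))
    vol = np.empty(shape, dtype=float)
    for iz in range(nz):
        cxz = cx + slope * (iz - (nz - 1) / 2.0)
        xx = (np.arange(nx)[None, :] - cxz) * voxel_size
        inside = yy**2 + xx**2 <= radius_um**2
        vol[iz] = np.where(inside, inside_level, outside_level)
    meta = {"generator": "cylinder", "radius_um": radius_um, "tilt_deg": tilt_deg}
    return VolumeStack(vol, voxel_size, meta)


def project_thickness(binary: np.ndarray, voxel_size: float) -> np.ndarray:
    """Line-integral of a binary volume along the beam axis (y).

    Material thickness per pixel = (foreground voxels along y) · voxel size,
    in µm, as a non-negative (nz, nx) map. An empty volume projects to the
    all-zero map.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise ValidationError("binary volume must be 3D (z, y, x)")
    return binary.sum(axis=1).astype(float) * voxel_size


def make_phase_object(spec: PhantomSpec, kind: str = "fat_cells") -> np.ndarray:
    """Projected-thickness map (µm per pixel) of the binary phantom.

    Input to the Fresnel forward model: the undegraded fiber or fat-cell
    phantom is binarized at the level midpoint and integrated along y (the
    beam axis for a projection with the rotation axis z).
    """
    if kind == "fat_cells":
        vol = make_fat_cell_phantom(spec)
    elif kind == "fibers":
        vol = make_fiber_phantom(spec)
    else:
        raise ValidationError(f"kind must be 'fibers' or 'fat_cells', got {kind!r}")
    mid = 0.5 * (spec.fiber_level + spec.matrix_level)
    return project_thickness(vol.data > mid, spec.voxel_size)
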