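"""The four image-quality metrics for fiber/fat-cell sub-volumes.

* **Spatial resolution** — power-spectral-density (PSD) criterion: 1D line
  profiles in x and y on three z-slices, averaged PSDs, and the lowest
  spatial frequency at which the smoothed PSD falls to twice the
  high-frequency noise floor; reported as the full period 1/f* in µm.
* **FMCR** — fiber-to-matrix contrast ratio, the contrast-to-noise ratio
  with fibers as signal and the inter-fiber matrix as background:
  (Im_F − Im_M) / sqrt((σ²_F + σ²_M)/2).
* **UTS** — uncertainty of threshold-based segmentation: the percentage of
  voxels whose gray value falls between the threshold that precisely
  selects the matrix and the one that precisely selects the fibers, both
  obtained from a three-class Otsu decomposition of the histogram.
* **GSE** — gradient sharpness at edges: mean per-slice gradient magnitude
  over edge voxels (edges classified by Otsu's threshold on the
  gradient-magnitude histogram), on fat-cell sub-volumes whose spheres
  have sharp, well-defined borders.

All Otsu computations use a fixed 256-bin histogram over the sub-volume
min–max so results are deterministic and directly comparable against an
exhaustive threshold search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .errors import ComputationError, ValidationError
from .volume import SubVolume

N_BINS = 256
#: Minimum voxel count per mask for FMCR — statistical floor so the two
#: means/SDs are well estimated.
MIN_MASK_VOXELS = 1_000


@dataclass
class QualityResult:
    """Per-sub-volume metric values with provenance."""

    content_label: str
    origin: tuple[int, int, int]
    resolution_um: float | None = None
    fmcr: float | None = None
    uts_pct: float | None = None
    gse: float | None = None
    params: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "content_label": self.content_label,
            "origin_z": self.origin[0],
            "origin_y": self.origin[1],
            "origin_x": self.origin[2],
            "resolution_um": self.resolution_um,
            "fmcr": self.fmcr,
            "uts_pct": self.uts_pct,
            "gse": self.gse,
        }
        for k, v in sorted(self.params.items()):
            row[k] = v
        return row


@dataclass
class MetricSummary:
    """Mean ± sample SD and coefficient of variability over repeats."""

    mean: float
    sd: float
    cv: float
    n_repeats: int


def summarize(values) -> MetricSummary:
    """Mean, sample SD (n−1 denominator) and CV = SD/mean of repeats."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValidationError(f"need at least 2 repeats, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mean == 0:
        raise ComputationError("CV undefined: mean of repeats is 0")
    return MetricSummary(mean=mean, sd=sd, cv=sd / abs(mean), n_repeats=int(vals.size))


# ---------------------------------------------------------------------------
# Spatial resolution (PSD criterion)
# ---------------------------------------------------------------------------

#: Fraction of the highest frequencies used to estimate the noise floor.
FLOOR_FRACTION = 0.1
#: Width (frequency samples) of the moving-average smoothing of the PSD.
PSD_SMOOTH = 5


def _slice_indices(nz: int, n_slices: int) -> np.ndarray:
    idx = np.unique(np.linspace(0, nz - 1, n_slices).round().astype(int))
    return idx


def estimate_resolution(sub: SubVolume, n_slices: int = 3) -> float:
    """Spatial resolution in µm from the PSD noise-floor criterion.

    For ``n_slices`` z-slices (top, middle, end of the sub-volume) the 1D
    periodograms of every row (x direction) and every column (y direction)
    are averaged. The noise floor L is the median PSD over the top 10% of
    frequencies; the resolution period is 1/f* where f* is the lowest
    frequency at which the smoothed PSD first falls to 2L. Periods are
    clamped below at the Nyquist period 2·voxel_size (a flat, pure-noise
    spectrum saturates there), and the per-slice, per-direction estimates
    are averaged.

    Raises
    ------
    ComputationError
        If the PSD never reaches 2L (signal above the noise floor at every
        frequency); a larger sub-volume is needed.
    ValidationError
        If the sub-volume is not fiber-labeled or any dimension is < 64.
    """
    if sub.content_label != "fibers":
        raise ValidationError("resolution is defined on fiber sub-volumes")
    if min(sub.shape) < 64:
        raise ValidationError(
            f"every dimension must be >= 64 voxels for a usable spectrum, "
            f"got {sub.shape}"
        )
    nz = sub.shape[0]
    vs = sub.voxel_size
    nyquist_period = 2.0 * vs
    periods = []
    for iz in _slice_indices(nz, n_slices):
        sl = sub.data[iz]
        for profiles in (sl, sl.T):  # rows = x-profiles, then y-profiles
            freqs, psd = signal.periodogram(
                profiles, fs=1.0 / vs, axis=-1, detrend="constant"
            )
            psd_mean = psd.mean(axis=0)[1:]  # drop DC
            freqs = freqs[1:]
            n_floor = max(1, int(np.ceil(FLOOR_FRACTION * freqs.size)))
            floor = float(np.median(psd_mean[-n_floor:]))
            smoothed = ndimage.uniform_filter1d(psd_mean, PSD_SMOOTH, mode="nearest")
            below = smoothed <= 2.0 * floor
            if below[0]:
                # Spectrum already at the noise floor at the lowest
                # frequency: noise-limited, saturate at Nyquist.
                periods.append(nyquist_period)
                continue
            if not below.any():
                raise ComputationError(
                    "PSD never falls to twice the noise floor (signal above "
                    "noise at every frequency); use a larger sub-volume"
                )
            f_star = float(freqs[int(np.argmax(below))])
            periods.append(max(1.0 / f_star, nyquist_period))
    return float(np.mean(periods))


# ---------------------------------------------------------------------------
# Fiber-to-matrix contrast ratio
# ---------------------------------------------------------------------------

def fmcr(sub: SubVolume, fiber_mask: np.ndarray, matrix_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio between fiber and matrix regions.

    FMCR = (Im_F − Im_M) / sqrt((σ²_F + σ²_M)/2) with Im the mean voxel
    value and σ the standard deviation inside each mask. The sign is
    preserved: inverted contrast yields a negative value.
    """
    fiber_mask = np.asarray(fiber_mask, dtype=bool)
    matrix_mask = np.asarray(matrix_mask, dtype=bool)
    if fiber_mask.shape != sub.shape or matrix_mask.shape != sub.shape:
        raise ValidationError("masks must match the sub-volume shape")
    if np.any(fiber_mask & matrix_mask):
        raise ValidationError("fiber and matrix masks overlap")
    nf, nm = int(fiber_mask.sum()), int(matrix_mask.sum())
    if nf < MIN_MASK_VOXELS or nm < MIN_MASK_VOXELS:
        raise ValidationError(
            f"each mask needs >= {MIN_MASK_VOXELS} voxels, got fibers={nf}, "
            f"matrix={nm}"
        )
    f_vals = sub.data[fiber_mask]
    m_vals = sub.data[matrix_mask]
    noise = np.sqrt(0.5 * (f_vals.var() + m_vals.var()))
    return float((f_vals.mean() - m_vals.mean()) / noise)


# ---------------------------------------------------------------------------
# Uncertainty of threshold-based segmentation
# ---------------------------------------------------------------------------

def three_class_otsu(hist: np.ndarray) -> tuple[int, int]:
    """Exact three-class Otsu on a histogram: the pair of threshold bin
    indices (i, j), i < j, maximizing the between-class variance of the
    classes [0..i], [i+1..j], [j+1..end].

    Fully exhaustive (vectorized over all ~N²/2 pairs); ties resolve to the
    smallest (i, j) in lexicographic order. Empty classes are permitted —
    for a perfectly bimodal histogram the middle class comes out empty.
    """
    h = np.asarray(hist, dtype=float)
    n = h.size
    if n < 3 or h.sum() <= 0:
        raise ValidationError("histogram must have >= 3 bins and positive mass")
    p = h / h.sum()
    bins = np.arange(n, dtype=float)
    cw = np.cumsum(p)  # cumulative weight up to and including bin k
    cm = np.cumsum(p * bins)  # cumulative first moment
    total_mean = cm[-1]

    i = np.arange(n - 2)[:, None]  # 0 .. n-3
    j = np.arange(1, n - 1)[None, :]  # 1 .. n-2
    valid = j > i

    w1 = cw[i] * np.ones_like(j, dtype=float)
    m1 = cm[i] * np.ones_like(j, dtype=float)
    w2 = cw[j] - cw[i]
    m2 = cm[j] - cm[i]
    w3 = 1.0 - cw[j] * np.ones_like(i, dtype=float)
    m3 = total_mean - cm[j] * np.ones_like(i, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = (
            np.where(w1 > 0, m1**2 / w1, 0.0)
            + np.where(w2 > 0, m2**2 / w2, 0.0)
            + np.where(w3 > 0, m3**2 / w3, 0.0)
        )
    bcv = np.where(valid, bcv, -np.inf)
    flat = int(np.argmax(bcv))  # row-major: smallest i, then smallest j
    ii, jj = divmod(flat, bcv.shape[1])
    return int(ii), int(jj + 1)


def uts(sub: SubVolume, prefilter_sigma: float | None = None) -> tuple[float, dict]:
    """Segmentation-uncertainty percentage and the thresholds used.

    Optionally Gaussian-filters the sub-volume (``prefilter_sigma`` in
    voxels — used for the lower-magnification profile, where unfiltered
    noise biases the thresholds), builds a 256-bin histogram over min–max,
    finds the three-class Otsu thresholds t_low < t_high (t_low precisely
    selects the matrix, t_high precisely selects the fibers), and returns
    100 · (#voxels strictly between the matrix class and the fiber class) /
    (#voxels), together with a dict holding the thresholds in gray units.
    """
    if sub.content_label != "fibers":
        raise ValidationError("UTS is defined on fiber sub-volumes")
    data = sub.data
    if prefilter_sigma is not None and prefilter_sigma > 0:
        data = ndimage.gaussian_filter(data, prefilter_sigma, mode="reflect")
    lo, hi = float(data.min()), float(data.max())
    if not hi > lo:
        raise ComputationError("degenerate histogram: constant sub-volume")
    hist, edges = np.histogram(data, bins=N_BINS, range=(lo, hi))
    i, j = three_class_otsu(hist)
    middle = int(hist[i + 1:j + 1].sum())
    value = 100.0 * middle / data.size
    params = {
        "t_low": float(edges[i + 1]),
        "t_high": float(edges[j + 1]),
        "prefilter_sigma": prefilter_sigma,
        "n_bins": N_BINS,
    }
    return value, params


# ---------------------------------------------------------------------------
# Gradient sharpness at edges
# ---------------------------------------------------------------------------

def gse(sub: SubVolume, mode_3d: bool = False) -> float:
    """Mean gradient magnitude over detected edge voxels (gray/voxel).

    Gradient by central differences, per 2D slice by default (3D behind the
    flag). Edge voxels are those whose gradient magnitude exceeds Otsu's
    threshold of the pooled gradient-magnitude histogram (256 bins); GSE is
    the average magnitude over them — high for sharp fat-cell borders,
    reduced by blur.
    """
    if sub.content_label != "fat_cells":
        raise ValidationError("GSE is defined on fat-cell sub-volumes")
    if mode_3d:
        gz, gy, gx = np.gradient(sub.data)
        grad_mag = np.sqrt(gz**2 + gy**2 + gx**2)
    else:
        mags = []
        for sl in sub.data:
            gy, gx = np.gradient(sl)
            mags.append(np.sqrt(gy**2 + gx**2))
        grad_mag = np.stack(mags)
    if not grad_mag.max() > grad_mag.min():
        raise ComputationError("no edges detected: uniform gradient magnitude")
    thr = threshold_otsu(grad_mag, nbins=N_BINS)
    edge = grad_mag > thr
    if not edge.any():
        raise ComputationError("no edges detected: no voxel exceeds the threshold")
    return float(grad_mag[edge].mean())


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def fiber_matrix_masks(
    sub: SubVolume, prefilter_sigma: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fiber / matrix masks from the three-class Otsu decomposition.

    Voxels above t_high are fibers, voxels at or below t_low matrix; the
    ambiguous middle band belongs to neither, so the masks are disjoint by
    construction.
    """
    data = sub.data
    if prefilter_sigma is not None and prefilter_sigma > 0:
        data = ndimage.gaussian_filter(data, prefilter_sigma, mode="reflect")
    lo, hi = float(data.min()), float(data.max())
    if not hi > lo:
        raise ComputationError("degenerate histogram: constant sub-volume")
    hist, edges = np.histogram(data, bins=N_BINS, range=(lo, hi))
    i, j = three_class_otsu(hist)
    t_low, t_high = edges[i + 1], edges[j + 1]
    return data > t_high, data <= t_low


def analyze_subvolume(
    sub: SubVolume, prefilter_sigma: float | None = None
) -> QualityResult:
    """Compute every metric legal for the sub-volume's content label."""
    result = QualityResult(content_label=sub.content_label, origin=sub.origin)
    if sub.content_label == "fibers":
        result.resolution_um = estimate_resolution(sub)
        result.uts_pct, params = uts(sub, prefilter_sigma)
        result.params.update(params)
        fiber_mask, matrix_mask = fiber_matrix_masks(sub, prefilter_sigma)
        result.fmcr = fmcr(sub, fiber_mask, matrix_mask)
    else:
        result.gse = gse(sub)
    return result
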