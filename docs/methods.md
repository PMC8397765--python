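# Methods

This note documents the models, parameter choices and numerical decisions
behind `tendonct`, and what the synthetic phantoms do and do not establish
about real tendon volumes.

## Scope and design

The pipeline analyzes reconstructed 3D gray-scale volumes (multi-page TIFF
with a JSON sidecar carrying the isotropic voxel size in µm) and, for the
wave-optics stage, 2D projection stacks with flat/dark frames. Tomographic
reconstruction itself is upstream and out of scope; the Fresnel forward
propagator exists to close the loop on phase retrieval, not to simulate a
beamline. Axis convention is (z, y, x), z the tendon axis, 0-based indices.

The package is organized as plain functions over small dataclasses
(`VolumeStack`, `SubVolume`, `PhantomSpec`, `OpticsConfig`, `RunConfig`)
with a thin click CLI; the computation has no fit/predict structure that
would warrant estimator classes.

## Synthetic phantoms

The generator emulates the two structural motifs the metrics rely on:

- **Fibers**: cylinders of radius `fiber_radius` on a hexagonal lattice
  (densest packing, matching tightly packed fiber bundles) with center
  pitch `2·fiber_radius + fiber_gap`, axes along z, optionally crimped
  sinusoidally in x. Voxels take exactly `fiber_level` inside and
  `matrix_level` outside, so phase means are analytic ground truth.
- **Fat cells**: non-overlapping spheres, radii uniform in
  `sphere_radius_range`, placed by rejection sampling (≤ 10 000 attempts,
  spheres fully inside the volume), sharp borders by construction.
- **Degradation**, applied in a fixed order: 3D Gaussian blur of
  `psf_sigma` µm (reflective boundaries, so edge slices remain usable and
  the mean is conserved to ≲ 0.1 %), additive zero-mean Gaussian noise of
  SD `noise_sigma`, then a concentric ring bias `ring_amplitude·sin(r)`
  with r the in-plane radius in voxels — the simplest radial structure
  that defeats naive thresholding.

Every generator is a pure function of (spec, seed); identical inputs give
bit-identical volumes.

Default geometry: `fiber_radius` = 8 µm with a 3 µm matrix rim. Real fiber
diameter statistics for Achilles tendon are not established at these
voxel sizes; the default is an assumption chosen so that a fiber spans
~10 voxels at the 1.63 µm profile (several voxels of plateau between
edges) and the inter-fiber matrix remains resolvable. Fat-cell radii
default to 8–20 µm. Gray levels are abstract floats (fibers 1, matrix 0 by
default); integer export windowing is an I/O concern.

What the phantoms deliberately omit: beam hardening, glycerol/fixation
chemistry, cell-scale texture inside fibers, crimp disorder, crack
morphology, and spatially correlated noise. Passing tests therefore
establish correctness of the *measurement* operators under the stated
noise model, not the tendon-specific values of any metric on real data;
the published tendon means serve only as plausibility ranges.

## Wave optics

- Wavelength λ = hc/E (0.827 Å at 15 keV). First-fringe distance
  z_D = (2p)²/λ, the upper bound of the single-distance regime: 128.6 mm
  (≈130) at p = 1.63 µm and 5.27 mm (≈5) at p = 0.33 µm. Experimentally
  optimized distances may exceed this rule; `distance_zd_mm` is a free
  parameter.
- Flat/dark correction (I − D̄)/(F̄ − D̄) with pixelwise mean frames; any
  pixel with F̄ ≤ D̄ is a hard error (it signals broken references). The
  corrected transmission is floored at 10⁻⁶ of the flat level so
  logarithms stay finite without materially biasing retrieval.
- Forward model: complex transmission exp(−µt/2 − ik δt) with
  µ = 4πβ/λ, propagated by the paraxial transfer function
  exp(−iπλz(f²ₓ+f²ᵧ)). An aliasing guard rejects z beyond N·p²/λ (phase
  increment of the transfer function reaching π per frequency sample) and
  reports the maximum safe distance.
- Paganin retrieval uses the filter 1/(1 + z(δ/µ)|q|²), |q| = 2πf, with
  symmetric padding to the next fast FFT size (stripped on return);
  boundary handling is otherwise unspecified in the method and symmetric
  padding minimizes wrap-around ringing. δ is derived as
  `delta_beta_ratio · β` with β = 9.3 × 10⁻⁹ fixed for soft tissue;
  the default ratio 50 reflects the profile-based choice between 10
  (fringe visible), 50 (fringe filtered, features kept) and 100 (small
  features lost). The three-ratio sweep is exposed as a diagnostic
  (`ratio_sweep` + 200-px line profiles), not an automatic optimizer,
  because the selection is a visual-inspection judgment.

Forward→inverse consistency on sphere phantoms at the 1.63 µm/150 mm
configuration recovers projected thickness with RMSE < 2 % of its maximum;
the residual is concentrated at sharp borders where the homogeneous-object
linearization is weakest.

## Quality metrics

**Resolution (PSD criterion).** Three z-slices (top, middle, end); all row
and column profiles per slice; periodograms (mean-detrended, no window)
averaged per direction. The noise floor L is the median PSD over the top
10 % of frequencies; the PSD is smoothed with a 5-sample moving average;
f* is the lowest frequency at which the smoothed PSD first falls to 2L,
and the estimate is the mean of 1/f* over slices and directions. Two
conventions required decisions: (a) the floor/smoothing procedure, and
(b) full period 1/f* rather than half-period — the full period is the
conservative reading and is configurable in principle via the returned
per-profile machinery. A spectrum already at the floor at its lowest
frequency (pure noise) saturates at the Nyquist period 2·voxel_size; a
spectrum that never reaches 2L is an error advising a larger sub-volume.
Minimum sub-volume dimension: 64 voxels (≥ 31 usable frequency samples).

**FMCR.** Eq. form (Im_F − Im_M)/√((σ²_F+σ²_M)/2) on user-supplied
disjoint masks of ≥ 1000 voxels each (statistical floor). Sign preserved.
Being a ratio of a mean difference to a pooled SD it is invariant under
affine gray rescaling; on phantoms with level difference Δ and noise s it
recovers Δ/s to within sampling error. Mask granularity (single fibers vs
bundles) changes the value on real data; masks are recorded with results.

**UTS.** The two thresholds come from an exact three-class Otsu: the pair
of 256-bin histogram indices maximizing between-class variance
(exhaustive, vectorized; ties resolve to the lexicographically smallest
pair, which empties the middle class on perfectly bimodal data). UTS is
the percentage of voxels in the middle band (t_low, t_high]. The
three-class construction is the minimal reading that yields one
matrix-precise and one fiber-precise threshold; note it assigns a sizable
middle band to heavily blurred two-phase fields (the demo's ~29 %), so
UTS values are comparable only within one operationalization. Histograms
are always 256 bins over the sub-volume min–max, for determinism and
oracle comparability. The 1-voxel Gaussian prefilter is the default for
the 1.63 µm profile and disabled for the 0.33 µm profile, where filtering
does not change the thresholds; threshold stability under prefiltering
holds to within one bin only when the field is already band-limited well
below the filter scale (blur σ ≳ 3 voxels), and to a few bins otherwise.

**GSE.** Per-slice 2D central-difference gradient magnitude (3D mode
behind a flag); edge voxels classified by Otsu's threshold on the pooled
gradient-magnitude histogram; GSE = mean magnitude over edge voxels, in
gray units per voxel. Uniform volumes raise "no edges detected". GSE
scales linearly with gray rescaling — values are comparable only within
one gray window, which is why a run applies one export window per profile.

**Summaries.** Mean, sample SD (n−1), CV = SD/mean over ≥ 2 repeats;
CV is an error when the mean is 0.

## Morphometry

Reorientation thresholds the whole volume (Otsu), requires principal-axis
anisotropy ≥ 1.5 (largest/second eigenvalue), and applies the Rodrigues
rotation aligning the dominant axis with z by trilinear resampling,
recording the matrix. Sub-volumes are cut at regular z offsets (disjoint
when stride ≥ size), centered in x,y on the foreground centroid, with the
whole span centered in z. Cross-sectional area: central z-window of
~500 µm; per non-overlapping 100-slice block (anchored at the window
start, remainder dropped), the maximum-intensity projection is binarized
by Otsu, holes filled, the largest connected component kept, and area
reported in mm². Hole filling and the largest-component rule make the
area robust to internal fat/matrix voids and ring bias; both post-steps
are recorded in output. On cylinder phantoms the area is exact to < 0.5 %
and the fresh-vs-shrunk area ratio of two radii r₁ > r₂ recovers (r₂/r₁)².

## Problem sizes and numerics

Test and demo problem sizes were chosen as the smallest at which each
property is cleanly measurable: 96²–256² cross-sections and 64-voxel
sub-volumes for metric tests, 512² pixels for the retrieval round trip,
500 × 224² voxels for the area block test, ≥ 10⁶ voxels per mask for the
analytic FMCR check. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; the end-to-end demo is byte-identical
across runs with the same config. Floating point is float64 throughout;
16-bit export quantizes over an explicit window and reading restores
values to within half a quantization step.

## Known limitations

- The resolution criterion's floor estimation and period convention are
  choices; absolute values should not be compared across differently
  parameterized implementations of PSD-based resolution.
- UTS depends on the three-class reading of the two-threshold Otsu; other
  constructions (e.g. two independent binary Otsu runs on restricted
  ranges) give different absolute values.
- The ring-artifact model is a radial sinusoid, not a physical detector
  gain map; it exercises robustness, not realism.
- `reorient` assumes one dominant elongated object; multi-object scenes
  need cropping first.
- No hypothesis testing across preparation groups is provided — only
  mean ± SD and CV, matching the intended reporting.
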