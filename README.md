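# tendonct

Quantitative image-quality analysis and morphometry for propagation-based
phase-contrast synchrotron micro-CT of soft tissue — built around the use
case of Achilles tendon volumes, where faint contrast between collagen
fibers and the non-collagenous matrix is amplified by free-space
propagation and recovered by single-distance phase retrieval.

The package is for imaging scientists who need to compare sample
preparations or instrument configurations *quantitatively*: it computes
four complementary quality metrics on sub-volumes, handles the wave-optics
stage (flat/dark correction, Paganin retrieval, δ:β diagnostics), measures
cross-sectional shrinkage, and ships a synthetic phantom generator so the
whole pipeline is testable without beamline data.

## The science in brief

**Optics.** With the complex refractive index n = 1 − δ + iβ, the
single-distance regime is bounded by the first-fringe rule
z_D = (2p)²/λ for pixel size p; at 15 keV (λ ≈ 0.827 Å) this gives
≈ 130 mm for 1.63 µm pixels and ≈ 5 mm for 0.33 µm pixels. Projected
thickness is recovered from one flat-corrected projection by the Paganin
filter

t = −(1/µ) ln 𝓕⁻¹[ 𝓕(I/I₀) / (1 + z_D (δ/µ) |q|²) ],  µ = 4πβ/λ,

with the retrieval strength set through the δ:β ratio (β fixed at
9.3 × 10⁻⁹ for soft tissue; ratio 50 by default, with a 10/50/100
line-profile sweep available as a diagnostic).

**Quality metrics**, computed per sub-volume and summarized as
mean ± SD with CV = SD/mean:

- *Spatial resolution* — lowest spatial frequency at which the averaged
  1D power spectral density of x/y line profiles falls to twice the
  high-frequency noise floor; reported as the period 1/f* in µm.
- *FMCR* — fiber-to-matrix contrast-to-noise ratio,
  (Im_F − Im_M)/√((σ²_F + σ²_M)/2).
- *UTS* — percentage of voxels between the matrix-precise and
  fiber-precise thresholds of a three-class Otsu decomposition: voxels
  that cannot be uniquely assigned to either phase.
- *GSE* — mean gradient magnitude over Otsu-detected edge voxels of
  fat-cell sub-volumes (sharpness; decreases with blur).

**Morphometry** — principal-axis reorientation, sub-volume extraction
along the tendon axis, and cross-sectional area from maximum-intensity
projections over 100-slice blocks of the central ~500 µm, binarized and
reduced to the largest connected component.

## Worked example

The `demo` subcommand runs the full synthetic pipeline — hexagonally packed
fiber phantom and fat-cell phantom at the 4×/1.63 µm instrument profile,
degraded with a 1-voxel PSF and gray-level noise of 0.08, three fiber
sub-volumes along z plus one fat-cell sub-volume — and writes a CSV of
per-sub-volume metrics plus summaries:

```bash
$ tendonct demo --seed 1 --out-dir demo_out
demo complete: 4 sub-volumes, 3 metric summaries in demo_out
$ cat demo_out/summary.txt
tendonct 0.1.0 quality report
sub-volumes analyzed: 4
fmcr: mean=5.665 sd=0.006434 cv=0.001 n=3
resolution_um: mean=5.011 sd=0.04183 cv=0.008 n=3
uts_pct: mean=28.59 sd=0.1119 cv=0.004 n=3
cross-sectional area: 0.004173 ± 1.879e-06 mm² over 2 blocks
```

Reading the numbers: at 1.63 µm voxels with a one-voxel PSF the resolution
estimate is ~5 µm (≈ 3 voxel periods — blur plus noise, not the Nyquist
floor of 3.26 µm); FMCR ≈ 5.7 means the fiber–matrix gray-level difference
is 5.7× the pooled noise SD (easily segmentable; ~2 is the usual limit for
reliable segmentation); the UTS of ~29 % reflects the wide ambiguous band a
three-class decomposition assigns to this strongly blurred two-phase field;
and the CVs (≤ 0.01) show the three sub-volumes along z agree closely, as
expected for a z-invariant phantom. The same `--seed` always reproduces
these numbers byte-for-byte.

The equivalent library calls are `make_fiber_phantom` → `degrade` →
`extract_subvolumes` → `analyze_subvolume` → `write_report`; see
`tendonct.session.run_demo`.

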