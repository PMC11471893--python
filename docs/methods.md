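# Methods

This note documents the models, conventions and numerical choices behind
`mtlattice`, what the synthetic data does and does not emulate, and the
known limitations.

## The measurement model

A microtubule is a near-periodic helical lattice: `n_pf` protofilaments
(typically 13) of tubulin monomers repeating every `a` Å along the
filament axis, arranged as an `n_start`-start helix (3-start at the
monomer level).  Each subunit step rises `r = n_start·a/n_pf` and twists
`−360/n_pf` degrees, so the monomer spacing and the helical rise are
interconvertible:

    a = r · n_pf / n_start          (helix module; exact inverse pair)

In the Fourier transform of a projected filament image, the axial repeat
produces layer lines at axial frequency `1/a` on either side of the
equator.  For a square analysis box of `box` pixels at `pixel_size` Å/px,
frequencies are sampled every `1/(pixel_size·box)` Å⁻¹, so a layer line
`k` rows from the equator corresponds to

    spacing = pixel_size · box / k.

The measurement is therefore intrinsically discrete: its output lies on
the grid `{pixel_size·box/k}` and its granularity is one reciprocal-space
pixel.  All defaults assume the physical box edge `pixel_size·box =
2,235.1 Å` (1,030 px at 2.17 Å/px, ≈224 nm, spanning 26 complete 84 Å
heterodimers).  A binned configuration of 515 px at 4.34 Å/px preserves
that edge exactly and therefore the identical spacing grid, at 1/8 the
memory; the test suite uses it throughout.  Box sizes may be even or odd —
the centred-FFT origin is at index `box // 2` in both cases.

### Pipeline stages and conventions

1. **Backbone resampling** — traced backbones (0-based voxel coordinates)
   are resampled at even arc-length steps (default 5 voxels); the original
   endpoints are preserved, with the final sub-step gap closed by the last
   input point.
2. **Masking** — a soft cylindrical mask suppresses surrounding material:
   1 within `radius` (default 180 Å) of the backbone, cosine-tapered to 0
   over `soft_width` (default 40 Å).  Distances come from a Euclidean
   distance transform of the densely rasterised backbone (≈half-voxel
   accurate), which keeps the cost linear in the volume size.
3. **Tiling** — segment centres are spaced `box·(1−overlap)` voxels
   (default overlap 10%), shrunk evenly so the last box does not overhang;
   a filament no longer than the box yields one centred segment.
4. **Extraction/projection** — the masked volume is resampled by trilinear
   interpolation into a `box × box × depth` block whose image axis 0
   ("vertical") is the in-plane component of the filament axis and whose
   third axis is the original viewing (z) direction, then summed over
   depth (default: the full z extent, i.e. summed along the volume z
   axis).  Out-of-volume samples contribute 0.  Filaments parallel to the
   beam axis have no in-plane component and are rejected.
5. **Power spectra** — `|FFT|²` with the unnormalised-DFT convention
   (Parseval: `sum(PS) = box²·sum(image²)`), centred by `fftshift`.
   Spectra of all segments of one filament are summed.
6. **Profile and peak location** — the meridional profile is the *mean*
   over columns within ±`lateral_halfwidth` (default 10 px) of the
   meridian, per axial row.  The equator is the detected maximum within
   ±2 rows of the geometric centre (not assumed at the centre).  On each
   side, the layer line is the integer-row argmax over the offsets whose
   spacing lies in the search band (default 38–46 Å), ties broken toward
   the smaller offset.  A peak counts as detected only if it exceeds the
   band's local median + 3·MAD; otherwise the filament is reported
   unmeasurable ("no detectable layer line").  One-sided mode (default)
   uses the stronger side; two-sided mode averages the two offsets and can
   produce half-integer offsets.  An optional 3-point parabolic sub-pixel
   refinement exists but is off by default, matching the discrete grid on
   which results are reported.

### Behaviour near snap boundaries

The integer-row argmax snaps a true spacing `a` to the grid value whose
row is nearest `pixel_size·box/a` — except within a few hundredths of an
Ångström of a boundary, where the direction of the snap is decided by the
sampled fine structure of the transform (the Gaussian form factor of the
density and the off-meridian Bessel lobes of the helix, both of which tilt
the two flanking samples slightly).  Example at the 2,235.1 Å edge: a
true `a` = 41.0 Å has `2235.1/41 = 54.515`, sitting 0.015 px above the
k = 54.5 boundary, yet the discrete transform of the ideal lattice is
larger at row 54 than at row 55 (verified against a direct
complex-exponential sum over the lattice points, independent of the
rendering/FFT pipeline), so the measurement reports 41.39 Å rather than
40.64 Å.  This is a property of the method's granularity, not an
implementation artifact; the guaranteed accuracy is one grid step
(≤0.85 Å in the 40–44 Å band), and away from boundaries the measurement
equals the nearest grid value exactly on noise-free data.

### Profile SNR

Profile quality is summarised as `SNR = mean(signal)²/std(signal)²` with
the *population* (divisor-n) standard deviation — the squared inverse
coefficient of variation of the plotted profile values.  In
`measure_filament` it is evaluated over the search-band rows on both
sides of the equator.  Two properties of this statistic are worth
stating explicitly:

* it is scale-invariant and increases with any constant offset, so noisy
  spectra (whose noise floor adds a positive offset) can score *higher*
  than noise-free ones;
* summing the spectra of independent-noise particles of the same
  structure reduces the fluctuation part of the profile variance
  (`SNR_n ≈ mean²/(var_structural + c/n)`), so the SNR rises from n = 1
  and then saturates at the structural limit.  The summation benefit is
  therefore tested as "summed beats single" rather than as strict
  per-step monotonicity, which is not a property of a saturating
  statistic under finite replication; with tiled (rather than replicated)
  segments the structural term itself differs per segment (mask-fade at
  the filament ends), further breaking per-step ordering.

### Classification

Spacings below 41.3 Å are classified *compacted*, at or above *expanded*
(right-closed rule at the threshold).  41.3 Å is the midpoint of the gap
between the compacted (≈40.8–41.1 Å) and expanded (≥41.5 Å) bands and is
configurable.

## Synthetic data

The generator produces the inputs the measurement assumes, with known
ground truth.

* **Lattice** — an ideal `n_start`-start helix of unit-amplitude isotropic
  Gaussian blobs (default σ = 12 Å) on a cylinder of radius 105 Å (the
  density mid-wall of a 25-nm microtubule).  Protofilament `p` sits at
  azimuth `p·360/n_pf` with axial stagger `p·r`; monomers along one
  protofilament are spaced exactly `a`.  The B-lattice seam and the α/β
  monomer distinction are not modelled: the 1/a layer-line position is
  unaffected by them at this resolution.  `centered_filament_spec` picks
  the largest lattice that fits a grid with a 24 Å margin, mirroring a
  filament spanning the full analysis box (~26 heterodimers).
* **Missing wedge** — a hard binary mask in Fourier space about a chosen
  tilt axis (default ±60°; the emulated instruments span ±45–63°).  A
  frequency is kept iff some tilt plane passes through it; the mask is
  sign-canonicalised and symmetrised at Nyquist bins so it is exactly
  Hermitian, making the operation a real-valued, idempotent, L2
  non-expansive projection.  Frequencies on the tilt-axis line are always
  kept.  Note that for a filament imaged in projection along z the kz = 0
  plane survives any tilt range containing 0°, so the wedge mainly
  reshapes the noise.
* **Noise** — additive white Gaussian, seeded.  No CTF, detector, or
  projection/reconstruction model: layer-line *position* is insensitive to
  the CTF, which only modulates amplitudes.  `sigma_for_projection_snr`
  converts a target variance-ratio SNR of the z-projected image into a
  voxel sigma (`σ = sqrt(var(projection)/(SNR·nz))`); the robustness
  condition in the acceptance suite uses projected-image SNR 2, and the
  summation-benefit test uses 0.1, the magnitude typical of cryo-ET.
* **Bead scenes** — source beads uniform in the field of view, destination
  `T(src) + N(0, σ²)` per axis for a known similarity transform.
* **Spacing cohorts** — normal draws per group, snapped by default to the
  reciprocal grid of the standard box (36–48 Å), emulating measured
  cohorts.  Snapping introduces heavy ties; under the null this makes the
  permutation p-value conservative rather than uniform, so calibration
  checks are run on unsnapped draws.

What passing tests on this data do **not** show: robustness to CTF
modulation and reconstruction artifacts, curved or lattice-defect
filaments, protofilament-number variation, crowding by other cellular
densities, or errors in backbone tracing (backbones are inputs).

## Registration

`fit_similarity` implements the closed-form least-squares similarity fit
(Umeyama): centroids removed, SVD of the cross-covariance, rotation
`U·Vᵀ`, scale `Σσᵢ / var(src)`.  Flags disable rotation (pure
scale + translation, the fixed-geometry integrated-FM mode) or scale.
Reflections are rejected rather than silently corrected: if the
unconstrained optimum has determinant −1 the fit raises, since a
reflected "best fit" indicates wrong correspondences or handedness.
Degenerate configurations (n < 3 in 2D / n < 4 in 3D for rotational fits,
collinear/coplanar beads) raise with the geometric defect named.
Leave-one-out refits the transform without each bead, predicts it, and
reports per-axis *sample* (divisor n−1) SDs of the deviations, in the
destination units, which are carried through unconverted.  LOO
calibration simulations keep the bead noise below ~2% of the field of
view: when noise approaches the transformed field spread the rotation
becomes unidentifiable and the reflection guard triggers by design (real
workflows operate near 0.3% of the field).

## Statistics

The two-group comparison is an unpaired two-tailed permutation test with
the pooled-variance t as the statistic (Welch available as a switch; under
permutation either yields an exact test).  Monte-Carlo mode permutes
labels uniformly (seed mandatory) and reports `p = (count+1)/(n_iter+1)`,
never exactly zero — with 10,000 iterations the smallest attainable p is
1/10,001 < 10⁻⁴.  Exhaustive mode enumerates all `C(n, n_a)` label splits
(capped, default 200,000) and reports `count/n_splits`; the observed
labelling is included, so p > 0.  The two-tailed criterion
`|t_perm| ≥ |t_obs|` uses a 10⁻¹² relative tolerance against
floating-point ties.  Zero-variance permutations give t = 0.  Cohort
summaries report the fraction below the compacted/expanded threshold and
linear-interpolation quartiles.

## Problem sizes

All simulation-backed tests run at the binned 515-px/4.34 Å configuration
(grids ≤128×515×72) or smaller 256-px boxes where the standard spacing
grid is not required; the heaviest checks are 50 seeded wedge+noise
measurements and 1,000 + 200 permutation-test replicates.

## Known limitations

* Straight filament axes only (the backbone may be a polyline, but
  segment orientation uses the end-to-end direction); no supertwist or
  lattice-accommodation models.
* Layer-line localisation assumes a single dominant peak in the search
  band; closely spaced mixed lattices within one filament are averaged,
  not separated.
* The MRC reader accepts isotropic voxels only and converts integer modes
  to float32.
* No image-based (intensity) registration and no automated filament
  tracing; both are upstream of this package's scope.
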