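# Methods

`popsim` models projection imaging under structured light-sheet
illumination: a sinusoidally patterned, obliquely tilted light sheet is
swept through the sample during a single camera exposure while the image is
sheared synchronously on the detector, so each raw frame is an optical sum
projection of the volume (the shear-warp transform).  Nine such frames —
three pattern azimuths times three pattern phases — feed a 2D
structured-illumination reconstruction that roughly doubles the lateral
resolution of the projection.  This note documents the model, its
parameters and the numerical choices.

## Coordinate and unit conventions

* 2D images are `(row = y, col = x)`, 0-based, origin at the top-left pixel
  center; 3D volumes are `(z, y, x)`.  All physical lengths are nm.
* Pattern phases and affine transforms are defined about the image center
  (pixel `((H-1)/2, (W-1)/2)`); phantom emitter coordinates are nm relative
  to that center (z from the bottom plane).
* Azimuths are measured in the top-down plane from +x towards +y, degrees.

## Forward model

For orientation *i* with pattern azimuth θᵢ and phase φₚ, a raw frame is

    D_{i,p} = Bin{ Warp_i[ ( P(S · I_{i,p}) ) ⊗ h ] } + noise

where

* `S` is the 3D fluorophore density (photons/voxel/exposure),
* `I_{i,p}(r) = 1 + m cos(2π k_i · r + φ_p)` is the structured light sheet
  with lateral wave vector `|k_i| = 1/line_spacing` (default 390 nm, m =
  0.8); an optional axial component of `k` emulates a depth-tilted pattern,
* `P` is the sheared axial sum projection: plane z is displaced laterally by
  `(s − tan τ)·z / stretch(τ)` along the orientation's azimuth before
  summation, with `s` the applied shear factor and τ the 45° tilt.  At the
  geometrically correct shear `s* = tan τ = 1` the projection is
  height-independent ("top-down"); a mis-set shear makes features walk
  laterally with height,
* `h` is the 2D projection PSF, an isotropic Gaussian in the common frame
  whose FWHM (default 381 nm) is a *measured* quantity of the projection
  modality, not a diffraction-limited PSF: the optical sum projection
  integrates out-of-focus light, which broadens the in-focus lateral
  response.  An anisotropic, physically derived PSF is deliberately not
  modeled — the configured FWHM is the calibration target,
* `Warp_i` maps the common top-down frame into orientation *i*'s raw camera
  frame: rotate by −θᵢ, stretch by `1/cos τ = √2` along the frame's x axis,
  divided by the stretch Jacobian so photons are conserved,
* `Bin` sums 2×2 blocks: simulation runs at 50 nm lateral pitch and is
  binned to the 100 nm camera pixel (Nyquist-safe for a ~170 nm target
  FWHM),
* noise, when enabled, is `gain·(Poisson(photon_scale·x) + N(0, σ_read)) +
  offset` with one read event per frame — the analog-summation advantage
  over digital projections of N separately read planes, quantified by
  `snr_projection_comparison`: `S/√(S+σ²)` vs `S/√(S+Nσ²)`.

Choosing the isotropic-PSF-in-common-frame convention means the PSF appears
√2-elongated along the shear axis of each raw frame, which mirrors the
physical origin of the blur (summation along the projection direction) and
makes the registered widefield projection isotropic at the configured FWHM.

### Phantoms

`make_bead_phantom` renders solid spheres by supersampled voxel occupancy
(sub-voxel beads become trilinear point deposits); each bead's in-grid mass
is normalized to its brightness.  Placement is rejection sampling with a
minimum pairwise distance; `placement="disc"` confines centers to the
inscribed disc so that no content is clipped by the ±60° rotations and the
√2 stretch of the raw frames.  `make_dual_layer_phantom` puts dense small
(100 nm) beads at z = 0 and sparse large (500 nm) beads at z = gap
(default 30 µm), with a cross-layer lateral exclusion at the same minimum
distance so the two layers remain individually detectable in projection —
the construction that makes the shear factor identifiable.

## Registration

Raw frames are first normalized geometrically (`to_common_frame`): compress
by `cos τ` along the shear axis, rotate by 0/+60/−60°, zero-fill outside.
Data-driven refinement then registers orientations 2 and 3 onto the fixed
orientation 1:

1. coarse translation from the FFT cross-correlation peak, refined to
   sub-pixel by Nelder–Mead simplex on normalized cross-correlation (NCC);
2. pyramidal affine: 6 parameters (translation ×2, rotation, two
   log-scales, shear, all about the image center), fitted coarsest-first on
   a Gaussian-antialiased decimation pyramid (default 16×…1×, blur
   σ = 2·ds/6 before each decimation; levels below 16 px are skipped).
   Parameters are expressed in full-resolution pixels, so between levels
   only the image coordinates rescale — equivalent to rescaling the
   translation.  Each level runs Nelder–Mead with an explicit initial
   simplex (≈2·ds px translation steps, 1° rotation, 0.02 log-scale/shear),
   at most 400 evaluations, parameter tolerance 1e−4, and never regresses
   below its initialization.  NCC is the metric at every level (robust to
   per-orientation intensity differences); MSE is a config alternative.
   `converged` means the finest level improved by less than 1e−3.

`warp` is inverse-mapped bilinear resampling with exact zero-fill; the
identity transform short-circuits to a copy so it is bit-exact.

## Shear calibration

`calibrate_shear` sweeps candidate shear factors on the dual-layer phantom.
Per candidate it simulates one unmodulated frame per orientation (geometry
does not depend on the pattern phase), runs the full registration chain,
detects beads in the three registered images (local maxima above
median + 5·MAD with a 2%-of-peak floor, 700 nm non-maximum suppression,
centroid refinement) and scores the overlap: mutually-nearest matches
within a 1000 nm gate for each orientation pair, mean residual in nm, with
unmatched detections penalized at the gate distance.  The score is reported
per layer (detections labeled by the nearest ground-truth emitter).  The
bottom layer (z = 0) always registers; the top layer's residual grows as
`|s − s*|·gap` with different directions per orientation, so the sweep is
minimized at the true shear.  A candidate is "successful" when both layers
stay below one camera pixel — reproducing the binary converges/does-not
reading — while the continuous score makes the argmin well-defined.  A
sweep whose score range stays below half a camera pixel is flagged
non-identifiable (a zero-gap phantom has no height lever arm).  Candidate
registration failures score at twice the gate rather than raising.

## SIM reconstruction

Per orientation, the three phase frames are Fourier-transformed and a 3×3
linear system `M[p,j] = (m/2)^{|j|} e^{i j φ_p}` (orders j = 0, ±1) is
solved pixel-wise to separate the zero-order band from the sidebands; the
mixing-matrix condition number is reported and degenerate phase sets raise.
Phases handed to the solver are corrected by `−2π k·r_center`, the offset
between the center-referenced pattern phase and the FFT origin.

Sidebands are shifted by ±k exactly: each band is embedded in a 2× finer
Fourier grid (the unpaired Nyquist row/column of even grids is zeroed to
preserve Hermitian symmetry) and multiplied by a real-space linear phase
ramp.  Band OTFs are the analytically shifted Gaussian OTF
`exp(−2π²σ²|f + jk|²)` of the configured projection PSF.

Combination, per the configured method:

* **wiener** — generalized Wiener `Σ OTFⱼ·Bⱼ / (Σ OTFⱼ² + w)` with
  `w = 1e−2` relative to unit-peak OTFs, followed by a triangle apodization
  to the extended cutoff (the 1e−3 OTF-support radius plus `|k|`);
* **rl** — plain sum averaged over overlapping OTF supports
  (support = OTF > 1e−3·max), inverse transform, negatives clipped (the
  fraction is logged), then Richardson–Lucy deconvolution with the
  effective PSF (inverse transform of the support-averaged OTF), 5
  iterations by default (5–10 supported).  RL is applied post-combination,
  not per band.

The combined spectrum of real inputs is Hermitian; the inverse transform's
residual imaginary fraction is recorded on the result
(`max_imag_ratio`, ~1e−16 in the tests).  The Wiener output is left signed.

## Resolution analysis

* **FWHM** — per-bead 2D elliptical Gaussian fits with offset
  (`FWHM = 2√(2 ln 2)·σ` per axis), windows sized to ≈3 expected FWHM,
  beads excluded when a neighbor is within 3× the expected FWHM, the window
  leaves the image, or the normalized fit residual exceeds 0.2; the report
  carries mean ± sd and exclusion counts.  The raw-profile alternative was
  rejected: at 100 nm sampling the fit is far more stable.
* **Decorrelation** — Pearson-type correlation between the (edge-tapered)
  spectrum and its phase-normalized copy under binary low-pass masks of
  increasing radius, over 20 radii × 10 Gaussian high-pass widths
  (geomspace from ¼ image size to 1 px), peak position refined by parabolic
  interpolation; resolution = `2·pixel/r₀` with `r₀` the largest
  local-maximum radius.  White noise yields no local maximum → `None`.
* **Two-frame average** — paired (⌊T/2⌋ frames) or sliding (T−1) mean of
  consecutive timepoints, suppressing frame-alternating artifacts.

On the default simulation the decorrelation estimate agrees with the fitted
FWHM within 25% on the Richardson–Lucy output; on the Wiener output the
triangle apodization biases the decorrelation peak to lower frequencies
(≈30% above the fitted FWHM), so the agreement property is stated for the
RL path.

## Default study conditions and problem sizes

The test suite and the acceptance script use a desk-scale rendition of the
bead experiments: 25 isolated 100 nm beads (≥22 enter the statistics) in a
13 µm disc inside a 19.2 µm grid (192² camera pixels at 100 nm), 390 nm
pattern at 0/+60/−60°, modulation 0.8, three equidistant phases, noiseless
by default; the dual-layer calibration phantom uses 24 bottom + 6 top beads
with a 30 µm gap and an 11-candidate sweep (0.95…1.05, step 0.01) over 5
seeds.  These sizes were chosen so a full run completes in minutes on one
CPU while keeping ≥22 beads per statistic; the CLI defaults use a larger
512² field.  Measured on this simulation: widefield FWHM ≈ 399 nm
(the configured 381 nm plus ~4–5% broadening from the three bilinear
resampling steps and pixel binning), Wiener ≈ 168 nm, RL(5) ≈ 104 nm,
ratio ≈ 0.42.

The noiseless simulation lets 5-iteration RL sharpen further than it does
on real, noisy data; the pipeline-level claims are therefore stated as
orderings (RL ≤ Wiener < widefield, ratio ≤ 0.55) rather than absolute RL
numbers.

## What the generator does and does not emulate

Emulated: the 9-frame acquisition geometry, sheared sum projection with a
√2 stretch, measured-scale projection PSF, finite bead size (solid-sphere
rendering), equidistant-phase uniformity, Poisson + Gaussian camera noise
with analog summation, dual-layer calibration samples, pattern depth
mis-calibration (optional axial k).  Not emulated: polarization,
photobleaching, sCMOS fixed-pattern and rolling-shutter edge artifacts, the
axial confinement profile of the light sheet (the sum is uniform over the
swept range), sample-induced aberrations, and the optics of the remote
focusing train.  Passing tests therefore validate the computational chain
— geometry, registration, calibration, band algebra, deconvolution and
metrology — under an idealized but physically scaled image model; they do
not certify performance on real camera data.

## Known limitations

* The Gaussian OTF model is shared between simulator and reconstruction;
  real-data OTF estimation is out of scope.
* Pattern wave vector and phases are taken from frame metadata; blind
  estimation from data is not implemented.
* Registration assumes bead-like sparse content fills the field reasonably
  uniformly; very sparse or symmetric scenes can leave the 6-parameter
  affine poorly constrained.
* The shear-calibration score saturates at the matching gate, so the sweep
  curve is flat far from the optimum; candidates should bracket the truth.
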