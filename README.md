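# popsim

Simulation, calibration and reconstruction pipeline for **projective
oblique-plane structured illumination microscopy** — light-sheet imaging in
which a sinusoidally structured, 45°-tilted sheet is swept through the
sample during a single exposure while the image is sheared on the camera,
so every raw frame is an *optical sum projection* of the volume.  Nine raw
frames (3 pattern orientations × 3 phases) per timepoint are enough to
reconstruct a super-resolved projection of a whole cell, where conventional
3D SIM needs 15 z-stacks.

The package is aimed at microscopy method developers: it provides

* a forward simulator of the 9-frame acquisition (3D bead phantoms,
  structured illumination, sheared sum projection with the √2 stretch of
  the 45° geometry, a 381 nm projection PSF, Poisson + read noise);
* the registration chain mapping the three orientations into one frame
  (fixed compress-by-1/√2 + rotate-by-±60° normalization, coarse
  cross-correlation, coarsest-first pyramidal affine on normalized
  cross-correlation);
* shear calibration on a dual-layer bead phantom (dense 100 nm beads at
  z = 0, sparse 500 nm beads 30 µm above): sweeping candidate shear
  factors and scoring whether both layers register simultaneously;
* the 2D SIM reconstruction: per-pixel Fourier band separation, exact
  sideband shifting on a 2× grid, overlap-averaged combination, and either
  generalized-Wiener filtering or Richardson–Lucy deconvolution with the
  effective PSF;
* resolution metrology: bead detection, per-bead Gaussian-fit FWHM
  statistics, image-decorrelation resolution, two-frame averaging.

## The model in brief

A raw frame for orientation *i*, phase *p* is

    D_ip = Bin{ Warp_i[ P( S · (1 + m cos(2π k_i·r + φ_p)) ) ⊗ h ] } + noise

with sample density `S`, pattern wave vector `|k_i| = 1/390 nm⁻¹` at
azimuth 0/+60/−60°, sheared axial sum projection `P`, Gaussian projection
PSF `h` (FWHM 381 nm), and the common→raw frame warp (rotate −θᵢ, stretch
√2).  Reconstruction solves the 3×3 mixing system
`M[p,j] = (m/2)^{|j|} e^{ijφ_p}` per Fourier pixel, shifts the sidebands by
±k, and combines all nine bands — Wiener
(`Σ OTFⱼBⱼ / (Σ OTFⱼ² + w)`, triangle apodization) or plain overlap
averaging followed by 5 Richardson–Lucy iterations.  See
`docs/methods.md` for the full account.

## Worked example

```python
import popsim as ps
import numpy as np

# 25 isolated 100 nm beads in a 13 um disc; simulate the 9 raw frames
phantom = ps.make_bead_phantom(n_beads=25, field_size=13000,
                               grid_extent=19200, min_separation=1800,
                               placement="disc", seed=5)
frames = ps.simulate_raw_frames(phantom)          # (3, 3, 192, 192) @ 100 nm

# fixed geometric normalization + pairwise affine registration
common = np.stack([
    np.stack([ps.to_common_frame(frames.images[i, p], i + 1, 45.0)
              for p in range(3)])
    for i in range(3)])
results = ps.register_orientations([c.sum(axis=0) for c in common],
                                   levels=(8, 4, 2, 1))
registered = np.stack([
    np.stack([ps.warp(common[i, p], results[i].transform) for p in range(3)])
    for i in range(3)])
reg = ps.FrameSet(registered, frames.patterns, frames.pixel_size,
                  registered=True)

# reconstruct and measure
recon = ps.reconstruct(reg, settings=ps.ReconSettings(method="wiener"))
wf_pos = ps.detect_beads(recon.widefield, 100.0, min_separation=1500)
wf = ps.fwhm_stats(recon.widefield, wf_pos, 100.0, expected_fwhm_nm=381)
sim_pos = ps.detect_beads(recon.reconstruction, recon.pixel_size, 1500)
sim = ps.fwhm_stats(recon.reconstruction, sim_pos, recon.pixel_size,
                    expected_fwhm_nm=200)
print(f"widefield FWHM {wf.mean_fwhm_x:.0f} x {wf.mean_fwhm_y:.0f} nm "
      f"(n={wf.n})")
print(f"SIM FWHM       {sim.mean_fwhm_x:.0f} x {sim.mean_fwhm_y:.0f} nm "
      f"(n={sim.n}), ratio {sim.mean_fwhm / wf.mean_fwhm:.2f}")
```

prints

```
widefield FWHM 401 x 396 nm (n=24)
SIM FWHM       168 x 170 nm (n=24), ratio 0.42
```

— the uniform-illumination projection measures at the ~381 nm projection
PSF scale (plus a few percent of resampling broadening), while the
structured-illumination reconstruction cuts the bead FWHM by more than
half.  Replacing `method="wiener"` with `method="rl"` (5 Richardson–Lucy
iterations) sharpens further.

The same chain is available from the shell:

```bash
popsim run --seed 5 --out run/          # simulate -> register -> reconstruct -> analyze
popsim calibrate --gap-um 30 --candidates 0.9:1.1:0.01 --out cal/
popsim analyze --image run/recon.tif --report report.json
```

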