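# Default synthetic-eardrum phantom: geometry and per-channel photometry.
# Geometry is stated at the reference raster of 976 x 494 px (the resolution
# of the color CCD used for otoscopic capture) and scales proportionally for
# other raster sizes. Intensities are on [0, 1].
geometry:
  width: 976
  height: 494
  tm_ellipse: {cx: 488.0, cy: 250.0, a: 300.0, b: 185.0, theta: 0.15}
  malleus: {width: 16.0, angle: -1.75}       # direction center -> upper rim, rad (y down)
  cone_of_light: {angle: 1.35, extent: 0.45, radial_fraction: 0.85}
  n_vessels: 8
  vessel_width: 3.0

# Per-channel photometry. The values encode the contrast structure seen in
# multispectral otoscopy of a healthy eardrum:
#  - red: strong membrane/canal contrast, no visible vessels, malleus at the
#    same intensity as the canal wall, low-noise homogeneous canal wall;
#  - white/green: small membrane/canal separation (overlapping histograms),
#    clearly visible dark vessels, bright malleus;
#  - blue: dim (low illumination) and by far the noisiest.
photometry:
  white: {tm_mean: 0.62, outside_mean: 0.52, malleus_mean: 0.70, vessel_contrast: 0.25, cone_gain: 0.20, noise_sd: 0.040}
  red:   {tm_mean: 0.75, outside_mean: 0.35, malleus_mean: 0.35, vessel_contrast: 0.00, cone_gain: 0.15, noise_sd: 0.020}
  green: {tm_mean: 0.55, outside_mean: 0.47, malleus_mean: 0.62, vessel_contrast: 0.30, cone_gain: 0.18, noise_sd: 0.035}
  blue:  {tm_mean: 0.22, outside_mean: 0.18, malleus_mean: 0.26, vessel_contrast: 0.10, cone_gain: 0.10, noise_sd: 0.100}
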