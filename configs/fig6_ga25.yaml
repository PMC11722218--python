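# Depth-series BSE simulation: 25 at.% Ga implantation.
# 3 at.% Pb stain squares at 0-5 ... 20-25 nm depth in Epon-Araldite,
# 1.5 keV beam, 3000 trajectories/pixel, 3 nm pixels, all-BSE detection.
seed: 20250921
output_dir: scratch/fig6_ga25
materials:
  epon:
    elements: {C: 0.54, H: 0.36, O: 0.09, N: 0.01}
    density: 1.25
phantom:
  kind: depth_series
  matrix: epon
  ga_fraction: 0.25
  stain_fraction: 0.03
  lateral_size: 50.0
  spacing: 50.0
beam:
  energy_ev: 1500.0
  trajectories: 3000
  cutoff_ev: 50.0
detector:
  grid_voltage: 0.0   # count all backscattered electrons
scan:
  pixel_size: 3.0
  height: 60.0
analysis:
  # Rose-type visibility threshold on (mean_region - mean_bg)/sigma_bg,
  # calibrated once for the depth-series study; see docs/methods.md.
  cnr_threshold: 1.0
  min_region_pixels: 30
  guard_nm: 6.0
  shrink_nm: 3.0
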