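# Named presets for the fiber bundles, distal focal elements and lasers
# characterized with this system. Quality-area diameters in mm, inter-core
# distances in um, bundle lengths in m, bending radii in mm.
bundles:
  BundleF:
    quality_area_diameter: 0.550
    n_cores: 15000
    inter_core_distance: 4.5
    length: 2.0
    bending_radius: 30.0
  S-BundleS:
    quality_area_diameter: 0.900
    n_cores: 18000
    inter_core_distance: 8.0
    length: 0.895
    bending_radius: 5.0
  L-BundleS:
    quality_area_diameter: 1.450
    n_cores: 18000
    inter_core_distance: 11.6
    length: 1.35
    bending_radius: 5.0

focal_elements:
  GRIN:
    magnification: 2.2
    working_distance: 0.2
    diameter: 1.3
  MiniObjective:
    magnification: 3.0
    working_distance: 1.0
    diameter: 3.0

lasers:
  imaging:
    wavelength: 920.0       # nm
    pulse_width: 130.0      # fs
    rep_rate: 80.0          # MHz
    max_power: 4.0          # W
    spm_threshold: 10.0     # mW/core; valid only at 920 nm / 130 fs / 80 MHz
  photostimulation:
    wavelength: 1030.0
    pulse_width: 420.0
    rep_rate: 1.2
    max_power: 54.0
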