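# Full-analysis configuration for `chiralsfg run-all`.
#
# Either point at real trajectory files ...
#   topology_path: system.pdb
#   trajectory_path: production.dcd
#   charge_table: system.charges.json   # or "tip4pew"
# ... or use a synthetic preset (helix | slab | template):
preset: template
preset_params:
  n_waters: 60
  seed: 1
  n_frames: 5

output_dir: results/run_template

# spectrum settings
element: zyx            # zyx (chiral, psp) or yyz (achiral, ssp)
grid: [2800.0, 4000.0, 1.0]
lineshape: lorentzian
width: 5.0
# map_file: null        # defaults to the shipped O-H stretch map

# hydrogen-bond criteria
hbond:
  heavy_distance_max: 3.5
  angle_min: 135.0
  strong_H_to_O_max: 1.6

# water-ordering diagnostics
dipole_resolution: 1.0
depth_range: [0.0, 14.0]
retention_time_step: 1.0

# strides: spectra are usually computed on a denser stride than
# shells/dipoles/retention (10 fs vs 1 ps storage in production use)
spectrum_stride: 1
analysis_stride: 1

seed: 1
vacuum_axis: z
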