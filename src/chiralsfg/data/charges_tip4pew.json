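{
  "_comment": "TIP4P-Ew water model: site partial charges (e), rigid geometry (Angstrom, degrees), O-M virtual site offset along the HOH bisector.",
  "charges": {
    "O": 0.0,
    "H1": 0.52422,
    "H2": 0.52422,
    "virtual": -1.04844
  },
  "geometry": {
    "r_OH": 0.9572,
    "theta_HOH": 104.52,
    "virtual_site_offset": 0.125
  },
  "lennard_jones_O": {
    "sigma": 3.16435,
    "epsilon_kcal_mol": 0.16275
  }
}
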