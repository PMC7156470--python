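{
  "version": 1,
  "comment": "Per-element atomic data at 7.14 keV photon energy. Photoabsorption cross sections (A^2/atom, neutral ground state) follow the standard Henke f2 tabulation; sequential ionization energies (eV) are NIST ground-state values; K-hole decay rates (1/fs) follow tabulated K-level widths via Gamma = hbar/tau; K fluorescence yields are the standard Krause values. Charge-state dependence of the cross section and K binding is applied by the loader (screened-hydrogenic scaling).",
  "photon_energy_keV": 7.14,
  "elements": {
    "H": {
      "Z": 1,
      "mass": 1.008,
      "sigma_photo": 2.0e-11,
      "kshell_binding": 13.598,
      "kshell_shift_per_charge": 0.0,
      "valence_binding": [13.598],
      "auger_rate": 0.0,
      "fluorescence_yield": 0.0
    },
    "C": {
      "Z": 6,
      "mass": 12.011,
      "sigma_photo": 1.13e-6,
      "kshell_binding": 284.2,
      "kshell_shift_per_charge": 15.0,
      "valence_binding": [11.26, 24.383, 47.888, 64.494, 392.09, 489.993],
      "auger_rate": 0.152,
      "fluorescence_yield": 0.0028
    },
    "N": {
      "Z": 7,
      "mass": 14.007,
      "sigma_photo": 2.24e-6,
      "kshell_binding": 409.9,
      "kshell_shift_per_charge": 17.0,
      "valence_binding": [14.534, 29.601, 47.449, 77.474, 97.89, 552.067, 667.046],
      "auger_rate": 0.197,
      "fluorescence_yield": 0.0052
    },
    "O": {
      "Z": 8,
      "mass": 15.999,
      "sigma_photo": 4.0e-6,
      "kshell_binding": 543.1,
      "kshell_shift_per_charge": 19.0,
      "valence_binding": [13.618, 35.121, 54.936, 77.414, 113.899, 138.119, 739.327, 871.41],
      "auger_rate": 0.244,
      "fluorescence_yield": 0.0083
    },
    "S": {
      "Z": 16,
      "mass": 32.06,
      "sigma_photo": 6.93e-5,
      "kshell_binding": 2472.0,
      "kshell_shift_per_charge": 25.0,
      "valence_binding": [10.36, 23.338, 34.86, 47.222, 72.595, 88.053, 280.954, 328.794, 379.84, 447.74, 504.55, 564.41, 652.2, 707.0, 3223.9, 3494.2],
      "auger_rate": 0.893,
      "fluorescence_yield": 0.078
    }
  }
}
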