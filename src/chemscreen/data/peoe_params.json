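{
  "version": 1,
  "comment": "Orbital electronegativity parameters chi(q) = a + b*q + c*q^2 (eV). Sigma parameters are the published partial-equalization (PEOE) values; pi and lone-pair tables are reconstructed approximations (see docs/methods.md). 'cation' is chi evaluated at q=+1 used as the normalization in the charge-transfer step; hydrogen uses the conventional 20.02.",
  "hydrogen_cation_chi": 20.02,
  "sigma": {
    "H":  {"s":   [7.17, 6.24, -0.56]},
    "C":  {"sp3": [7.98, 9.18, 1.88], "sp2": [8.79, 9.32, 1.51], "sp": [10.39, 9.45, 0.73]},
    "N":  {"sp3": [11.54, 10.82, 1.36], "sp2": [12.87, 11.15, 0.85], "sp": [15.68, 11.70, -0.27]},
    "O":  {"sp3": [14.18, 12.92, 1.39], "sp2": [17.07, 13.79, 0.47]},
    "F":  {"sp3": [14.66, 13.85, 2.31]},
    "Cl": {"sp3": [11.00, 9.69, 1.35]},
    "Br": {"sp3": [10.08, 8.47, 1.16]},
    "I":  {"sp3": [9.90, 7.96, 0.96]},
    "S":  {"sp3": [10.14, 9.13, 1.38], "sp2": [10.88, 9.49, 1.33]}
  },
  "pi": {
    "C":  {"sp2": [5.60, 8.93, 0.75], "sp": [7.60, 9.17, 0.62]},
    "N":  {"sp2": [7.95, 9.73, 0.27], "sp": [10.07, 10.43, 0.33]},
    "O":  {"sp2": [10.09, 11.73, 1.67]},
    "S":  {"sp2": [7.65, 8.40, 1.20]}
  },
  "lone_pair": {
    "N":  {"sp3": [12.32, 11.20, 1.10], "sp2": [13.60, 11.50, 0.90], "sp": [15.90, 12.00, 0.70]},
    "O":  {"sp3": [15.25, 13.20, 1.20], "sp2": [17.90, 14.10, 0.60]},
    "F":  {"sp3": [16.60, 14.00, 1.90]},
    "Cl": {"sp3": [12.45, 10.10, 1.30]},
    "Br": {"sp3": [11.30, 9.00, 1.10]},
    "I":  {"sp3": [10.70, 8.40, 0.90]},
    "S":  {"sp3": [11.40, 9.60, 1.30], "sp2": [12.10, 10.00, 1.20]}
  },
  "polarizability": {
    "H": 0.387, "C": 1.061, "N": 0.964, "O": 0.637, "F": 0.296,
    "S": 2.900, "Cl": 2.315, "Br": 3.013, "I": 5.415, "P": 1.538
  },
  "covalent_radius": {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "P": 1.07
  }
}
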