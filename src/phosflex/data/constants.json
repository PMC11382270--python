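{
  "version": 1,
  "comment": "Physical constants (SI) and gyromagnetic ratios in rad T^-1 s^-1.",
  "k_B": 1.380649e-23,
  "R": 8.31446261815324,
  "hbar": 1.054571817e-34,
  "mu0_over_4pi": 1e-07,
  "gamma": {
    "31P": 108400000.0,
    "1H": 267522187.44,
    "2H": 41066279.1,
    "13C": 67282840.0,
    "19F": 251814800.0
  }
}
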