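{
  "version": 1,
  "comment": "SYNTHETIC stand-in calibration for binary D2O/DMSO-d6 dynamic viscosity. Endpoint values are literature-like (eta(D2O, 298 K) ~ 1.095 mPa s, eta(DMSO-d6, 298 K) ~ 2.0 mPa s); mixing uses a Grunberg-Nissan excess term giving an interior maximum. Replace via configuration to use measured tables.",
  "units": {"eta": "mPa s", "T": "K"},
  "domain": {"phi": [0.0, 1.0], "T": [270.0, 360.0]},
  "vft_d2o": {"eta0": 0.03598, "B": 507.88, "T0": 149.3},
  "vft_dmso": {"eta0": 0.021208, "B": 900.0, "T0": 100.0},
  "grunberg_nissan_G": 3.0,
  "calibration_table_298K": {
    "phi": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "eta_mPa_s": [1.0949, 1.5232, 1.9956, 2.4623, 2.8612, 3.1311, 3.2269, 3.132, 2.8628, 2.4644, 1.9979]
  }
}
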