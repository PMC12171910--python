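{
  "ward": {
    "rho_ecw": 273.9,
    "rho_icw": 650.0,
    "body_density": 1.05,
    "kb": 4.3,
    "citation": "Apparent resistivity set in the style of the adult wrist-to-ankle coefficients of Ward and colleagues; rho_icw adjusted to keep rho_icw/rho_ecw below 5/2 (see methods note). Verify against the original publication before field use."
  },
  "moon": {
    "rho_ecw": 235.5,
    "rho_icw": 560.0,
    "body_density": 1.05,
    "kb": 4.3,
    "citation": "Apparent resistivity set in the style of Moon and colleagues; rho_icw adjusted to keep rho_icw/rho_ecw below 5/2 (see methods note). Verify against the original publication before field use."
  },
  "moissl": {
    "rho_ecw": 273.9,
    "rho_icw": 650.0,
    "body_density": 1.05,
    "kb": 4.3,
    "moissl_ecw_a": 0.188,
    "moissl_ecw_b": 0.2883,
    "moissl_icw_a": 5.8758,
    "moissl_icw_b": 0.4194,
    "citation": "BMI-adjusted mixture coefficients k = a/BMI + b after Moissl et al. (2006) Physiol Meas 27:921-933; intracellular volume here retains the Hanai implicit relation (see methods note)."
  }
}
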