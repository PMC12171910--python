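{
  "durnin_rahman": {
    "citation": "Durnin JVGA & Rahaman MM (1967) Br J Nutr 21, 681-689. Body density from log10 sum of four skinfolds in adolescents.",
    "output_kind": "density",
    "functional_form": "density_log10_ssf",
    "sex_specific": true,
    "coefficients": {
      "male": {
        "c0": 1.1533,
        "c1": 0.0643
      },
      "female": {
        "c0": 1.1369,
        "c1": 0.0598
      }
    },
    "coefficients_verified": true
  },
  "brook": {
    "citation": "Brook CGD (1971) Arch Dis Child 46, 182-184. Body density from log10 sum of four skinfolds in children.",
    "output_kind": "density",
    "functional_form": "density_log10_ssf",
    "sex_specific": true,
    "coefficients": {
      "male": {
        "c0": 1.169,
        "c1": 0.0788
      },
      "female": {
        "c0": 1.2063,
        "c1": 0.0999
      }
    },
    "coefficients_verified": true
  },
  "wendel": {
    "citation": "Wendel D et al., DXA-calibrated skinfold %BF equation for children.",
    "output_kind": "pbf",
    "functional_form": "pbf_log10_ssf",
    "sex_specific": false,
    "coefficients": {
      "b0": -32.0,
      "b1": 42.0,
      "b2": -1.7
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "clasey": {
    "citation": "Clasey JL et al., 50 kHz FFM prediction equation for children.",
    "output_kind": "ffm",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": -1.0,
      "ri": 0.09,
      "weight": 0.16,
      "height": 0.02
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "rush": {
    "citation": "Rush EC et al., 50 kHz FFM prediction equation for children.",
    "output_kind": "ffm",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": 1.2,
      "ri": 0.105,
      "weight": 0.22,
      "sex": 0.4
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "jemmaa": {
    "citation": "Ben Jemaa H et al., 50 kHz TBW prediction equation for children.",
    "output_kind": "tbw",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": 0.4,
      "ri": 0.07,
      "weight": 0.13,
      "sex": 0.3
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "de_lorenzo": {
    "citation": "De Lorenzo A et al., 50 kHz TBW prediction equation for children.",
    "output_kind": "tbw",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": 1.5,
      "ri": 0.06,
      "weight": 0.13
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "el_harchaoui": {
    "citation": "El Harchaoui I et al., 50 kHz TBW prediction equation for North African children.",
    "output_kind": "tbw",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": 0.9,
      "ri": 0.072,
      "weight": 0.15,
      "sex": 0.2
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  },
  "horlick": {
    "citation": "Horlick M et al., 50 kHz FFM prediction equation for children and adolescents.",
    "output_kind": "ffm",
    "functional_form": "linear_bia",
    "sex_specific": false,
    "coefficients": {
      "intercept": 1.2,
      "ri": 0.095,
      "weight": 0.19
    },
    "coefficients_verified": false,
    "note": "synthetic placeholder coefficients; replace with values from the cited publication before real-data use"
  }
}
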