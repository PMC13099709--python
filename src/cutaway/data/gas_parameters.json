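{
  "provenance": "CO2 impulse-response function: Joos et al. (2013) multi-model mean (PD100). CH4 and N2O perturbation lifetimes and stratospheric-adjusted radiative efficiencies: IPCC AR6 WG1 Chapter 7. The CH4 indirect factor folds in tropospheric ozone and stratospheric water vapour enhancement. CO2 marginal radiative efficiency is computed at run time by linearizing the simplified logarithmic concentration-forcing expression (5.35 ln(C/C0) W m-2) at the background concentration of each year.",
  "atmosphere": {
    "total_mass_kg": 5.135e18,
    "mean_molar_mass": 28.97
  },
  "co2_log_forcing_coefficient_w_m2": 5.35,
  "gases": {
    "CO2": {
      "molar_mass": 44.01,
      "impulse_response": {
        "fractions": [0.2173, 0.224, 0.2824, 0.2763],
        "time_constants_years": [null, 394.4, 36.54, 4.304]
      },
      "indirect_factor": 1.0
    },
    "CH4": {
      "molar_mass": 16.043,
      "lifetime_years": 11.8,
      "radiative_efficiency_w_m2_ppb": 0.000388,
      "indirect_factor": 1.65
    },
    "N2O": {
      "molar_mass": 44.013,
      "lifetime_years": 109.0,
      "radiative_efficiency_w_m2_ppb": 0.003,
      "indirect_factor": 1.0
    }
  }
}
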