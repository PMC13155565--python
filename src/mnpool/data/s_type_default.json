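{
  "schema_version": 1,
  "units": {
    "voltage": "mV (relative to rest)",
    "conductance": "uS",
    "capacitance": "pF",
    "current": "nA",
    "time": "ms",
    "geometry": "um",
    "resistance": "Mohm"
  },
  "n_units": 20,
  "smallest": {
    "geometry": {
      "soma_length_um": 77.5,
      "soma_diameter_um": 77.5,
      "dendrite_length_um": 5500.0,
      "dendrite_diameter_um": 41.5
    },
    "specific_capacitance_uF_cm2": 1.0,
    "axial_resistivity_ohm_cm": 70.0,
    "g_leak_soma_uS": 0.18869190875623695,
    "g_leak_dendrite_uS": 0.5975571026515587,
    "g_na_uS": 0.7547676350249478,
    "g_kfast_uS": 0.22643029050748434,
    "g_kslow_uS": 1.2076282160399165,
    "g_ca_uS": 0.0,
    "e_leak_mV": 0.0,
    "e_na_mV": 120.0,
    "e_kfast_mV": -10.0,
    "e_kslow_mV": -25.0,
    "e_ca_mV": 140.0,
    "e_excit_mV": 70.0,
    "e_inhib_mV": -16.0,
    "g_excit_uS": 0.97,
    "g_inhib_uS": 3.0,
    "rheobase_nA": 3.5,
    "input_resistance_Mohm": 1.956843392233214,
    "gating": {
      "pulse_ms": 0.6,
      "alpha_m": 22.0,
      "beta_m": 13.0,
      "alpha_h": 0.5,
      "beta_h": 4.0,
      "alpha_n": 1.5,
      "beta_n": 0.1,
      "alpha_q": 8.0,
      "beta_q": 0.02,
      "beta_p": 0.008
    }
  },
  "largest": {
    "geometry": {
      "soma_length_um": 82.5,
      "soma_diameter_um": 82.5,
      "dendrite_length_um": 6800.0,
      "dendrite_diameter_um": 62.5
    },
    "specific_capacitance_uF_cm2": 1.0,
    "axial_resistivity_ohm_cm": 70.0,
    "g_leak_soma_uS": 0.2138246499849553,
    "g_leak_dendrite_uS": 1.1126473981463851,
    "g_na_uS": 0.8552985999398212,
    "g_kfast_uS": 0.2565895799819463,
    "g_kslow_uS": 1.368477759903714,
    "g_ca_uS": 0.0,
    "e_leak_mV": 0.0,
    "e_na_mV": 120.0,
    "e_kfast_mV": -10.0,
    "e_kslow_mV": -25.0,
    "e_ca_mV": 140.0,
    "e_excit_mV": 70.0,
    "e_inhib_mV": -16.0,
    "g_excit_uS": 1.25,
    "g_inhib_uS": 3.0,
    "rheobase_nA": 6.5,
    "input_resistance_Mohm": 1.235953878209449,
    "gating": {
      "pulse_ms": 0.6,
      "alpha_m": 22.0,
      "beta_m": 13.0,
      "alpha_h": 0.5,
      "beta_h": 4.0,
      "alpha_n": 1.5,
      "beta_n": 0.1,
      "alpha_q": 8.0,
      "beta_q": 0.02,
      "beta_p": 0.008
    }
  }
}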