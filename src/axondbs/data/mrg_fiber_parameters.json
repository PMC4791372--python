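{
  "comment": "Double-cable myelinated axon parameters (McIntyre-Richardson-Grill mammalian motor axon, ModelDB 3810). Geometry rows keyed by fiber outer diameter in micrometers. Lengths/diameters in um, conductance densities in S/cm2, capacitances in uF/cm2, resistivities in ohm-cm, potentials in mV.",
  "global": {
    "rho_axial_ohm_cm": 70.0,
    "node_length_um": 1.0,
    "mysa_length_um": 3.0,
    "n_stin_per_internode": 6,
    "periaxonal_space_node_um": 0.002,
    "periaxonal_space_mysa_um": 0.002,
    "periaxonal_space_flut_um": 0.004,
    "periaxonal_space_stin_um": 0.004,
    "c_axolemma_uf_cm2": 2.0,
    "myelin_c_per_lamella_uf_cm2": 0.1,
    "myelin_g_per_lamella_s_cm2": 0.001,
    "g_pas_mysa_s_cm2": 0.001,
    "g_pas_flut_s_cm2": 0.0001,
    "g_pas_stin_s_cm2": 0.0001,
    "e_pas_mv": -80.0,
    "v_rest_mv": -80.0,
    "temperature_c": 36.0
  },
  "node": {
    "gnaf_max_s_cm2": 3.0,
    "gnap_max_s_cm2": 0.01,
    "gks_max_s_cm2": 0.08,
    "glk_s_cm2": 0.007,
    "e_na_mv": 50.0,
    "e_k_mv": -90.0,
    "e_lk_mv": -90.0,
    "c_m_uf_cm2": 2.0
  },
  "diameters": {
    "5.7": {
      "internode_spacing_um": 500.0,
      "node_diameter_um": 1.9,
      "mysa_diameter_um": 1.9,
      "axon_diameter_um": 3.4,
      "flut_length_um": 35.0,
      "n_myelin_lamellae": 80
    },
    "10.0": {
      "internode_spacing_um": 1150.0,
      "node_diameter_um": 3.3,
      "mysa_diameter_um": 3.3,
      "axon_diameter_um": 6.9,
      "flut_length_um": 46.0,
      "n_myelin_lamellae": 120
    },
    "15.0": {
      "internode_spacing_um": 1450.0,
      "node_diameter_um": 5.0,
      "mysa_diameter_um": 5.0,
      "axon_diameter_um": 11.5,
      "flut_length_um": 60.0,
      "n_myelin_lamellae": 145
    }
  }
}
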