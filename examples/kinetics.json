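{
  "r_enzyme": 3.0,
  "enzyme_out": 5e-7,
  "substrate_out_0": 8e-5,
  "k_cat": 3.0,
  "K_M": 0.004,
  "permeability": 1e-7,
  "diameter_um": 1.3,
  "unitary_volume": 50.0,
  "t_end": 1800.0,
  "output_step": 1.0
}
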