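{
 "nu": 0.1,
 "phi": 0.1,
 "phi_2": 10.0,
 "gamma_a": 1.0,
 "gamma_m": 0.01,
 "gamma_m2": 0.01,
 "gamma_g": 1.0,
 "gamma_e": 0.1,
 "gamma_h": 0.1,
 "k_n": 0.01,
 "k_g": 0.1,
 "k_h": 0.1,
 "k_m": 0.0001,
 "k_m1": 30.0,
 "k_m2": 0.3,
 "beta_a": 0.1,
 "beta_n": 0.1,
 "beta_c": 0.12,
 "beta_g": 0.01,
 "nu_2": 0.01,
 "chi_h": 1.0,
 "r_1": 1.0,
 "r_2": 1.0
}
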