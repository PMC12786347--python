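# Two-population (PING) firing-rate-equation node: excitatory and
# inhibitory QIF mean fields with NMDA gating toward both populations.
# Time constants in ms; the Lorentzian centers put isolated populations
# in the excitable low-rate regime.
tau_e: 10.0
tau_i: 10.0
tau_N: 100.0
Delta_e: 1.0
Delta_i: 1.0
eta_e: -5.0
eta_i: -5.0
g_e: 0.0
g_i: 0.0
J_ee_N: 15.0
J_ie_N: 15.0
J_A: 1.0
J_ei_G: 8.0
J_ii_G: 8.0
a: 1.0
G: 0.0
J: 1.0
I_ext_e: 0.0
I_ext_i: 0.0
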