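# Standard resting-state parameter set of the balanced
# excitation-inhibition (reduced Wong-Wang) model.  Under these values an
# isolated node fires spontaneously at ~3 Hz.
# Units: currents nA, time constants ms, gain slope nC^-1, curvature s.
W_E: 1.0
W_I: 0.7
I_o: 0.382
w_plus: 1.4
J_N: 0.15
lambda_: 0.0
a_E: 310.0
b_E: 125.0
d_E: 0.16
a_I: 615.0
b_I: 177.0
d_I: 0.087
tau_E: 100.0
tau_I: 10.0
gamma_kin: 0.641
I_ext: 0.0
G: 0.0
J: 1.0
g_E: 1.0
g_I: 1.0
gain_scale: 0.0
receptor_density: 0.0
modulate_inhibitory: false
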