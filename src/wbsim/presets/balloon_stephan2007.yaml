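# Balloon-Windkessel hemodynamic constants (Stephan-et-al.-2007-style
# parameterization; readout coefficients derived from theta0 = 40.3 1/s,
# r0 = 25 1/s, TE = 0.04 s, epsilon = 0.5).
kappa: 0.65
gamma_h: 0.41
tau_h: 0.98
alpha: 0.32
rho: 0.34
v0: 0.04
k1: 2.356744     # 4.3 * 40.3 * rho * TE
k2: 0.17         # epsilon * 25 * rho * TE
k3: 0.5          # 1 - epsilon
variant: standard
sampling_period: 2.0
drive_scale: 0.5
drive_offset: 3.0
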