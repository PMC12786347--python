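# Methods

This note records the modelling assumptions, unit conventions, numerical
choices, and limitations behind `wbsim`, in the order the pipeline runs.

## Structural connectivity and delays

A connectome is a full, nonnegative `weights` matrix with no symmetry
assumption (directed tractography estimates are used as-is); row *k*
collects the incoming connections of region *k*, so the network input to
*k* is `sum_j C[k, j] * x_j`.  Self-connections are not modelled: a
nonzero diagonal is zeroed at load with a warning rather than rejected,
since such entries are almost always artefacts of the tractography
pipeline.  Tract lengths (mm) are optional; when present, conduction
delays are `round(L / (v * dt))` integration steps with
half-away-from-zero rounding (the dominant convention among reference
simulators; the choice only matters at the half-step boundary).  Delayed
coupling reads the state at the nearest whole step — no interpolation —
which is exact for delays that are multiples of `dt` and accurate to
`O(dt)` otherwise.

The synthetic connectome generator draws an Erdős–Rényi directed graph
(edge probability = `density`), log-normal weights rescaled so the
maximum equals `weight_scale`, and uniform tract lengths on existing
edges.  Defaults (density 0.3, max weight 1, lengths 20–160 mm) give
row sums and weight dispersion in the range of empirical
parcellation-level connectomes after the usual max-normalization.  What
the generator does *not* emulate: the lognormal-with-distance-decay
weight–length correlation, hemispheric symmetry, and community
structure of real connectomes.  Tests passing on these graphs therefore
establish correctness of the machinery, not goodness-of-fit to any
empirical dataset.

## Unit conventions

Time is in milliseconds everywhere in the dynamics; firing rates are in
Hz, currents in nA, conduction speed in mm/ms.  Where a rate multiplies
a time derivative (the BEI gating equations, the AdEx adaptation
equation) the implicit Hz → 1/ms factor of 1e-3 is applied, so time
constants can be stated in their customary ms values.  Hemodynamic
constants are in seconds and 1/s (the literature's convention); the
BOLD integrators convert `dt` internally.  The FRE equations are kept in
their natural nondimensionalized form (r in 1/ms); the observable
`r_e_Hz` reports 1000·r for comparison with the other models.

## BEI model

The gain function `H(I) = x / (1 - exp(-d x))`, `x = M (a I - b)`, is
evaluated with `expm1` and switches to its Taylor form `1/d + x/2`
inside `|d x| < 1e-10`, making it continuous through the analytic limit
`H = 1/d` at `I = b/a`.  The shipped `bei_deco2014` preset is the
standard resting-state set (`W_E = 1`, `W_I = 0.7`, `I_o = 0.382` nA,
`w_+ = 1.4`, `J_N = 0.15` nA, `a_E = 310`, `b_E = 125`, `d_E = 0.16`,
`a_I = 615`, `b_I = 177`, `d_I = 0.087`, `tau_E = 100` ms,
`tau_I = 10` ms, `gamma = 0.641`); its isolated-node deterministic fixed
point sits at r_E = 3.08 Hz, the "~3 Hz" spontaneous regime of the
electrophysiology literature.  Under the default stochastic conditions
(sigma = 0.01 on both gating equations, dt = 0.1 ms) the *time-averaged*
isolated rate is slightly higher (~3.3–3.4 Hz) because the gain function
is convex around the operating point; this is a property of the model
under noise, not an integration artefact.

Receptor-density gain modulation applies to the excitatory gain by
default (`M_k^E = g_E (1 + s rho_k)`); an explicit
`modulate_inhibitory` flag extends the same form to `M^I`, since the
neuromodulation literature describes the scaling as acting on both
populations while only printing the excitatory form.

## FRE model

The two-population (PING) node follows the whole-brain extension of the
QIF mean field, with NMDA gating variables `S_ee, S_ie` driven by the
excitatory rate, GABA weights into both populations, a long-range AMPA
term `G J_A tau_e sum C S_ee`, and per-region FIC factors `J_j` on the
I→E weight.  The electrical-synapse "virtual chemical synapse" term
`g ln(a) tau r` is included in both voltage equations so that the
single-population limit (G = 0, GABA weights 0, `tau_N = dt` slaving the
gating variables under Euler-type schemes) recovers the one-population
equations exactly; at spike asymmetry `a = 1` the term vanishes and
only the subtractive `-g r` effect of gap junctions remains.  Noise,
when enabled, targets only the two gating variables (mask
`FREModel.noise_mask`).

## Mean-field AdEx

The printed formulation of the first-order mean equations and the
adaptation equation is anti-relaxational (trajectories diverge from the
transfer function and adaptation grows without bound); `wbsim`
implements the stable convention `T dnu/dt = F - nu`,
`dW/dt = -W/tau_w + b nu_e`, and offers `strict_signs=True` to
reproduce the printed signs for side-by-side comparison.

The transfer function is the semi-analytic error-function form: synaptic
shot-noise theory maps (nu_e, nu_i, W) to the subthreshold membrane
statistics (mu_V, sigma_V, tau_V) of a conductance-based neuron
(defaults: g_L = 10 nS, E_L = -65 mV, C = 200 pF, E_e = 0, E_i = -80 mV,
Q_e = 1.5 nS, Q_i = 5 nS, tau_syn = 5 ms, K_e = 400, K_i = 100), and
`F = erfc((V_eff - mu_V) / (sqrt(2) sigma_V)) / (2 tau_V)`.  The
effective threshold `V_eff` is a quadratic polynomial in the normalized
statistics with a pluggable 10-coefficient vector; the shipped default
keeps only the constant term (-50 mV).  Deriving fitted coefficient
vectors from single-neuron simulations is out of scope, so quantitative
claims about any specific published AdEx parameterization are not made;
the default is smooth, nonnegative, and monotone in nu_e over the
physiological range (verified by grid scan in the tests).

Second-order covariance dynamics follow the standard finite-size
expansion with `A = F (1/T - F) / N` on the diagonal; first and second
derivatives of F are central finite differences with step 1e-4 Hz.
Because the Hessian divides float rounding by h², two independent
evaluations of the same second-order derivative agree to ~1e-8 absolute
rather than machine precision; the tests assert 1e-6 relative there and
1e-12 for the algebraic models.

## Integration and noise

Four fixed-step schemes: Euler, Euler–Maruyama, Heun, stochastic Heun.
Additive noise enters as `sigma * sqrt(dt) * xi` per variable and
region, with one draw per step; stochastic Heun shares that single
draw between predictor and corrector (the standard choice for additive
noise).  The coupling term is evaluated once per step from the delay
history and held fixed across Heun's two stages.  Default `dt` is
0.1 ms.  The delay ring buffer is pre-filled with the initial
coupling-variable values (zeros for the default zero initial state).
Monitors record the post-step state; named observables (e.g. `r_E`) are
those computed by the derivative call at the step's start, a half-step
offset that is irrelevant at the averaging periods used (≥ 1 ms).

Empirical convergence orders (global error 1 for Euler, 2 for Heun on a
linear test equation) and the Ornstein–Uhlenbeck stationary variance
`sigma^2 tau / 2` are asserted in the test suite.

## BOLD

The Balloon–Windkessel equations use the neural drive
`drive = 0.5 r + 3` as printed in the source formulation, kept behind
configurable `(drive_scale, drive_offset)` so the conventional
`drive = r` form is available.  The inflow equation is `df/dt = s`
(the transit time tau_h appears only in the volume and deoxyhemoglobin
equations), resolving a typographical ambiguity in the printed system
in favour of the standard hemodynamic model.  Constants default to a
Stephan-2007-style parameterization (kappa = 0.65/s, gamma = 0.41/s,
tau_h = 0.98 s, alpha = 0.32, rho = 0.34, v0 = 0.04, TE = 0.04 s,
k1 = 4.3·40.3·rho·TE, k2 = 0.5·25·rho·TE, k3 = 0.5) shipped as the
`balloon_stephan2007` preset and fully overridable.  The ODEs are
integrated with deterministic Euler at the input sampling step; the
log-state variant integrates ln f, ln v, ln q (derivative F(z)/z) and
exponentiates, guaranteeing positivity at any step size, while the
standard variant raises (never clips) if a positive state crosses zero.
Default TR is 2 s.

The HRF route convolves each region with the first-order Volterra
kernel `exp(-t / (2 tau_s)) sin(omega t) / omega`,
`omega = sqrt(1/tau_f - 1/(4 tau_s^2))` (tau_s = 0.8 s, tau_f = 0.4 s,
20 s support) — the impulse response of the linearized flow cascade.

## Observables

Static FC is the Pearson correlation across time; zero-variance regions
yield flagged NaN entries that are excluded (and counted) rather than
silently dropped.  swFCD computes FC per sliding window and correlates
upper-triangle vectors across window pairs, returning the upper
triangle of the window-similarity matrix as the FCD sample (defaults:
window 30 samples, step 3).  Phase FCD demeans each region, takes
Hilbert-transform phases, forms the instantaneous coherence
`cos(phi_i - phi_j)`, summarizes each window by its time-mean
upper-triangle coherence vector, and compares windows by cosine
similarity.  This is one concrete realization of the phase-FCD idea —
descriptions in the literature are loose on the pairwise-window
reduction — and alternative constructions can be plugged in behind the
same contract.  No narrowband pre-filter is applied by default.
Distances: two-sample KS statistic on FCD samples, L2 on matched
observables, Pearson on FC upper triangles.

## Feedback Inhibition Control

The published description fixes the goal (excitatory rates clamped at
~3 Hz for every G) but not the optimizer.  `fic_tune` uses a
multiplicative update `J_k <- J_k (1 + eta_k (r_k - target) / target)`
with per-region steps halved whenever a region's error changes sign
(floored at `eta_min` so that measurement noise cannot freeze the
iteration); rates are measured from Euler–Maruyama runs (defaults: 2 s
settle, 8 s measurement, sigma = 0.01, tolerance 0.3 Hz, at most 50
iterations).  The rate-based rule targets the quantity the clamp is
stated in; the classical current-based criterion (mean excitatory input
clamped at `b_E/a_E - 0.026` nA) is available as `strategy="current"`.
Non-convergence returns the best-so-far J with the full deviation trace
rather than raising.

Measurement design matters more than the update rule here.  A clamped
network at sizeable G lives close to the ignition instability and shows
slow, spatially coherent rate fluctuations (multi-second correlation
times; on a 20-node graph, 10-s block means of the network rate vary by
+-0.5 Hz around the target).  A single measurement window is therefore
a seed-dependent estimate of the expected rate, and a stopping rule
that accepts the first window inside the tolerance band systematically
selects noise excursions, returning a mis-tuned J.  `fic_tune` guards
against this by switching, once the deviation enters twice the
tolerance band, to measurements averaged over four independent windows
(fresh noise seeds — more effective against slow collective
fluctuations than one equally long window) and declaring convergence
only on such seed-averaged estimates.  `rate_sweep` reuses the loop
across a G grid (warm-starting J from the previous grid point) to
generate maximum-rate-versus-G curves with and without FIC.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run desk-scale versions of
the study conditions: 30 s single-node and 20-node simulations at
dt = 0.1 ms for the rate targets, 10 s windows inside FIC (averaged
over four independent seeds near convergence, and over eight fresh
30 s re-simulations when reporting the clamped network rate — the
slow collective fluctuations described above make single windows
±0.3–0.4 Hz estimates of the expectation), 1–2 min of synthetic rate
input for the hemodynamic cross-checks, and 10^6 state updates for
the stochastic-integrator calibration.  These sizes were chosen so
the full pipeline re-runs from scratch in minutes on one CPU while
keeping every statistical assertion inside its stated tolerance.

## Known limitations

* No EEG/MEG forward models; BOLD is the only measurement model.
* Linear coupling only (matching the scope of the simulated platform);
  other coupling functions would slot into `linear_coupling`'s
  contract.
* No adaptive step size or higher-order SDE schemes; parameter sweeps
  parallelize at the process level, not inside a step.
* AdEx transfer-function coefficients are not fitted to any specific
  single-neuron model (see above).
* The delay buffer stores the full dense history at the maximum lag;
  memory grows as `max_delay x n_regions`, which is negligible for
  parcellation-scale models but would matter for vertex-level surfaces.
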