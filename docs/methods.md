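# Methods

## The models

`massfield` implements the exact mean-field ("next-generation") description
of all-to-all coupled quadratic integrate-and-fire (QIF) populations with
both chemical synapses and gap junctions, together with the microscopic
network it reduces, its spatial (neural field) extension with axonal delays,
and the linear stability theory of the spatially uniform state.

**Microscopic network.** N QIF neurons,

    tau dv_i/dt = eta_i + v_i^2 + (kappa_v/N) sum_j (v_j - v_i)
                  + (kappa_s/N) sum_{j,m} s(t - T_j^m),

with reset v -> v_r on reaching v_th, Lorentzian-distributed background
drives eta_i (median eta0, half-width gamma), and the synaptic response
s(t) = alpha^2 t e^{-alpha t} H(t), the Green's function of
Q = (1 + alpha^-1 d/dt)^2.  Time is in milliseconds throughout; rates R are
in spikes/ms per neuron (so 0.02 corresponds to 20 Hz).

**Mean field.** In the thermodynamic limit the network reduces exactly to

    tau dR/dt = -kappa_v R + 2 R V + gamma/(pi tau)
    tau dV/dt = eta0 + V^2 - pi^2 tau^2 R^2 + kappa_s U,     Q U = R.

Gap junctions appear as the -kappa_v R damping of the rate equation;
heterogeneity gamma acts as a rate source.  The complex Kuramoto order
parameter is recovered through the conformal (Moebius) map
Z = (1 - W*)/(1 + W*), W = pi tau R + i V; the package always evolves
(R, V, U) and obtains |Z| through the map (the equivalent Z-ODE is not
integrated).  External stimulation enters as eta0 -> eta0 + A(t).

**Two populations.** The E-I extension carries (R_a, V_a) for a in {E, I}
and four synaptic variables U_ab (target a, source b), each with its own
rise rate alpha_ab; gap junctions act only within a population.  Connection
subscripts are target-source: kappa_s_IE is the excitatory drive onto I.
Inhibition is encoded by the sign of kappa_s_ab.

**Neural field.** On a periodic interval or square the local dynamics are
unchanged but QU = Psi with the delayed spatial drive

    Psi(r, t) = Int w(|r - r'|) R(r', t - |r - r'|/c) dr',

with the balanced wizard-hat kernels w(x) = (|x|-1)e^{-|x|} (1D) and
w(r) = (r/2-1)e^{-r}/(2 pi) (2D) and axonal speed c.  kappa_s > 0 gives the
inverted hat (long-range excitation); kappa_s < 0 realises the regular hat.
Gap junctions have no spatial extent: they live inside the local mass
dynamics only.

## Numerics

**Mass/E-I integration** uses adaptive RK45 (`scipy.solve_ivp`) with
rtol 1e-8 (1e-6 for large attractor sweeps, where only classification and
extrema matter), a blow-up event at |y| = 1e6, and fixed output sampling.

**Network integration** is fixed step (default dt = 0.01 tau) but solves
the stiff local problem exactly: with the coupling drive frozen over a
step, each neuron obeys a constant-coefficient Riccati equation
tau dv/dt = v^2 - kappa_v v + a_i whose flow has tan/tanh closed forms.
Threshold passages are located exactly within the step and the neuron is
restarted from v_r for the remainder.  Naive explicit stepping is useless
here: with v_th = -v_r = 1000 the quadratic term makes dt v^2/tau overshoot
the entire subthreshold range from reset.  The exact local flow leaves only
the O(dt) error of freezing the coupling; the tonic-neuron period is
reproduced to 0.13% at the default step.  Population observables: the rate
is a 5 ms (default) centred boxcar count; the population voltage excludes
samples within 1 ms of a reset to suppress the spike/reset artefact of the
finite threshold (unstated in the source material for the corresponding
published traces; declared here); Z is the phase average of
exp(2i arctan v).

**Delayed convolution.** Distances are minimum-image on the periodic
domain; the kernel is truncated where |w| < 1e-8 (radius ~ 21).  Each
spatial offset contributes its quadrature weight w(d) dx^dim at delay d/c,
split linearly between the two neighbouring solver steps - exact linear
interpolation of the rate history in time.  The self-weight is corrected so
the discrete weights sum exactly to zero ("discrete balance"), making the
uniform steady state an equilibrium of the discrete scheme as it is of the
continuum model.  Two evaluation paths implement the identical quadrature:
a direct per-offset summation (reference, used on small grids and in the
equivalence test) and the default spectral path, which stores the FFT of
each history slice once and accumulates Psi-hat = sum_j W-hat_j R-hat(t - j
dt).  Time stepping is explicit Heun; the predictor rate is pushed into the
history ring so the corrector sees a consistent t + dt drive.  Step limits:
dt <= tau/100 and dt <= 0.25 dx/c (delay resolution; waived when the whole
truncated kernel is reached within one step, i.e. effectively instantaneous
interactions).

A subtlety worth recording: a *time-varying* spatially uniform state is not
equivalent to the uncoupled mass model, because the delayed zero mode
G(0, lambda) vanishes only at lambda = 0.  The uniform reduction is exact
at the steady state and in the c -> infinity limit, and is tested in both
forms.

**Linear stability.** Linearising about the uniform steady state
(R0, V0, U0 = 0 by kernel balance) and eliminating the synapse gives the
scalar characteristic function

    E(k, lambda) = (tau lambda + kappa_v - 2 V0)(tau lambda - 2 V0)(1 + lambda/alpha)^2
                   + 4 pi^2 tau^2 R0^2 (1 + lambda/alpha)^2
                   - 2 R0 kappa_s G(k, lambda),

with G the Fourier transform of w(.) e^{-lambda|.|/c} (closed forms in
`kernels.py`, checked against quadrature to 1e-8).  In 1D, multiplying by
(beta^2 + k^2)^2 (beta = 1 + lambda/c) clears G exactly and E = 0 becomes a
degree-8 polynomial; roots violating the causal branch Re(beta) > 0 are
discarded.  In 2D (half-integer powers, principal branch with Re >= 0) the
leading root is found by damped Newton iteration with multi-starts (the
kappa_s = 0 factors, the 1D roots, the previous k) and continuation along
the k grid.  Thresholds are bisected on the branch growth rate to 1e-6 in
the parameter; classification uses eps_k = eps_omega = 1e-3 (Hopf: k_c ~ 0,
omega_c > 0; Turing: k_c > 0, omega_c ~ 0; Turing-Hopf: both positive).
The Turing-Hopf branch measure is the dispersion maximum away from k = 0
(beyond the first interior minimum when a k = 0 lobe dominates).  k is
treated as continuous (infinite-domain idealisation); quantised modes
2 pi m / L are used only when comparing against simulations.

**Attractor sweeps** (E-I bistability) run forward and backward
continuation (each attractor's end state seeds the next parameter value)
plus a perturbed fixed point and a large kick at every grid point,
classify trajectories by post-transient extrema (oscillatory if
peak-to-peak > 1e-4 with >= 5 periods, with a decay guard comparing the two
half-windows), and call two oscillations distinct when their extrema
differ by more than 5 noise floors (0.02) plus 10% of scale.  Window edges
are sharpened by bisection that continues the dying branch from its nearest
surviving state (T = 1500 ms per probe, edge tolerance 0.05).  Unstable
orbits are not continued; everything reported is an attractor of the flow.

**Spectrograms.** The default path is a 6-cycle analytic Morlet continuous
wavelet transform evaluated in the frequency domain with unit-energy
normalisation per scale; total-power reconstruction uses a numerically
self-calibrated reconstruction constant (transform of a unit impulse) and
recovers white-noise variance within ~1%.  An STFT path
(`scipy.signal.ShortTimeFFT`, PSD scaling) is available and the rebound
verdicts agree across both.  Beta band: 13-30 Hz on the millisecond time
base.  The movement protocol applies a first-order-filtered square pulse
(400 ms, magnitude 3 units of drive, tau_f = 50 ms; verdicts are
insensitive over tau_f in [20, 100] ms) to eta0; baseline is the mean band
power of the synaptic current kappa_s U over the 1000 ms before onset;
"drop" means < 0.8 baseline during the pulse, "overshoot" > 1.2 baseline
within 500 ms after offset, and a "rebound" verdict requires an oscillatory
baseline as well - without one, an overshoot only measures the pulse
transient against a noise floor.

## Study conditions and problem sizes

Defaults reproduce the studied regimes: the mean-field validation run
(eta0=2, kappa_v=kappa_s=1, tau=16, alpha=0.5, gamma=0.5, N=1000,
v_th=-v_r=1000), the beta-band mass regime (tau=15, alpha=0.1), the E-I
regime (tau=1 ms populations, mixed alphas, strong cross couplings), the 1D
wave regime (eta0=1, kappa_s=10, tau=15) and the 2D rotating-wave regime
(eta0=2, kappa_s=12, tau=20).  For the spatial runs the source material does
not state domain sizes or grids; this package uses L = 40 pi, n = 256 in 1D
and L = 30, n = 64 in 2D (dx ~ 0.47, about 16 points per critical
wavelength 2 pi / k_c with k_c ~ 0.82), sizes chosen so that a handful of
pattern wavelengths fit while long transients (3-5 s of model time) remain
affordable; pattern-level quantities are treated as scale-reduced
reproductions.  The 2D rotating-wave protocol perturbs the uniform state
with a periodic lattice matched to k_c (4 cells per side) plus small seeded
noise - a perfectly symmetric lattice preserves the D4 symmetry and
oscillates as a standing lattice indefinitely; rotation requires the
symmetry to be broken.  The synchrony probe is the grid point with the
largest temporal standard deviation of |Z|, which by construction sits next
to a rotating core.

The synthetic initial conditions (noise, Gaussian bump, bars, lattice,
single modes) emulate the perturbation protocols of the studied
experiments, not biological variability: there is no measurement noise, no
parameter heterogeneity beyond the Lorentzian drives, and no spatial
heterogeneity of the kernel.  Passing tests therefore certify the
mathematical behaviour of the model under these idealised conditions, not
goodness-of-fit to recorded EEG/MEG data.

## Known limitations

- Attractor sweeps see only stable objects.  In the E-I bistability regime
  the moderate-amplitude branch loses orbital stability near eta0_I ~ -4.8
  in this implementation (deterministic escape, tolerance-independent), so
  the stable-coexistence window reported by sweeps is narrower from above
  than a continuation-based branch diagram; the lower edge agrees with the
  published value.  Certifying the branch beyond that point would require
  periodic-orbit continuation with Floquet analysis, which is out of scope.
- The saturated limit-cycle frequency of the single population is nearly
  flat in kappa_v, while the linear (Hopf) frequency grows with it;
  monotone frequency growth holds for the eigenvalue measure.
- The reference direct convolution is O(n^2) per delay slice and only
  suitable for small grids; production runs use the spectral path, whose
  equivalence is asserted to 1e-12 in the tests.
- Spatial quadrature of the kernel is a rectangle rule: transfer-function
  ratios measured on the grid agree with the closed forms to O(dx^2)
  (about 2% at dx ~ 0.5, 0.1% at dx ~ 0.12).
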