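# Methods

This note documents the model, the numerical choices and the open design
decisions behind `quasiburst`, in the spirit of a package methods
appendix. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Model and reduction chain

**Microscopic level.** `N_E` excitatory and `N_I` inhibitory two-state
neurons, all-to-all coupled with population-level synaptic weights
`W_ee, W_ei, W_ie, W_ii ≥ 0` (each synapse carries `W/N` of the total,
inhibitory signs applied in the input), external drives `h_E, h_I`,
deactivation rates `α_E, α_I` and activation rates `β_i f(s_i)` with a
logistic response `f(s) = 1/(1+e^{−s})`. The aggregate state `(k, l)` of
active counts is a Markov jump process with four channels
(`k·α_E`, `(N_E−k)·β_E f(s_E)`, `l·α_I`, `(N_I−l)·β_I f(s_I)`), which
`simulate_gillespie` samples exactly. A per-neuron raster is recovered
afterwards by assigning each aggregate event to a uniformly chosen
eligible neuron — exact in distribution by exchangeability, and orders of
magnitude faster than a per-neuron event queue.

**Rate level.** Population activities follow stochastic Wilson–Cowan
equations with multiplicative noise of variance
`((1−E)β_E f(s_E) + α_E E)/N_E` (and the I analogue). `simulate_rate_sde`
integrates them by Euler–Maruyama (default `dt = 0.01 ms`), clipping to
`[0, 1]` and logging clip counts (a warning fires above 0.1% of steps).

**Linear level.** Around the stable fixed point, fluctuations scaled by
`√N` obey linear SDEs with drift matrix `A` and additive noise
`σ_E = √(2 α_E E₀*)`, `σ_I = √(2 α_I I₀*)`. Both printed algebraic forms
of the `A` entries (the `f′`-based and the fixed-point-substituted one)
are implemented and agree to `1e−10` — an identity that holds only for
the logistic response, which is why logistic is the default and the
alternative (`erf`) is opt-in.

**Envelope–phase level.** With `λ = −ν ± iω₀`,
`ν = −(A₁₁+A₂₂)/2 > 0` in transient synchrony, stochastic averaging gives
the Rayleigh-process envelope and a phase performing envelope-dependent
Brownian motion, with a single effective noise strength `D`.
`simulate_sam` never integrates the envelope equation directly; it uses
the exact representation as the modulus/angle of two independent OU
processes, which keeps `Z ≥ 0` by construction.

## The two pairings of the noise intensities in D

The stochastic-averaging result is

    D = −(A₁₂ / 2ω₀²) (−A₁₂ σ_I² + A₂₁ σ_E²)        (default, "sam")

The package certifies this form against an independent exact benchmark:
the stationary variance `Σ₁₁` of the linear system from the Lyapunov
equation. The reduction predicts `E[Z²] = D/ν = 2Σ₁₁`; at the four
standard working points the two sides agree to 1.2%, 0.7%, 0.3%, 0.15% —
an error `O(ν/ω₀)` that vanishes toward the oscillatory transition,
exactly as an averaging approximation should.

A second pairing, with `σ_E²` and `σ_I²` interchanged ("swapped"), is
7–15% smaller at these points. It does **not** match the Lyapunov
benchmark, but it is the convention under which the widely quoted
reference (ν, D, R) tables for the four working points were produced, so
it is kept available and is what `scripts/acceptance.py` reports for the
D and R targets. Note that one reference table entry
(D = 0.0613 at the third point) is internally inconsistent with its own
R = 1.6900 via `R = √(D/2ν)`; the value consistent with R is 0.0631 (a
digit transposition). Every *time-domain* burst statistic is invariant to
this choice: thresholds scale with R, so durations and frequency
statistics depend only on (ν, ω₀).

## Dynamical regimes

- `transient_synchrony`: `ν > 0`, `ω₀ > 0` — damped spiral, rhythm
  sustained by noise (quasi-cycle). The reduction applies only here.
- `high_synchrony`: `ν < 0`, `ω₀ > 0` — above the Hopf bifurcation,
  oscillations persist without noise.
- `asynchronous`: real eigenvalues with `ν > 0` — a stable node, no
  rhythm. (Real eigenvalues with `ν < 0` are flagged
  `unstable_non_oscillatory`.) The `ν = 0` contour and the real-eigenvalue
  boundary are obtained from dense grids plus bisection
  (`nu_zero_crossing`), not continuation software.

## Numerical choices

- **Fixed point**: forward integration of the deterministic flow from
  `(0.1, 0.1)` followed by root polishing; residual must be `< 1e−10`.
  Under multistability this selects the attractor of that initial
  condition; `find_fixed_points` enumerates all roots for diagnostics.
- **Linear SDEs are sampled exactly.** Euler–Maruyama inflates the
  stationary variance of a damped oscillator by `≈ |λ|² dt / 2ν` — about
  7% at the working points for `dt = 0.01 ms`, which would contaminate
  every envelope comparison. `simulate_lna` therefore uses the exact
  Gaussian transition (Van Loan block exponential for the propagator and
  integrated noise covariance), and the OU pair behind `simulate_sam`
  uses the exact OU update; both are unbiased at any step size.
- **Burn-in**: 500 ms discarded by default from every simulator (the
  microscopic chain also starts at the rounded mean-field fixed point, so
  transients are short).
- **Envelope sampling step for burst work**: 0.05 ms. Threshold-crossing
  statistics of a diffusion are resolution-dependent (finer sampling
  resolves brief sub-threshold dips that split epochs); at 0.05 ms mean
  durations change by under 2% on further halving.
- **Monte-Carlo passage times** use Euler–Maruyama with sign-mirroring at
  the reflecting boundary and the standard continuity correction
  (absorbing barrier shifted inward by `0.5826 √(D dt)`) to cancel the
  `O(√dt)` discrete-monitoring bias.
- **LFP construction**: mean removal then a 2nd-order Butterworth
  band-pass (default 20–100 Hz) applied forward–backward, so filtering is
  zero-phase and burst timing is not lagged. Note a 2nd-order band-pass is
  not flat across the band: the squared response at 85 Hz is ≈ 0.74, and
  the unit-gain point is the geometric band centre (≈ 45 Hz); tests check
  gains against the designed transfer function, not against 1.
- **Instantaneous frequency**: centred difference of the unwrapped Hilbert
  phase, then a 5 ms moving average; the first/last two mean periods are
  excluded from all statistics (edge effects).

## Burst extraction

Candidates are maximal intervals with `env > b`; boundaries are the
`b`-crossings with linear interpolation (sub-sample accuracy). The
secondary two-cycle criterion that removes threshold-grazing fluctuations
exists in two formalizations:

- `min_duration` (default): the candidate must span at least
  `2·2π/ω₀` and exceed the envelope mean somewhere inside it;
- `super_mean_run`: the candidate must contain a *contiguous* two-cycle
  stretch above the envelope mean.

The default reproduces the reference mean duration at the intermediate
working point (74.5–76 ms over 500 s runs); the stricter run-based
variant discards many medium-length epochs and yields systematically
longer means (~120 ms there). Per-burst peak frequency is the periodogram
maximum of the LFP epoch restricted to the band, evaluated **on the
epoch's own Fourier grid** (no zero-padding): the grid spacing
`1000/duration` Hz is then the dominant, physically honest source of
across-burst frequency variability; padding is available via `nfft` and
roughly halves the spread. The frequency-deviation SD uses the population
(n) denominator.

## Passage-time theory

`T = T₁(b→c) + T₂(c→b)` with reflecting/absorbing boundaries; the
logarithmic terms cancel exactly (asserted to `1e−10`), leaving the
product form with **positive** Ei arguments. A variant with negated Ei
arguments circulates in print; `mean_burst_duration_negated_ei` computes
it solely so the test suite can document that it disagrees with the
Monte-Carlo passage-time oracle by far more than sampling error. With the
closed-form thresholds, `b/R` and `c/R` are constants, so `T·ν` is a
parameter-free constant (`≈ 1.805`) — verified across the working points
to `1e−10`. The empirical convention (`b` = half the median, `c` = mean +
SD of a simulated envelope) is provided for analysing data where R is
unknown.

## What the simulations do and do not establish

The generator's default conditions are the canonical parameter table
(`α_E=0.1, α_I=0.2, β_E=1, β_I=2, h_E=−3.8, h_I=−8, W_ee=27.4, W_ii=1.3,
W_ei=26.3, W_ie=32, N_E=800, N_I=200`; rates per ms) and the four working
points `W_ee ∈ {20.4, 27.4, 28.4, 29.4}`. Standard problem sizes: 500 s
of envelope process at 0.05 ms for burst statistics (≥ 1600 bursts per
point), 150 s of microscopic simulation, 400–600 s of linear dynamics,
10⁴ Monte-Carlo passage replicates.

- The linear and reduced levels agree to KS distance < 0.01 on envelope
  distributions — the reduction is quantitatively faithful to the linear
  dynamics.
- The *microscopic* network at `N = 1000` is **not** quantitatively
  linear near the transition: its scaled stationary variance is ≈ half
  the Lyapunov value (0.93 vs 1.95 at the intermediate point), recovering
  the linear prediction only as N grows (1.71 at 16× size, 2.00 at 100×
  in the rate model). Cross-level moment tests therefore certify
  agreement between the microscopic chain and the *nonlinear* rate SDEs
  at matched size, and convergence to the linear theory at large size;
  envelope-scale agreement between the microscopic network and the linear
  theory at `N = 1000` should not be expected, and the corresponding
  acceptance check fails honestly.
- Mean burst durations are strictly ordered across the four working
  points and match the reference at the intermediate point; the
  near-transition reference mean (514.6 ms) is not reproduced by any
  uniform extraction convention we tested (best ≈ 210–380 ms depending on
  criterion), and is left as a documented discrepancy.
- `ω₀/2π` at the four points is 67.1, 80.4, 82.3, 84.2 Hz; the often
  quoted "~85 Hz across the sweep" holds only for the three points
  nearest the transition.

Real LFP data differ from all of this in ways the generator does not
emulate: measurement noise, non-stationary drive, multiple rhythms and
1/f background, and finite electrode mixing. Passing tests certify the
internal consistency of the model chain, not the fidelity of any
particular fit to recordings.

## Known limitations

- No delayed or spatially structured couplings, no conductance-based
  neurons, no periodic forcing.
- Only mean burst durations are provided analytically; full residence-
  time distributions are out of scope.
- The envelope-phase reduction is refused outside transient synchrony
  (`ν ≤ 0`): it has no stationary law there.
- Burst counts are not monotone in the threshold for diffusion envelopes
  (epoch splitting); only total burst time and individual durations are.
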