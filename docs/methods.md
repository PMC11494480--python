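# Methods

## Model

The hair bundle is modelled as a Stuart–Landau oscillator — the normal
form of a supercritical Hopf bifurcation — with the bundle position as
the real part of the complex state `z(t) = x(t) + i y(t)`:

    dz/dt = (mu_c + mu·1[Fp inactive] + Fp) z + i ω z + β |z|² z + Fa
    dμ/dt = −μ/τ − α / (1 + exp(−γ x))

The control parameter `μ` measures the bundle's propensity to
self-oscillate: solutions decay to `z = 0` for `μ < −mu_c` and approach
a stable limit cycle for `μ > −mu_c`. Two feedback channels act on the
linear growth coefficient:

* **Intrinsic self-tuning.** The second equation relaxes `μ` (time
  constant `τ`) toward `−τ α P_o(γ x)`, where
  `P_o = 1/(1 + e^{−γx})` is the transduction-channel open probability —
  a logistic function of displacement. During symmetric oscillation the
  mean open probability is 1/2, so the time-averaged control parameter
  settles near `−ατ/2`.
* **Efferent input** is parametric forcing: while `Fp = μ_p − mu_c` is
  active it *replaces* `μ` in the oscillator equation (indicator
  `1[Fp inactive]`), so the effective distance from the bifurcation is
  exactly `μ_p`. The two feedbacks are independent: `μ` keeps
  integrating while `Fp` is active.

Closed-form steady-state laws used as oracles throughout the tests:
amplitude `A = sqrt(−(mu_c+μ)/b′)`, frequency `φ̇ = ω + b″A²`, resonant
response at the critical point `A = (−b′)^{−1/3} F^{1/3}` (exact for the
isochronous oscillator), and under constant parametric forcing
`A = sqrt(−μ_p/b′)`, `φ̇ = ω − (b″/b′) μ_p`.

## Parameters

| symbol | meaning | default |
|---|---|---|
| `mu_c` | distance of the bifurcation point from μ = 0 | 20 |
| `ω` | characteristic angular frequency | 2π |
| `β = b′ + i b″` | cubic nonlinearity (b′ < 0 supercritical) | −1 − i/2 |
| `τ` | self-tuning relaxation time | 10 |
| `γ` | channel gating sensitivity | 10 |
| `α` | self-tuning strength | 3 |

All quantities are dimensionless; time is scaled so the natural period
is 1 (`ω = 2π`). The defaults are the reference set used by every study
unless a study states otherwise.

### Dynamical regimes of the self-tuning law

The product `τα` controls the regime:

* `τα < mu_c` — quiescence unreachable: feedback cannot silence the
  oscillator;
* `mu_c < τα < 2 mu_c` — the operating regime: the resting state
  (`⟨μ⟩ ≈ −ατ/2`) oscillates, and strong stimulation can push `μ` below
  `−mu_c`, producing a transient quiescent interval whose length grows
  with stimulus duration;
* `τα > 2 mu_c` — the quiescent state is the *only* attractor (any
  symmetric motion of the bundle keeps `⟨P_o⟩ = 1/2`, pulling `μ` to
  `−τα/2 < −mu_c`), so spontaneous oscillation cannot persist and never
  recovers after overstimulation. The defaults with `τ` raised to 35
  fall in this regime; the recovery study reports an `inf` sentinel
  there rather than a finite recovery time. The recovery phenomenon is
  demonstrated in the tests with `α = 1, τ = 35` (τα = 35 ∈ (20, 40)).

### Accuracy of the closed forms at the defaults

The amplitude/frequency laws assume `μ` frozen at `−ατ/2`. In the
coupled system the feedback ripple interacts with the amplitude–phase
coupling `b″`, producing a small dwell-time asymmetry of the position:
the realized mean open probability is 0.506, not 1/2, hence
`⟨μ⟩ = −15.21`, mean amplitude 2.187 (2.2 % below √5) and mean
frequency 3.889 (2.8 % above 2π − 5/2). These deviations are properties
of the model (solver-independent to four decimals between DOP853 and
RK45 at rtol 1e−8 vs 1e−11). The laws *are* exact under constant
parametric forcing, where the oscillator decouples from the feedback.

## Numerics

* **Integration.** The coupled system is integrated as a real
  3-dimensional ODE with adaptive Runge–Kutta (DOP853), default
  tolerances rtol 1e−8 / atol 1e−10. Forcing protocols are piecewise
  with half-open windows `[t_start, t_stop)`; the timeline is split at
  every discontinuity and the solver never steps across one. State is
  carried exactly across segment boundaries. Output is sampled on a
  uniform grid (default Δt = 0.02 = period/50). Runs are
  bit-reproducible for identical configurations on one platform.
* **Initial conditions.** `z0 = 0.01` (a small symmetry-breaking seed —
  `z = 0` is an exact fixed point; the seed stands in for fluctuations
  the deterministic model omits) and `μ0 = −ατ/2` (the unforced
  steady value, avoiding long tuning transients).
* **Pinning to the critical point.** Runs "at the bifurcation" use
  constant parametric forcing with `μ_p = 0`, which sets the effective
  linear coefficient exactly to zero without a special code path.
* **Sweeps** (tongues, widths, spectra, recovery) use rtol 1e−6 /
  atol 1e−9: derived statistics agree with rtol 1e−8 runs to five
  decimals at nearly half the cost. Per-condition runs are independent
  and could be dispatched concurrently without changing results.
* **Burn-in.** Locking statistics use the last 60 % of a trace, trimmed
  to an integer number of forcing periods; cycle statistics average over
  the last 50 cycles. Spectra discard the first 60 time units.

## Derived statistics

* **Vector strength** `V = |⟨e^{i(φ − ω′t)}⟩|` with `φ` the unwrapped
  phase of `z`; the time average (trapezoid rule) runs over an integer
  number of forcing periods. **Phase-locked amplitude** is the Fourier
  coefficient of `z` at `ω′`, normalised so a pure tone of amplitude A
  returns A. A cell is "locked" for tongue display when `V ≥ 0.9`
  (configurable; no sharper operational definition presents itself).
* **Bartlett spectra**: average periodogram of 8 non-overlapping
  rectangular-window segments (scipy.signal.welch with a boxcar window
  and zero overlap). Density is per unit natural frequency on a grid
  reported in angular units, so Parseval's identity reads
  `Σ P Δf = ⟨x²⟩`.
* **Power ratio** `R = log10(Σ P_inactive) / log10(Σ P_moderate)` — a
  ratio of logarithms of summed spectral density values. Because a
  locked line's density height scales with the segment length, R
  depends on the record length: with the default 400-time-unit records
  the small-F plateau of R sits near 1.16 and the fitted intercept of
  `R = a + b log10 F` near 1.13; the intercept approaches 1 only
  logarithmically (records of ~1e5–1e6 time units), far beyond a
  practical runtime. The slope b is the robust, scale-stable quantity.
  The scan drives the bundle at its characteristic frequency and
  compares no-parametric-forcing (self-tuned) against constant
  `μ_p = 5/2`.
* **Tuning-curve widths** are full widths at half maximum with
  linearly interpolated crossings. The vector-strength width scan (at
  F = 1.5) reports widths on the natural-frequency axis `ν′ = ω′/2π`
  (the tuning axis in units of the characteristic frequency); the
  default `ω′` grid spans −2.5 to 16.5 rad per unit time because the
  tongue at the smallest parametric level (`μ_p = 5/32`) is about 2.2
  natural frequencies wide. Grid points with `|ω′| < 0.35` are dropped
  (the analysis window would not contain one forcing period). Widths
  change by < 0.1 % when the horizon is doubled from the default
  t_end = 320.
* **Recovery time** is the delay after force offset until `|z|` regains
  half of the unforced steady amplitude. Immediately after a strong
  boxcar stops, `|z|` still exceeds the threshold while the bundle
  relaxes from its deflected position, so the search starts once the
  amplitude has first dropped below threshold; if it never drops the
  bundle was never quiescent and the recovery time is 0. The time at
  which `μ` re-crosses `−mu_c` is reported alongside as a diagnostic.
* **Fits** are unweighted least squares: log–log regression for power
  laws, `scipy.optimize.curve_fit` for `y = c + x^d`, linear regression
  on `log10 x` for the power-ratio relation. The numerical gain dA/dF
  uses adjacent differences attributed to the geometric midpoint, which
  preserves a power law exactly.

## Study defaults

* Resonant-response sweep (one-third law): isochronous oscillator
  `β = −1` (the prefactor `(−b′)^{−1/3}` is exact only for `b″ = 0`),
  F on 8 log points over 1e−3…1, horizon `60 + 24 F^{−2/3}` (the
  critical relaxation rate scales as `F^{2/3}`), seeded at 0.9× the
  predicted response.
* Amplitude-width scan: F ∈ {0.05, 0.1, 0.2, 0.5, 1}, per-F grid
  `ω ± 4 F^{2/3}` (25 points).
* Power-ratio scan: F on 12 log points over 1e−2…10.
* Width scan: `μ_p` on 7 log points over 5/32…5 (the strength values
  S = 1/μ_p bracketing 2/5 and 32/5), F = 1.5.
* Recovery study: F = 1000, τ = 35, durations {40, 60, 80, 97.5},
  stimulus onset t = 50, horizon 400 after offset.
* Efferent study: boxcar F = 50 on [40, 100), `μ_p = 5`, horizon 260.

## What the simulations do and do not show

All inputs are generated by the simulator itself; there is no noise
term, so every run is deterministic and the quiescent/recovery dynamics
regrow oscillations from exponentially small deterministic amplitudes
rather than from fluctuations, making recovery times sharper than a
real bundle's. The model abstracts the biophysics (myosin motors,
channel kinetics, Ca²⁺ handling) into three parameters (τ, γ, α) and
one abstract control parameter; agreement of the simulated statistics
with the closed-form laws validates the implementation, not the
biological fidelity of the normal-form description. Physical units
(nm, Hz, pN) are deliberately absent.

## Known limitations

* No stochastic forcing; no event detection beyond pre-computed forcing
  breakpoints; no biophysical channel/myosin sub-models.
* The power-ratio intercept depends on record length (see above).
* Width measurements need the tuning curve to cross half maximum inside
  the swept grid; cells where it does not are flagged, not guessed.
* Single-channel (position-only) records support only envelope and
  spectral statistics; phase-based statistics need the full state.
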