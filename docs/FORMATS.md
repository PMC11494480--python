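# File formats

All quantities are dimensionless (time in natural periods of the
oscillator's characteristic frequency, `omega = 2*pi` by default).

## Trace CSV

Columns `t,x,y,mu`, one row per output sample on a uniform grid.

| column | meaning |
|---|---|
| `t` | time (strictly increasing, uniform spacing `dt_out`) |
| `x` | bundle position, `Re z` |
| `y` | conjugate coordinate, `Im z` |
| `mu` | intrinsic control parameter |

Each trace CSV is accompanied by a sidecar JSON (same stem, `.json`)
holding full provenance: package version, model parameters, both forcing
protocols, solver settings and the simulated span. The sidecar is
sufficient to re-run the producing command bit-identically.

## Position CSV (experimental records)

Two columns, time and position, any header names. Only
amplitude-envelope and spectral statistics are available for these;
phase-based statistics require the full complex state.

## Sweep CSV

One row per swept condition. Common columns per study:

* recovery: `duration,F,t_stop,mu_at_stop,mu_crossing,t_recovery,recovered`
  (`t_recovery = inf` means never recovered within the horizon)
* tongue: `F,omega_prime,mu_p,A_lock,V,locked,error`
* power-ratio: `F,total_power_inactive,total_power_moderate,R`
* off-resonance: `case,mu_p,F,omega_prime,A_lock,error`
* width: `mu_p,F,width,width_nat,error` (`width` in angular frequency,
  `width_nat = width / 2*pi` in units of the characteristic frequency)

Failed cells carry the error message in `error` and NaN statistics.

## Summary JSON

`{"meta": {...study configuration...}, "fits": {name: {form,
coefficients, residual_norm, x_range}}}`. Fit coefficient order follows
the written form: `y = c x^b` -> `(c, b)`; `y = c + x^d` -> `(c, d)`;
`y = a + b log10 x` -> `(a, b)`.

## Config YAML/JSON

Blocks `model`, `additive`, `parametric`, `integration`, `analysis`,
plus `t_span`. Keys follow the model symbols (`mu_c, omega, b_real,
b_imag, tau, gamma, alpha`; forcing blocks use `variant, F,
omega_prime, t_start, t_stop, mu_p`). Unknown keys are rejected. An
empty config reproduces the reference defaults throughout.
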