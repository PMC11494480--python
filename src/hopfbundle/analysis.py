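"""Derived statistics of oscillator traces.

Everything the simulation studies report is computed here: instantaneous
amplitude and phase, cycle-averaged steady-state statistics, vector
strength and phase-locked amplitude against a reference tone, Bartlett
power spectra, the ratio of logarithmic total powers, widths at half
maximum of tuning curves, recovery times after overstimulation, and the
least-squares fits of the scaling relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal
from scipy.optimize import curve_fit

from .model import TWO_PI, Trace

__all__ = [
    "amplitude_phase",
    "instantaneous_frequency",
    "steady_cycle_stats",
    "vector_strength",
    "phase_locked_amplitude",
    "SpectrumEstimate",
    "bartlett_psd",
    "power_ratio",
    "half_width",
    "recovery_time",
    "mu_crossing_time",
    "NOT_RECOVERED",
    "FitResult",
    "fit_relation",
]

#: sentinel returned by :func:`recovery_time` when oscillations never
#: reach the recovery threshold within the simulated horizon
NOT_RECOVERED = math.inf


# ---------------------------------------------------------------------------
# amplitude / phase / frequency
# ---------------------------------------------------------------------------

def amplitude_phase(trace: Trace) -> Tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude ``A = |z|`` and unwrapped phase ``arg z``.

    Phase is undefined where the amplitude is exactly zero; those samples
    are returned as NaN and excluded from any downstream frequency
    statistic.
    """
    a = trace.amplitude
    phi = np.unwrap(np.arctan2(trace.y, trace.x))
    phi = np.where(a > 0, phi, np.nan)
    return a, phi


def instantaneous_frequency(trace: Trace) -> np.ndarray:
    """Angular frequency ``dphi/dt`` by central differences of the phase."""
    _, phi = amplitude_phase(trace)
    return np.gradient(phi, trace.t)


def steady_cycle_stats(trace: Trace, n_cycles: int = 50) -> Tuple[float, float]:
    """Mean amplitude and mean angular frequency over the last ``n_cycles``.

    Cycle boundaries are taken from the unwrapped phase: the averaging
    window ends at the final sample and starts where the phase lags it by
    ``2*pi*n_cycles`` (located by interpolation).  The mean frequency is
    exactly ``2*pi*n_cycles`` divided by the window duration; the mean
    amplitude is the time average of ``A(t)`` over the window.
    """
    a, phi = amplitude_phase(trace)
    if np.any(~np.isfinite(phi)):
        raise ValueError("phase undefined (zero amplitude) within the trace")
    total = phi[-1] - phi[0]
    span = TWO_PI * n_cycles
    if abs(total) < span:
        raise ValueError(
            f"trace contains only {abs(total)/TWO_PI:.1f} cycles, "
            f"need {n_cycles}"
        )
    target = phi[-1] - math.copysign(span, total)
    # phase is monotone over the steady part; search from the end
    idx = np.searchsorted(phi, target) if total > 0 else \
        len(phi) - np.searchsorted(phi[::-1], target)
    idx = int(np.clip(idx, 1, len(phi) - 1))
    t_start = float(np.interp(target, phi[idx - 1:idx + 1], trace.t[idx - 1:idx + 1])) \
        if phi[idx] != phi[idx - 1] else float(trace.t[idx])
    duration = trace.t[-1] - t_start
    a_start = float(np.interp(t_start, trace.t, a))
    tt = np.concatenate(([t_start], trace.t[idx:]))
    aa = np.concatenate(([a_start], a[idx:]))
    mean_a = float(np.trapezoid(aa, tt) / duration)
    mean_freq = float(span / duration) * math.copysign(1.0, total)
    return mean_a, mean_freq


# ---------------------------------------------------------------------------
# locking statistics
# ---------------------------------------------------------------------------

def _locking_window(trace: Trace, omega_prime: float, window_fraction: float):
    """Index of the analysis window: an integer number of forcing periods
    ending at the final sample, drawn from the last ``window_fraction`` of
    the trace (the rest is treated as burn-in)."""
    if omega_prime == 0:
        raise ValueError("omega_prime must be nonzero")
    period = TWO_PI / abs(omega_prime)
    avail = window_fraction * (trace.t[-1] - trace.t[0])
    n_periods = int(avail / period)
    if n_periods < 1:
        raise ValueError(
            f"analysis window ({avail:.3g} time units) is shorter than one "
            f"forcing period ({period:.3g})"
        )
    t_start = trace.t[-1] - n_periods * period
    i0 = int(np.searchsorted(trace.t, t_start - 1e-12))
    return i0, n_periods


def vector_strength(
    trace: Trace, omega_prime: float, window_fraction: float = 0.6
) -> float:
    """Phase coherence ``V = |< exp(i(phi - omega' t)) >|`` in [0, 1].

    ``phi`` is the oscillator's unwrapped phase and ``omega' t`` the phase
    of the reference tone; the average runs over an integer number of
    forcing periods at the end of the trace.  ``V = 1`` signals perfect
    phase locking, ``V = 0`` a uniformly drifting phase difference.
    """
    i0, _ = _locking_window(trace, omega_prime, window_fraction)
    _, phi = amplitude_phase(trace)
    seg = slice(i0, len(trace.t))
    t = trace.t[seg]
    w = np.exp(1j * (phi[seg] - omega_prime * t))
    if np.any(~np.isfinite(w)):
        raise ValueError("phase undefined (zero amplitude) inside the window")
    if len(t) == 2:
        v = 0.5 * (w[0] + w[1])  # plain average for a two-sample window
    else:
        v = np.trapezoid(w, t) / (t[-1] - t[0])
    return float(abs(v))


def phase_locked_amplitude(
    trace: Trace, omega_prime: float, window_fraction: float = 0.6
) -> float:
    """Modulus of the Fourier coefficient of ``z(t)`` at ``omega'``.

    Normalised so that a pure tone ``z = A exp(i omega' t)`` returns ``A``.
    Uses the same integer-period end window as :func:`vector_strength`.
    """
    i0, _ = _locking_window(trace, omega_prime, window_fraction)
    seg = slice(i0, len(trace.t))
    t = trace.t[seg]
    integrand = trace.z[seg] * np.exp(-1j * omega_prime * t)
    c = np.trapezoid(integrand, t) / (t[-1] - t[0])
    return float(abs(c))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumEstimate:
    """Bartlett power-spectral-density estimate of a position record.

    ``omega`` is the one-sided angular-frequency grid; ``power`` is the
    spectral density per unit natural frequency (cycles per time unit), so
    Parseval's identity reads ``sum(power) * dnu == <x^2>`` with
    ``dnu = domega / 2 pi``.
    """

    omega: np.ndarray
    power: np.ndarray
    n_segments: int
    record_length: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.power) < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def frequency(self) -> np.ndarray:
        """Grid in natural-frequency units (``omega / 2 pi``)."""
        return self.omega / TWO_PI

    @property
    def total_power(self) -> float:
        """Sum of spectral density values over the grid."""
        return float(np.sum(self.power))

    def mean_square(self) -> float:
        dnu = float(self.frequency[1] - self.frequency[0])
        return self.total_power * dnu


def bartlett_psd(
    x: np.ndarray, sample_interval: float, n_segments: int = 8
) -> SpectrumEstimate:
    """Bartlett's method: average periodogram of non-overlapping segments.

    The record is split into ``n_segments`` equal rectangular-window
    segments (trailing samples that do not fill a segment are dropped) and
    the per-segment periodograms are averaged.
    """
    x = np.asarray(x, dtype=float)
    if n_segments < 1 or n_segments > len(x):
        raise ValueError(
            f"n_segments={n_segments} invalid for a record of {len(x)} samples"
        )
    nper = len(x) // n_segments
    f, pxx = _signal.welch(
        x[: nper * n_segments],
        fs=1.0 / sample_interval,
        window="boxcar",
        nperseg=nper,
        noverlap=0,
        detrend=False,
        scaling="density",
    )
    return SpectrumEstimate(
        omega=TWO_PI * f,
        power=pxx,
        n_segments=n_segments,
        record_length=nper * n_segments * sample_interval,
    )


def power_ratio(psd_inactive: SpectrumEstimate, psd_moderate: SpectrumEstimate) -> float:
    """Ratio of logarithmic total powers,
    ``R = log10(sum P_inactive) / log10(sum P_moderate)``.

    Note this is a ratio of logarithms, not the logarithm of a ratio.
    The spectra must share a grid; a denominator total of 1 (log = 0) or a
    non-positive total is rejected.
    """
    if psd_inactive.omega.shape != psd_moderate.omega.shape or not np.allclose(
        psd_inactive.omega, psd_moderate.omega
    ):
        raise ValueError("spectra are on different frequency grids")
    ti, tm = psd_inactive.total_power, psd_moderate.total_power
    if ti <= 0 or tm <= 0:
        raise ValueError("total power must be positive")
    denom = math.log10(tm)
    if denom == 0:
        raise ValueError("denominator total power equals 1 (log10 = 0)")
    return math.log10(ti) / denom


# ---------------------------------------------------------------------------
# curve geometry
# ---------------------------------------------------------------------------

def half_width(grid: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a sampled, single-peaked curve.

    The maximum must lie strictly inside the grid and the curve must fall
    below half of it on both sides; each crossing is located by linear
    interpolation between the neighbouring samples.  Invariant under
    uniform vertical scaling.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(grid) != len(values) or len(grid) < 3:
        raise ValueError("need >= 3 matched samples")
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        raise ValueError(
            "maximum lies on the grid boundary; widen the frequency range"
        )
    half = values[i] / 2.0
    left = np.nonzero(values[: i + 1] < half)[0]
    right = np.nonzero(values[i:] < half)[0]
    if len(left) == 0 or len(right) == 0:
        side = "left" if len(left) == 0 else "right"
        raise ValueError(
            f"curve does not fall below half maximum on the {side} side; "
            "widen the frequency range"
        )
    li = left[-1]
    ri = i + right[0]
    x_left = grid[li] + (grid[li + 1] - grid[li]) * (half - values[li]) / (
        values[li + 1] - values[li]
    )
    x_right = grid[ri - 1] + (grid[ri] - grid[ri - 1]) * (half - values[ri - 1]) / (
        values[ri] - values[ri - 1]
    )
    return float(x_right - x_left)


# ---------------------------------------------------------------------------
# recovery after overstimulation
# ---------------------------------------------------------------------------

def recovery_time(
    trace: Trace,
    t_stop: float,
    threshold_fraction: float = 0.5,
    reference_amplitude: Optional[float] = None,
) -> float:
    """Delay after ``t_stop`` until oscillations regain ``threshold_fraction``
    of ``reference_amplitude``.

    If no reference is given, the pre-stimulus steady amplitude implied by
    the trace's own parameters (amplitude law at ``mu = -alpha*tau/2``) is
    used.  Immediately after strong forcing stops, ``|z|`` can still exceed
    the threshold while the bundle relaxes from its deflected position, so
    the search for the recovery crossing starts once the amplitude has
    first dropped below the threshold; if it never drops below, the bundle
    was never quiescent and the recovery time is 0.  Returns
    :data:`NOT_RECOVERED` (``inf``) when the threshold is not reached again
    within the trace.
    """
    if reference_amplitude is None:
        from .model import Parameters, steady_amplitude

        p = Parameters.from_dict(trace.meta["parameters"])
        reference_amplitude = steady_amplitude(p, -p.alpha * p.tau / 2.0)
    if reference_amplitude < 0:
        raise ValueError("reference_amplitude must be >= 0")
    if trace.t[-1] <= t_stop:
        raise ValueError("trace does not extend beyond t_stop")
    thr = threshold_fraction * reference_amplitude
    m = trace.t > t_stop
    t, a = trace.t[m], trace.amplitude[m]
    below = np.nonzero(a < thr)[0]
    if len(below) == 0:
        return 0.0  # never quiescent
    j0 = below[0]
    above = np.nonzero(a[j0:] >= thr)[0]
    if len(above) == 0:
        return NOT_RECOVERED
    return float(t[j0 + above[0]] - t_stop)


def mu_crossing_time(trace: Trace, t_stop: float, level: float) -> float:
    """First time after ``t_stop`` at which ``mu`` rises through ``level``.

    Diagnostic companion to :func:`recovery_time`: oscillations can only
    recover once the control parameter has re-crossed the critical point.
    Returns :data:`NOT_RECOVERED` if it never does.
    """
    m = trace.t > t_stop
    t, mu = trace.t[m], trace.mu[m]
    hits = np.nonzero((mu[:-1] < level) & (mu[1:] >= level))[0]
    if len(hits) == 0:
        return 0.0 if mu[0] >= level else NOT_RECOVERED
    i = hits[0]
    tc = t[i] + (t[i + 1] - t[i]) * (level - mu[i]) / (mu[i + 1] - mu[i])
    return float(tc - t_stop)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of one of the supported functional forms.

    ``form`` is one of ``"power_law"`` (``y = c x^b``, fitted in log-log),
    ``"offset_power"`` (``y = c + x^d``, nonlinear least squares) and
    ``"log10_linear"`` (``y = a + b log10 x``).  ``coefficients`` are in
    the order the form is written.
    """

    form: str
    coefficients: Tuple[float, ...]
    residual_norm: float
    x_range: Tuple[float, float]

    _NCOEF = {"power_law": 2, "offset_power": 2, "log10_linear": 2}

    def __post_init__(self) -> None:
        if self.form not in self._NCOEF:
            raise ValueError(f"unknown fit form {self.form!r}")
        if len(self.coefficients) != self._NCOEF[self.form]:
            raise ValueError("coefficient count does not match the form")

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "coefficients": list(self.coefficients),
            "residual_norm": self.residual_norm,
            "x_range": list(self.x_range),
        }


def fit_relation(x: Sequence[float], y: Sequence[float], form: str) -> FitResult:
    """Unweighted least-squares fit of a scaling relation.

    power_law
        regress ``log y`` on ``log x``; coefficients ``(c, b)`` of
        ``y = c x^b``.  Requires positive data.
    offset_power
        nonlinear least squares for ``y = c + x^d``; coefficients
        ``(c, d)``.  Requires positive x.
    log10_linear
        linear regression of ``y`` on ``log10 x``; coefficients ``(a, b)``
        of ``y = a + b log10 x``.  Requires positive x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 matched points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for logarithmic/power forms")

    if form == "power_law":
        if np.any(y <= 0):
            raise ValueError("y must be positive for a log-log fit")
        b, logc = np.polyfit(np.log(x), np.log(y), 1)
        coef = (float(np.exp(logc)), float(b))
        resid = y - coef[0] * x ** coef[1]
    elif form == "offset_power":
        popt, _ = curve_fit(
            lambda xx, c, d: c + xx**d, x, y, p0=(0.0, -0.5), maxfev=20000
        )
        coef = (float(popt[0]), float(popt[1]))
        resid = y - (coef[0] + x ** coef[1])
    elif form == "log10_linear":
        b, a = np.polyfit(np.log10(x), y, 1)
        coef = (float(a), float(b))
        resid = y - (coef[0] + coef[1] * np.log10(x))
    else:
        raise ValueError(f"unknown fit form {form!r}")

    return FitResult(
        form=form,
        coefficients=coef,
        residual_norm=float(np.linalg.norm(resid)),
        x_range=(float(x.min()), float(x.max())),
    )
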