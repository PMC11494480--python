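"""Normal-form model of an actively tuned hair bundle.

The hair bundle is represented by a Stuart-Landau oscillator -- the normal
form of a supercritical Hopf bifurcation -- whose control parameter ``mu``
measures the bundle's propensity to self-oscillate.  Two feedback channels
act on it:

* an intrinsic self-tuning law that relaxes ``mu`` toward a value set by the
  transduction-channel open probability (a logistic function of bundle
  displacement), keeping the oscillator near its critical point; and
* an efferent input modelled as *parametric* forcing ``Fp`` which, while
  active, replaces the intrinsic control parameter in the oscillator
  equation.

The full state is ``(z, mu)`` with ``z = x + i y`` complex; ``x = Re z`` is
the bundle position.  The governing equations are

    dz/dt  = (mu_c + mu*[Fp inactive] + Fp) z + i omega z + beta |z|^2 z + Fa
    dmu/dt = -mu/tau - alpha / (1 + exp(-gamma x))

with ``beta = b' + i b''``, ``b' < 0`` (supercritical branch).  This module
holds the parameter set, the forcing protocols, the right-hand side, and the
closed-form steady-state predictions that the simulations are checked
against.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "Parameters",
    "AdditiveForcing",
    "ParametricForcing",
    "Trace",
    "rhs",
    "open_probability",
    "steady_amplitude",
    "steady_frequency",
    "resonant_response_at_bifurcation",
    "parametric_steady_predictions",
    "selftuning_fixed_point",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Parameters:
    """Constants of the oscillator and its self-tuning feedback.

    Defaults are the reference parameter set used throughout:
    ``mu_c=20``, ``omega=2*pi``, ``beta=-1-i/2``, ``tau=10``, ``gamma=10``,
    ``alpha=3``.  All quantities are dimensionless; time is scaled so that
    ``omega=2*pi`` gives a natural period of 1.

    Attributes
    ----------
    mu_c : float
        Distance of the bifurcation point from the origin of the control
        parameter axis (> 0).  The oscillator is quiescent for
        ``mu < -mu_c`` and self-oscillates for ``mu > -mu_c``.
    omega : float
        Characteristic angular frequency of the limit cycle at onset.
    b_real, b_imag : float
        Real and imaginary parts of the cubic coefficient ``beta``.
        ``b_real`` must be negative (supercritical branch); ``b_imag``
        couples amplitude to frequency (``b_imag = 0`` is isochronous).
    tau : float
        Relaxation time of the self-tuning feedback (> 0).
    gamma : float
        Sensitivity of the channel open probability to displacement (> 0).
    alpha : float
        Strength of the calcium-mediated feedback on ``mu`` (>= 0).
    """

    mu_c: float = 20.0
    omega: float = TWO_PI
    b_real: float = -1.0
    b_imag: float = -0.5
    tau: float = 10.0
    gamma: float = 10.0
    alpha: float = 3.0

    def __post_init__(self) -> None:
        if not self.mu_c > 0:
            raise ValueError(f"mu_c must be > 0, got {self.mu_c}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.b_real < 0:
            raise ValueError(
                f"b_real must be < 0 (supercritical branch), got {self.b_real}"
            )
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")

    @property
    def beta(self) -> complex:
        return complex(self.b_real, self.b_imag)

    @property
    def natural_period(self) -> float:
        return TWO_PI / self.omega

    def replace(self, **kwargs) -> "Parameters":
        import dataclasses

        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "mu_c": self.mu_c,
            "omega": self.omega,
            "b_real": self.b_real,
            "b_imag": self.b_imag,
            "tau": self.tau,
            "gamma": self.gamma,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        return cls(**d)


# ---------------------------------------------------------------------------
# forcing protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdditiveForcing:
    """Piecewise additive force ``Fa(t)`` applied to the oscillator state.

    Variants
    --------
    none
        ``Fa = 0`` everywhere.
    boxcar
        ``Fa = F`` (real) on the half-open window ``[t_start, t_stop)``,
        0 outside.
    sinusoid
        complex rotating tone ``Fa = F exp(i omega' t)``, optionally gated
        by a half-open window.

    Windows are half-open so the step value applies at ``t_start`` but no
    longer at ``t_stop``, which keeps the piecewise definition single-valued
    at the discontinuities.
    """

    variant: str = "none"
    amplitude: float = 0.0
    omega_prime: Optional[float] = None
    t_start: Optional[float] = None
    t_stop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in ("none", "boxcar", "sinusoid"):
            raise ValueError(f"unknown additive forcing variant {self.variant!r}")
        if self.amplitude < 0:
            raise ValueError("forcing amplitude F must be >= 0")
        if self.variant == "boxcar":
            if self.t_start is None or self.t_stop is None:
                raise ValueError("boxcar forcing requires t_start and t_stop")
            if not self.t_start < self.t_stop:
                raise ValueError("boxcar window requires t_start < t_stop")
        if self.variant == "sinusoid":
            if self.omega_prime is None or self.omega_prime == 0.0:
                raise ValueError("sinusoid forcing requires a nonzero omega_prime")
            if (self.t_start is None) != (self.t_stop is None):
                raise ValueError("sinusoid window requires both t_start and t_stop")

    # -- constructors -------------------------------------------------------

    @classmethod
    def none(cls) -> "AdditiveForcing":
        return cls()

    @classmethod
    def boxcar(cls, amplitude: float, t_start: float, t_stop: float) -> "AdditiveForcing":
        return cls(variant="boxcar", amplitude=amplitude, t_start=t_start, t_stop=t_stop)

    @classmethod
    def sinusoid(
        cls,
        amplitude: float,
        omega_prime: float,
        window: Optional[Tuple[float, float]] = None,
    ) -> "AdditiveForcing":
        t0, t1 = window if window is not None else (None, None)
        return cls(
            variant="sinusoid",
            amplitude=amplitude,
            omega_prime=omega_prime,
            t_start=t0,
            t_stop=t1,
        )

    # -- evaluation ---------------------------------------------------------

    def _in_window(self, t: float) -> bool:
        if self.t_start is None:
            return True
        return self.t_start <= t < self.t_stop

    def __call__(self, t: float) -> complex:
        """Exact piecewise value of ``Fa`` at time ``t`` (total function)."""
        if self.variant == "none" or self.amplitude == 0.0:
            return 0j
        if self.variant == "boxcar":
            return complex(self.amplitude) if self._in_window(t) else 0j
        if not self._in_window(t):
            return 0j
        return self.amplitude * cmath.exp(1j * self.omega_prime * t)

    def breakpoints(self) -> Tuple[float, ...]:
        """Times at which the functional form of ``Fa`` changes."""
        if self.t_start is None:
            return ()
        return (self.t_start, self.t_stop)

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        if self.variant != "none":
            d["F"] = self.amplitude
        if self.omega_prime is not None:
            d["omega_prime"] = self.omega_prime
        if self.t_start is not None:
            d["t_start"] = self.t_start
            d["t_stop"] = self.t_stop
        return d


@dataclass(frozen=True)
class ParametricForcing:
    """Efferent input as parametric forcing of the control parameter.

    While active, the value ``Fp = mu_p - mu_c`` replaces the intrinsic
    control parameter ``mu`` in the oscillator equation, so the effective
    linear growth coefficient becomes ``mu_c + Fp = mu_p``:  ``mu_p`` is the
    oscillator's distance from the bifurcation point during forcing.  The
    forcing strength is ``S = 1/mu_p``.

    Variants: ``none`` (never active), ``rectangular`` (active on the
    half-open window ``[t_start, t_stop)``) and ``constant`` (always
    active).  Activity is decided by window membership, not by comparing
    the value against zero; a protocol with ``mu_p == mu_c`` (identically
    zero value while active) is therefore rejected at construction.
    """

    variant: str = "none"
    mu_p: float = 0.0
    mu_c: float = 20.0
    t_start: Optional[float] = None
    t_stop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in ("none", "rectangular", "constant"):
            raise ValueError(f"unknown parametric forcing variant {self.variant!r}")
        if self.variant == "rectangular":
            if self.t_start is None or self.t_stop is None:
                raise ValueError("rectangular forcing requires t_start and t_stop")
            if not self.t_start < self.t_stop:
                raise ValueError("rectangular window requires t_start < t_stop")
        if self.variant != "none" and self.mu_p == self.mu_c:
            raise ValueError(
                "mu_p == mu_c gives an identically zero parametric force on its "
                "active window, which makes activity ill-defined; use the 'none' "
                "variant instead"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def none(cls) -> "ParametricForcing":
        return cls()

    @classmethod
    def rectangular(
        cls, mu_p: float, mu_c: float, t_start: float, t_stop: float
    ) -> "ParametricForcing":
        return cls(
            variant="rectangular", mu_p=mu_p, mu_c=mu_c, t_start=t_start, t_stop=t_stop
        )

    @classmethod
    def constant(cls, mu_p: float, mu_c: float) -> "ParametricForcing":
        return cls(variant="constant", mu_p=mu_p, mu_c=mu_c)

    # -- evaluation ---------------------------------------------------------

    @property
    def strength(self) -> float:
        """Forcing strength ``S = 1/mu_p`` (defined for ``mu_p > 0``)."""
        if self.variant == "none" or self.mu_p <= 0:
            raise ValueError("strength S = 1/mu_p is defined only for mu_p > 0")
        return 1.0 / self.mu_p

    def __call__(self, t: float) -> Tuple[float, bool]:
        """Return ``(value, active)`` at time ``t``.

        ``active`` is True exactly when the returned value is the nonzero
        in-window value ``mu_p - mu_c``.
        """
        if self.variant == "none":
            return 0.0, False
        if self.variant == "rectangular" and not (self.t_start <= t < self.t_stop):
            return 0.0, False
        return self.mu_p - self.mu_c, True

    def breakpoints(self) -> Tuple[float, ...]:
        if self.variant == "rectangular":
            return (self.t_start, self.t_stop)
        return ()

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        if self.variant != "none":
            d["mu_p"] = self.mu_p
            d["mu_c"] = self.mu_c
        if self.t_start is not None:
            d["t_start"] = self.t_start
            d["t_stop"] = self.t_stop
        return d


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Time-stamped samples of the full state ``(x, y, mu)``.

    ``meta`` records the provenance of the trace (parameters, protocols,
    solver settings) so that any derived statistic can be traced back to the
    run that produced it.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.mu) == n):
            raise ValueError("trace channels must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def z(self) -> np.ndarray:
        return self.x + 1j * self.y

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def window(self, t_lo: float, t_hi: float) -> "Trace":
        """Sub-trace with samples in the closed interval ``[t_lo, t_hi]``."""
        m = (self.t >= t_lo) & (self.t <= t_hi)
        if not np.any(m):
            raise ValueError(f"no samples in window [{t_lo}, {t_hi}]")
        return Trace(self.t[m], self.x[m], self.y[m], self.mu[m], dict(self.meta))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "mu": self.mu})


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def open_probability(gamma: float, x: float):
    """Transduction-channel open probability, ``Po = 1/(1 + exp(-gamma x))``.

    Overflow-safe logistic; accepts scalars or arrays.
    """
    u = np.multiply(gamma, x)
    if np.ndim(u) == 0:
        u = float(u)
        if u >= 0:
            return 1.0 / (1.0 + math.exp(-u))
        e = math.exp(u)
        return e / (1.0 + e)
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def rhs(
    z: complex,
    mu: float,
    params: Parameters,
    fa: complex = 0j,
    fp_value: float = 0.0,
    fp_active: bool = False,
) -> Tuple[complex, float]:
    """Time derivatives ``(dz/dt, dmu/dt)`` of the coupled system.

    The linear coefficient of ``z`` is ``mu_c + mu`` while the parametric
    force is inactive and ``mu_c + fp_value`` while it is active: efferent
    forcing supplants the intrinsic control parameter.  The self-tuning
    equation for ``mu`` integrates regardless -- the intrinsic feedback and
    the efferent input are independent processes.
    """
    if not (cmath.isfinite(z) and math.isfinite(mu)):
        raise FloatingPointError(f"non-finite state z={z!r}, mu={mu!r}")
    lin = params.mu_c + (fp_value if fp_active else mu)
    dz = (lin + 1j * params.omega) * z + params.beta * abs(z) ** 2 * z + fa
    dmu = -mu / params.tau - params.alpha * open_probability(params.gamma, z.real)
    return dz, dmu


# ---------------------------------------------------------------------------
# closed-form steady-state predictions
# ---------------------------------------------------------------------------

def steady_amplitude(params: Parameters, mu: float) -> float:
    """Limit-cycle amplitude ``A = sqrt(-(mu_c + mu)/b')`` at fixed ``mu``.

    Returns 0 on the quiescent side (``mu <= -mu_c``), where the stable
    solution is the node at ``z = 0``.
    """
    excess = params.mu_c + mu
    if excess <= 0:
        return 0.0
    return math.sqrt(-excess / params.b_real)


def steady_frequency(params: Parameters, amplitude: float) -> float:
    """Angular frequency ``phidot = omega + b'' A^2`` of steady oscillation."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    return params.omega + params.b_imag * amplitude**2


def resonant_response_at_bifurcation(params: Parameters, force: float) -> float:
    """One-third power law ``A = (-b')^(-1/3) F^(1/3)``.

    Phase-locked response amplitude to a resonant tone applied exactly at
    the bifurcation point (``mu = -mu_c``).  Exact for the isochronous
    oscillator; for ``b'' != 0`` the cubic coefficient's magnitude enters
    and the prefactor is ``|beta|^(-1/3)`` instead.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    return (-params.b_real) ** (-1.0 / 3.0) * force ** (1.0 / 3.0)


def parametric_steady_predictions(params: Parameters, mu_p: float) -> Tuple[float, float]:
    """Steady amplitude and frequency under constant parametric forcing.

    With ``Fp = mu_p - mu_c`` active, the oscillator sits at distance
    ``mu_p`` from its bifurcation point, so
    ``A = sqrt(-mu_p/b')`` and ``phidot = omega - (b''/b') mu_p``
    (which equals ``omega + b'' A^2``, consistently with the free-running
    frequency law).  Returns amplitude 0 for ``mu_p <= 0``.
    """
    if mu_p <= 0:
        return 0.0, params.omega
    a = math.sqrt(-mu_p / params.b_real)
    freq = params.omega - (params.b_imag / params.b_real) * mu_p
    return a, freq


def selftuning_fixed_point(params: Parameters, x_held: float) -> float:
    """Equilibrium of the self-tuning law at clamped displacement ``x``.

    ``mu* = -tau * alpha * Po(gamma, x)``; at the resting position
    ``x = 0`` this is ``-alpha*tau/2``, the value around which the
    time-averaged control parameter settles during free oscillation.
    """
    return -params.tau * params.alpha * open_probability(params.gamma, x_held)
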