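"""Deterministic integration of the coupled oscillator/self-tuning system.

The forcing protocols are piecewise-defined with step discontinuities, so a
run is split into segments at every protocol breakpoint and each segment is
integrated separately with an adaptive Runge-Kutta solver; the solver never
steps across a discontinuity.  The final state of one segment seeds the
next, so the state itself is continuous everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model import AdditiveForcing, Parameters, ParametricForcing, Trace

__all__ = [
    "IntegrationConfig",
    "IntegrationError",
    "segment_timeline",
    "integrate",
    "refine_check",
]


class IntegrationError(RuntimeError):
    """Solver failure or state blow-up, annotated with segment and time."""


@dataclass(frozen=True)
class IntegrationConfig:
    """Solver settings and initial state.

    ``z0`` defaults to a small nonzero seed because ``z = 0`` is an exact
    fixed point of the dynamics: a spontaneous-oscillation run started at
    exactly zero would stay there forever.  The seed stands in for the
    fluctuations present in a real bundle, which the deterministic model
    omits.  ``mu0 = None`` means "start from the unforced self-tuned value
    ``-alpha*tau/2``", which avoids long tuning transients.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = math.inf
    dt_out: float = 0.02
    z0: complex = 0.01 + 0j
    mu0: Optional[float] = None
    method: str = "DOP853"

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be > 0")
        if not self.dt_out > 0:
            raise ValueError("dt_out must be > 0")

    def to_dict(self) -> dict:
        return {
            "rtol": self.rtol,
            "atol": self.atol,
            "max_step": self.max_step,
            "dt_out": self.dt_out,
            "z0_real": self.z0.real,
            "z0_imag": self.z0.imag,
            "mu0": self.mu0,
            "method": self.method,
        }


def segment_timeline(
    additive: AdditiveForcing,
    parametric: ParametricForcing,
    t_span: Tuple[float, float],
) -> np.ndarray:
    """Sorted unique breakpoints partitioning ``t_span`` into segments.

    Within each segment both forcing protocols keep a single functional
    form (same window membership, same activity flag).
    """
    t0, t1 = t_span
    if not t0 < t1:
        raise ValueError(f"empty time span {t_span}")
    pts = {t0, t1}
    for b in (*additive.breakpoints(), *parametric.breakpoints()):
        if t0 < b < t1:
            pts.add(float(b))
    return np.array(sorted(pts))


def _make_rhs(params: Parameters, additive: AdditiveForcing, seg_mid: float,
              fp_value: float, fp_active: bool):
    """Scalar-arithmetic RHS for one segment.

    Within a segment the forcing structure is constant, so the additive
    force is either the smooth rotating tone or the constant value taken
    at the segment midpoint, and the parametric activity flag is frozen.
    """
    mu_c, om = params.mu_c, params.omega
    br, bi = params.b_real, params.b_imag
    tau, gam, al = params.tau, params.gamma, params.alpha
    sinusoid = (
        additive.variant == "sinusoid"
        and additive.amplitude != 0.0
        and additive._in_window(seg_mid)
    )
    if sinusoid:
        famp, omp = additive.amplitude, additive.omega_prime
    else:
        f0 = additive(seg_mid)

    def fun(t, s):
        x, y, mu = s
        r2 = x * x + y * y
        lin = mu_c + (fp_value if fp_active else mu)
        gx = gam * x
        if gx >= 0:
            po = 1.0 / (1.0 + math.exp(-gx))
        else:
            e = math.exp(gx)
            po = e / (1.0 + e)
        if sinusoid:
            far = famp * math.cos(omp * t)
            fai = famp * math.sin(omp * t)
        else:
            far, fai = f0.real, f0.imag
        return (
            lin * x - om * y + (br * x - bi * y) * r2 + far,
            lin * y + om * x + (bi * x + br * y) * r2 + fai,
            -mu / tau - al * po,
        )

    return fun


def integrate(
    params: Parameters,
    config: Optional[IntegrationConfig] = None,
    additive: Optional[AdditiveForcing] = None,
    parametric: Optional[ParametricForcing] = None,
    t_span: Tuple[float, float] = (0.0, 100.0),
) -> Trace:
    """Integrate the coupled system over ``t_span`` and sample uniformly.

    The run is segmented at every forcing discontinuity; within a segment
    the additive forcing is smooth and the parametric activity flag is
    constant, evaluated at the segment midpoint.  Output is sampled on the
    uniform grid ``t0, t0+dt_out, ...``; the result is bit-reproducible for
    identical inputs on the same platform.
    """
    config = config or IntegrationConfig()
    additive = additive or AdditiveForcing.none()
    parametric = parametric or ParametricForcing.none()

    breaks = segment_timeline(additive, parametric, t_span)
    t0, t1 = float(breaks[0]), float(breaks[-1])
    n_out = int(math.floor((t1 - t0) / config.dt_out + 1e-9)) + 1
    t_out = t0 + config.dt_out * np.arange(n_out)

    mu0 = config.mu0 if config.mu0 is not None else -params.alpha * params.tau / 2.0
    state = np.array([config.z0.real, config.z0.imag, float(mu0)])

    xs = np.empty(n_out)
    ys = np.empty(n_out)
    mus = np.empty(n_out)
    filled = 0

    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        fp_value, fp_active = parametric(mid)
        fun = _make_rhs(params, additive, mid, fp_value, fp_active)
        # grid points inside [a, b); the segment endpoint is integrated to
        # but recorded only as the next segment's initial state
        in_seg = t_out[(t_out >= a - 1e-12) & (t_out < b - 1e-12)]
        t_eval = np.append(in_seg, b)
        sol = solve_ivp(
            fun,
            (a, b),
            state,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            max_step=config.max_step,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"solver failed in segment [{a}, {b}] "
                f"(reached t={sol.t[-1] if len(sol.t) else a}): {sol.message}"
            )
        k = len(in_seg)
        xs[filled:filled + k] = sol.y[0, :k]
        ys[filled:filled + k] = sol.y[1, :k]
        mus[filled:filled + k] = sol.y[2, :k]
        filled += k
        state = sol.y[:, -1]

    if filled < n_out:  # final grid point coincides with t1
        xs[filled:], ys[filled:], mus[filled:] = state[0], state[1], state[2]
        filled = n_out

    meta = {
        "parameters": params.to_dict(),
        "additive": additive.to_dict(),
        "parametric": parametric.to_dict(),
        "integration": config.to_dict(),
        "t_span": [t0, t1],
    }
    return Trace(t_out, xs, ys, mus, meta)


class RefineResult(NamedTuple):
    max_dz: float
    max_dmu: float


def refine_check(trace_coarse: Trace, trace_fine: Trace) -> RefineResult:
    """Maximum state discrepancy between two runs of the same protocol.

    The fine trace is interpolated onto the coarse grid; returns the
    maxima of ``|z_coarse - z_fine|`` and ``|mu_coarse - mu_fine|``.
    Intended for convergence diagnostics where the fine run used halved
    tolerances or a finer output grid.
    """
    for key in ("parameters", "additive", "parametric"):
        if trace_coarse.meta.get(key) != trace_fine.meta.get(key):
            raise ValueError(f"traces come from different protocols ({key} differs)")
    t = trace_coarse.t
    if t[0] < trace_fine.t[0] - 1e-9 or t[-1] > trace_fine.t[-1] + 1e-9:
        raise ValueError("fine trace does not cover the coarse trace's span")
    xf = np.interp(t, trace_fine.t, trace_fine.x)
    yf = np.interp(t, trace_fine.t, trace_fine.y)
    mf = np.interp(t, trace_fine.t, trace_fine.mu)
    dz = np.hypot(trace_coarse.x - xf, trace_coarse.y - yf)
    dmu = np.abs(trace_coarse.mu - mf)
    return RefineResult(float(dz.max()), float(dmu.max()))
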