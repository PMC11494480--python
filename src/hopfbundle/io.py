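"""Configuration parsing and trace/summary file I/O.

Configs are flat YAML (JSON is valid YAML) with one block per concern;
every key has a documented default and unknown keys are rejected so typos
fail loudly.  Traces are CSV files with columns ``t,x,y,mu`` accompanied
by a JSON sidecar carrying full provenance (parameters, protocols, solver
settings, package version), which is sufficient to re-run the producing
command bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrate import IntegrationConfig
from .model import AdditiveForcing, Parameters, ParametricForcing, Trace

__all__ = [
    "RunConfig",
    "ConfigError",
    "parse_config",
    "write_trace",
    "read_trace",
    "read_position_csv",
    "write_json",
]


class ConfigError(ValueError):
    """Invalid configuration, annotated with the offending key."""


DEFAULT_ANALYSIS = {
    "window_fraction": 0.6,
    "n_segments": 8,
    "lock_threshold": 0.9,
    "threshold_fraction": 0.5,
    "n_cycles": 50,
}

_MODEL_KEYS = {"mu_c", "omega", "b_real", "b_imag", "tau", "gamma", "alpha"}
_ADDITIVE_KEYS = {"variant", "F", "omega_prime", "t_start", "t_stop"}
_PARAMETRIC_KEYS = {"variant", "mu_p", "t_start", "t_stop"}
_INTEGRATION_KEYS = {"rtol", "atol", "max_step", "dt_out", "z0_real",
                     "z0_imag", "mu0", "method"}
_TOP_KEYS = {"model", "additive", "parametric", "integration", "analysis",
             "t_span"}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration of a single simulation run."""

    params: Parameters = Parameters()
    additive: AdditiveForcing = AdditiveForcing.none()
    parametric: ParametricForcing = ParametricForcing.none()
    integration: IntegrationConfig = IntegrationConfig()
    analysis: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSIS))
    t_span: Tuple[float, float] = (0.0, 100.0)

    def to_dict(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "additive": self.additive.to_dict(),
            "parametric": self.parametric.to_dict(),
            "integration": self.integration.to_dict(),
            "analysis": dict(self.analysis),
            "t_span": list(self.t_span),
        }


def _check_keys(block: dict, allowed: set, where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in {where!r} block "
                f"(allowed: {sorted(allowed)})"
            )


def _build_additive(block: dict) -> AdditiveForcing:
    _check_keys(block, _ADDITIVE_KEYS, "additive")
    variant = block.get("variant", "none")
    try:
        if variant == "none":
            return AdditiveForcing.none()
        if variant == "boxcar":
            return AdditiveForcing.boxcar(
                block["F"], block["t_start"], block["t_stop"]
            )
        if variant == "sinusoid":
            window = None
            if "t_start" in block:
                window = (block["t_start"], block["t_stop"])
            return AdditiveForcing.sinusoid(block["F"], block["omega_prime"], window)
    except KeyError as exc:
        raise ConfigError(f"additive block missing key {exc.args[0]!r}") from None
    raise ConfigError(f"additive.variant must be none|boxcar|sinusoid, got {variant!r}")


def _build_parametric(block: dict, mu_c: float) -> ParametricForcing:
    _check_keys(block, _PARAMETRIC_KEYS, "parametric")
    variant = block.get("variant", "none")
    try:
        if variant == "none":
            return ParametricForcing.none()
        if variant == "constant":
            return ParametricForcing.constant(block["mu_p"], mu_c)
        if variant == "rectangular":
            return ParametricForcing.rectangular(
                block["mu_p"], mu_c, block["t_start"], block["t_stop"]
            )
    except KeyError as exc:
        raise ConfigError(f"parametric block missing key {exc.args[0]!r}") from None
    raise ConfigError(
        f"parametric.variant must be none|rectangular|constant, got {variant!r}"
    )


def parse_config(
    source: Union[str, Path, dict, None] = None,
    overrides: Optional[dict] = None,
) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML/JSON file or dict.

    ``overrides`` is a nested dict merged on top of the file contents
    (command-line flags use this).  An empty or missing config yields the
    reference defaults throughout.  Unknown keys and invariant violations
    raise :class:`ConfigError` naming the offending key.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            raw.setdefault(key, {})
            raw[key] = {**raw[key], **sub}
        else:
            raw[key] = sub

    _check_keys(raw, _TOP_KEYS, "top-level")
    model_block = raw.get("model", {})
    _check_keys(model_block, _MODEL_KEYS, "model")
    try:
        params = Parameters(**{**Parameters().to_dict(), **model_block})
    except ValueError as exc:
        raise ConfigError(f"model block invalid: {exc}") from None

    additive = _build_additive(raw.get("additive", {}))
    try:
        parametric = _build_parametric(raw.get("parametric", {}), params.mu_c)
    except ValueError as exc:
        raise ConfigError(f"parametric block invalid: {exc}") from None

    integ_block = dict(raw.get("integration", {}))
    _check_keys(integ_block, _INTEGRATION_KEYS, "integration")
    z0 = complex(integ_block.pop("z0_real", 0.01), integ_block.pop("z0_imag", 0.0))
    try:
        integration = IntegrationConfig(z0=z0, **integ_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"integration block invalid: {exc}") from None

    analysis = dict(DEFAULT_ANALYSIS)
    _check_keys(raw.get("analysis", {}), set(DEFAULT_ANALYSIS), "analysis")
    analysis.update(raw.get("analysis", {}))

    t_span = tuple(raw.get("t_span", (0.0, 100.0)))
    if len(t_span) != 2 or not t_span[0] < t_span[1]:
        raise ConfigError(f"t_span must be an increasing pair, got {t_span}")

    return RunConfig(params, additive, parametric, integration, analysis, t_span)


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: Union[str, Path]) -> Path:
    """Write a trace as ``t,x,y,mu`` CSV plus a provenance JSON sidecar."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(".json")
    write_json({"version": __version__, **trace.meta}, sidecar)
    return sidecar


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a ``t,x,y,mu`` CSV trace, picking up the sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "mu"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path} is not a trace CSV (missing columns {sorted(missing)}); "
            "two-column position records are read with read_position_csv"
        )
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Trace(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(),
                 df["mu"].to_numpy(), meta)


def read_position_csv(path: Union[str, Path]):
    """Read a plain two-column time/position CSV (e.g. an experimental
    bundle trace).  Returns ``(t, x)`` arrays.

    Single-channel records support amplitude-envelope and spectral
    statistics only; phase-based statistics need the full complex state.
    """
    df = pd.read_csv(Path(path))
    if df.shape[1] < 2:
        raise ValueError("position CSV needs two columns (time, position)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    return t, x


def write_json(obj: dict, path: Union[str, Path]) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
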