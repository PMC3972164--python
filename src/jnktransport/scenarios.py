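"""Scenario construction: default parameterization, profiles, config files.

The default scenario places every protein at the cell body as a narrow
Gaussian (std 0.5 um; 0.16 um for the KIF5 motor, which is anchored close
to the centrosome), the phosphatase M3/6 uniformly along the axon, and all
complexes at zero:

* [JNK](x)  = 10 exp(-x^2 / (2 * 0.5^2)) uM
* [MKK7](x) = 1.6 exp(-x^2 / (2 * 0.5^2)) uM
* [KIF5](x) = 10 exp(-x^2 / (2 * 0.16^2)) uM
* [JIP1](x) = sigma * 10 exp(-x^2 / (2 * 0.5^2)) uM  (0 <= sigma <= 2 is the
  published range; sigma is the scaffold-to-kinase amplitude ratio)
* [M3/6](x) = 0.1 uM uniform (an alternate preset of 1.0 uM is available,
  see ``M36_PRESETS``; the two values circulate for this parameter set and
  the phosphatase level is swept in the sensitivity analysis anyway).

The motor speed is set through the Peclet number Pe = v L / D_JNK.
Scenario files are flat YAML with nested sections for grid / transport /
constants / diffusion / profiles; loading validates the schema strictly and
a save -> load round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .reactions import RateConstants, default_constants
from .registry import DEFAULT_DIFFUSION, SPECIES, SpeciesRegistry, default_registry
from .solver import Grid1D, TransportParams

__all__ = [
    "InitialProfile",
    "ScenarioConfig",
    "gaussian_profile",
    "default_scenario",
    "with_operating_point",
    "load_config",
    "save_config",
    "M36_PRESETS",
]

#: M3/6 uniform concentration presets (uM): "table" is the default
#: parameter-set value, "text" the alternate one quoted with the methods.
M36_PRESETS: dict[str, float] = {"table": 0.1, "text": 1.0}

_PROFILE_KINDS = ("gaussian", "uniform", "zero")


def gaussian_profile(amplitude: float, width: float, x: np.ndarray) -> np.ndarray:
    """Gaussian concentration profile centered at x = 0 (uM).

    field[i] = amplitude * exp(-x_i^2 / (2 width^2)).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-(x**2) / (2.0 * width**2))


@dataclass(frozen=True)
class InitialProfile:
    """Initial spatial distribution of one species."""

    kind: str
    amplitude: float = 0.0
    width: float | None = None
    center: float = 0.0

    def __post_init__(self):
        if self.kind not in _PROFILE_KINDS:
            raise ValueError(f"kind must be one of {_PROFILE_KINDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "gaussian" and (self.width is None or self.width <= 0):
            raise ValueError("gaussian profile requires width > 0")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "zero":
            return np.zeros_like(x)
        if self.kind == "uniform":
            return np.full_like(x, self.amplitude)
        return gaussian_profile(self.amplitude, self.width, x - self.center)

    def as_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind != "zero":
            d["amplitude"] = float(self.amplitude)
        if self.kind == "gaussian":
            d["width"] = float(self.width)
            if self.center:
                d["center"] = float(self.center)
        return d


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, self-contained description of one simulation."""

    grid: Grid1D
    transport: TransportParams
    constants: RateConstants
    profiles: dict[str, InitialProfile]
    diffusion: dict[str, float]
    double_motor_catalysis: bool = False
    registry: SpeciesRegistry = field(default_factory=default_registry, compare=False)

    def validate(self) -> None:
        """Raise ValueError listing every schema violation."""
        errors = []
        for name in self.registry.names:
            if name not in self.profiles:
                errors.append(f"missing initial profile for species {name!r}")
        for name in self.profiles:
            if name not in self.registry.names:
                errors.append(f"profile given for unknown species {name!r}")
        for i, (name, mob) in enumerate(zip(self.registry.names, self.registry.mobility)):
            if mob == "diffusive" and name not in self.diffusion:
                errors.append(f"missing diffusion coefficient for {name!r}")
        for name, val in self.diffusion.items():
            if name not in self.registry.names:
                errors.append(f"diffusion coefficient for unknown species {name!r}")
            elif val < 0:
                errors.append(f"negative diffusion coefficient for {name!r}")
        if errors:
            raise ValueError("invalid scenario:\n  " + "\n  ".join(errors))

    def initial_state(self) -> np.ndarray:
        """(species, cells) concentration array at t = 0."""
        x = self.grid.cell_centers
        out = np.empty((len(self.registry.names), self.grid.n_cells))
        for i, name in enumerate(self.registry.names):
            out[i] = self.profiles[name].evaluate(x)
        return out

    def d_jnk(self) -> float:
        return float(self.diffusion["JNK"])


def _default_profiles(sigma: float, m36_conc: float) -> dict[str, InitialProfile]:
    jnk_amp = 10.0
    profiles: dict[str, InitialProfile] = {}
    for name in SPECIES:
        profiles[name] = InitialProfile(kind="zero")
    profiles["JNK"] = InitialProfile("gaussian", jnk_amp, 0.5)
    profiles["MKK7"] = InitialProfile("gaussian", 1.6, 0.5)
    profiles["KIF5"] = InitialProfile("gaussian", 10.0, 0.16)
    profiles["M3/6"] = InitialProfile("uniform", m36_conc)
    if sigma > 0:
        profiles["JIP1"] = InitialProfile("gaussian", sigma * jnk_amp, 0.5)
    return profiles


def default_scenario(
    sigma: float = 0.0,
    pe: float = 0.0,
    *,
    L: float = 100.0,
    n_cells: int = 200,
    m36_conc: float = M36_PRESETS["table"],
    t_end: float = 10_000.0,
    safety: float = 0.8,
    record_every: float = 50.0,
    series_every: float = 1.0,
    reaction_method: str = "heun",
    limiter: bool = True,
    double_motor_catalysis: bool = False,
) -> ScenarioConfig:
    """The published parameter set at a given (sigma, Pe) operating point.

    ``sigma`` scales the JIP1 Gaussian amplitude (sigma * 10 uM); ``pe``
    sets the motor speed v = Pe * D_JNK / L.  (0, 0) is the pure-diffusion
    baseline used to normalize signal amplification.
    """
    if sigma < 0 or pe < 0:
        raise ValueError("sigma and pe must be >= 0")
    grid = Grid1D(L=L, n_cells=n_cells)
    diffusion = dict(DEFAULT_DIFFUSION)
    v = pe * diffusion["JNK"] / L
    transport = TransportParams(
        v=v,
        safety=safety,
        t_end=t_end,
        record_every=record_every,
        series_every=series_every,
        reaction_method=reaction_method,
        limiter=limiter,
    )
    return ScenarioConfig(
        grid=grid,
        transport=transport,
        constants=default_constants(),
        profiles=_default_profiles(sigma, m36_conc),
        diffusion=diffusion,
        double_motor_catalysis=double_motor_catalysis,
    )


def with_operating_point(scenario: ScenarioConfig, sigma: float, pe: float) -> ScenarioConfig:
    """Re-target a scenario to a new (sigma, Pe) point.

    The JIP1 amplitude becomes sigma times the JNK amplitude (both share
    the same Gaussian width, so the amplitude ratio is the concentration
    ratio at every x) and v = Pe * D_JNK / L.
    """
    if sigma < 0 or pe < 0:
        raise ValueError("sigma and pe must be >= 0")
    jnk = scenario.profiles["JNK"]
    if jnk.kind != "gaussian" or jnk.amplitude <= 0:
        raise ValueError("operating point requires a Gaussian JNK profile")
    profiles = dict(scenario.profiles)
    if sigma > 0:
        profiles["JIP1"] = InitialProfile("gaussian", sigma * jnk.amplitude, jnk.width)
    else:
        profiles["JIP1"] = InitialProfile("zero")
    v = pe * scenario.d_jnk() / scenario.grid.L
    return replace(
        scenario,
        profiles=profiles,
        transport=replace(scenario.transport, v=v),
    )


# ---------------------------------------------------------------------------
# config file round-tripping
# ---------------------------------------------------------------------------

_TOP_KEYS = {"grid", "transport", "constants", "profiles", "diffusion", "double_motor_catalysis"}
_GRID_KEYS = {"L", "n_cells"}
_TRANSPORT_KEYS = {
    "v",
    "safety",
    "t_end",
    "record_every",
    "series_every",
    "reaction_method",
    "limiter",
    "clamp_tol",
}


def scenario_to_dict(scenario: ScenarioConfig) -> dict:
    return {
        "grid": {"L": float(scenario.grid.L), "n_cells": int(scenario.grid.n_cells)},
        "transport": {
            "v": float(scenario.transport.v),
            "safety": float(scenario.transport.safety),
            "t_end": float(scenario.transport.t_end),
            "record_every": float(scenario.transport.record_every),
            "series_every": float(scenario.transport.series_every),
            "reaction_method": scenario.transport.reaction_method,
            "limiter": bool(scenario.transport.limiter),
            "clamp_tol": float(scenario.transport.clamp_tol),
        },
        "constants": scenario.constants.as_dict(),
        "double_motor_catalysis": bool(scenario.double_motor_catalysis),
        "diffusion": {k: float(v) for k, v in scenario.diffusion.items()},
        "profiles": {name: p.as_dict() for name, p in scenario.profiles.items()},
    }


def scenario_from_dict(data: dict) -> ScenarioConfig:
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    for section in ("grid", "transport", "constants", "profiles", "diffusion"):
        if section not in data:
            errors.append(f"missing section {section!r}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    gd = dict(data["grid"])
    if set(gd) - _GRID_KEYS:
        errors.append(f"unknown grid keys: {sorted(set(gd) - _GRID_KEYS)}")
    td = dict(data["transport"])
    if set(td) - _TRANSPORT_KEYS:
        errors.append(f"unknown transport keys: {sorted(set(td) - _TRANSPORT_KEYS)}")

    profiles: dict[str, InitialProfile] = {}
    for name, pd in dict(data["profiles"]).items():
        try:
            profiles[name] = InitialProfile(**pd)
        except (TypeError, ValueError) as exc:
            errors.append(f"bad profile for {name!r}: {exc}")

    constants = None
    try:
        constants = RateConstants.from_dict(data["constants"])
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"bad rate constants: {exc}")

    grid = transport = None
    try:
        grid = Grid1D(**gd)
    except (TypeError, ValueError) as exc:
        errors.append(f"bad grid: {exc}")
    try:
        transport = TransportParams(**td)
    except (TypeError, ValueError) as exc:
        errors.append(f"bad transport: {exc}")

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    scenario = ScenarioConfig(
        grid=grid,
        transport=transport,
        constants=constants,
        profiles=profiles,
        diffusion={k: float(v) for k, v in dict(data["diffusion"]).items()},
        double_motor_catalysis=bool(data.get("double_motor_catalysis", False)),
    )
    scenario.validate()
    return scenario


def save_config(scenario: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML; floats keep full precision (repr)."""
    with open(path, "w") as fh:
        fh.write("# jnktransport scenario (units: uM, s, um)\n")
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return scenario_from_dict(data)
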