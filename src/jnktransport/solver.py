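"""1-D explicit reaction-diffusion-advection integrator.

The axon is a 1-D domain [0, L] with the cell body at x = 0 and the
periphery (nerve-terminal side) at x = L, discretized on a uniform mesh of
``n_cells`` points (default 200).  Per time step the solver applies Lie
splitting in the fixed order reaction -> diffusion -> advection:

* reaction: explicit Heun (default) or Euler on the mass-action network;
* diffusion: Forward-Time Central-Space (FTCS) with zero-flux (Neumann)
  boundaries at both ends;
* advection: second-order Lax-Wendroff in conservative flux form, directed
  toward increasing x.  The inflow side (x = 0) carries a zero-concentration
  Dirichlet condition (zero inflow flux); the outflow flux at x = L is set
  to zero, so advected cargo accumulates in the terminal cell and total
  mass is conserved.

Both boundaries are therefore closed to net flux and the five molecular
moiety totals are conserved to machine precision over a run, which is the
solver's primary self-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .reactions import RateConstants, moiety_totals
from .registry import SpeciesRegistry, default_registry

__all__ = [
    "Grid1D",
    "TransportParams",
    "Kymograph",
    "stable_dt",
    "diffusion_step",
    "advection_step",
    "run_simulation",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when the explicit scheme loses stability or positivity."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D mesh on [0, L]; positions x_i = i * dx, dx = L / n_cells."""

    L: float = 100.0
    n_cells: int = 200

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not self.L > 0:
            raise ValueError("L must be positive")

    @property
    def dx(self) -> float:
        return self.L / self.n_cells

    @property
    def cell_centers(self) -> np.ndarray:
        return np.arange(self.n_cells) * self.dx


@dataclass(frozen=True)
class TransportParams:
    """Motor speed and time-stepping controls.

    ``v`` is the uniform anterograde motor speed (um/s, cell body ->
    periphery).  ``safety`` scales the explicit stability bound; the actual
    dt additionally divides ``series_every`` so that recording times are
    exact.  ``record_every`` controls full-state snapshots, ``series_every``
    the peripheral JNK* trace used by the metrics.
    """

    v: float = 0.0
    safety: float = 0.8
    t_end: float = 10_000.0
    record_every: float = 50.0
    series_every: float = 1.0
    reaction_method: str = "heun"
    limiter: bool = True
    clamp_tol: float = 1e-12

    def __post_init__(self):
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if not 0 < self.safety <= 1:
            raise ValueError("safety must be in (0, 1]")
        if self.reaction_method not in ("heun", "euler"):
            raise ValueError("reaction_method must be 'heun' or 'euler'")
        if self.record_every < self.series_every:
            raise ValueError("record_every must be >= series_every")


@dataclass
class Kymograph:
    """Space x time record of a run.

    ``conc`` has shape (species, frames, cells) in uM.  ``series`` is the
    finely sampled free-JNK* concentration in the terminal cell (the
    periphery), recorded every ``series_every`` seconds regardless of the
    frame interval.
    """

    species: tuple[str, ...]
    grid: Grid1D
    times: np.ndarray
    conc: np.ndarray
    series_times: np.ndarray
    series: np.ndarray
    dt: float
    clamped_mass: float = 0.0
    v: float = 0.0

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in kymograph") from None

    def moiety_totals(self, registry: SpeciesRegistry | None = None) -> np.ndarray:
        """Conserved-moiety totals per frame, shape (frames, 5)."""
        reg = registry or default_registry()
        out = np.empty((self.conc.shape[1], len(reg.moiety_names)))
        for t in range(self.conc.shape[1]):
            out[t] = moiety_totals(self.conc[:, t, :], self.grid.dx, reg)
        return out


def stable_dt(
    grid: Grid1D,
    params: TransportParams,
    d_max: float,
) -> float:
    """Largest stable explicit step: safety * min(dx^2/(2 D_max), dx/v).

    The advective (CFL) bound is omitted when v = 0; raises if there is no
    transport process to bound at all.
    """
    bounds = []
    if d_max > 0:
        bounds.append(grid.dx**2 / (2.0 * d_max))
    if params.v > 0:
        bounds.append(grid.dx / params.v)
    if not bounds:
        raise ValueError("no transport process: D_max = 0 and v = 0")
    return params.safety * min(bounds)


def diffusion_step(field: np.ndarray, grid: Grid1D, dt: float, D: float) -> np.ndarray:
    """One FTCS diffusion step with zero-flux ends, in conservative form.

    Conserves ``sum(field) * dx`` exactly; raises on an unstable dt.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n_cells,):
        raise ValueError("field length must equal n_cells")
    if D < 0:
        raise ValueError("D must be >= 0")
    if D > 0 and dt > grid.dx**2 / (2.0 * D) * (1 + 1e-12):
        raise SolverError(f"unstable diffusion step: dt={dt} exceeds dx^2/(2D)")
    flux = np.zeros(grid.n_cells + 1)
    flux[1:-1] = -D * np.diff(field) / grid.dx
    return field - dt / grid.dx * np.diff(flux)


def advection_step(
    field: np.ndarray,
    grid: Grid1D,
    dt: float,
    v: float,
    *,
    limiter: bool = False,
) -> np.ndarray:
    """One Lax-Wendroff advection step toward increasing x, closed ends.

    Courant number c = v dt / dx must be <= 1.  At c = 1 the interior update
    is an exact one-cell shift.  With ``limiter=True`` a minmod flux limiter
    suppresses the dispersive undershoot of the plain scheme.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n_cells,):
        raise ValueError("field length must equal n_cells")
    if v < 0:
        raise ValueError("v must be >= 0")
    if v == 0:
        return field.copy()
    c = v * dt / grid.dx
    if c > 1 + 1e-12:
        raise SolverError(f"Courant number {c:.4g} exceeds 1")
    n = grid.n_cells
    flux = np.zeros(n + 1)
    um = field[:-1]
    up = field[1:]
    if limiter:
        du = up - um
        dum = np.empty(n - 1)
        dum[0] = um[0]  # zero ghost cell upstream of the inflow boundary
        dum[1:] = um[1:] - um[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(du != 0.0, dum / np.where(du == 0.0, 1.0, du), 0.0)
        phi = np.clip(r, 0.0, 1.0)
        flux[1:-1] = v * um + 0.5 * v * (1.0 - c) * phi * du
    else:
        flux[1:-1] = v * (0.5 * (um + up) - 0.5 * c * (up - um))
    return field - dt / grid.dx * np.diff(flux)


def _resolve_dt(
    grid: Grid1D,
    params: TransportParams,
    d_max: float,
    rate_scale: float = 0.0,
) -> tuple[float, int]:
    """dt that satisfies stability and divides series_every exactly.

    ``rate_scale`` (1/s) is an upper bound on the fastest local reaction
    rate; it caps dt at safety/rate_scale so the explicit reaction substep
    stays stable on coarse meshes, where the transport bounds alone would
    allow steps longer than the binding timescale.
    """
    dt0 = stable_dt(grid, params, d_max)
    if rate_scale > 0:
        dt0 = min(dt0, params.safety / rate_scale)
    steps = max(1, math.ceil(params.series_every / dt0 - 1e-12))
    return params.series_every / steps, steps


def _reaction_rate_scale(scenario, conc0: np.ndarray, dx: float) -> float:
    """Pessimistic bound on the fastest pseudo-first-order reaction rate.

    Second-order rate constants times the largest concentration any species
    can reach: the initial maximum, or one conserved moiety piled into a
    single cell (advected cargo accumulates in the terminal cell).
    """
    k = scenario.constants
    k2max = max(k.kf.max(), k.b.max())
    k1max = max(k.kb.max(), k.kcat.max(), k.u.max())
    totals = moiety_totals(conc0, dx, scenario.registry)
    c_bound = max(float(conc0.max()), float(totals.max()) / dx)
    return max(k2max * c_bound, k1max)


def run_simulation(scenario, **overrides) -> Kymograph:
    """Integrate a scenario and return its kymograph.

    ``scenario`` is a :class:`jnktransport.scenarios.ScenarioConfig`;
    keyword overrides (``t_end``, ``record_every``, ...) replace the
    corresponding :class:`TransportParams` fields for this run only.
    """
    from .scenarios import ScenarioConfig  # local import to avoid a cycle

    if not isinstance(scenario, ScenarioConfig):
        raise TypeError("scenario must be a ScenarioConfig")
    scenario.validate()
    params = replace(scenario.transport, **overrides) if overrides else scenario.transport
    grid = scenario.grid
    reg = scenario.registry
    dcoef = reg.diffusion_array(scenario.diffusion)
    adv_idx = np.where(reg.advective_mask())[0].astype(np.int64)
    diff_idx = np.where(reg.diffusive_mask())[0].astype(np.int64)

    conc = scenario.initial_state().copy()
    dt, steps_per_sample = _resolve_dt(
        grid, params, float(dcoef.max()), _reaction_rate_scale(scenario, conc, grid.dx)
    )
    n_samples = int(round(params.t_end / params.series_every))
    if n_samples < 1:
        raise ValueError("t_end must cover at least one series interval")
    frame_stride = max(1, int(round(params.record_every / params.series_every)))
    n_frames = n_samples // frame_stride + 1
    series = np.empty(n_samples + 1)
    frames = np.empty((n_frames, len(reg.names), grid.n_cells))
    k = scenario.constants
    kq = k.kcat[4] + (k.kcat[5] if scenario.double_motor_catalysis else 0.0)

    status, clamped, done = _kernel.run_kernel(
        conc,
        dcoef,
        adv_idx,
        diff_idx,
        float(params.v),
        grid.dx,
        dt,
        n_samples,
        steps_per_sample,
        frame_stride,
        k.kf,
        k.kb,
        k.kcat,
        k.b,
        k.u,
        kq,
        params.reaction_method == "heun",
        params.limiter,
        params.clamp_tol,
        series,
        frames,
    )
    if status == _kernel.NEGATIVE:
        raise SolverError(
            f"concentration fell below -clamp_tol at t ~ {done * params.series_every:.1f} s"
        )
    if status == _kernel.NOT_FINITE:
        raise SolverError(
            f"non-finite concentration (instability) at t ~ {done * params.series_every:.1f} s"
        )

    return Kymograph(
        species=reg.names,
        grid=grid,
        times=np.arange(n_frames) * frame_stride * params.series_every,
        conc=np.ascontiguousarray(np.swapaxes(frames, 0, 1)),
        series_times=np.arange(n_samples + 1) * params.series_every,
        series=series,
        dt=dt,
        clamped_mass=clamped,
        v=float(params.v),
    )
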