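"""Transport metrics, regime classification and (sigma, Pe) phase scans.

Two dimensionless coordinates span the strategy space:

* sigma = [JIP1]_0 / [JNK]_0, the scaffold-to-kinase abundance ratio
  (ratio of the initial Gaussian amplitudes; both share the same width, so
  it is the concentration ratio at every x);
* Pe = v L / D_JNK, the Peclet number: the ratio of the diffusive transit
  time L^2/D to the advective transit time L/v.

Two output metrics quantify delivery of active kinase to the periphery:

* signaling rate R = 1 / t_max, where t_max is the time at which free JNK*
  in the terminal cell peaks;
* signal amplification A = peak / baseline peak, the peripheral JNK*
  maximum normalized by the pure-diffusion (sigma = 0, Pe = 0) run of the
  same scenario.

The (sigma, Pe) plane splits into four regimes: (1) motors slower than
diffusion (Pe <= 1), (2) no scaffold (sigma = 0), (3) effective motor
delivery (rate well above the diffusion baseline), (4) transport present
but ineffective -- empty scaffolds or motors outpacing cargo binding.  The
3/4 boundary is operationalized as rate > theta * baseline rate with
theta = 2 by default (the transition is a sharp jump, so the classification
is insensitive to theta within a broad band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import ScenarioConfig, with_operating_point
from .solver import Kymograph, run_simulation

__all__ = [
    "sigma",
    "peclet",
    "peripheral_series",
    "signaling_rate",
    "amplification",
    "classify_region",
    "MetricsResult",
    "PhaseDiagram",
    "scan_phase_diagram",
    "optimum_point",
    "sensitivity_scan",
    "ScanPointError",
]


class ScanPointError(RuntimeError):
    """Solver failure at one grid point, with its coordinates attached."""

    def __init__(self, sigma_val: float, pe_val: float, cause: Exception):
        super().__init__(f"scan point (sigma={sigma_val}, pe={pe_val}) failed: {cause}")
        self.sigma = sigma_val
        self.pe = pe_val
        self.cause = cause


def sigma(jip1_amp: float, jnk_amp: float) -> float:
    """Scaffold abundance ratio sigma = [JIP1]_0 / [JNK]_0."""
    if jnk_amp <= 0:
        raise ValueError("JNK amplitude must be positive")
    return jip1_amp / jnk_amp


def peclet(v: float, L: float, d_jnk: float) -> float:
    """Peclet number Pe = v L / D_JNK."""
    if L <= 0 or d_jnk <= 0:
        raise ValueError("L and D_JNK must be positive")
    return v * L / d_jnk


def peripheral_series(kymo: Kymograph) -> tuple[np.ndarray, np.ndarray]:
    """(times, free [JNK*] in the terminal cell), at the fine sampling.

    Only free JNK* counts as peripheral activity; phosphatase-bound
    JNK*-M3/6 is excluded.
    """
    kymo.species_index("JNK*")  # raises KeyError when absent
    if kymo.series is not None and len(kymo.series):
        return kymo.series_times, kymo.series
    idx = kymo.species_index("JNK*")
    return kymo.times, kymo.conc[idx, :, -1]


@dataclass(frozen=True)
class MetricsResult:
    """Peripheral-delivery metrics of one run."""

    t_max: float
    rate: float
    peak_conc: float
    amplification: float | None = None


def signaling_rate(series: np.ndarray, times: np.ndarray) -> MetricsResult:
    """Signaling rate R = 1 / t_max from a peripheral JNK* time series.

    ``t_max`` is the earliest time at which the series attains its global
    maximum (ties within a relative tolerance of 1e-9 break to the earliest
    frame).  An identically zero series has no defined rate.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise ValueError("series and times must have the same shape")
    peak = series.max() if series.size else 0.0
    if not peak > 0:
        raise ValueError("peripheral series has no positive maximum; rate undefined")
    at_peak = np.flatnonzero(series >= peak * (1.0 - 1e-9))
    t_max = float(times[at_peak[0]])
    if t_max <= 0:
        raise ValueError("maximum attained at t = 0; rate undefined")
    return MetricsResult(t_max=t_max, rate=1.0 / t_max, peak_conc=float(peak))


def amplification(peak_conc: float, baseline_peak: float) -> float:
    """Signal amplification A = peak / baseline peak (baseline: sigma=Pe=0)."""
    if baseline_peak <= 0:
        raise ValueError("baseline peak must be positive")
    return peak_conc / baseline_peak


def classify_region(
    sigma_val: float,
    pe_val: float,
    rate: float,
    baseline_rate: float,
    *,
    theta: float = 2.0,
    pe_threshold: float = 1.0,
) -> int:
    """Label a (sigma, Pe) point with its transport regime 1..4.

    2: no scaffold (sigma = 0); 1: motors slower than diffusion
    (Pe <= pe_threshold); 3: effective motor delivery
    (rate > theta * baseline); 4: transport present but ineffective.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    if sigma_val == 0:
        return 2
    if pe_val <= pe_threshold:
        return 1
    return 3 if rate > theta * baseline_rate else 4


@dataclass
class PhaseDiagram:
    """Metrics on a (sigma, Pe) grid; grids are indexed [sigma, pe]."""

    sigma_axis: np.ndarray
    pe_axis: np.ndarray
    rate: np.ndarray
    amplification: np.ndarray
    region: np.ndarray
    t_max: np.ndarray
    peak: np.ndarray
    baseline_rate: float
    baseline_peak: float
    theta: float = 2.0
    pe_threshold: float = 1.0
    errors: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (sigma, pe, rate_per_s, amplification, region)."""
        s, p = np.meshgrid(self.sigma_axis, self.pe_axis, indexing="ij")
        return pd.DataFrame(
            {
                "sigma": s.ravel(),
                "pe": p.ravel(),
                "rate_per_s": self.rate.ravel(),
                "amplification": self.amplification.ravel(),
                "region": self.region.ravel(),
            }
        )


def _point_metrics(kymo: Kymograph) -> MetricsResult:
    times, series = peripheral_series(kymo)
    return signaling_rate(series, times)


def scan_phase_diagram(
    scenario: ScenarioConfig,
    sigma_axis,
    pe_axis,
    *,
    theta: float = 2.0,
    pe_threshold: float = 1.0,
    baseline: MetricsResult | None = None,
    known: dict | None = None,
    on_error: str = "raise",
) -> PhaseDiagram:
    """Run one simulation per (sigma, Pe) grid point and collect metrics.

    A single shared baseline run (sigma = 0, Pe = 0) normalizes the
    amplification grid; a precomputed ``baseline`` may be supplied.
    ``known`` maps (sigma, pe) -> (t_max, peak) for points already computed
    (scan resume).  With ``on_error="record"`` per-point solver failures are
    recorded in ``diagram.errors`` (NaN metrics, region 0) and the scan
    continues; the default propagates them as :class:`ScanPointError`.
    """
    sigma_axis = np.asarray(sigma_axis, dtype=float)
    pe_axis = np.asarray(pe_axis, dtype=float)
    if sigma_axis.size == 0 or pe_axis.size == 0:
        raise ValueError("sigma and Pe axes must be nonempty")
    if on_error not in ("raise", "record"):
        raise ValueError("on_error must be 'raise' or 'record'")

    if baseline is None:
        base_kymo = run_simulation(with_operating_point(scenario, 0.0, 0.0))
        baseline = _point_metrics(base_kymo)

    shape = (sigma_axis.size, pe_axis.size)
    rate = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    tmax = np.full(shape, np.nan)
    peak = np.full(shape, np.nan)
    region = np.zeros(shape, dtype=int)
    errors: list[ScanPointError] = []
    known = known or {}

    for i, s in enumerate(sigma_axis):
        for j, p in enumerate(pe_axis):
            if (s, p) in known:
                t_max_ij, peak_ij = known[(s, p)]
                res = MetricsResult(t_max=t_max_ij, rate=1.0 / t_max_ij, peak_conc=peak_ij)
            elif s == 0.0 and p == 0.0:
                res = baseline
            else:
                try:
                    res = _point_metrics(run_simulation(with_operating_point(scenario, s, p)))
                except Exception as exc:  # noqa: BLE001 - coordinates attached below
                    err = ScanPointError(s, p, exc)
                    if on_error == "raise":
                        raise err from exc
                    errors.append(err)
                    continue
            rate[i, j] = res.rate
            tmax[i, j] = res.t_max
            peak[i, j] = res.peak_conc
            amp[i, j] = amplification(res.peak_conc, baseline.peak_conc)
            region[i, j] = classify_region(
                s, p, res.rate, baseline.rate, theta=theta, pe_threshold=pe_threshold
            )

    return PhaseDiagram(
        sigma_axis=sigma_axis,
        pe_axis=pe_axis,
        rate=rate,
        amplification=amp,
        region=region,
        t_max=tmax,
        peak=peak,
        baseline_rate=baseline.rate,
        baseline_peak=baseline.peak_conc,
        theta=theta,
        pe_threshold=pe_threshold,
        errors=errors,
    )


def optimum_point(diagram: PhaseDiagram) -> tuple[float, float, float]:
    """(sigma*, Pe*, A_max): argmax of amplification, ties toward smaller
    sigma then smaller Pe."""
    amp = diagram.amplification
    if np.all(np.isnan(amp)):
        raise ValueError("phase diagram has no finite amplification values")
    best = np.nanmax(amp)
    cells = np.argwhere(amp >= best)  # lexicographic: smallest sigma, then Pe
    i, j = cells[0]
    return float(diagram.sigma_axis[i]), float(diagram.pe_axis[j]), float(best)


_SENSITIVITY_SPECIES = ("M3/6", "KIF5", "JNK")


def sensitivity_scan(
    scenario: ScenarioConfig,
    which: str,
    levels,
    sigma_axis,
    pe_axis,
    **scan_kwargs,
) -> pd.DataFrame:
    """How the amplification optimum moves with a component's abundance.

    For each level the named species' initial amplitude is rescaled and a
    full phase scan (with its own rescaled baseline) is run.  Returns a
    table with columns (level, sigma_opt, pe_opt, a_max).
    """
    if which not in _SENSITIVITY_SPECIES:
        raise ValueError(f"which must be one of {_SENSITIVITY_SPECIES}, got {which!r}")
    levels = [float(l) for l in levels]
    if not levels:
        raise ValueError("levels must be nonempty")
    if any(l <= 0 for l in levels):
        raise ValueError("levels must be positive")

    from dataclasses import replace

    rows = []
    for level in levels:
        prof = scenario.profiles[which]
        scaled = replace(prof, amplitude=prof.amplitude * level)
        sc = replace(scenario, profiles={**scenario.profiles, which: scaled})
        diag = scan_phase_diagram(sc, sigma_axis, pe_axis, **scan_kwargs)
        s_opt, p_opt, a_max = optimum_point(diag)
        rows.append({"level": level, "sigma_opt": s_opt, "pe_opt": p_opt, "a_max": a_max})
    return pd.DataFrame(rows)
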