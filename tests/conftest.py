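"""Shared fixtures.

Expensive phase scans are session-scoped and run on a 100-cell mesh so the
whole suite stays within a routine CI budget; the scans are qualitative
(regime structure, optimum locations) and are only ever compared within
one grid resolution.
"""

from __future__ import annotations

import numpy as np
import pytest

import jnktransport as jt


@pytest.fixture(scope="session")
def constants():
    return jt.default_constants()


@pytest.fixture(scope="session")
def registry():
    return jt.default_registry()


@pytest.fixture()
def grid():
    return jt.Grid1D(L=100.0, n_cells=200)


def coarse_scenario(sigma=0.0, pe=0.0, **kw):
    """100-cell scan-resolution scenario used by the slower analyses.

    The 6000 s horizon covers every optimum examined (peaks land well
    before 4000 s on this mesh).
    """
    kw.setdefault("n_cells", 100)
    kw.setdefault("L", 100.0)
    kw.setdefault("t_end", 6000.0)
    return jt.default_scenario(sigma, pe, **kw)


@pytest.fixture(scope="session")
def biphasic_scan():
    """8x8 (sigma, Pe) phase diagram of the default scenario, 100-cell mesh.

    sigma axis: {0} plus 7 log-spaced points in (0, 3]; Pe axis includes the
    pure-diffusion column and the reference speeds 2 and 5.
    """
    sigma_axis = np.concatenate([[0.0], np.geomspace(0.3, 3.0, 7)])
    pe_axis = np.array([0.0, 1.0, 2.0, 3.5, 5.0, 6.5, 8.0, 10.0])
    return jt.scan_phase_diagram(coarse_scenario(), sigma_axis, pe_axis)


@pytest.fixture(scope="session")
def sensitivity_curves():
    """Optimum trajectories for 0.5x/1x/2x abundance of M3/6, KIF5, JNK.

    The unscaled (level 1.0) scan is identical for all three components
    and computed once.
    """
    from dataclasses import replace

    levels = [0.5, 1.0, 2.0]
    sigma_axis = [0.5, 1.0, 2.0, 3.0]
    pe_axis = [2.0, 5.0, 10.0]
    sc = coarse_scenario()
    cache: dict = {}

    def optimum_for(which, level):
        key = ("default", 1.0) if level == 1.0 else (which, level)
        if key not in cache:
            prof = sc.profiles[which]
            scaled = replace(prof, amplitude=prof.amplitude * level)
            sc_level = replace(sc, profiles={**sc.profiles, which: scaled})
            diag = jt.scan_phase_diagram(sc_level, sigma_axis, pe_axis)
            cache[key] = jt.optimum_point(diag)
        return cache[key]

    curves = {}
    for which in ("M3/6", "KIF5", "JNK"):
        rows = []
        for level in levels:
            s_opt, p_opt, a_max = optimum_for(which, level)
            rows.append(
                {"level": level, "sigma_opt": s_opt, "pe_opt": p_opt, "a_max": a_max}
            )
        curves[which] = rows
    return curves
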