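"""Metric definitions, regime classification, and small phase scans."""

import numpy as np
import pytest

import jnktransport as jt


class TestDimensionless:
    def test_sigma_examples(self):
        assert jt.sigma(0.0, 10.0) == 0.0
        assert jt.sigma(10.0, 10.0) == 1.0
        assert jt.sigma(20.0, 10.0) == 2.0

    def test_sigma_requires_positive_jnk(self):
        with pytest.raises(ValueError):
            jt.sigma(1.0, 0.0)

    def test_peclet_examples(self):
        assert jt.peclet(0.0, 100.0, 10.0) == 0.0
        assert jt.peclet(0.1, 100.0, 10.0) == pytest.approx(1.0)
        assert jt.peclet(1.0, 100.0, 10.0) == pytest.approx(10.0)

    def test_peclet_requires_positive_geometry(self):
        with pytest.raises(ValueError):
            jt.peclet(1.0, 0.0, 10.0)


class TestSignalingRate:
    @pytest.mark.parametrize("t_peak,rate", [(490.0, 1 / 490.0), (3300.0, 1 / 3300.0)])
    def test_rate_is_inverse_peak_time(self, t_peak, rate):
        times = np.arange(0.0, 5001.0)
        series = np.exp(-((times - t_peak) ** 2) / (2 * 300.0**2))
        res = jt.signaling_rate(series, times)
        assert res.t_max == t_peak
        assert res.rate == pytest.approx(rate, rel=1e-12)

    def test_earliest_time_wins_on_plateau(self):
        times = np.arange(0.0, 10.0)
        series = np.array([0, 1, 2, 3, 3, 3, 2, 1, 0, 0], dtype=float)
        assert jt.signaling_rate(series, times).t_max == 3.0

    def test_flat_zero_series_has_no_rate(self):
        with pytest.raises(ValueError):
            jt.signaling_rate(np.zeros(10), np.arange(10.0))


class TestAmplification:
    def test_baseline_against_itself_is_one(self):
        assert jt.amplification(0.0389, 0.0389) == pytest.approx(1.0)

    def test_printed_reference_ratio(self):
        # ratio of the two reference kymograph maxima
        assert jt.amplification(0.0645, 0.0389) == pytest.approx(1.658, abs=5e-4)

    def test_zero_peak_gives_zero(self):
        assert jt.amplification(0.0, 0.0389) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            jt.amplification(1.0, 0.0)


class TestClassifyRegion:
    def test_no_scaffold_is_region_2(self):
        assert jt.classify_region(0.0, 5.0, 1.0, 0.1) == 2

    def test_slow_motor_is_region_1(self):
        assert jt.classify_region(1.0, 0.5, 1.0, 0.1) == 1

    def test_fast_rate_is_region_3_else_4(self):
        base = 1e-3
        assert jt.classify_region(1.0, 5.0, 3e-3, base) == 3
        assert jt.classify_region(1.0, 5.0, base, base) == 4

    def test_theta_is_configurable(self):
        assert jt.classify_region(1.0, 5.0, 2.5e-3, 1e-3, theta=2.0) == 3
        assert jt.classify_region(1.0, 5.0, 2.5e-3, 1e-3, theta=3.0) == 4


class TestOptimumPoint:
    def _diagram(self, amp):
        amp = np.asarray(amp, dtype=float)
        shape = amp.shape
        return jt.PhaseDiagram(
            sigma_axis=np.arange(shape[0], dtype=float),
            pe_axis=np.arange(shape[1], dtype=float),
            rate=np.ones(shape),
            amplification=amp,
            region=np.ones(shape, dtype=int),
            t_max=np.ones(shape),
            peak=amp,
            baseline_rate=1.0,
            baseline_peak=1.0,
        )

    def test_single_peak_found(self):
        s, p, a = jt.optimum_point(self._diagram([[1, 2], [5, 3]]))
        assert (s, p, a) == (1.0, 0.0, 5.0)

    def test_ties_break_to_smaller_sigma_then_pe(self):
        s, p, a = jt.optimum_point(self._diagram([[2, 2], [2, 2]]))
        assert (s, p) == (0.0, 0.0)


@pytest.fixture(scope="module")
def tiny_scenario():
    # coarse, short-horizon scenario: structure checks only
    return jt.default_scenario(0.0, 0.0, n_cells=40, L=100.0, t_end=800)


class TestScanPhaseDiagram:
    def test_trivial_baseline_cell(self, tiny_scenario):
        diag = jt.scan_phase_diagram(tiny_scenario, [0.0], [0.0])
        assert diag.amplification[0, 0] == pytest.approx(1.0)
        assert diag.region[0, 0] == 2
        assert diag.rate[0, 0] == pytest.approx(diag.baseline_rate)

    def test_sigma_zero_row_is_all_region_2(self, tiny_scenario):
        diag = jt.scan_phase_diagram(tiny_scenario, [0.0], [0.0, 2.0, 5.0])
        assert set(diag.region[0]) == {2}

    def test_grid_is_a_partition(self, tiny_scenario):
        diag = jt.scan_phase_diagram(tiny_scenario, [0.0, 1.0], [0.5, 5.0])
        assert diag.region.shape == (2, 2)
        assert np.all(np.isin(diag.region, [1, 2, 3, 4]))

    def test_long_format_table(self, tiny_scenario):
        diag = jt.scan_phase_diagram(tiny_scenario, [0.0, 1.0], [0.0, 5.0])
        df = diag.to_frame()
        assert list(df.columns) == ["sigma", "pe", "rate_per_s", "amplification", "region"]
        assert len(df) == 4

    def test_empty_axes_rejected(self, tiny_scenario):
        with pytest.raises(ValueError):
            jt.scan_phase_diagram(tiny_scenario, [], [0.0])


class TestSensitivityScan:
    def test_unknown_species_rejected(self):
        sc = jt.default_scenario(0, 0, n_cells=40, t_end=100)
        with pytest.raises(ValueError, match="M3/6"):
            jt.sensitivity_scan(sc, "JIP1", [1.0], [1.0], [2.0])

    def test_empty_levels_rejected(self):
        sc = jt.default_scenario(0, 0, n_cells=40, t_end=100)
        with pytest.raises(ValueError):
            jt.sensitivity_scan(sc, "JNK", [], [1.0], [2.0])

    def test_default_level_matches_plain_scan(self):
        sc = jt.default_scenario(0, 0, n_cells=40, L=100.0, t_end=800)
        curve = jt.sensitivity_scan(sc, "KIF5", [1.0], [1.0, 2.0], [3.0, 6.0])
        diag = jt.scan_phase_diagram(sc, [1.0, 2.0], [3.0, 6.0])
        s, p, a = jt.optimum_point(diag)
        row = curve.iloc[0]
        assert (row.sigma_opt, row.pe_opt) == (s, p)
        assert row.a_max == pytest.approx(a)


class TestPeripheralSeries:
    def test_missing_species_raises(self):
        sc = jt.default_scenario(0, 0, n_cells=20, t_end=10)
        kymo = jt.run_simulation(sc)
        kymo.species = tuple(s for s in kymo.species if s != "JNK*")
        with pytest.raises(KeyError):
            jt.peripheral_series(kymo)

    def test_series_is_free_jnkstar_in_terminal_cell(self):
        sc = jt.default_scenario(0, 0, n_cells=20, L=100.0, t_end=50)
        kymo = jt.run_simulation(sc, record_every=1.0)
        times, series = jt.peripheral_series(kymo)
        idx = kymo.species_index("JNK*")
        # frame times are a subset of series times; values agree there
        sel = np.isin(kymo.series_times, kymo.times)
        assert np.allclose(series[sel], kymo.conc[idx, :, -1])
        assert len(times) == len(series)
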