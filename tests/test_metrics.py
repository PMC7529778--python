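import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioloop import (MetricsError, beat_statistics, cardiac_indexes,
                        comparison_report, normalize_waveform, nsd,
                        pv_loop_work, relative_variation)
from cardioloop.metrics import BeatSeries


def beat(y, rr=0.8):
    t = np.linspace(0.0, rr, len(y))
    return BeatSeries(site="s", kind="P", t=t, y=np.asarray(y, float),
                      rr=rr)


class TestBeatStatistics:
    def test_constant_signal(self):
        s = beat(np.full(500, 7.5))
        st = beat_statistics(s)
        assert st["mean"] == pytest.approx(7.5)
        assert st["pulse"] == 0.0

    def test_sine_oracle(self):
        rr, a, b = 0.8, 3.0, 11.0
        t = np.linspace(0, rr, 4001)
        s = BeatSeries("s", "P", t, a * np.sin(2 * np.pi * t / rr) + b, rr)
        st = beat_statistics(s)
        assert st["mean"] == pytest.approx(b, abs=1e-6)
        assert st["pulse"] == pytest.approx(2 * a, rel=1e-6)

    def test_incomplete_beat_rejected(self):
        t = np.linspace(0, 0.4, 100)
        s = BeatSeries("s", "P", t, np.sin(t), rr=0.8)
        with pytest.raises(MetricsError, match="incomplete"):
            beat_statistics(s)

    def test_quadrature_grid_independence(self):
        rr = 0.8
        for n in (500, 1000):
            t = np.linspace(0, rr, n + 1)
            y = 90 + 20 * np.sin(2 * np.pi * t / rr) ** 2
            s = BeatSeries("s", "P", t, y, rr)
            if n == 500:
                ref = beat_statistics(s)["mean"]
            else:
                assert beat_statistics(s)["mean"] == pytest.approx(
                    ref, rel=1e-4)


class TestNormalization:
    def test_zero_mean_unit_sd(self):
        tp, y = normalize_waveform(beat(np.random.default_rng(0)
                                        .normal(50, 5, 700)))
        assert np.trapezoid(y, tp) == pytest.approx(0.0, abs=1e-9)
        assert np.trapezoid(y * y, tp) == pytest.approx(1.0, rel=1e-9)

    def test_affine_invariance(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 600)) + 0.3
        _, n1 = normalize_waveform(beat(y))
        _, n2 = normalize_waveform(beat(3.0 * y + 5.0))
        assert np.allclose(n1, n2, atol=1e-12)

    def test_idempotence(self):
        y = np.cos(np.linspace(0, 2 * np.pi, 600))
        tp, n1 = normalize_waveform(beat(y))
        _, n2 = normalize_waveform(BeatSeries("s", "P", tp, n1, 1.0))
        assert np.allclose(n1, n2, atol=1e-6)

    def test_constant_signal_rejected(self):
        with pytest.raises(MetricsError, match="constant"):
            normalize_waveform(beat(np.full(100, 4.0)))


class TestNSD:
    def test_identical_signals_zero(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 800)) + 2
        assert nsd(beat(y), beat(3 * y + 1)) == pytest.approx(0.0,
                                                              abs=1e-9)

    def test_complementary_steps_reach_two(self):
        n = 20000
        y1 = np.where(np.linspace(0, 1, n) < 0.5, 1.0, -1.0)
        assert nsd(beat(y1), beat(-y1)) == pytest.approx(2.0, abs=5e-3)

    def test_shifted_sine_quadrature_oracle(self):
        # closed-form oracle evaluated by high-resolution quadrature
        tq = np.linspace(0, 1, 1_000_001)
        a = np.sqrt(2) * np.sin(2 * np.pi * tq)
        b = np.sqrt(2) * np.sin(2 * np.pi * (tq - 0.25))
        oracle = np.trapezoid(np.abs(a - b), tq)
        t = np.linspace(0, 1, 3001)
        v = nsd(beat(np.sin(2 * np.pi * t)),
                beat(np.sin(2 * np.pi * (t - 0.25))))
        assert v == pytest.approx(oracle, rel=1e-3)

    def test_randomized_properties(self, rng):
        """Bounds, symmetry and the correlation bound
        NSD <= sqrt(2 (1 - rho)) on >= 1000 random smooth signal pairs."""
        t = np.linspace(0, 1, 400)
        for _ in range(1000):
            k = rng.integers(1, 6, size=2)
            ph = rng.uniform(0, 2 * np.pi, size=2)
            amp = rng.uniform(0.5, 3.0, size=2)
            y1 = amp[0] * np.sin(2 * np.pi * k[0] * t + ph[0]) \
                + rng.normal(0, 0.1, t.size)
            y2 = amp[1] * np.sin(2 * np.pi * k[1] * t + ph[1]) \
                + rng.normal(0, 0.1, t.size)
            v12 = nsd(beat(y1), beat(y2))
            v21 = nsd(beat(y2), beat(y1))
            assert v12 == pytest.approx(v21, abs=1e-12)
            assert 0.0 <= v12 <= 2.0 + 1e-9
            tp, a = normalize_waveform(beat(y1))
            _, b = normalize_waveform(beat(y2))
            rho = np.trapezoid(a * b, tp)
            assert v12 <= np.sqrt(max(0.0, 2 * (1 - rho))) + 1e-6


class TestNSDHypothesis:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-50.0, 50.0),
           k=st.integers(1, 5), ph=st.floats(0.0, 6.28))
    def test_affine_invariance_property(self, a, b, k, ph):
        t = np.linspace(0, 1, 300)
        y = np.sin(2 * np.pi * k * t + ph) + 0.2 * np.sin(7 * t)
        assert nsd(beat(y), beat(a * y + b)) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x=st.floats(0.1, 1e3), p=st.floats(-0.9, 0.9))
    def test_relative_variation_scaling(self, x, p):
        assert relative_variation(x, x * (1 + p)) == pytest.approx(
            100 * p, abs=1e-9)


class TestIndexesArithmetic:
    def test_ef_definition(self):
        sv, v_lved = 70.0, 120.0
        assert 100 * sv / v_lved == pytest.approx(58.333, abs=1e-3)

    def test_cvp_is_mean_of_cavae(self):
        assert 0.5 * (6.48 + 6.50) == pytest.approx(6.49)

    def test_rectangular_pv_loop_work(self):
        # P cycles 10 -> 110 at V extremes 50 and 120 ml: area 7000
        v = np.array([120.0, 120.0, 50.0, 50.0, 120.0])
        p = np.array([10.0, 110.0, 110.0, 10.0, 10.0])
        assert pv_loop_work(p[:-1], v[:-1]) == pytest.approx(7000.0)

    def test_relative_variation_printed_examples(self):
        assert relative_variation(92.61, 83.19) == pytest.approx(-10.17,
                                                                 abs=0.005)
        assert relative_variation(0.25, 0.11) == pytest.approx(-56.00,
                                                               abs=0.005)
        assert relative_variation(5.0, 5.0) == 0.0
        with pytest.raises(MetricsError):
            relative_variation(0.0, 1.0)


class TestOnSimulatedRun:
    def test_map_between_dias_and_syst(self, steady_1g):
        idx = cardiac_indexes(steady_1g)
        assert idx.p_aa_dias <= idx.map <= idx.p_aa_syst
        assert idx.pp_aa == pytest.approx(idx.p_aa_syst - idx.p_aa_dias)
        assert 0 < idx.v_lves < idx.v_lved
        assert 0 < idx.ef < 100

    def test_missing_site_raises(self, steady_1g):
        import copy
        store = copy.copy(steady_1g)
        store.signals = {k: v for k, v in steady_1g.signals.items()
                        if k != "svc:P"}
        with pytest.raises(MetricsError, match="svc"):
            cardiac_indexes(store)

    def test_comparison_report_identical_runs(self, steady_1g):
        report = comparison_report(steady_1g, steady_1g,
                                   ["asc_aorta", "l_femoral"])
        means = report["means"]
        assert np.allclose(means["P_variation_pct"], 0.0)
        assert np.allclose(report["nsd"]["NSD_P"], 0.0)
        assert set(report) >= {"means", "extremes", "nsd"}

    def test_comparison_report_site_mismatch(self, steady_1g):
        with pytest.raises(MetricsError, match="not recorded"):
            comparison_report(steady_1g, steady_1g, ["no_such_site"])
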