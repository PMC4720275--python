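"""Wavelet transform, t-scalogram, minimum search, Hotelling, detection."""

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

import tonocortex as tc
from tonocortex.preprocess import EpochSet
from tonocortex.protocol import StimulusType
from tonocortex.synthetic import pink_noise
from tonocortex.tcwt import TScalogram, hotelling_t2_reduced


class TestWavelet:
    def test_scale_grid(self):
        g = tc.scale_grid()
        assert len(g) == 120
        assert g[0] == pytest.approx(8.33) and g[-1] == pytest.approx(250.0)
        assert np.all(np.diff(g) > 0)
        np.testing.assert_allclose(np.diff(g), (250.0 - 8.33) / 119)

    def test_mexican_hat_values(self):
        assert tc.mexican_hat(0.0) == pytest.approx(
            2.0 / (np.sqrt(3.0) * np.pi ** 0.25), abs=1e-12)
        assert tc.mexican_hat(1.0) == 0.0
        assert tc.mexican_hat(-1.0) == 0.0
        integral, _ = scipy.integrate.quad(tc.mexican_hat, -10, 10)
        assert abs(integral) < 1e-8           # admissibility (zero mean)
        norm, _ = scipy.integrate.quad(lambda u: tc.mexican_hat(u) ** 2, -10, 10)
        assert norm == pytest.approx(1.0, abs=1e-8)    # unit L2 norm


class TestCWT:
    def test_zero_signal_and_linearity(self, rng):
        grid = tc.scale_grid()[:20]
        z = tc.cwt(np.zeros(400), grid)
        assert not z.values.any()
        x, y = rng.normal(size=400), rng.normal(size=400)
        a = 2.5
        lhs = tc.cwt(a * x + y, grid).values
        rhs = a * tc.cwt(x, grid).values + tc.cwt(y, grid).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_matched_wavelet_argmax(self):
        """Input = the wavelet at scale s0 centered at 100 ms -> argmax there."""
        t = np.arange(400.0)                  # 0..399 ms at 1 kHz
        s0 = tc.scale_grid()[10]              # ~28.7 ms: support well inside
        x = tc.mexican_hat((t - 100.0) / s0)
        sg = tc.cwt(x, tc.scale_grid())
        si, ti = np.unravel_index(np.argmax(np.abs(sg.values)), sg.values.shape)
        assert ti == 100
        assert sg.scales_ms[si] == pytest.approx(s0, rel=0.05)

    def test_time_shift_covariance(self, rng):
        """Shifting the input shifts every scalogram row (interior region)."""
        grid = tc.scale_grid()[:10]           # small scales: padding stays clear
        x = np.zeros(600)
        x[250:280] = rng.normal(size=30)
        delta = 40
        y = np.roll(x, delta)
        a = tc.cwt(x, grid).values
        b = tc.cwt(y, grid).values
        interior = slice(200, 350)
        np.testing.assert_allclose(b[:, interior.start + delta:interior.stop + delta],
                                   a[:, interior], atol=1e-10)


class TestTScalogram:
    def test_zero_variance_raises(self):
        grid = tc.scale_grid()[:5]
        scal = tc.cwt(np.ones(100), grid)
        with pytest.raises(ZeroDivisionError):
            tc.t_scalogram([scal, scal])      # identical trials -> sd 0

    def test_two_opposite_trials_give_t_zero(self, rng):
        x = rng.normal(size=200)
        grid = tc.scale_grid()[:5]
        a, b = tc.cwt(x, grid), tc.cwt(-x, grid)
        ts = tc.t_scalogram([a, b])
        np.testing.assert_allclose(ts.t_values, 0.0, atol=1e-9)

    def test_null_t_distribution(self, rng):
        """i.i.d. N(0,1) trials at a point: t ~ Student-t(n-1), |t|<4 a.s."""
        n = 200
        draws = rng.standard_normal((10_000, n))
        t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(n))
        # agreement with the Student-t reference
        ks = scipy.stats.kstest(t, scipy.stats.t(df=n - 1).cdf)
        assert ks.pvalue > 0.01
        assert np.mean(np.abs(t) < 4) >= 0.999


class TestLocateMinimum:
    def _ts(self, values, times=None):
        times = np.arange(-50, 350.0) if times is None else times
        return TScalogram(t_values=values, scales_ms=tc.scale_grid(),
                          time_axis_ms=times, n_trials=10)

    def test_engineered_minimum(self):
        vals = np.zeros((120, 400))
        si = int(np.argmin(np.abs(tc.scale_grid() - 50.0)))
        vals[si, 150] = -5.0                  # t = 100 ms, scale ~50 ms
        lat, scale, tmin = tc.locate_minimum(self._ts(vals))
        assert lat == 100.0
        assert scale == pytest.approx(50.0, abs=2.0)
        assert tmin == -5.0

    def test_monotone_returns_window_edge(self):
        vals = np.tile(-np.arange(400.0), (120, 1))   # decreasing in time
        lat, _, _ = tc.locate_minimum(self._ts(vals))
        assert lat == 150.0                   # right edge of [80, 150]

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive double-loop scan agrees on 100 random fields."""
        times = np.arange(-50, 350.0)
        scales = tc.scale_grid()
        for _ in range(100):
            vals = rng.normal(size=(120, 400))
            lat, scale, tmin = tc.locate_minimum(self._ts(vals))
            best = (np.inf, None, None)
            for ti, t in enumerate(times):
                if not 80 <= t <= 150:
                    continue
                for si in range(len(scales)):
                    if vals[si, ti] < best[0]:
                        best = (vals[si, ti], t, scales[si])
            assert (tmin, lat, scale) == (best[0], best[1], best[2])


class TestHotelling:
    def test_p1_equals_squared_t(self, rng):
        x = rng.normal(0.3, 1.0, size=(50, 1))
        t2, p = tc.hotelling_t2(x)
        t = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert t2 == pytest.approx(t ** 2, abs=1e-9)
        # and the F(1, n-1) p-value equals the two-sided t-test p-value
        t_p = scipy.stats.ttest_1samp(x[:, 0], 0.0).pvalue
        assert p == pytest.approx(t_p, abs=1e-9)

    def test_null_calibration_and_power(self, rng):
        """Type I error ~5% under H0; power ~1 for a 1 SD shift (p=5, n=100)."""
        p_dim, n, reps = 5, 100, 4000
        rejections = 0
        for _ in range(reps):
            _, p = tc.hotelling_t2(rng.standard_normal((n, p_dim)))
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06
        power = 0
        for _ in range(200):
            _, p = tc.hotelling_t2(rng.standard_normal((n, p_dim)) + 1.0)
            power += p < 0.05
        assert power / 200 > 0.99

    def test_null_pvalues_uniform(self, rng):
        p_dim, n = 3, 40
        ps = [tc.hotelling_t2(rng.standard_normal((n, p_dim)))[1]
              for _ in range(2000)]
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_singular_covariance_raises(self, rng):
        x = rng.standard_normal((30, 2))
        x = np.hstack([x, x[:, :1]])          # exact linear dependence
        with pytest.raises(np.linalg.LinAlgError):
            tc.hotelling_t2(x)
        # the reduced variant works in the occupied subspace
        t2, p, r = hotelling_t2_reduced(x)
        assert r == 2 and np.isfinite(t2) and 0 <= p <= 1

    def test_shape_preconditions(self, rng):
        with pytest.raises(ValueError):
            tc.hotelling_t2(rng.standard_normal((5, 5)))   # n <= p


def _single_condition_epochs(data, cond):
    return EpochSet(data=data, time_axis_ms=np.arange(-50, 350.0),
                    channel_labels=["Cz"], labels=[cond] * data.shape[0])


class TestDetectN100:
    def test_strong_signal_recovered(self, a_condition, rng):
        """-8 uV bump at 100 ms in 4 uV pink noise: detected within 10 ms."""
        n = 120
        t = np.arange(-50, 350.0)
        bump = -8.0 * np.exp(-0.5 * ((t - 100.0) / 15.0) ** 2)
        noise = np.stack([pink_noise(400, 1, 4.0, rng) for _ in range(n)])
        ep = _single_condition_epochs(bump[None, None, :] + noise, a_condition)
        det = tc.detect_n100(ep, a_condition)
        assert det.significant
        assert 90 <= det.latency_ms <= 110
        assert det.t_min < 0
        assert det.p_value < 0.05

    def test_insufficient_trials(self, a_condition):
        ep = _single_condition_epochs(np.random.default_rng(0)
                                      .normal(size=(3, 1, 400)), a_condition)
        with pytest.raises(ValueError, match="insufficient trials"):
            tc.detect_n100(ep, a_condition)

    def test_determinism(self, a_condition, rng):
        data = np.stack([pink_noise(400, 1, 5.0, rng) for _ in range(40)])
        ep = _single_condition_epochs(data, a_condition)
        d1 = tc.detect_n100(ep, a_condition, seed=3)
        d2 = tc.detect_n100(ep, a_condition, seed=3)
        assert d1 == d2

    def test_detection_rate_monotone_in_amplitude(self, a_condition):
        """Detection rate grows with injected amplitude (0 -> 2 -> 6 uV)."""
        rng = np.random.default_rng(1)
        t = np.arange(-50, 350.0)
        rates = []
        for amp in (0.0, 2.0, 6.0):
            hits = 0
            for i in range(12):
                bump = -amp * np.exp(-0.5 * ((t - 100.0) / 15.0) ** 2)
                noise = np.stack([pink_noise(400, 1, 5.0, rng)
                                  for _ in range(60)])
                ep = _single_condition_epochs(bump[None, None, :] + noise,
                                              a_condition)
                hits += tc.detect_n100(ep, a_condition, n_flips=100, seed=i).significant
            rates.append(hits / 12)
        assert rates[0] <= 0.25               # near-null
        assert rates[2] == 1.0                # strong signal always found
        assert rates[2] >= rates[1] >= rates[0]
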