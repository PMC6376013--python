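"""Synthetic session generator: envelope statistics, carriers, geometry
and forward consistency."""

import numpy as np
import pytest

from deepesi.preprocess import to_average_reference
from deepesi.simulate import (SimulationConfig, default_head, gen_alpha_source,
                              gen_correlated_envelopes, gen_envelope,
                              sensor_layout, simulate_session)
from deepesi.spectral import find_alpha_peak, welch_psd
from deepesi.preprocess import to_bipolar
from deepesi.simulate import lead_layout_from_labels
from deepesi.recording import Recording


def _acf_one_over_e_lag(env, fs):
    x = env - env.mean()
    ac = np.correlate(x, x, "full")[len(x) - 1:]
    ac = ac / ac[0]
    return np.argmax(ac < 1.0 / np.e) / fs


class TestEnvelope:
    def test_seed_determinism(self):
        a = gen_envelope(2.0, 300.0, 250.0, seed=7)
        b = gen_envelope(2.0, 300.0, 250.0, seed=7)
        assert np.array_equal(a, b)

    def test_positive_with_positive_mean(self):
        env = gen_envelope(2.0, 60.0, 100.0, seed=0)
        assert np.all(env > 0) and env.mean() > 0

    def test_autocorrelation_decays_on_the_requested_timescale(self):
        """Empirical 1/e lag lies in [0.5, 2] x timescale across seeds."""
        lags = [_acf_one_over_e_lag(gen_envelope(2.0, 300.0, 50.0, seed=s), 50.0)
                for s in range(50)]
        lags = np.asarray(lags)
        assert np.all(lags >= 0.5 * 2.0) and np.all(lags <= 2.0 * 2.0)

    @pytest.mark.parametrize("timescale,duration", [(0.0, 10.0), (2.0, 0.0), (-1.0, 5.0)])
    def test_nonpositive_parameters_rejected(self, timescale, duration):
        with pytest.raises(ValueError):
            gen_envelope(timescale, duration, 100.0, seed=0)


class TestCorrelatedEnvelopes:
    def test_rho_one_identical(self):
        a, b = gen_correlated_envelopes(2.0, 1.0, 60.0, 100.0, seed=3)
        assert np.allclose(a, b)

    def test_rho_zero_uncorrelated_within_sampling_error(self):
        rs = [np.corrcoef(*gen_correlated_envelopes(2.0, 0.0, 300.0, 50.0, s))[0, 1]
              for s in range(50)]
        # effective sample size ~ T / (2 tau) = 75 -> sd ~ 0.12
        assert abs(np.median(rs)) < 0.15
        assert abs(np.mean(rs)) < 0.05

    def test_rho_calibration_at_intermediate_value(self):
        rs = [np.corrcoef(*gen_correlated_envelopes(2.0, 0.6, 300.0, 50.0, s))[0, 1]
              for s in range(30)]
        assert 0.45 <= np.median(rs) <= 0.75
        assert np.mean(rs) == pytest.approx(0.6, abs=0.08)

    @pytest.mark.parametrize("rho", [-0.1, 1.2])
    def test_rho_out_of_range_rejected(self, rho):
        with pytest.raises(ValueError):
            gen_correlated_envelopes(2.0, rho, 10.0, 100.0, seed=0)


class TestAlphaSource:
    def test_constant_envelope_gives_pure_tone(self):
        x = gen_alpha_source(np.ones(2500), 9.0, 250.0, seed=0)
        rec = Recording(x[None, :], 250.0, ["c0"], reference="average")
        psd = welch_psd(rec)
        assert abs(psd.freqs[np.argmax(psd.power[0])] - 9.0) <= 0.5

    def test_zero_envelope_gives_zero_output(self):
        assert np.all(gen_alpha_source(np.zeros(100), 9.0, 250.0, seed=0) == 0)

    def test_hilbert_envelope_recovers_input(self):
        from scipy.signal import hilbert

        env = gen_envelope(2.0, 120.0, 250.0, seed=5)
        x = gen_alpha_source(env, 9.0, 250.0, seed=5)
        rec_env = np.abs(hilbert(x))
        sl = slice(500, -500)
        assert np.corrcoef(rec_env[sl], env[sl])[0, 1] >= 0.99

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            gen_alpha_source(np.ones(100), 130.0, 250.0, seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sampling_rate": 18.0},               # below 2*(alpha_peak+1)
        {"interhemi_rho": 1.5},
        {"cortico_deep_rho": -0.2},
        {"duration": 10.001, "sampling_rate": 100.0},  # non-integer samples
        {"deep_source_positions": ((0.0, 0.0, 85.0), (22.0, -12.0, 8.0))},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        cfg_kwargs = dict(sampling_rate=250.0, duration=10.0, n_sensors=8)
        cfg_kwargs.update(kwargs)
        with pytest.raises(ValueError):
            cfg = SimulationConfig(**cfg_kwargs)
            simulate_session(cfg, default_head(cfg.n_sensors))


class TestSensorLayout:
    def test_on_scalp_and_reasonably_uniform(self):
        pts = sensor_layout(128, 92.0)
        assert np.allclose(np.linalg.norm(pts, axis=1), 92.0)
        assert pts[:, 2].min() >= -0.31 * 92.0
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].max() / d[:, 1].min() < 2.5


class TestSession:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(sampling_rate=250.0, duration=10.0, n_sensors=16, seed=9)
        head = default_head(16)
        s1, i1, g1 = simulate_session(cfg, head)
        s2, i2, g2 = simulate_session(cfg, head)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(i1.data, i2.data)
        assert np.array_equal(g1.source_envelopes, g2.source_envelopes)

    def test_noiseless_single_source_in_leadfield_column_space(self):
        cfg = SimulationConfig(sampling_rate=250.0, duration=4.0, n_sensors=24,
                               sensor_noise_sd=0.0, lfp_noise_sd=0.0,
                               n_cortical_sources=0, interhemi_rho=1.0, seed=1,
                               deep_source_positions=((-22.0, -12.0, 8.0),))
        head = default_head(24)
        scalp, _, gt = simulate_session(cfg, head)
        avg = to_average_reference(scalp).data
        # project onto the average-referenced gain column of the true source
        from deepesi.forward import dipole_kernel

        g = dipole_kernel(head, gt.source_positions[0]) @ gt.orientations[0]
        g = g - g.mean()
        resid = avg - np.outer(g, (g @ avg) / (g @ g))
        assert np.abs(resid).max() <= 1e-9 * np.abs(avg).max()

    def test_doubling_envelope_scale_doubles_noiseless_scalp(self):
        base = dict(sampling_rate=250.0, duration=4.0, n_sensors=24,
                    sensor_noise_sd=0.0, lfp_noise_sd=0.0, seed=5)
        head = default_head(24)
        s1, _, _ = simulate_session(SimulationConfig(**base, deep_moment=120.0,
                                                     cortical_moment=10.0), head)
        s2, _, _ = simulate_session(SimulationConfig(**base, deep_moment=240.0,
                                                     cortical_moment=20.0), head)
        assert np.allclose(s2.data, 2.0 * s1.data, atol=1e-10)

    def test_intracranial_bipolar_has_alpha_peak(self):
        """Across seeds the deepest bipolar pair shows a clear spectral
        peak at the configured alpha frequency."""
        head = default_head(16)
        for seed in range(10):
            cfg = SimulationConfig(sampling_rate=250.0, duration=60.0,
                                   n_sensors=16, seed=seed)
            _, ic, _ = simulate_session(cfg, head)
            bip = to_bipolar(ic, lead_layout_from_labels(ic.labels))
            band = find_alpha_peak(welch_psd(bip), channels=np.array([0]))
            assert band.peak_found
            assert abs(band.f_peak - cfg.alpha_peak) <= 0.5

    def test_contacts_collinear_along_lead(self, small_session):
        *_, gt = small_session
        for lead in gt.contact_positions:
            d = np.diff(lead, axis=0)
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
            assert np.allclose(d, d[0], atol=1e-9)

    def test_uncoupled_deep_and_cortical_envelopes_uncorrelated(self):
        head = default_head(16)
        rs = []
        for seed in range(12):
            cfg = SimulationConfig(sampling_rate=125.0, duration=240.0,
                                   n_sensors=16, interhemi_rho=0.0,
                                   cortico_deep_rho=0.0, seed=seed)
            _, _, gt = simulate_session(cfg, head)
            deep = gt.source_envelopes[0]
            cort = gt.source_envelopes[gt.meta["n_deep"]]
            rs.append(np.corrcoef(deep, cort)[0, 1])
        assert abs(np.mean(rs)) < 0.08
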