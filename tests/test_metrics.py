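"""Correlation maps, lag curves, distance profiles and localization."""

import numpy as np
import pytest

from deepesi.forward import SourceSpace
from deepesi.imaging import EnvelopeField
from deepesi.metrics import (CorrelationMap, cross_correlation_lags,
                             distance_profile, envelope_correlation_map,
                             localization_report, window_robustness)
from deepesi.simulate import gen_envelope


def _field(env, fs=25.0):
    env = np.atleast_2d(np.asarray(env, dtype=float))
    return EnvelopeField(env=env, fs=fs, band=(8.0, 10.0),
                         valid=np.ones(env.shape[1], dtype=bool),
                         thresholded=True)


def _grid_space(n_side=5, spacing=10.0):
    ax = (np.arange(n_side) - n_side // 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.column_stack(np.unravel_index(np.arange(len(pts)), X.shape))
    return SourceSpace(points=pts, spacing=spacing, grid_index=idx,
                       grid_shape=X.shape, origin=np.full(3, ax[0]))


class TestCorrelationMap:
    def test_identical_series_correlate_perfectly(self):
        ref = gen_envelope(2.0, 40.0, 25.0, seed=1)
        field = _field(np.vstack([ref, ref[::-1]]))
        cmap = envelope_correlation_map(field, ref)
        assert cmap.r[0] == pytest.approx(1.0)

    def test_negative_correlations_zeroed_but_kept_raw(self):
        t = np.linspace(0, 1, 200)
        field = _field(2.0 - t[None, :])
        cmap = envelope_correlation_map(field, t)
        assert cmap.r[0] == 0.0
        assert cmap.r_raw[0] == pytest.approx(-1.0)

    def test_constant_point_series_set_to_zero_and_counted(self):
        ref = gen_envelope(2.0, 40.0, 25.0, seed=2)
        field = _field(np.vstack([np.full(ref.shape, 3.0), ref]))
        cmap = envelope_correlation_map(field, ref)
        assert cmap.r[0] == 0.0 and cmap.n_degenerate == 1

    def test_independent_envelopes_mostly_weakly_correlated(self):
        """Independent seconds-scale envelopes at 300 s: |raw r| < 0.2 at
        95% of points (effective sample size ~ duration / 2 tau)."""
        frac_ok = []
        for seed in range(20):
            env = np.vstack([gen_envelope(2.0, 300.0, 25.0, seed=1000 * seed + k)
                             for k in range(40)])
            ref = gen_envelope(2.0, 300.0, 25.0, seed=999_000 + seed)
            cmap = envelope_correlation_map(_field(env), ref)
            frac_ok.append(np.mean(np.abs(cmap.r_raw) < 0.2))
        assert np.mean(frac_ok) >= 0.95

    def test_affine_rescaling_invariance(self):
        ref = gen_envelope(2.0, 40.0, 25.0, seed=5)
        env = np.vstack([gen_envelope(2.0, 40.0, 25.0, seed=6)])
        c1 = envelope_correlation_map(_field(env), ref)
        c2 = envelope_correlation_map(_field(3.0 * env + 2.0), 0.5 * ref + 1.0)
        assert np.allclose(c1.r_raw, c2.r_raw, atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="time base"):
            envelope_correlation_map(_field(np.ones((2, 10))), np.ones(11))


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero_with_r_one(self):
        a = gen_envelope(2.0, 120.0, 25.0, seed=3)
        lags, r = cross_correlation_lags(a, a, max_lag_s=5.0, fs=25.0)
        assert lags[np.argmax(r)] == 0.0
        assert r.max() == pytest.approx(1.0)

    def test_pure_delay_recovered(self):
        a = gen_envelope(2.0, 120.0, 25.0, seed=4)
        shift = int(1.2 * 25)
        b = np.roll(a, shift)
        lags, r = cross_correlation_lags(a, b, max_lag_s=5.0, fs=25.0)
        assert lags[np.argmax(r)] == pytest.approx(1.2)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlation_lags(np.ones(100), np.arange(100.0),
                                   max_lag_s=0.5, fs=25.0)

    def test_overlong_max_lag_rejected(self):
        a = np.arange(100.0)
        with pytest.raises(ValueError):
            cross_correlation_lags(a, a, max_lag_s=2.0, fs=25.0)


class TestDistanceProfile:
    def test_uniform_map_gives_flat_profile(self):
        src = _grid_space()
        cmap = CorrelationMap(r=np.full(src.n_points, 0.4),
                              r_raw=np.full(src.n_points, 0.4),
                              reference="x", n_samples=100)
        _, mean, _ = distance_profile(cmap, src, np.zeros(3), bin_mm=4.0)
        filled = mean[~np.isnan(mean)]
        assert np.allclose(filled, 0.4)

    def test_peaked_map_decays_beyond_peak_bin(self):
        src = _grid_space(7, 8.0)
        contact = np.zeros(3)
        d = np.linalg.norm(src.points - contact, axis=1)
        r = np.exp(-d / 15.0)
        cmap = CorrelationMap(r=r, r_raw=r, reference="x", n_samples=100)
        centers, mean, sd = distance_profile(cmap, src, contact, bin_mm=4.0)
        ok = ~np.isnan(mean)
        assert np.all(np.diff(mean[ok]) <= sd[ok][:-1] + 1e-12)

    def test_bin_width_and_errors(self):
        src = _grid_space()
        cmap = CorrelationMap(r=np.zeros(src.n_points), r_raw=np.zeros(src.n_points),
                              reference="x", n_samples=10)
        centers, _, _ = distance_profile(cmap, src, np.zeros(3), bin_mm=4.0)
        assert centers[0] == pytest.approx(2.0)  # bins from 0 in 4-mm steps
        with pytest.raises(ValueError):
            distance_profile(cmap, src, np.zeros(3), bin_mm=0.0)
        with pytest.raises(ValueError, match="outside"):
            distance_profile(cmap, src, np.array([500.0, 0, 0]), bin_mm=4.0)


class TestLocalization:
    def _cmap(self, src, r):
        return CorrelationMap(r=r, r_raw=r, reference="x", n_samples=100)

    def test_peak_at_contact_gives_zero_distance(self):
        src = _grid_space()
        r = np.zeros(src.n_points)
        j = int(np.argmin(np.linalg.norm(src.points, axis=1)))
        r[j] = 0.9
        sig = r > 0.5
        rep = localization_report(self._cmap(src, r), sig, src, np.zeros(3))
        assert rep.significant and rep.distance_mm == pytest.approx(0.0)

    def test_single_point_cluster_distance_and_range(self):
        src = _grid_space()
        j = int(np.argmin(np.linalg.norm(src.points - np.array([20.0, 0, 0]),
                                         axis=1)))
        r = np.zeros(src.n_points)
        r[j] = 0.8
        rep = localization_report(self._cmap(src, r), r > 0.5, src, np.zeros(3))
        assert rep.distance_mm == pytest.approx(20.0)
        assert rep.significant_range_mm == (pytest.approx(20.0), pytest.approx(20.0))

    def test_closest_cluster_wins_even_if_weaker(self):
        src = _grid_space(7, 8.0)
        r = np.zeros(src.n_points)
        near = int(np.argmin(np.linalg.norm(src.points - np.array([8.0, 0, 0]), axis=1)))
        far = int(np.argmin(np.linalg.norm(src.points + np.array([24.0, 0, 0]), axis=1)))
        r[near], r[far] = 0.6, 0.9
        rep = localization_report(self._cmap(src, r), r > 0.5, src, np.zeros(3))
        assert rep.distance_mm == pytest.approx(8.0)

    def test_no_significant_points_marked_ns(self):
        src = _grid_space()
        r = np.zeros(src.n_points)
        rep = localization_report(self._cmap(src, r), r > 0.5, src, np.zeros(3))
        assert not rep.significant and rep.distance_mm is None

    def test_translation_invariance(self):
        src = _grid_space()
        r = np.random.default_rng(0).uniform(size=src.n_points)
        sig = r > 0.7
        rep1 = localization_report(self._cmap(src, r), sig, src, np.array([5.0, 5, 5]))
        shifted = SourceSpace(points=src.points + 100.0, spacing=src.spacing,
                              grid_index=src.grid_index, grid_shape=src.grid_shape,
                              origin=src.origin + 100.0)
        rep2 = localization_report(self._cmap(shifted, r), sig, shifted,
                                   np.array([105.0, 105, 105]))
        assert rep1.distance_mm == pytest.approx(rep2.distance_mm)
        assert rep1.significant_range_mm == pytest.approx(rep2.significant_range_mm)


class TestWindowRobustness:
    def test_full_record_window_trivial(self):
        env = np.vstack([gen_envelope(2.0, 120.0, 25.0, seed=s) for s in range(12)])
        field = _field(env)
        ref = env[3] + 0.1 * gen_envelope(2.0, 120.0, 25.0, seed=99)
        rob = window_robustness(field, ref, [120.0])
        per = rob["per_size"][120.0]
        assert per["n_windows"] == 1
        assert per["sd_r"] == pytest.approx(0.0)
        assert per["map_similarity"] == pytest.approx(1.0)

    def test_white_noise_reference_near_zero_correlation(self):
        """A white-noise reference is uncorrelated with envelope fields:
        the map is globally near zero, and even at its (selection-biased)
        maximum the window correlations stay small."""
        rng = np.random.default_rng(8)
        env = np.vstack([gen_envelope(2.0, 240.0, 25.0, seed=s) for s in range(15)])
        field = _field(env)
        ref = rng.normal(size=env.shape[1]) + 10.0
        rob = window_robustness(field, ref, [60.0])
        assert np.median(np.abs(rob["full_map"].r_raw)) < 0.05
        assert abs(rob["per_size"][60.0]["mean_r"]) < 0.3

    def test_window_longer_than_record_rejected(self):
        field = _field(np.ones((3, 100)) + np.random.default_rng(1).uniform(size=(3, 100)))
        with pytest.raises(ValueError, match="exceeds"):
            window_robustness(field, np.random.default_rng(2).uniform(size=100), [10.0])
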