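import numpy as np
import pytest

from tempokit.synth import MovieSynthSpec, WaveSpec, gen_movie_pair
from tempokit.waves import (
    WaveEvent,
    analyze_wave_event,
    delay_map,
    fit_slowness,
    flow_map,
    plane_fit_velocity,
    spacetime_project,
    velocity_distributions,
)


def wave_movie(slowness=(0.02, 0.0), noise=0.0, shape=(300, 32, 32),
               fs=100.0, pitch=0.0625, freq=4.0, seed=0, t0=1.5):
    spec = MovieSynthSpec(shape=shape, fs=fs, pixel_pitch=pitch,
                          waves=(WaveSpec(slowness=slowness, freq=freq,
                                          amplitude=0.01, t0=t0),),
                          noise=noise * 0.01, seed=seed)
    movie, truth = gen_movie_pair(spec)
    return movie.gevi.astype(np.float64) - 1.0, truth, fs, pitch


class TestDelayMap:
    def test_plane_wave_delays_linear(self):
        v, truth, fs, pitch = wave_movie(slowness=(0.02, 0.0))
        dm = delay_map(v, seed=(16, 0), x_min=0.7, max_lag=0.6, fs=fs,
                       pixel_pitch=pitch)
        # delay grows linearly along x with slope = slowness
        cols = np.arange(v.shape[2])
        row_delays = dm.delay[16, :]
        ok = np.isfinite(row_delays)
        slope = np.polyfit(cols[ok] * pitch, row_delays[ok], 1)[0]
        assert slope == pytest.approx(0.02, rel=0.05)

    def test_seed_pixel_self_correlation(self):
        v, _, fs, pitch = wave_movie()
        dm = delay_map(v, seed=(16, 16), x_min=0.5, max_lag=0.3, fs=fs,
                       pixel_pitch=pitch)
        assert dm.peak_corr[16, 16] == pytest.approx(1.0, abs=1e-9)
        assert dm.delay[16, 16] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_wave_delay_field_correlates_with_truth(self):
        # SNR 3 per pixel; 4x4 spatial binning (as done in practice to
        # improve fit quality) before the seed correlation
        v, _, fs, pitch = wave_movie(slowness=(0.015, 0.0), noise=1 / 3)
        vb = v.reshape(300, 8, 4, 8, 4).mean(axis=(2, 4))
        dm = delay_map(vb, seed=(4, 4), window=(110, 190), x_min=0.75,
                       max_lag=0.5, fs=fs, pixel_pitch=pitch * 4)
        rows, cols = np.nonzero(np.isfinite(dm.delay))
        truth_delay = 0.015 * (cols - 4) * pitch * 4
        r = np.corrcoef(dm.delay[rows, cols], truth_delay)[0, 1]
        assert r > 0.95

    def test_zero_variance_seed_raises(self):
        v = np.zeros((50, 8, 8))
        with pytest.raises(ValueError):
            delay_map(v, seed=(4, 4), fs=100.0)


class TestPlaneFit:
    @staticmethod
    def _dmap_from_plane(A, B, h=16, w=16, pitch=1.0):
        from tempokit.waves import DelayMap
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        delay = A * cols * pitch + B * rows * pitch
        return DelayMap(peak_corr=np.ones((h, w)), delay=delay, seed=(0, 0),
                        x_min=0.75, pixel_pitch=pitch)

    def test_pure_x_gradient(self):
        fit = plane_fit_velocity(self._dmap_from_plane(0.02, 0.0))
        vx, vy = fit.velocity_gradient
        assert vx == pytest.approx(50.0, rel=1e-6)
        assert abs(vy) < 1e-6
        assert fit.speed == pytest.approx(50.0, rel=1e-6)

    def test_both_conventions_reported(self):
        fit = plane_fit_velocity(self._dmap_from_plane(0.01, 0.01))
        np.testing.assert_allclose(fit.velocity_reciprocal, (100.0, 100.0), rtol=1e-6)
        assert np.hypot(*fit.velocity_reciprocal) == pytest.approx(141.42, rel=1e-3)
        np.testing.assert_allclose(fit.velocity_gradient, (50.0, 50.0), rtol=1e-6)
        assert np.hypot(*fit.velocity_gradient) == pytest.approx(70.71, rel=1e-3)

    def test_noisy_recovery_within_5pct(self, rng):
        dm = self._dmap_from_plane(0.02, 0.0)
        dm.delay = dm.delay + 0.002 * rng.standard_normal(dm.delay.shape)
        fit = plane_fit_velocity(dm)
        assert fit.speed == pytest.approx(50.0, rel=0.05)

    def test_too_few_pixels_raises(self):
        dm = self._dmap_from_plane(0.02, 0.0)
        dm.delay[:] = np.nan
        dm.delay[0, :5] = 0.1
        with pytest.raises(ValueError):
            plane_fit_velocity(dm)


class TestFlowMap:
    def test_uniform_wave_directions_aligned(self):
        v, _, fs, pitch = wave_movie(slowness=(0.02, 0.0), shape=(300, 32, 32))
        fm = flow_map(v, tile_size=16, fs=fs, pixel_pitch=pitch,
                      x_min=0.6, max_lag=0.6)
        assert len(fm["directions"]) >= 2
        devs = np.abs((fm["directions"] - 0.0 + 180) % 360 - 180)
        assert np.max(devs) < 5.0
        # circular s.d.
        rad = np.deg2rad(fm["directions"])
        R = np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad)))
        circ_sd = np.degrees(np.sqrt(-2 * np.log(max(R, 1e-12))))
        assert circ_sd < 5.0

    def test_opposite_halffield_waves_bimodal(self):
        v1, _, fs, pitch = wave_movie(slowness=(0.02, 0.0), shape=(300, 32, 32))
        v2, _, _, _ = wave_movie(slowness=(-0.02, 0.0), shape=(300, 32, 32))
        combined = np.concatenate([v1[:, :16, :], v2[:, 16:, :]], axis=1)
        fm = flow_map(combined, tile_size=16, fs=fs, pixel_pitch=pitch,
                      x_min=0.6, max_lag=0.6)
        dirs = fm["directions"]
        assert len(dirs) >= 2
        folded = np.abs((dirs + 180) % 360 - 180)
        assert folded.min() < 10.0       # one mode near 0 deg
        assert folded.max() > 170.0      # one mode near 180 deg

    def test_static_movie_no_tiles(self):
        v = np.zeros((100, 32, 32)) + 0.5
        fm = flow_map(v, tile_size=16, fs=100.0, pixel_pitch=0.05)
        assert len(fm["speeds"]) == 0
        assert fm["n_dropped"] > 0


class TestSpacetimeProject:
    def test_separable_movie(self):
        t = np.linspace(0, 1, 50)
        g = np.sin(2 * np.pi * 3 * t)
        fx = np.linspace(1, 2, 12)
        movie = g[:, None, None] * fx[None, None, :] * np.ones((1, 10, 1))
        rp, cp, coords = spacetime_project(movie, pixel_pitch=0.1)
        # both projections reproduce g(t) up to scale
        for proj in (rp, cp):
            r = np.corrcoef(proj[:, 3], g)[0, 1]
            assert r > 0.999999
        assert coords["cols_mm"][-1] == pytest.approx(1.1)

    def test_x_wave_tilted_vs_vertical_crests(self):
        v, _, fs, pitch = wave_movie(slowness=(0.1, 0.0))
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        # crest times along x (columns) spread widely; along y constant
        t_cols = np.argmax(cp, axis=0)
        t_rows = np.argmax(rp, axis=0)
        assert np.ptp(t_cols) > 5 * max(np.ptp(t_rows), 1)

    def test_checkerboard_noise_flat(self, rng):
        movie = rng.standard_normal((100, 16, 16))
        rp, cp, _ = spacetime_project(movie)
        assert np.std(rp) < 0.5 * np.std(movie)


class TestFitSlowness:
    def test_known_slowness_axis_aligned(self):
        v, _, fs, pitch = wave_movie(slowness=(0.02, 0.0))
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        fit = fit_slowness(rp, cp, fs=fs, pixel_pitch=pitch)
        assert fit.speed == pytest.approx(50.0, rel=0.05)
        assert abs(fit.direction) < 5.0

    def test_diagonal_slowness(self):
        v, _, fs, pitch = wave_movie(slowness=(0.02, 0.02))
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        fit = fit_slowness(rp, cp, fs=fs, pixel_pitch=pitch)
        assert fit.speed == pytest.approx(35.36, rel=0.05)
        assert fit.direction == pytest.approx(45.0, abs=5.0)

    def test_degenerate_peaks_alpha_zero(self):
        rp = np.zeros((50, 10))
        rp[25] = 1.0  # all positions peak at the same time bin
        fit = fit_slowness(rp, rp, fs=100.0, pixel_pitch=0.05)
        assert fit.alpha_x == 0.0
        assert fit.p_x == 1.0
        assert fit.speed == np.inf

    def test_too_few_positions_raises(self):
        with pytest.raises(ValueError):
            fit_slowness(np.zeros((50, 4)), np.zeros((50, 4)))

    def test_methods_agree_on_noiseless_wave(self):
        v, _, fs, pitch = wave_movie(slowness=(0.014, 0.014),
                                     shape=(400, 32, 32))
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        st = fit_slowness(rp, cp, fs=fs, pixel_pitch=pitch)
        dm = delay_map(v, seed=(16, 16), x_min=0.6, max_lag=1.0, fs=fs,
                       pixel_pitch=pitch)
        pf = plane_fit_velocity(dm, convention="gradient")
        assert st.speed == pytest.approx(pf.speed, rel=0.02)
        assert abs(st.direction - pf.direction) < 2.0

    def test_rotation_equivariance(self):
        v, _, fs, pitch = wave_movie(slowness=(0.02, 0.0))
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        base = fit_slowness(rp, cp, fs=fs, pixel_pitch=pitch)
        v_rot = np.rot90(v, k=1, axes=(1, 2))
        rp2, cp2, _ = spacetime_project(v_rot, pixel_pitch=pitch)
        rot = fit_slowness(rp2, cp2, fs=fs, pixel_pitch=pitch)
        assert rot.speed == pytest.approx(base.speed, rel=0.02)
        # np.rot90 on (row, col) axes is a -90 deg rotation in the (x, y)
        # convention (image rows point down), so direction moves by 270
        ddir = (rot.direction - base.direction) % 360
        assert ddir == pytest.approx(270.0, abs=2.0)

    @pytest.mark.parametrize("speed,direction", [
        (30.0, 0.0), (100.0, 135.0), (300.0, 270.0)])
    def test_recovery_with_noise(self, speed, direction):
        s = 1.0 / speed
        slow = (s * np.cos(np.deg2rad(direction)),
                s * np.sin(np.deg2rad(direction)))
        v, _, fs, pitch = wave_movie(slowness=slow, noise=0.5,
                                     shape=(300, 64, 64), fs=300.0, t0=0.5)
        rp, cp, _ = spacetime_project(v, pixel_pitch=pitch)
        fit = fit_slowness(rp, cp, fs=fs, pixel_pitch=pitch, smooth_hz=8.0)
        assert fit.speed == pytest.approx(speed, rel=0.05)
        derr = abs((fit.direction - direction + 180) % 360 - 180)
        assert derr < 5.0


class TestVelocityDistributions:
    @staticmethod
    def _event(speed, direction):
        from tempokit.waves import SlownessFit
        s = 1.0 / speed
        return WaveEvent(
            window=(0, 10), method="spacetime_regression",
            fit=SlownessFit(alpha_x=s * np.cos(np.deg2rad(direction)),
                            alpha_y=s * np.sin(np.deg2rad(direction)),
                            se_x=1e-5, se_y=1e-5, p_x=1e-4, p_y=1e-4,
                            n_pixels=64),
            accepted=True)

    def test_identical_events_degenerate(self):
        events = [self._event(50.0, 30.0)] * 5
        out = velocity_distributions(events)
        assert out["median_speed"] == pytest.approx(50.0, rel=1e-6)
        assert (out["speed_hist"][0] > 0).sum() == 1

    def test_two_direction_modes_recovered(self, rng):
        events = ([self._event(50.0, d) for d in rng.normal(0, 3, 40)]
                  + [self._event(50.0, d) for d in rng.normal(90, 3, 40)])
        out = velocity_distributions(events, direction_bins=36)
        dirs = out["directions"]
        near0 = np.abs((dirs + 180) % 360 - 180) < 15
        near90 = np.abs(dirs - 90) < 15
        assert near0.sum() == 40
        assert near90.sum() == 40
        # the two dominant well-separated histogram bins sit on the modes
        hist, edges = out["direction_hist"]
        centers = 0.5 * (edges[:-1] + edges[1:])
        first = int(np.argmax(hist))
        far = np.abs(centers - centers[first]) > 45
        second = int(np.flatnonzero(far)[np.argmax(hist[far])])
        found = sorted([centers[first], centers[second]])
        assert abs(found[0] - 0.0) <= 10
        assert abs(found[1] - 90.0) <= 10

    def test_equal_median_ranksum(self, rng):
        n_pass = 0
        for trial in range(100):
            r = np.random.default_rng(trial)
            sp1 = r.normal(50, 5, 30)
            sp2 = r.normal(50, 5, 30)
            events = [self._event(s, 0.0) for s in sp1] + \
                     [self._event(s, 90.0) for s in sp2]
            masks = (np.arange(60) < 30, np.arange(60) >= 30)
            out = velocity_distributions(events, compare_modes=masks)
            if out["ranksum_p"] > 0.05:
                n_pass += 1
        assert n_pass >= 90

    def test_no_accepted_events_raises(self):
        ev = self._event(50.0, 0.0)
        ev.accepted = False
        with pytest.raises(ValueError):
            velocity_distributions([ev])


class TestHarmonicSeparability:
    def test_harmonic_copropagates_independent_does_not(self):
        # a pure second harmonic of a 5-Hz wave shares its velocity;
        # an independently propagating 10-Hz wave does not
        base = dict(shape=(400, 32, 32), fs=100.0, pixel_pitch=0.0625)
        carrier = WaveSpec(slowness=(0.02, 0.0), freq=5.0, amplitude=0.01,
                           t0=2.0, n_cycles=2.0)
        harmonic = WaveSpec(slowness=(0.02, 0.0), freq=10.0, amplitude=0.004,
                            t0=2.0, n_cycles=2.0)
        indep = WaveSpec(slowness=(0.0, 0.04), freq=10.0, amplitude=0.004,
                         t0=2.0, n_cycles=2.0)
        from tempokit.preprocess import bandpass

        def gamma_velocity(waves):
            spec = MovieSynthSpec(waves=waves, **base)
            movie, _ = gen_movie_pair(spec)
            v = movie.gevi.astype(np.float64) - 1.0
            vg = np.apply_along_axis(bandpass, 0, v, 100.0, 8.0, 12.0)
            rp, cp, _ = spacetime_project(vg, pixel_pitch=0.0625)
            return fit_slowness(rp, cp, fs=100.0, pixel_pitch=0.0625)

        fit_h = gamma_velocity((carrier, harmonic))
        assert fit_h.speed == pytest.approx(50.0, rel=0.10)
        assert abs(fit_h.direction) < 10.0
        fit_i = gamma_velocity((carrier, indep))
        assert fit_i.speed == pytest.approx(25.0, rel=0.10)
        assert abs(abs(fit_i.direction) - 90.0) < 10.0


class TestAnalyzeWaveEvent:
    def test_accepted_event(self):
        v, _, fs, pitch = wave_movie(slowness=(0.02, 0.01))
        ev = analyze_wave_event(v, (0, v.shape[0]), fs, pitch)
        assert ev.accepted
        assert ev.fit.speed == pytest.approx(1.0 / np.hypot(0.02, 0.01),
                                             rel=0.05)

    def test_flat_movie_rejected(self):
        v = np.zeros((100, 16, 16))
        v[50] = 1.0
        ev = analyze_wave_event(v, (0, 100), 100.0, 0.05)
        assert not ev.accepted
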