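import numpy as np
import pytest
from scipy import stats

import difftrans as dt
from difftrans.simulate import SimulationConfig, molecules_for_occupancy


def _cfg(**kw):
    base = dict(
        n_particles=100,
        box_size=(10.0, 10.0),
        diffusion_coefficients=[(1.0, 1.0)],
        frame_interval=0.01,
        n_frames=50,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _cfg(diffusion_coefficients=[(1.0, 0.5), (2.0, 0.4)])

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            _cfg(diffusion_coefficients=[(-1.0, 1.0)])

    def test_nonpositive_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            _cfg(frame_interval=0.0)


class TestBrownianTracks:
    def test_zero_diffusion_tracks_constant(self):
        ts = dt.simulate_brownian_tracks(_cfg(diffusion_coefficients=[(0.0, 1.0)]))
        for _, g in ts.tracks():
            assert g["x_um"].nunique() == 1 and g["y_um"].nunique() == 1

    def test_one_step_msd_matches_4ddt(self):
        """D=0.5, dt=10 ms, no noise: mean squared step = 0.02 um^2 within 3 SE."""
        cfg = _cfg(
            n_particles=1000,
            n_frames=100,
            box_size=(100.0, 100.0),
            diffusion_coefficients=[(0.5, 1.0)],
        )
        d = dt.extract_displacements(dt.simulate_brownian_tracks(cfg), lag=1)
        sq = d.r**2
        assert abs(sq.mean() - 0.02) < 3 * sq.std(ddof=1) / np.sqrt(len(sq))

    def test_mixture_state_fractions(self):
        cfg = _cfg(
            n_particles=4000,
            n_frames=2,
            diffusion_coefficients=[(0.32, 0.76), (4.10, 0.24)],
        )
        ts = dt.simulate_brownian_tracks(cfg)
        frac = (ts.df.groupby("track_id")["state_truth"].first() == 0).mean()
        se = np.sqrt(0.76 * 0.24 / 4000)
        assert abs(frac - 0.76) < 3 * se

    def test_seed_determinism(self):
        a = dt.simulate_brownian_tracks(_cfg(seed=42))
        b = dt.simulate_brownian_tracks(_cfg(seed=42))
        assert a.df.equals(b.df)

    def test_one_step_displacements_rayleigh(self):
        """Steps follow Rayleigh(sqrt(2 D dt + 2 sigma^2)) (KS at alpha=0.01, >=95% of seeds)."""
        scale = np.sqrt(2 * 1.0 * 0.01 + 2 * 0.02**2)
        passed = 0
        for seed in range(100):
            cfg = _cfg(
                n_particles=40,
                n_frames=25,
                box_size=(200.0, 200.0),
                localization_sigma=0.02,
                seed=seed,
            )
            # start away from walls so reflection never distorts steps
            ts = dt.simulate_brownian_tracks(cfg)
            d = dt.extract_displacements(ts, lag=1)
            p = stats.kstest(d.r, stats.rayleigh(scale=scale).cdf).pvalue
            passed += p > 0.01
        assert passed >= 95


class TestSwitchingTracks:
    def test_symmetric_rates_half_occupancy(self):
        cfg = _cfg(
            n_particles=300,
            n_frames=200,
            diffusion_coefficients=[(0.1, 0.5), (2.0, 0.5)],
            switching_rates=(5.0, 5.0),
        )
        ts = dt.simulate_switching_tracks(cfg)
        frac = (ts.df["state_truth"] == 0).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_stationary_fraction_three_to_one(self):
        """k_f->s = 3, k_s->f = 1: slow occupancy 0.75 over >=1e5 particle-frames."""
        cfg = _cfg(
            n_particles=600,
            n_frames=200,
            diffusion_coefficients=[(0.1, 0.5), (2.0, 0.5)],
            switching_rates=(1.0, 3.0),
        )
        ts = dt.simulate_switching_tracks(cfg)
        assert len(ts.df) >= 1e5
        frac = (ts.df["state_truth"] == 0).mean()
        assert abs(frac - 0.75) < 0.02

    def test_zero_rates_reduce_to_static_mixture(self):
        cfg = _cfg(
            diffusion_coefficients=[(0.1, 0.3), (2.0, 0.7)],
            switching_rates=(0.0, 0.0),
        )
        a = dt.simulate_switching_tracks(cfg)
        b = dt.simulate_brownian_tracks(cfg)
        assert a.df.equals(b.df)

    def test_missing_rates_rejected(self):
        with pytest.raises(ValueError):
            dt.simulate_switching_tracks(
                _cfg(diffusion_coefficients=[(0.1, 0.5), (2.0, 0.5)])
            )


class TestCotrackedPairs:
    def test_perfect_tether_identical_positions(self):
        cfg = _cfg(
            n_particles=20, bound_fraction_two_color=1.0, tether_sigma=0.0
        )
        a, b = dt.simulate_cotracked_pairs(cfg)
        pa = a.df.sort_values(["track_id", "frame"])
        partner = b.df.groupby("track_id")["partner_id"].first()
        for tb, g in b.df.groupby("track_id"):
            ga = pa[pa.track_id == partner[tb]]
            assert np.allclose(
                g.sort_values("frame")[["x_um", "y_um"]].to_numpy(),
                ga[["x_um", "y_um"]].to_numpy(),
            )

    def test_bound_count_exact(self):
        cfg = _cfg(n_particles=100, bound_fraction_two_color=0.3, tether_sigma=0.05)
        _, b = dt.simulate_cotracked_pairs(cfg)
        n_bound = (b.df.groupby("track_id")["state_truth"].first() == 1).sum()
        assert n_bound == 30

    def test_unbound_channels_independent(self):
        """f=0: nearest-neighbor A-B distances match the CSR expectation."""
        cfg = _cfg(
            n_particles=120,
            box_size=(30.0, 30.0),
            n_frames=10,
            bound_fraction_two_color=0.0,
        )
        a, b = dt.simulate_cotracked_pairs(cfg)
        rec = dt.frame_matched_distances(a, b)
        nn = rec.groupby(["frame", "track_a"])["distance_um"].min()
        lam = 120 / 900.0  # B-track density
        expected = 0.5 / np.sqrt(lam)  # CSR mean NN distance
        assert abs(nn.mean() - expected) / expected < 0.15

    def test_negative_tether_rejected(self):
        with pytest.raises(ValueError):
            _cfg(bound_fraction_two_color=0.5, tether_sigma=-0.1)


class TestPhotonTraces:
    CFG3 = dict(
        box_size=(2.6, 2.6, 4.4),
        bin_width=1e-5,
        n_frames=50_000,
        focal_waist=0.26,
        axial_ratio=5.0,
    )

    def test_no_molecules_pure_background(self):
        cfg = _cfg(n_particles=1, brightness=0.0, background=2e4, **self.CFG3)
        tr = dt.simulate_photon_traces(cfg)
        mean = tr.counts.mean()
        se = tr.counts.std(ddof=1) / np.sqrt(len(tr.counts))
        assert abs(mean - 0.2) < 3 * se

    def test_mean_rate_matches_expected(self):
        # fast species + many molecules: occupancy noise on the trace mean
        # stays at the few-percent level over 1 s
        cfg = _cfg(
            n_particles=300,
            brightness=1e5,
            background=1e3,
            diffusion_coefficients=[(50.0, 1.0)],
            box_size=(2.6, 2.6, 4.4),
            bin_width=1e-5,
            n_frames=100_000,
        )
        tr = dt.simulate_photon_traces(cfg)
        w, kappa = 0.26, 5.0
        mean_w = (np.pi / 2) ** 1.5 * w**3 * kappa / (2.6 * 2.6 * 4.4)
        expected = 1e5 * 300 * mean_w + 1e3
        assert abs(tr.mean_rate - expected) / expected < 0.10

    def test_seed_determinism_bit_identical(self):
        cfg = _cfg(n_particles=30, brightness=1e5, seed=11, **self.CFG3)
        t1 = dt.simulate_photon_traces(cfg)
        t2 = dt.simulate_photon_traces(cfg)
        assert np.array_equal(t1.counts, t2.counts)

    def test_first_lag_amplitude_tracks_occupancy(self):
        """G(first lag) ~ 1/<N> for a dilute species."""
        cfg = _cfg(
            n_particles=1,
            brightness=2e5,
            background=0.0,
            diffusion_coefficients=[(2.0, 1.0)],
            box_size=(2.6, 2.6, 4.4),
            bin_width=1e-5,
            n_frames=500_000,
            seed=21,
        )
        cfg.n_particles = molecules_for_occupancy(2.0, cfg)
        rng = np.random.default_rng(21)
        curves = [
            dt.multitau_correlate(dt.simulate_photon_traces(cfg, rng=rng))
            for _ in range(4)
        ]
        avg = dt.average_curves(curves)
        n_eff = cfg.n_particles * dt.FocalVolume(0.26, 5.0).effective_volume_um3 / (
            2.6 * 2.6 * 4.4
        )
        assert abs(avg.G[0] - 1 / n_eff) / (1 / n_eff) < 0.20

    def test_independent_channels_cross_consistent_with_zero(self):
        cfg = _cfg(
            n_particles=60,
            brightness=1e5,
            background=0.0,
            bound_fraction_two_color=0.0,
            diffusion_coefficients=[(2.0, 1.0)],
            **self.CFG3,
        )
        ta, tb = dt.simulate_photon_traces(cfg)
        c = dt.multitau_correlate(ta, tb)
        # first-lag z-score only: neighboring multi-tau lags are correlated
        assert abs(c.G[0] / c.sem[0]) < 4.0

    def test_triplet_stationary_dark_fraction(self):
        """The telegraph chain holds the configured dark fraction at any bin width."""
        from difftrans.simulate import _telegraph_dark

        rng = np.random.default_rng(3)
        for lifetime in (5e-6, 2e-4):
            cfg = _cfg(
                triplet_fraction=0.3, triplet_lifetime=lifetime, **self.CFG3
            )
            dark = _telegraph_dark(40_000, 30, cfg, rng)
            assert abs(dark.mean() - 0.3) < 0.02

    def test_triplet_blinking_reduces_mean_rate(self):
        kw = dict(
            n_particles=300,
            brightness=1e5,
            background=0.0,
            diffusion_coefficients=[(50.0, 1.0)],
            box_size=(2.6, 2.6, 4.4),
            bin_width=1e-5,
            n_frames=100_000,
        )
        r0 = dt.simulate_photon_traces(_cfg(**kw)).mean_rate
        r1 = dt.simulate_photon_traces(
            _cfg(triplet_fraction=0.3, triplet_lifetime=5e-6, **kw)
        ).mean_rate
        assert r1 < r0
        assert abs(r1 / r0 - 0.7) < 0.1

    def test_coarse_bin_width_warns(self):
        cfg = _cfg(
            n_particles=5,
            diffusion_coefficients=[(100.0, 1.0)],
            box_size=(2.6, 2.6, 4.4),
            bin_width=1e-3,
            n_frames=2000,
        )
        with pytest.warns(UserWarning):
            dt.simulate_photon_traces(cfg)


class TestBeadField:
    def test_identity_noiseless(self):
        t = dt.AffineTransform2D.identity()
        p1, p2 = dt.simulate_bead_field(10, t, noise_sigma=0.0, seed=1)
        assert np.allclose(p1, p2)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            dt.simulate_bead_field(2, dt.AffineTransform2D.identity())

    def test_known_transform_recovered(self):
        th = np.deg2rad(5.0)
        t = dt.AffineTransform2D(
            np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]),
            np.array([3.2, -1.7]),
        )
        p1, p2 = dt.simulate_bead_field(40, t, noise_sigma=0.0, seed=2)
        fit = dt.fit_affine(p1, p2)
        assert np.max(np.abs(fit.matrix - t.matrix)) < 1e-9
        assert np.max(np.abs(fit.offset - t.offset)) < 1e-9

    def test_noise_propagates_to_residual(self):
        t = dt.AffineTransform2D.identity()
        p1, p2 = dt.simulate_bead_field(100, t, noise_sigma=0.1, seed=3)
        fit = dt.fit_affine(p1, p2)
        assert abs(fit.rms_residual - 0.1 * np.sqrt(2)) / (0.1 * np.sqrt(2)) < 0.20
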