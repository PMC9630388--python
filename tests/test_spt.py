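import numpy as np
import pandas as pd
import pytest

import difftrans as dt
from difftrans.spt import (
    DisplacementSet,
    TrajectorySet,
    diffusion_map,
    exploration_area,
    extract_displacements,
    fit_cdf_global,
    fit_cdf_two_component,
    link_detections,
    msd_curve,
)


def _track_df(points, tid=0):
    return pd.DataFrame(
        {
            "track_id": tid,
            "frame": np.arange(len(points)),
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
        }
    )


class TestLinking:
    def test_single_particle_full_track(self):
        det = _track_df([(0.0, 0.0), (0.05, 0.0), (0.1, 0.02)])[
            ["frame", "x_um", "y_um"]
        ]
        ts = link_detections(det, max_link_distance=0.2)
        assert ts.n_tracks == 1
        assert len(ts.df) == 3

    def test_distant_particles_stay_separate(self):
        rows = []
        for f in range(5):
            rows.append((f, 0.0, 0.0))
            rows.append((f, 5.0, 5.0))
        det = pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])
        ts = link_detections(det, max_link_distance=1.0)
        assert ts.n_tracks == 2

    def test_linking_accuracy_on_sparse_field(self):
        """At NN spacing >> step size, >=95% of links match ground truth."""
        cfg = dt.SimulationConfig(
            n_particles=50,
            box_size=(30.0, 30.0),
            diffusion_coefficients=[(0.5, 1.0)],
            frame_interval=0.01,
            n_frames=20,
            seed=3,
        )
        truth = dt.simulate_brownian_tracks(cfg)
        det = truth.df[["frame", "x_um", "y_um"]].copy()
        linked = link_detections(det, max_link_distance=0.5, frame_interval=0.01)
        # map recovered links back to true identity through positions
        merged = linked.df.merge(
            truth.df, on=["frame", "x_um", "y_um"], suffixes=("_l", "_t")
        )
        correct = 0
        total = 0
        for _, g in merged.groupby("track_id_l"):
            ids = g.sort_values("frame")["track_id_t"].to_numpy()
            total += len(ids) - 1
            correct += int(np.sum(ids[1:] == ids[:-1]))
        assert total > 0
        assert correct / total >= 0.95


class TestDisplacements:
    def test_static_track(self):
        ts = TrajectorySet(_track_df([(1.0, 1.0)] * 5), 0.01)
        d = extract_displacements(ts)
        assert np.allclose(d.r, 0.0)

    def test_three_four_five(self):
        ts = TrajectorySet(_track_df([(0.0, 0.0), (3.0, 4.0)]), 0.01)
        d = extract_displacements(ts)
        assert len(d) == 1 and np.isclose(d.r[0], 5.0)

    def test_msd_matches_4dt(self):
        cfg = dt.SimulationConfig(
            n_particles=500,
            box_size=(50.0, 50.0),
            diffusion_coefficients=[(1.0, 1.0)],
            frame_interval=0.01,
            n_frames=20,
            seed=5,
        )
        d = extract_displacements(dt.simulate_brownian_tracks(cfg))
        msd = np.mean(d.r**2)
        se = np.std(d.r**2, ddof=1) / np.sqrt(len(d))
        assert abs(msd - 0.04) < 3 * se

    def test_gap_pairs_skipped(self):
        df = _track_df([(0, 0), (1, 0), (2, 0)])
        df = df[df.frame != 1]
        d = extract_displacements(TrajectorySet(df, 0.01), lag=1)
        assert len(d) == 0


class TestCDFFit:
    @staticmethod
    def _mixture_displacements(rng, n, a_slow, d1, d2, t):
        slow = rng.random(n) < a_slow
        d = np.where(slow, d1, d2)
        return DisplacementSet(np.sqrt(rng.exponential(4 * d * t)), t)

    def test_single_population_degenerate(self, rng):
        d = DisplacementSet(np.sqrt(rng.exponential(4 * 0.5 * 0.01, 5000)), 0.01)
        fit = fit_cdf_two_component(d)
        # either a degenerate pair near the truth or one dominant component
        dom = fit.d_slow if fit.a_slow > 0.5 else fit.d_fast
        weight = max(fit.a_slow, 1 - fit.a_slow)
        eff = fit.a_slow * fit.d_slow + (1 - fit.a_slow) * fit.d_fast
        assert abs(eff - 0.5) / 0.5 < 0.05 or (
            weight > 0.9 and abs(dom - 0.5) / 0.5 < 0.05
        )

    def test_cdf_limits(self, rng):
        d = self._mixture_displacements(rng, 3000, 0.7, 0.3, 4.0, 0.005)
        fit = fit_cdf_two_component(d)
        assert fit.predict(np.array([0.0]))[0] == 0.0
        assert fit.predict(np.array([50.0]))[0] == pytest.approx(1.0)

    def test_invariant_to_order_and_duplication(self, rng):
        d = self._mixture_displacements(rng, 2000, 0.6, 0.2, 3.0, 0.005)
        f1 = fit_cdf_two_component(d)
        shuffled = DisplacementSet(d.r[::-1].copy(), d.lag_time)
        f2 = fit_cdf_two_component(shuffled)
        doubled = DisplacementSet(np.concatenate([d.r, d.r]), d.lag_time)
        f3 = fit_cdf_two_component(doubled)
        for other in (f2, f3):
            assert np.isclose(f1.a_slow, other.a_slow, atol=1e-8)
            assert np.isclose(f1.d_slow, other.d_slow, rtol=1e-6)

    def test_global_fit_matches_single_on_identical_data(self, rng):
        d = self._mixture_displacements(rng, 4000, 0.7, 0.3, 4.0, 0.005)
        single = fit_cdf_two_component(d)
        g1, g2 = fit_cdf_global([d, DisplacementSet(d.r.copy(), d.lag_time)])
        assert np.isclose(g1.a_slow, single.a_slow, atol=5e-3)
        assert np.isclose(g1.d_slow, single.d_slow, rtol=5e-2)
        assert np.isclose(g1.a_slow, g2.a_slow, atol=1e-8)

    def test_shared_fit_residual_nesting(self, rng):
        """Constraining shared D's cannot beat the free per-dataset fits."""
        da = self._mixture_displacements(rng, 3000, 0.8, 0.2, 3.0, 0.005)
        db = self._mixture_displacements(rng, 3000, 0.4, 0.35, 5.0, 0.005)
        from difftrans.spt import _ecdf, _mixture_cdf

        def sse(fit, d):
            x, f = _ecdf(d.r)
            return np.sum(
                (_mixture_cdf(x, fit.a_slow, fit.d_slow, fit.d_fast, fit.lag_time) - f)
                ** 2
            )

        free = sse(fit_cdf_two_component(da), da) + sse(fit_cdf_two_component(db), db)
        ga, gb = fit_cdf_global([da, db])
        shared = sse(ga, da) + sse(gb, db)
        assert shared >= free - 1e-9

    def test_incompatible_frame_times_rejected(self, rng):
        da = self._mixture_displacements(rng, 500, 0.5, 0.3, 3.0, 0.005)
        db = self._mixture_displacements(rng, 500, 0.5, 0.3, 3.0, 0.010)
        with pytest.raises(ValueError):
            fit_cdf_global([da, db])


class TestDiffusionMap:
    def test_homogeneous_field(self):
        cfg = dt.SimulationConfig(
            n_particles=200,
            box_size=(2.0, 2.0),
            diffusion_coefficients=[(0.5, 1.0)],
            frame_interval=0.01,
            n_frames=50,
            seed=9,
        )
        ts = dt.simulate_brownian_tracks(cfg)
        m = diffusion_map(ts, timescale=0.01)
        vals = m.values[np.isfinite(m.values)]
        assert abs(np.mean(vals) - 0.5) / 0.5 < 0.10

    def test_immobile_particles_zero(self):
        df = pd.concat(
            [_track_df([(x, y)] * 10, tid=i) for i, (x, y) in enumerate([(0, 0), (0.5, 0.5)])],
            ignore_index=True,
        )
        m = diffusion_map(TrajectorySet(df, 0.01), timescale=0.01, min_count=1)
        vals = m.values[np.isfinite(m.values)]
        assert np.allclose(vals, 0.0)

    def test_infinite_radius_equals_global_estimate(self):
        cfg = dt.SimulationConfig(
            n_particles=30,
            box_size=(2.0, 2.0),
            diffusion_coefficients=[(0.3, 1.0)],
            frame_interval=0.01,
            n_frames=20,
            seed=4,
        )
        ts = dt.simulate_brownian_tracks(cfg)
        m = diffusion_map(ts, spacing=10.0, radius=1e9, timescale=0.01, min_count=1)
        d = extract_displacements(ts, lag=1)
        expected = np.mean(d.r**2) / (4 * 0.01)
        vals = m.values[np.isfinite(m.values)]
        assert np.allclose(vals, expected, rtol=1e-12)

    def test_undefined_nodes_are_nan_not_zero(self):
        df = _track_df([(0.0, 0.0), (0.01, 0.0)] * 3)
        m = diffusion_map(TrajectorySet(df, 0.01), timescale=0.01, min_count=10**6)
        assert np.all(np.isnan(m.values))

    def test_non_multiple_timescale_rejected(self):
        df = _track_df([(0, 0), (0.1, 0)])
        with pytest.raises(ValueError):
            diffusion_map(TrajectorySet(df, 0.01), timescale=0.015)


class TestPerTrackDiffusion:
    def test_two_population_histogram_bimodal(self):
        """Per-track apparent D from a two-population field clusters around
        both ground-truth coefficients (modes within 20%, no noise)."""
        cfg = dt.SimulationConfig(
            n_particles=1500,
            box_size=(30.0, 30.0),
            diffusion_coefficients=[(0.32, 0.5), (4.10, 0.5)],
            frame_interval=0.005,
            n_frames=20,
            seed=13,
        )
        ts = dt.simulate_brownian_tracks(cfg)
        d_est = []
        for _, g in ts.tracks():
            steps = np.diff(g[["x_um", "y_um"]].to_numpy(), axis=0)
            d_est.append((steps**2).sum(axis=1).mean() / (4 * 0.005))
        d_est = np.asarray(d_est)
        split = np.sqrt(0.32 * 4.10)
        mode_slow = np.median(d_est[d_est < split])
        mode_fast = np.median(d_est[d_est >= split])
        assert abs(mode_slow - 0.32) / 0.32 < 0.20
        assert abs(mode_fast - 4.10) / 4.10 < 0.20


class TestMSD:
    def test_brownian_slope(self):
        cfg = dt.SimulationConfig(
            n_particles=400,
            box_size=(60.0, 60.0),
            diffusion_coefficients=[(1.0, 1.0)],
            frame_interval=0.01,
            n_frames=30,
            seed=6,
        )
        msd = msd_curve(dt.simulate_brownian_tracks(cfg), max_lag=8)
        slope = np.polyfit(msd.lag_s, msd.msd_um2, 1)[0]
        assert abs(slope - 4.0) < 0.15

    def test_static_zero(self):
        msd = msd_curve(TrajectorySet(_track_df([(1, 2)] * 12), 0.01), max_lag=6)
        assert np.allclose(msd.msd_um2, 0.0)
        area = exploration_area(msd)
        assert area.area_um2 == 0.0 and not area.no_plateau

    def test_confined_plateau(self):
        """Reflective box of side L: MSD plateaus near L^2/3 (order-1 coefficient)."""
        L = 0.5
        cfg = dt.SimulationConfig(
            n_particles=150,
            box_size=(L, L),
            diffusion_coefficients=[(1.0, 1.0)],
            frame_interval=0.01,
            n_frames=120,
            seed=8,
        )
        msd = msd_curve(dt.simulate_brownian_tracks(cfg), max_lag=40)
        area = exploration_area(msd)
        assert not area.no_plateau
        assert abs(area.area_um2 - L**2 / 3) / (L**2 / 3) < 0.25

    def test_free_brownian_flagged_no_plateau(self):
        cfg = dt.SimulationConfig(
            n_particles=200,
            box_size=(80.0, 80.0),
            diffusion_coefficients=[(1.0, 1.0)],
            frame_interval=0.01,
            n_frames=40,
            seed=2,
        )
        area = exploration_area(msd_curve(dt.simulate_brownian_tracks(cfg), max_lag=12))
        assert area.no_plateau
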