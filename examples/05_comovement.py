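"""Two-color co-movement: find B-channel tracks tethered to A-channel tracks.

30% of channel-B molecules ride along channel-A tracks (50 nm tether);
pairs dwelling within 320 nm of each other for at least 10 ms are called
co-moving, and the annulus-normalized distance density shows the short-
distance enrichment.
"""

import difftrans as dt

cfg = dt.SimulationConfig(
    n_particles=100,
    box_size=(100.0, 100.0),
    diffusion_coefficients=[(1.0, 1.0)],
    frame_interval=0.01,
    n_frames=50,
    localization_sigma=0.02,
    bound_fraction_two_color=0.3,
    tether_sigma=0.05,
    seed=4,
)
chan_a, chan_b = dt.simulate_cotracked_pairs(cfg)

result = dt.detect_comoving(chan_a, chan_b, max_distance=0.32, min_dwell=0.010)
called = set(zip(result.pairs.track_a, result.pairs.track_b))
truth = chan_b.df.groupby("track_id").first()
bound = truth[truth.state_truth == 1]
hits = sum((int(bound.loc[t, "partner_id"]), t) in called for t in bound.index)
print(f"called pairs : {len(called)}")
print(f"recall       : {hits}/{len(bound)} bound tracks recovered")

records = dt.frame_matched_distances(chan_a, chan_b)
density = dt.distance_density(
    records[records.distance_um < 3.0], bin_width=0.05, r_max=3.0, baseline_beyond=0.64
)
print(f"density in first bin  : {density.density[0]:.1f} x baseline")
# A flat density at 1 means chance proximity only; the short-distance peak
# is the co-moving (bound) population.
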