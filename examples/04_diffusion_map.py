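"""Local diffusion heat map over a field with two mobility regions.

Slow molecules (0.05 μm²/s) occupy the left half, fast ones (1.0 μm²/s)
the right; apparent D is mapped on a 20 nm grid by pooling displacements
originating within 80 nm of each node.
"""

import pandas as pd

import difftrans as dt

frames = []
for i, (d, x_offset) in enumerate([(0.05, 0.0), (1.0, 2.0)]):
    cfg = dt.SimulationConfig(
        n_particles=150,
        box_size=(2.0, 2.0),
        diffusion_coefficients=[(d, 1.0)],
        frame_interval=0.01,
        n_frames=60,
        seed=20 + i,
    )
    df = dt.simulate_brownian_tracks(cfg).df
    df["x_um"] += x_offset
    df["track_id"] += i * 1_000_000
    frames.append(df)

tracks = dt.TrajectorySet(pd.concat(frames, ignore_index=True), 0.01)
heat = dt.diffusion_map(tracks, spacing=0.020, radius=0.080, timescale=0.010)

grid = heat.to_frame().dropna()
left = grid[grid.x_um < 1.9]["d_app_um2_s"].median()
right = grid[grid.x_um > 2.1]["d_app_um2_s"].median()
print(f"defined nodes        : {len(grid)}")
print(f"left-region median D : {left:.3f} μm²/s (truth 0.05)")
print(f"right-region median D: {right:.3f} μm²/s (truth 1.0)")
# Spatial contrast in apparent D marks where molecules are bound or
# confined — translation 'hot spots' in the original setting.
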