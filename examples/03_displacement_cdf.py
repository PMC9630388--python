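"""Two-component fit of single-particle displacement distributions.

A 76%/24% mixture of slow (mRNA-bound-like, 0.32 μm²/s) and fast
(4.10 μm²/s) molecules is tracked at 200 Hz; the cumulative distribution of
one-step displacements is fit with the two-component Brownian mixture, and
a second condition (48% slow) is fit jointly with shared coefficients.
"""

import difftrans as dt


def displacements(a_slow, seed):
    cfg = dt.SimulationConfig(
        n_particles=2000,
        box_size=(15.0, 15.0),
        diffusion_coefficients=[(0.32, a_slow), (4.10, 1 - a_slow)],
        frame_interval=0.005,
        n_frames=11,
        seed=seed,
    )
    return dt.extract_displacements(dt.simulate_brownian_tracks(cfg), lag=1)


control = displacements(0.76, seed=1)
treated = displacements(0.48, seed=2)

single = dt.fit_cdf_two_component(control)
print(f"control fit : A_slow={single.a_slow:.3f}  "
      f"D_slow={single.d_slow:.3f}  D_fast={single.d_fast:.2f} μm²/s")

g_control, g_treated = dt.fit_cdf_global([control, treated])
print(f"global fit  : D_slow={g_control.d_slow:.3f}  D_fast={g_control.d_fast:.2f} μm²/s")
print(f"slow fraction: control {g_control.a_slow:.2f} (truth 0.76), "
      f"treated {g_treated.a_slow:.2f} (truth 0.48)")
# The drop in the slow fraction between conditions mirrors the loss of
# mRNA-bound molecules when initiation is inhibited.
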