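"""Fit the FCS diffusion model to a simulated single-species measurement.

A free protein (D = 15 μm²/s, like unbound eIF4E) diffuses through a
confocal volume (w = 0.26 μm, κ = 5); two 10 s photon traces are recorded,
multi-tau correlated, averaged, and fit with the one-component model.
"""

import numpy as np

import difftrans as dt

D_TRUE = 15.0  # μm²/s
cfg = dt.SimulationConfig(
    n_particles=1,
    box_size=(2.6, 2.6, 4.4),
    diffusion_coefficients=[(D_TRUE, 1.0)],
    bin_width=1e-5,
    n_frames=1_000_000,  # 10 s
    focal_waist=0.26,
    axial_ratio=5.0,
    brightness=1e5,
    background=1e3,
    seed=7,
)
cfg.n_particles = dt.molecules_for_occupancy(1.5, cfg)

rng = np.random.default_rng(cfg.seed)
curves = [
    dt.multitau_correlate(dt.simulate_photon_traces(cfg, rng=rng), n_levels=15)
    for _ in range(2)
]
avg = dt.average_curves(curves)
fit = dt.fit_fcs(avg, "one", fix={"T": 0.0})

volume = dt.FocalVolume(0.26, 5.0)
tau_ms = fit.params["tau1"] * 1e3
d_fit = dt.diffusion_time_to_coefficient(fit.params["tau1"], volume)
conc_nm = dt.estimate_concentration(fit.G0, fit.params["T"], volume) * 1e9

print(f"fitted diffusion time : {tau_ms:.3f} ms  (truth {0.26**2/4/D_TRUE*1e3:.3f} ms)")
print(f"diffusion coefficient : {d_fit:.2f} μm²/s (truth {D_TRUE})")
print(f"amplitude G0          : {fit.G0:.3f}  ->  apparent concentration {conc_nm:.0f} nM")
# The diffusion time is the mean dwell of one molecule in the focal spot;
# 1/G0 estimates the mean number of molecules occupying it.
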