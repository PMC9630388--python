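# difftrans

Binding of a small, fast protein to a large, slow partner — an initiation
factor such as eIF4E settling onto an mRNA — changes its diffusion by two
to three orders of magnitude.  `difftrans` turns that shift into a
quantitative read-out of binding in living cells.  It implements the two
complementary single-molecule measurements used for this purpose, plus the
synthetic data needed to validate them end to end:

* **FCS / FCCS** — multi-tau and brute-force correlators for binned photon
  traces; one- and two-component fits of the triplet-diffusion model

      G(τ) = G0·[1 − T + T e^(−τ/Tt)]·(1 + τ/τ_D)^(−1)·(1 + τ/(τ_D κ²))^(−1/2)

  with κ = 5 by default; conversions τ_D ↔ D via D = w²/(4τ_D);
  apparent concentrations from ⟨N⟩ = (1 − T)/G0; and dual-color
  cross-correlation bound fractions G0_cross/G0_auto.
* **Single-particle tracking** — two-component displacement-CDF fits
  f(x) = 1 − [A e^(−x²/4D₁t) + (1 − A) e^(−x²/4D₂t)] (single and global
  shared-D), local diffusion heat maps on a 20 nm grid (80 nm pooling
  radius), MSD curves and confinement (exploration-area) estimates.
* **Two-color co-movement** — calling track pairs that dwell within 320 nm
  of each other for ≥ 10 ms, and annulus-normalized distance densities.
* **Channel registration** — Gaussian-mask sub-pixel spot localization,
  mutual-nearest-neighbor bead matching, affine least squares, and
  nearest-neighbor image resampling that preserves the noise distribution.
* **Synthetic data** — Brownian/two-state/tethered trajectory fields and
  confocal photon traces (3D-Gaussian detection volume, Poisson counting,
  triplet blinking) with exact ground truth and bit-reproducible seeding.

It is aimed at microscopists and analysts who have correlation curves or
trajectory tables and want transparent, testable fits instead of vendor
black boxes.

## A worked example

`examples/01_fcs_single_species.py` simulates a free protein
(D = 15 μm²/s) crossing a confocal volume, records two 10 s photon traces,
averages their multi-tau correlations and fits the one-component model:

```
fitted diffusion time : 1.087 ms  (truth 1.127 ms)
diffusion coefficient : 15.54 μm²/s (truth 15.0)
amplitude G0          : 0.634  ->  apparent concentration 5 nM
```

The diffusion time is the mean dwell of one molecule in the focal spot,
the coefficient follows from the calibrated 0.26 μm waist, and 1/G0 is the
mean focal-volume occupancy, here ~1.6 molecules in 0.49 fL ≈ 5 nM.

The other scripts in `examples/` walk through FCCS binding fractions,
displacement-CDF mixtures and global fits, diffusion heat maps,
co-movement calling, and bead-field registration, each printing the
recovered numbers next to the ground truth it simulated.

There is also a thin CLI for shell use
(`difftrans correlate|fcs-fit|spt|comove|register|run`), including seeded
end-to-end workflows from YAML configs (`difftrans run workflow.yaml
--kind fcs --out rundir`).

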