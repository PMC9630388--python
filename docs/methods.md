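# Methods

`difftrans` detects molecular binding in living cells through the shift in
diffusion it causes: a small protein diffusing freely at ~15 μm²/s slows by
two to three orders of magnitude when it rides on an mRNA.  The package
implements the two complementary read-outs of that shift — fluorescence
correlation spectroscopy (FCS/FCCS) and single-particle tracking (SPT) —
together with a synthetic-data generator that provides ground truth for
every stage.

## Correlation analysis

A photon trace binned at width Δ is correlated as

    G(τ) = ⟨δI_a(t) δI_b(t+τ)⟩ / (⟨I_a⟩⟨I_b⟩),   δI = I − ⟨I⟩.

`direct_correlate` evaluates this definition at explicit integer lags
(the O(N²) oracle); `multitau_correlate` uses the multi-tau scheme — 16
lags per level, pairwise rebinning by 2 per level — to span seven decades
of lag.  Both use *symmetric normalization*: the means in the denominator
are computed over the same valid-t windows as the numerator, which
suppresses drift bias.  The value at level ℓ is, by construction, the
correlation of the 2^ℓ-rebinned trace; oracle-equivalence checks therefore
compare each level against the direct estimator on identically rebinned
traces.  Per-lag standard errors come from ten-block averaging of the
lagged products; they feed inverse-variance weights in the fits.
Optionally both correlators accept externally supplied normalization means
(e.g. pooled over repeated measurements), which removes the finite-trace
normalization bias; the default remains window-local.

## FCS model fits

The confocal detection profile is a 3D Gaussian with lateral 1/e² waist
`w` and axial elongation κ (fixed to 5 by default).  One species with
diffusion time τ_D gives

    G(τ) = G0 · [1 − T + T e^(−τ/Tt)] · (1 + τ/τ_D)^(−1) (1 + τ/(τ_D κ²))^(−1/2),

with triplet fraction T and lifetime Tt; the two-component variant mixes
two diffusion times with fraction A.  Two additions to the bare model are
deliberate:

* a free multiplicative amplitude `G0` — measured curves are not
  pre-normalized, and for an ideal dilute measurement G0 = 1/⟨N⟩;
* a free additive baseline (`fit_offset=True`) — correlation estimates
  from finite traces sit below the true curve by a nearly constant offset
  of order 2∫G dτ / T_trace (the normalization means are correlated with
  the signal), and closed-box simulations with a fixed molecule count add
  an exactly constant −1/N term.  A free baseline absorbs both.

Fits are weighted least squares (lmfit/Levenberg–Marquardt) with 1/sem
weights where available.  Initialization: τ from the half-amplitude lag,
A = 0.5, T = 0.1, Tt = 5 μs.  Tt is bounded above by 100 μs so the
triplet term cannot exchange with slow diffusion.  Two-component fits
parameterize τ₂ = τ₁·ratio with ratio ≥ 1, enforcing the ordering, and are
flagged `poorly_separated` below ratio 3.  `compare_models` reproduces the
one- vs two-component adequacy argument: the one-component fit's smoothed
residuals are compared against three robust SDs of the two-component
residuals (`residual_excess` > 1 means a second component is required).

Derived quantities: `calibrate_waist` (w = √(4Dτ)) pins the focal waist to
a known (τ, D) pair — the package default w = 0.26 μm comes from the fast
cap-binding-factor component (1.14 ms, 14.78 μm²/s); 
`diffusion_time_to_coefficient` inverts it (D = w²/4τ); concentrations use
⟨N⟩ = (1−T)/G0 over V_eff = π^{3/2} w³ κ.  For FCCS, the bound fraction of
species A is G0_cross/G0_auto,B and symmetrically for B, with standard
errors propagated from the amplitude uncertainties.

## Displacement statistics and maps

One-lag displacement magnitudes x at frame time t from a two-population
Brownian mixture follow the cumulative distribution

    f(x) = 1 − [A e^(−x²/4D₁t) + (1−A) e^(−x²/4D₂t)].

`fit_cdf_two_component` fits this to the empirical CDF evaluated at every
unique displacement (no binning — a bin width would be an undocumented
degrees-of-freedom knob); components are ordered so D_slow < D_fast and
the reported `a_slow` is the slow fraction.  `fit_cdf_global` shares
(D₁, D₂) across datasets with one fraction per dataset.  Coefficients are
*apparent*: no motion-blur or localization-noise correction is applied.

`diffusion_map` rasterizes local mobility: on a 20 nm grid, each node
pools the squared displacements (over a 10 or 20 ms timescale) whose
origin lies within 80 nm and reports mean(|Δr|²)/(4·timescale); nodes with
fewer than `min_count` (default 5) displacements stay undefined (NaN),
never zero.  `msd_curve` gives the time-and-ensemble-averaged MSD;
`exploration_area` reads its plateau as the mean over the final third of
lags, flagging `no_plateau` when the final-third slope exceeds 20% of the
initial slope (the plateau definition is a package convention; confined
motion in a reflective square of side L plateaus at L²/3).

## Co-movement

Two registered channels are compared frame by frame
(`frame_matched_distances` lists all cross-channel pair distances).  A
pair is called co-moving when its distance stays at or below 320 nm for at
least ⌈10 ms / frame interval⌉ + 1 *consecutive* co-sampled frames; the
proximity must hold on every frame of the window and a single excursion
resets the run (a `gap_tolerance` option relaxes this; default 0, the
stricter reading).  For population statistics, `distance_density` divides
the distance histogram by each bin's annulus area π(r_out²−r_in²) and can
rescale so the median density beyond twice the co-movement threshold is 1:
independent channels give a flat unit baseline, tethered pairs a short-
distance peak.

## Registration

`gaussian_mask_localize` refines spot positions by iteratively re-weighted
centroids under a Gaussian mask (background = border median), accurate to
~0.01 px on clean spots and <0.15 px RMS at SNR ~10.  Bead fields are
paired by mutual nearest neighbors and a 6-parameter 2D affine transform
is estimated by linear least squares (collinear fields are rejected as
rank-deficient).  Images are resampled strictly by nearest neighbor, so
the output pixel values are a subset of the input values and the camera
noise distribution survives registration; out-of-bounds pixels get a
recorded sentinel.

## Synthetic data

Trajectories: per frame, x(t+Δt) = x(t) + N(0, 2DΔt) per axis, reflective
boundaries (tracks stay in-frame), optional Gaussian localization noise
added afterwards and never fed back into the dynamics; state labels (which
D, bound-vs-free, tether partner) are carried in the output.  Two-state
switching uses per-frame flip probabilities 1−e^(−k Δt), started from the
stationary distribution.  Two-color fields tether exactly round(f·n) of
the B tracks to distinct A tracks with N(0, tether_sigma²) jitter per
frame.  Motion blur is not simulated (instantaneous, stroboscopic
sampling).

Photon traces: molecules diffuse in a periodic 3D box with the focal
volume at the center; per bin the expected count is background·Δ plus
Σ ε·Δ·exp(−2(x²+y²)/w²)·exp(−2z²/(κw)²) over bright molecules, and counts
are Poisson.  Triplet blinking is a per-molecule telegraph process whose
dark-dwell follows the triplet lifetime and whose entry probability is
tuned so the stationary dark fraction equals T exactly at any bin width.
For speed, each species group advances on its own time stride (held
positions between updates, ≥ ~200 updates per lateral diffusion time;
the axial coordinate, which only enters through the κ-times-wider axial
Gaussian, strides 16× coarser), with float32 increments and float64
position carry.  Determinism: identical (config, seed) reproduces output
bit for bit.

Known limitations of the generator: the closed periodic box has a fixed
molecule count, which depresses the correlation baseline by exactly −1/N
(absorbed by the fit baseline) and truncates correlation tails beyond the
box's slowest diffusive mode (~(L/πw)² τ_D laterally); boxes are chosen so
this sits an order of magnitude beyond the fitted decay.  No detector
afterpulsing, dead time, EMCCD gain noise, bleaching, or motion blur is
modeled, so passing tests validate the estimators on ideal-detector data,
not those instrument effects.

## Validation experiments and problem sizes

`difftrans.experiments` fixes the study conditions used by the test suite
and `scripts/acceptance.py`.  Optics: w = 0.26 μm, κ = 5.  Traces: 10 s at
10 μs bins, ~100 kHz per-molecule peak brightness, 1 kHz background,
2.6 × 2.6 × 4.4 μm box.  Because the statistical error of a normalized
correlation estimate is nearly independent of occupancy but scales as
1/√(T/τ) per trace, repeated measurements are averaged before fitting (as
in real in-cell FCS sessions), with more repeats for slower species: 2
repeats at ⟨N⟩ = 1.5 for D = 15 μm²/s, 8 at ⟨N⟩ = 0.75 for D = 1, 48 at
⟨N⟩ = 2 for D = 0.05, 30 at ⟨N⟩ = 2 total for the 50/50 two-component
mixture (τ ratio 300).  Tracking experiments use 20,000 displacements at
200 Hz for the CDF fits, 300 tracks for the two-region diffusion map, and
100 track pairs (30% tethered at 50 nm) in a 100 μm field for co-movement.
These sizes keep each experiment's sampling error safely inside the
tolerances it is tested against while remaining runnable on a laptop in
minutes.
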