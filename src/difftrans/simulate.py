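"""Synthetic data with known ground truth.

This module emulates the two kinds of measurement the analysis pipeline
consumes:

* camera-based single-particle tracking — 2D Brownian trajectories with a
  free/bound mixture of diffusion coefficients (optionally interconverting
  by exponential waiting times), Gaussian localization noise, reflective
  boundaries so tracks stay in-frame, and a two-color mode where a fraction
  of channel-B tracks is tethered to channel-A tracks;
* confocal photon-count traces — molecules diffusing in a 3D periodic box
  emit photons through a 3D-Gaussian detection profile
  exp(-2(x²+y²)/w²) exp(-2z²/(κw)²), with Poisson counting, flat
  background, and optional triplet (dark-state) blinking as a two-state
  telegraph process.

Ground-truth state labels are carried alongside every output so parameter
recovery can be scored exactly.  Identical (config, seed) reproduces
identical output bit for bit.  Motion blur is not simulated: positions are
sampled instantaneously (stroboscopic illumination).  Observation noise is
added after trajectory generation and never fed back into the dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .correlate import PhotonTrace
from .registration import AffineTransform2D
from .spt import TrajectorySet

__all__ = [
    "SimulationConfig",
    "simulate_brownian_tracks",
    "simulate_switching_tracks",
    "simulate_cotracked_pairs",
    "simulate_photon_traces",
    "simulate_bead_field",
    "molecules_for_occupancy",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for trajectory and photon-trace simulation.

    Lengths μm, times s, rates 1/s, diffusion coefficients μm²/s.
    ``diffusion_coefficients`` is a list of (D, fraction) pairs whose
    fractions must sum to 1.  ``box_size`` is per-axis: 2 entries for
    tracks (reflective boundaries), 3 for photon traces (periodic
    boundaries, focal volume at the box center).  For photon traces,
    ``n_frames`` counts bins of width ``bin_width``.
    """

    n_particles: int = 100
    box_size: tuple = (10.0, 10.0)
    diffusion_coefficients: list = field(default_factory=lambda: [(1.0, 1.0)])
    switching_rates: tuple | None = None  # (k_slow_to_fast, k_fast_to_slow), 1/s
    frame_interval: float = 0.01
    n_frames: int = 100
    localization_sigma: float = 0.0
    bound_fraction_two_color: float | None = None
    tether_sigma: float = 0.0
    focal_waist: float = 0.26
    axial_ratio: float = 5.0
    brightness: float = 5.0e4  # detected photons/s per molecule at focus
    background: float = 1.0e3  # photons/s
    bin_width: float = 1.0e-5
    triplet_fraction: float = 0.0
    triplet_lifetime: float = 5.0e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box_size entries must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be non-negative")
        if self.tether_sigma < 0:
            raise ValueError("tether_sigma must be non-negative")
        fracs = [f for _, f in self.diffusion_coefficients]
        if any(d < 0 for d, _ in self.diffusion_coefficients):
            raise ValueError("diffusion coefficients must be non-negative")
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("diffusion-coefficient fractions must sum to 1")
        if self.switching_rates is not None and any(k < 0 for k in self.switching_rates):
            raise ValueError("switching rates must be non-negative")
        if self.bound_fraction_two_color is not None and not (
            0.0 <= self.bound_fraction_two_color <= 1.0
        ):
            raise ValueError("bound_fraction_two_color must be in [0, 1]")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must be in [0, 1)")
        if not self.triplet_lifetime > 0:
            raise ValueError("triplet_lifetime must be positive")


def molecules_for_occupancy(
    mean_occupancy: float, config: SimulationConfig
) -> int:
    """Number of molecules in the 3D box giving a target mean focal occupancy <N>."""
    w, kappa = config.focal_waist, config.axial_ratio
    v_eff = math.pi**1.5 * w**2 * (kappa * w)
    v_box = float(np.prod(config.box_size))
    return max(1, round(mean_occupancy * v_box / v_eff))


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _assign_states(n: int, fracs: list, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(len(fracs), size=n, p=np.asarray(fracs, dtype=float))


def _reflect(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold positions into [0, L] per axis by reflection."""
    period = 2.0 * box
    p = np.mod(pos, period)
    return np.where(p > box, period - p, p)


def _tracks_frame(
    positions: np.ndarray, states: np.ndarray, config: SimulationConfig, channel: str
) -> pd.DataFrame:
    """Assemble a trajectory table from a (n_frames, n, 2) position array."""
    n_frames, n, _ = positions.shape
    tid = np.repeat(np.arange(n), n_frames)
    frame = np.tile(np.arange(n_frames), n)
    xs = positions[:, :, 0].T.ravel()
    ys = positions[:, :, 1].T.ravel()
    if states.ndim == 1:
        st = np.repeat(states, n_frames)
    else:
        st = states.T.ravel()
    return pd.DataFrame(
        {
            "track_id": tid,
            "frame": frame,
            "t_s": frame * config.frame_interval,
            "x_um": xs,
            "y_um": ys,
            "channel": channel,
            "state_truth": st,
        }
    )


def simulate_brownian_tracks(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    channel: str = "A",
) -> TrajectorySet:
    """2D Brownian trajectories from a static mixture of diffusion states.

    Each particle draws a state from ``diffusion_coefficients`` and keeps it;
    per frame the position advances by N(0, 2 D dt) per axis with reflective
    boundaries, and N(0, localization_sigma²) observation noise is added
    afterwards.  ``state_truth`` holds the state index.
    """
    if len(config.box_size) != 2:
        raise ValueError("tracks require a 2D box_size")
    r = _rng(config, rng)
    box = np.asarray(config.box_size, dtype=float)
    n = config.n_particles
    ds = np.array([d for d, _ in config.diffusion_coefficients])
    fracs = [f for _, f in config.diffusion_coefficients]
    states = _assign_states(n, fracs, r)
    sigma = np.sqrt(2.0 * ds[states] * config.frame_interval)  # per-particle step SD
    start = r.uniform(0.0, box, size=(n, 2))
    steps = r.standard_normal((config.n_frames - 1, n, 2)) * sigma[None, :, None]
    pos = np.concatenate([start[None], steps], axis=0).cumsum(axis=0)
    pos = _reflect(pos, box)
    if config.localization_sigma > 0:
        pos = pos + r.standard_normal(pos.shape) * config.localization_sigma
    return TrajectorySet(_tracks_frame(pos, states, config, channel), config.frame_interval)


def simulate_switching_tracks(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    channel: str = "A",
) -> TrajectorySet:
    """Two-state trajectories that switch by exponential waiting times.

    ``diffusion_coefficients`` must list (D_slow, ·), (D_fast, ·); the
    fractions are ignored in favor of the stationary occupancy implied by
    ``switching_rates`` = (k_slow→fast, k_fast→slow), from which particles
    start at stationarity.  Per frame the state flips with probability
    1 - exp(-k dt).  The stationary slow fraction is k_f→s/(k_f→s + k_s→f).
    """
    if config.switching_rates is None:
        raise ValueError("switching_rates are required")
    if len(config.diffusion_coefficients) != 2:
        raise ValueError("switching simulation needs exactly two diffusion states")
    if len(config.box_size) != 2:
        raise ValueError("tracks require a 2D box_size")
    k_sf, k_fs = config.switching_rates
    if k_sf == 0 and k_fs == 0:
        return simulate_brownian_tracks(config, rng=rng, channel=channel)
    r = _rng(config, rng)
    box = np.asarray(config.box_size, dtype=float)
    n, nf, dt = config.n_particles, config.n_frames, config.frame_interval
    ds = np.array([d for d, _ in config.diffusion_coefficients])  # [slow, fast]
    p_slow = k_fs / (k_sf + k_fs)
    p_sf = -np.expm1(-k_sf * dt)
    p_fs = -np.expm1(-k_fs * dt)
    states = np.empty((nf, n), dtype=np.int64)
    states[0] = (r.random(n) >= p_slow).astype(np.int64)  # 0 = slow, 1 = fast
    u = r.random((nf - 1, n))
    for i in range(1, nf):
        flip = np.where(states[i - 1] == 0, u[i - 1] < p_sf, u[i - 1] < p_fs)
        states[i] = np.where(flip, 1 - states[i - 1], states[i - 1])
    # step i (from frame i-1 to i) uses the state occupied during that interval
    sigma = np.sqrt(2.0 * ds[states[:-1]] * dt)
    start = r.uniform(0.0, box, size=(n, 2))
    steps = r.standard_normal((nf - 1, n, 2)) * sigma[:, :, None]
    pos = np.concatenate([start[None], steps], axis=0).cumsum(axis=0)
    pos = _reflect(pos, box)
    if config.localization_sigma > 0:
        pos = pos + r.standard_normal(pos.shape) * config.localization_sigma
    return TrajectorySet(_tracks_frame(pos, states, config, channel), config.frame_interval)


def simulate_cotracked_pairs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TrajectorySet, TrajectorySet]:
    """Two-color trajectory fields with a known co-moving (bound) fraction.

    Channel A holds ``n_particles`` Brownian tracks.  In channel B, exactly
    ``round(f * n_particles)`` tracks follow a distinct channel-A track's
    path plus N(0, tether_sigma²) per frame (``state_truth`` = 1, bound);
    the rest diffuse independently (``state_truth`` = 0).  Localization
    noise applies to both channels.
    """
    f = config.bound_fraction_two_color
    if f is None:
        raise ValueError("bound_fraction_two_color is required")
    r = _rng(config, rng)
    cfg0 = replace(config, localization_sigma=0.0)  # noise added once, at the end
    a = simulate_brownian_tracks(cfg0, rng=r, channel="A")
    n = config.n_particles
    n_bound = int(round(f * n))
    free = simulate_brownian_tracks(cfg0, rng=r, channel="B")
    free_df = free.df[free.df["track_id"] >= n_bound].copy()
    free_df["state_truth"] = 0
    free_df["partner_id"] = -1

    bound_partners = r.permutation(n)[:n_bound]
    bound_rows = []
    a_by_track = {tid: g for tid, g in a.df.groupby("track_id")}
    for j, partner in enumerate(bound_partners):
        g = a_by_track[partner].copy()
        npts = len(g)
        jitter = (
            r.standard_normal((npts, 2)) * config.tether_sigma
            if config.tether_sigma > 0
            else np.zeros((npts, 2))
        )
        g["x_um"] = g["x_um"].to_numpy() + jitter[:, 0]
        g["y_um"] = g["y_um"].to_numpy() + jitter[:, 1]
        g["track_id"] = j
        g["channel"] = "B"
        g["state_truth"] = 1
        g["partner_id"] = int(partner)
        bound_rows.append(g)
    parts = bound_rows + [free_df]
    b_df = pd.concat(parts, ignore_index=True)
    a_df = a.df.copy()
    a_df["partner_id"] = -1
    if config.localization_sigma > 0:
        for df in (a_df, b_df):
            noise = r.standard_normal((len(df), 2)) * config.localization_sigma
            df["x_um"] += noise[:, 0]
            df["y_um"] += noise[:, 1]
    return (
        TrajectorySet(a_df, config.frame_interval),
        TrajectorySet(b_df, config.frame_interval),
    )


def _species_sigmas(config: SimulationConfig, n: int, rng: np.random.Generator):
    ds = np.array([d for d, _ in config.diffusion_coefficients])
    fracs = [f for _, f in config.diffusion_coefficients]
    states = _assign_states(n, fracs, rng)
    return states, np.sqrt(2.0 * ds[states] * config.bin_width)


def _telegraph_dark(
    n_bins: int, n_mol: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean dark-state matrix (n_bins, n_mol) for triplet blinking.

    The dark dwell follows the triplet lifetime (exit probability per bin
    from the exponential waiting time); the entry probability is then tuned
    so the stationary dark fraction of the discrete chain equals
    ``triplet_fraction`` exactly, at any bin width.
    """
    t_frac, tl = config.triplet_fraction, config.triplet_lifetime
    p_off = -np.expm1(-config.bin_width / tl)  # dark -> bright
    p_on = min(p_off * t_frac / (1.0 - t_frac), 1.0)  # bright -> dark
    dark = np.empty((n_bins, n_mol), dtype=bool)
    dark[0] = rng.random(n_mol) < t_frac
    u = rng.random((n_bins - 1, n_mol))
    for i in range(1, n_bins):
        flip = np.where(dark[i - 1], u[i - 1] < p_off, u[i - 1] < p_on)
        dark[i] = dark[i - 1] ^ flip
    return dark


def _group_intensity(
    r: np.random.Generator,
    n_mol: int,
    sigma_bin: float,
    stride: int,
    box: np.ndarray,
    w: float,
    kappa: float,
    n_bins: int,
    chunk_bins: int,
    dark: np.ndarray | None,
) -> np.ndarray:
    """Summed detection-profile intensity of one species group, per bin.

    Lateral (x, y) positions advance every ``stride`` bins, axial every
    ``16 * stride`` (the axial profile is kappa² wider); between updates the
    position is held.  Increments are float32 (float64 carry across
    chunks); the exponent is clamped to avoid float32 subnormal slowdowns.
    """
    z_stride = 16 * stride
    chunk_bins = (chunk_bins // z_stride) * z_stride or z_stride
    w2 = np.float32(w**2)
    wz2 = np.float32((kappa * w) ** 2)
    half = (box / 2).astype(np.float32)
    boxf = box.astype(np.float32)
    sig_xy = np.float32(sigma_bin * math.sqrt(stride))
    sig_z = np.float32(sigma_bin * math.sqrt(z_stride))
    pos = r.uniform(-box / 2, box / 2, size=(n_mol, 3))
    lam = np.empty(n_bins)
    for s in range(0, n_bins, chunk_bins):
        m = min(chunk_bins, n_bins - s)
        mx = (m + stride - 1) // stride
        mz = (m + z_stride - 1) // z_stride
        steps = r.standard_normal((mx, n_mol, 2), dtype=np.float32)
        steps *= sig_xy
        steps[0] += pos[:, :2].astype(np.float32)
        np.cumsum(steps, axis=0, out=steps)
        steps += half[:2]
        np.mod(steps, boxf[:2], out=steps)
        steps -= half[:2]
        zsteps = r.standard_normal((mz, n_mol), dtype=np.float32)
        zsteps *= sig_z
        zsteps[0] += pos[:, 2].astype(np.float32)
        np.cumsum(zsteps, axis=0, out=zsteps)
        zsteps += half[2]
        np.mod(zsteps, boxf[2], out=zsteps)
        zsteps -= half[2]
        pos = np.column_stack(
            [steps[-1].astype(np.float64), zsteps[-1].astype(np.float64)]
        )
        arg = steps[:, :, 0] ** 2
        arg += steps[:, :, 1] ** 2
        arg *= np.float32(-2.0) / w2
        zarg = zsteps**2 * (np.float32(-2.0) / wz2)
        if z_stride > stride:
            arg += np.repeat(zarg, z_stride // stride, axis=0)[:mx]
        else:
            arg += zarg
        np.maximum(arg, np.float32(-60.0), out=arg)
        inten = np.exp(arg)
        if dark is not None:
            # dark is per-bin: average the bright fraction within each stride
            bright = (~dark[s : s + m]).astype(np.float32)
            npad = mx * stride - m
            if npad:
                bright = np.vstack([bright, np.zeros((npad, bright.shape[1]), np.float32)])
            bright = bright.reshape(mx, stride, -1).mean(axis=1)
            inten = inten * bright
        per_bin = inten.sum(axis=1, dtype=np.float64)
        lam[s : s + m] = np.repeat(per_bin, stride)[:m]
    return lam


def simulate_photon_traces(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    chunk_bins: int = 49_152,
) -> PhotonTrace | tuple[PhotonTrace, PhotonTrace]:
    """Confocal photon-count traces from molecules diffusing in a 3D box.

    Per bin, the expected count is ``background * bin_width`` plus, for
    every bright molecule, ``brightness * bin_width *
    exp(-2(x²+y²)/w²) exp(-2z²/(κw)²)``; observed counts are Poisson.  The
    box is periodic with the focal volume at its center.  With
    ``bound_fraction_two_color`` set, two traces are returned: each channel
    has ``n_particles`` molecules of which ``round(f * n_particles)`` are
    shared double-labeled molecules contributing to both channels.

    Step increments are generated in float32 for speed (positions carry in
    float64 across chunks); fastest-species steps should stay well below
    the waist (``bin_width << w²/4D``), and a bin width at or above the
    fastest diffusion time is warned about.
    """
    if len(config.box_size) != 3:
        raise ValueError("photon traces require a 3D box_size")
    w, kappa = config.focal_waist, config.axial_ratio
    box = np.asarray(config.box_size, dtype=float)
    if np.any(box[:2] < 4 * w) or box[2] < 3 * kappa * w:
        raise ValueError("box must span several focal volumes per axis")
    d_max = max(d for d, _ in config.diffusion_coefficients)
    if d_max > 0 and config.bin_width >= w**2 / (4 * d_max):
        warnings.warn(
            "bin_width is not small compared to the fastest diffusion time; "
            "correlation decays will be under-resolved"
        )
    r = _rng(config, rng)
    two_color = config.bound_fraction_two_color is not None
    n = config.n_particles
    if two_color:
        f = config.bound_fraction_two_color
        n_ab = int(round(f * n))
        n_a_only = n - n_ab
        n_b_only = n - n_ab
        n_mol = n_a_only + n_b_only + n_ab
        in_a = np.zeros(n_mol, dtype=bool)
        in_b = np.zeros(n_mol, dtype=bool)
        in_a[:n_a_only] = True
        in_b[n_a_only : n_a_only + n_b_only] = True
        in_a[n_a_only + n_b_only :] = True
        in_b[n_a_only + n_b_only :] = True
    else:
        n_mol = n
        in_a = np.ones(n_mol, dtype=bool)
        in_b = None

    n_bins = config.n_frames
    states, sigmas = _species_sigmas(config, n_mol, r)
    dark = (
        _telegraph_dark(n_bins, n_mol, config, r)
        if config.triplet_fraction > 0
        else None
    )
    eps_bin = config.brightness * config.bin_width
    bg_bin = config.background * config.bin_width

    # Positions are advanced on per-species time strides: the lateral
    # weighting varies on tau_D = w²/4D and the axial one kappa² slower, so
    # a species is propagated every `stride` bins (position held in
    # between) with the correspondingly larger step SD, at >= ~200 updates
    # per lateral diffusion time.  Independent molecules let each species
    # group be propagated separately; intensities add.
    ds = np.array([d for d, _ in config.diffusion_coefficients])
    lam_a = np.zeros(n_bins)
    lam_b = np.zeros(n_bins) if two_color else None
    groups: dict[tuple, np.ndarray] = {}
    for mol in range(n_mol):
        key = (int(states[mol]), bool(in_a[mol]), bool(in_b[mol] if two_color else True))
        groups.setdefault(key, []).append(mol)
    for (state, a_flag, b_flag), members in sorted(groups.items()):
        members = np.asarray(members)
        d_spec = ds[state]
        if d_spec > 0:
            tau_d_bins = (w**2 / (4 * d_spec)) / config.bin_width
            stride = int(min(32, max(1, tau_d_bins // 200)))
        else:
            stride = 32
        if dark is not None:
            stride = 1  # triplet blinking is per-bin; no position holding
        lam = _group_intensity(
            r, len(members), float(sigmas[members[0]]), stride, box, w, kappa,
            n_bins, chunk_bins, None if dark is None else dark[:, members],
        )
        if a_flag:
            lam_a += lam
        if two_color and b_flag:
            lam_b += lam
    counts_a = r.poisson(eps_bin * lam_a + bg_bin)
    trace_a = PhotonTrace(counts_a, config.bin_width, "A")
    if not two_color:
        return trace_a
    counts_b = r.poisson(eps_bin * lam_b + bg_bin)
    return trace_a, PhotonTrace(counts_b, config.bin_width, "B")


def simulate_bead_field(
    n: int,
    transform: AffineTransform2D,
    noise_sigma: float = 0.0,
    seed: int = 0,
    fov: float = 512.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched bead localization pairs for registration testing.

    Channel-1 points are uniform in a ``fov`` x ``fov`` pixel field;
    channel-2 points are the affine image of channel 1 plus
    N(0, noise_sigma²) per coordinate.  At least 3 beads are required for a
    downstream affine fit.
    """
    if n < 3:
        raise ValueError("need at least 3 beads (affine is underdetermined)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    r = np.random.default_rng(seed)
    pts1 = r.uniform(0.0, fov, size=(n, 2))
    pts2 = transform.apply(pts1)
    if noise_sigma > 0:
        pts2 = pts2 + r.standard_normal((n, 2)) * noise_sigma
    return pts1, pts2
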