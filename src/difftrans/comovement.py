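"""Two-channel trajectory co-movement.

Association between molecules imaged in two registered channels shows up as
sustained proximity of their trajectories.  A pair of tracks is called
co-moving when their distance stays below a threshold (320 nm default) over
a dwell of at least 10 ms of consecutive co-sampled frames — the proximity
must hold on *every* frame of the window, and a single frame outside the
threshold resets the run (an optional gap tolerance relaxes this).

For population statistics, the histogram of all cross-channel distances per
frame is normalized by the annulus area of each distance bin; independent
channels give a flat density while tethered pairs pile up at short
distances above the flat baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spt import TrajectorySet

__all__ = [
    "ComovementResult",
    "DistanceDensity",
    "frame_matched_distances",
    "detect_comoving",
    "distance_density",
]


@dataclass
class ComovementResult:
    """Colocalized track pairs and the parameters that produced them."""

    pairs: pd.DataFrame  # track_a, track_b, first_frame, n_frames, mean_distance_um
    max_distance: float
    min_dwell: float
    frame_interval: float
    gap_tolerance: int = 0


@dataclass
class DistanceDensity:
    """Annulus-normalized cross-channel distance histogram."""

    bin_edges: np.ndarray  # μm
    counts: np.ndarray
    density: np.ndarray  # counts per μm², optionally rescaled to unit baseline
    baseline: float | None = None  # raw density corresponding to density == 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def frame_matched_distances(a: TrajectorySet, b: TrajectorySet) -> pd.DataFrame:
    """All cross-channel pairwise distances per co-sampled frame.

    Returns a frame-ordered table ``frame, track_a, track_b, distance_um``.
    """
    fa = set(a.df["frame"].unique())
    fb = set(b.df["frame"].unique())
    common = sorted(fa & fb)
    if not common:
        warnings.warn("channels share no frames: empty distance table")
        return pd.DataFrame(columns=["frame", "track_a", "track_b", "distance_um"])
    ga = {f: g for f, g in a.df.groupby("frame") if f in fb}
    gb = {f: g for f, g in b.df.groupby("frame") if f in fa}
    rows = []
    for f in common:
        pa = ga[f]
        pb = gb[f]
        xa = pa[["x_um", "y_um"]].to_numpy()
        xb = pb[["x_um", "y_um"]].to_numpy()
        d = np.hypot(
            xa[:, None, 0] - xb[None, :, 0], xa[:, None, 1] - xb[None, :, 1]
        )
        ta = pa["track_id"].to_numpy()
        tb = pb["track_id"].to_numpy()
        ii, jj = np.meshgrid(np.arange(len(ta)), np.arange(len(tb)), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "track_a": ta[ii.ravel()],
                    "track_b": tb[jj.ravel()],
                    "distance_um": d.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def detect_comoving(
    a: TrajectorySet,
    b: TrajectorySet,
    max_distance: float = 0.32,
    min_dwell: float = 0.010,
    gap_tolerance: int = 0,
) -> ComovementResult:
    """Dwell-based colocalization of cross-channel track pairs.

    A pair qualifies when the distance is <= ``max_distance`` on at least
    ``ceil(min_dwell / frame_interval) + 1`` consecutive co-sampled frames
    (so the elapsed dwell time is >= ``min_dwell``).  ``min_dwell`` below
    one frame interval reduces to two consecutive frames.  Runs are broken
    by more than ``gap_tolerance`` consecutive disqualified frames.
    Output is ordered by (track_a, track_b, first_frame).
    """
    dt = a.frame_interval
    if not np.isclose(dt, b.frame_interval, rtol=1e-9):
        raise ValueError("channels must share the frame clock")
    n_req = int(math.ceil(min_dwell / dt - 1e-9)) + 1
    n_req = max(n_req, 2)
    rec = frame_matched_distances(a, b)
    rows = []
    if len(rec):
        close = rec[rec["distance_um"] <= max_distance]
        for (ta, tb), g in close.groupby(["track_a", "track_b"], sort=True):
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy()
            dist = g["distance_um"].to_numpy()
            run_start = 0
            for i in range(1, len(frames) + 1):
                broken = i == len(frames) or frames[i] - frames[i - 1] > 1 + gap_tolerance
                if broken:
                    n = i - run_start
                    if n >= n_req:
                        rows.append(
                            (
                                ta,
                                tb,
                                int(frames[run_start]),
                                int(n),
                                float(dist[run_start:i].mean()),
                            )
                        )
                    run_start = i
    pairs = pd.DataFrame(
        rows,
        columns=["track_a", "track_b", "first_frame", "n_frames", "mean_distance_um"],
    ).sort_values(["track_a", "track_b", "first_frame"], ignore_index=True)
    return ComovementResult(pairs, max_distance, min_dwell, dt, gap_tolerance)


def distance_density(
    distances: np.ndarray | pd.DataFrame,
    bin_width: float = 0.05,
    r_max: float = 2.0,
    baseline_beyond: float | None = None,
) -> DistanceDensity:
    """Distance histogram normalized by per-bin annulus area.

    Each bin count is divided by pi (r_out² - r_in²), turning the histogram
    into an average spot density as a function of distance.  With
    ``baseline_beyond`` set, the density is rescaled so the median of bins
    starting at or beyond that distance equals 1 (a flat unit baseline for
    independent channels).
    """
    if isinstance(distances, pd.DataFrame):
        distances = distances["distance_um"].to_numpy()
    distances = np.asarray(distances, dtype=float)
    if len(distances) == 0:
        raise ValueError("no distance records")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    density = counts / areas
    baseline = None
    if baseline_beyond is not None:
        sel = edges[:-1] >= baseline_beyond
        if not sel.any():
            raise ValueError("baseline window lies beyond r_max")
        baseline = float(np.median(density[sel]))
        if baseline <= 0:
            raise ValueError("empty baseline window: cannot rescale")
        density = density / baseline
    return DistanceDensity(edges, counts, density, baseline)
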