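"""Single-particle-tracking diffusion analysis.

Trajectories are 2D localizations (μm, image convention: y increases
downward, origin at the image corner) grouped by track id on a regular
frame clock.  From the one-lag displacement magnitudes ``x`` at frame time
``t`` the two-component Brownian mixture is fit through the cumulative
distribution

    f(x) = 1 - [A exp(-x^2 / 4 D1 t) + (1 - A) exp(-x^2 / 4 D2 t)],

with ``A`` the fraction of molecules with coefficient ``D1``.  Coefficients
are *apparent*: no motion-blur or localization-noise correction is applied
(an optional config can subtract 4 sigma_loc^2 from MSD-based estimates).
Local mobility is mapped on a fine spatial grid (20 nm default) by pooling
the squared displacements originating within a radius (80 nm default) of
each node; MSD curves and their plateau (exploration area) summarize
confined motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TrajectorySet",
    "DisplacementSet",
    "CDFFitResult",
    "DiffusionMap",
    "link_detections",
    "extract_displacements",
    "fit_cdf_two_component",
    "fit_cdf_global",
    "diffusion_map",
    "msd_curve",
    "exploration_area",
    "ExplorationArea",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "channel", "state_truth"]


@dataclass
class TrajectorySet:
    """A table of localizations (one row per point) plus the frame clock.

    ``df`` columns: ``track_id, frame, t_s, x_um, y_um, channel,
    state_truth`` (``state_truth`` is -1 when unknown).  Frames are strictly
    increasing within each track.
    """

    df: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        missing = [c for c in ("track_id", "frame", "x_um", "y_um") if c not in self.df]
        if missing:
            raise ValueError(f"missing trajectory columns: {missing}")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if "t_s" not in self.df:
            self.df = self.df.assign(t_s=self.df["frame"] * self.frame_interval)
        if "channel" not in self.df:
            self.df = self.df.assign(channel="0")
        if "state_truth" not in self.df:
            self.df = self.df.assign(state_truth=-1)
        if not np.isfinite(self.df[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("positions must be finite")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def tracks(self):
        """Iterate (track_id, frame-sorted sub-frame)."""
        for tid, g in self.df.groupby("track_id", sort=True):
            yield tid, g.sort_values("frame")

    def to_csv(self, path) -> None:
        self.df[TRACK_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float | None = None) -> "TrajectorySet":
        df = pd.read_csv(path)
        if len(df) == 0:
            raise ValueError(f"empty trajectory file: {path}")
        if frame_interval is None:
            t = df.sort_values(["track_id", "frame"])
            dt = t.groupby("track_id")["t_s"].diff() / t.groupby("track_id")["frame"].diff()
            dt = dt.dropna()
            if len(dt) == 0:
                raise ValueError("cannot infer frame interval from single-point tracks")
            frame_interval = float(dt.median())
        return cls(df, frame_interval)


@dataclass
class DisplacementSet:
    """Displacement magnitudes at a single lag time."""

    r: np.ndarray  # μm, >= 0
    lag_time: float  # seconds
    counts_per_track: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("displacement magnitudes must be non-negative")
        if not self.lag_time > 0:
            raise ValueError("lag_time must be positive")

    def __len__(self) -> int:
        return len(self.r)


def link_detections(
    detections: pd.DataFrame,
    max_link_distance: float,
    max_gap: int = 0,
    frame_interval: float = 0.01,
) -> TrajectorySet:
    """Greedy nearest-neighbor frame-to-frame linking (DiaTrack stand-in).

    Candidate links within ``max_link_distance`` are assigned greedily in
    order of increasing distance (ties broken by lowest detection index);
    a track head missing for up to ``max_gap`` frames may still be
    extended.  Unlinked detections start new tracks.
    """
    det = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    heads: list[dict] = []  # {'tid', 'x', 'y', 'frame'}
    rows: list[tuple] = []
    next_tid = 0
    for frame, grp in det.groupby("frame", sort=True):
        pts = grp[["x_um", "y_um"]].to_numpy()
        order = np.argsort(grp.index.to_numpy(), kind="stable")
        pts = pts[order]
        live = [h for h in heads if frame - h["frame"] <= max_gap + 1 and h["frame"] < frame]
        cands = []
        for j, h in enumerate(live):
            d = np.hypot(pts[:, 0] - h["x"], pts[:, 1] - h["y"])
            for i in np.nonzero(d <= max_link_distance)[0]:
                cands.append((d[i], int(i), j))
        cands.sort(key=lambda c: (c[0], c[1], live[c[2]]["tid"]))
        used_det: set[int] = set()
        used_head: set[int] = set()
        assign: dict[int, dict] = {}
        for dist, i, j in cands:
            if i in used_det or j in used_head:
                continue
            used_det.add(i)
            used_head.add(j)
            assign[i] = live[j]
        for i, (x, y) in enumerate(pts):
            if i in assign:
                h = assign[i]
            else:
                h = {"tid": next_tid}
                next_tid += 1
                heads.append(h)
            h.update(x=float(x), y=float(y), frame=int(frame))
            rows.append((h["tid"], int(frame), float(x), float(y)))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    return TrajectorySet(df, frame_interval)


def extract_displacements(tracks: TrajectorySet, lag: int = 1) -> DisplacementSet:
    """All in-track displacement magnitudes at ``lag`` frames (gap pairs skipped)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    mags: list[np.ndarray] = []
    counts: dict = {}
    for tid, g in tracks.tracks():
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        idx = {f: i for i, f in enumerate(frames)}
        i0 = np.array([idx[f] for f in frames if f + lag in idx], dtype=int)
        if len(i0) == 0:
            continue
        i1 = np.array([idx[f + lag] for f in frames if f + lag in idx], dtype=int)
        d = np.hypot(*(xy[i1] - xy[i0]).T)
        mags.append(d)
        counts[tid] = len(d)
    r = np.concatenate(mags) if mags else np.empty(0)
    return DisplacementSet(r, lag * tracks.frame_interval, counts)


@dataclass
class CDFFitResult:
    """Two-component displacement-CDF fit; ``d_slow < d_fast`` by convention."""

    a_slow: float  # fraction of the slow component (coefficient d_slow)
    d_slow: float  # μm²/s
    d_fast: float  # μm²/s
    lag_time: float  # s, fixed from the data
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def a_raw(self) -> float:
        """The mixture parameter as written (fraction with coefficient D1=d_slow)."""
        return self.a_slow

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.lag_time
        return 1.0 - (
            self.a_slow * np.exp(-(x**2) / (4 * self.d_slow * t))
            + (1 - self.a_slow) * np.exp(-(x**2) / (4 * self.d_fast * t))
        )


def _ecdf(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF evaluated at every unique displacement value."""
    x = np.sort(r)
    xu, counts = np.unique(x, return_counts=True)
    f = np.cumsum(counts) / len(x)
    return xu, f


def _mixture_cdf(x, a, d1, d2, t):
    return 1.0 - (a * np.exp(-(x**2) / (4 * d1 * t)) + (1 - a) * np.exp(-(x**2) / (4 * d2 * t)))


def fit_cdf_two_component(d: DisplacementSet) -> CDFFitResult:
    """Least-squares fit of the two-component mixture to the empirical CDF.

    All unique displacement values serve as abscissae (no binning).  The
    components are ordered so ``d_slow < d_fast`` and ``a_slow`` is the slow
    fraction.  A near-degenerate fit (ratio < 1.5) is flagged
    ``"degenerate_components"``.
    """
    if len(d) < 10:
        raise ValueError("too few displacements to fit")
    x, f = _ecdf(d.r)
    t = d.lag_time
    d_bar = max(float(np.mean(d.r**2)) / (4 * t), 1e-9)
    p = lmfit.Parameters()
    p.add("A", value=0.5, min=0.0, max=1.0)
    p.add("d1", value=d_bar / 5, min=1e-9, max=d_bar * 1e4)
    p.add("ratio", value=25.0, min=1.0, max=1e6)
    p.add("d2", expr="d1 * ratio")

    def resid(params):
        v = params.valuesdict()
        return _mixture_cdf(x, v["A"], v["d1"], v["d2"], t) - f

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    flags = []
    if not out.success:
        flags.append("non_convergent")
    if v["ratio"] < 1.5:
        flags.append("degenerate_components")
    stderr = {
        "a_slow": out.params["A"].stderr,
        "d_slow": out.params["d1"].stderr,
        "d_fast": out.params["d2"].stderr,
    }
    return CDFFitResult(
        a_slow=v["A"],
        d_slow=v["d1"],
        d_fast=v["d2"],
        lag_time=t,
        stderr=stderr,
        flags=flags,
    )


def fit_cdf_global(datasets: list[DisplacementSet]) -> list[CDFFitResult]:
    """Joint CDF fit sharing (d_slow, d_fast) across datasets, A free per dataset."""
    if len(datasets) < 2:
        raise ValueError("global fit needs at least two datasets")
    t = datasets[0].lag_time
    for ds in datasets[1:]:
        if not np.isclose(ds.lag_time, t, rtol=1e-9):
            raise ValueError("datasets must share a common frame time")
    grids = [_ecdf(ds.r) for ds in datasets]
    d_bar = max(float(np.mean(np.concatenate([ds.r for ds in datasets]) ** 2)) / (4 * t), 1e-9)
    p = lmfit.Parameters()
    p.add("d1", value=d_bar / 5, min=1e-9, max=d_bar * 1e4)
    p.add("ratio", value=25.0, min=1.0, max=1e6)
    p.add("d2", expr="d1 * ratio")
    for i in range(len(datasets)):
        p.add(f"A{i}", value=0.5, min=0.0, max=1.0)

    def resid(params):
        v = params.valuesdict()
        return np.concatenate(
            [
                _mixture_cdf(x, v[f"A{i}"], v["d1"], v["d2"], t) - f
                for i, (x, f) in enumerate(grids)
            ]
        )

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    results = []
    for i in range(len(datasets)):
        flags = [] if out.success else ["non_convergent"]
        results.append(
            CDFFitResult(
                a_slow=v[f"A{i}"],
                d_slow=v["d1"],
                d_fast=v["d2"],
                lag_time=t,
                stderr={
                    "a_slow": out.params[f"A{i}"].stderr,
                    "d_slow": out.params["d1"].stderr,
                    "d_fast": out.params["d2"].stderr,
                },
                flags=flags,
            )
        )
    return results


@dataclass
class DiffusionMap:
    """Grid of local apparent diffusion coefficients (NaN where undefined)."""

    origin: tuple[float, float]  # μm, (x0, y0) of node [0, 0]
    spacing: float  # μm
    values: np.ndarray  # (ny, nx), apparent D in μm²/s, NaN = undefined
    counts: np.ndarray  # displacements pooled per node
    radius: float  # μm
    timescale: float  # s

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.values.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing
        ys = self.origin[1] + np.arange(ny) * self.spacing
        xx, yy = np.meshgrid(xs, ys)
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "d_app_um2_s": self.values.ravel(),
                "n_displacements": self.counts.ravel(),
            }
        )


def diffusion_map(
    tracks: TrajectorySet,
    spacing: float = 0.020,
    radius: float = 0.080,
    timescale: float = 0.010,
    min_count: int = 5,
) -> DiffusionMap:
    """Local apparent D on a fine grid from displacements starting nearby.

    Each node pools the squared magnitudes of all displacements (over
    ``timescale``) whose origin lies within ``radius`` of the node and
    reports mean(|dr|²) / (4 * timescale); nodes with fewer than
    ``min_count`` displacements are NaN, never zero-filled.
    """
    lag_f = timescale / tracks.frame_interval
    lag = int(round(lag_f))
    if abs(lag_f - lag) > 1e-6 or lag < 1:
        raise ValueError("timescale must be an integer multiple of the frame interval")
    origins: list[np.ndarray] = []
    sq: list[np.ndarray] = []
    for _, g in tracks.tracks():
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        idx = {f: i for i, f in enumerate(frames)}
        pairs = [(idx[f], idx[f + lag]) for f in frames if f + lag in idx]
        if not pairs:
            continue
        i0, i1 = np.array(pairs).T
        origins.append(xy[i0])
        sq.append(((xy[i1] - xy[i0]) ** 2).sum(axis=1))
    if not origins:
        import warnings

        warnings.warn("no displacements: diffusion map is empty")
        return DiffusionMap((0.0, 0.0), spacing, np.full((1, 1), np.nan), np.zeros((1, 1), int), radius, timescale)
    o = np.vstack(origins)
    s = np.concatenate(sq)
    x0, y0 = o[:, 0].min(), o[:, 1].min()
    nx = int(np.floor((o[:, 0].max() - x0) / spacing)) + 1
    ny = int(np.floor((o[:, 1].max() - y0) / spacing)) + 1
    xs = x0 + np.arange(nx) * spacing
    ys = y0 + np.arange(ny) * spacing
    xx, yy = np.meshgrid(xs, ys)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    tree = cKDTree(o)
    values = np.full(len(nodes), np.nan)
    counts = np.zeros(len(nodes), dtype=int)
    hits = tree.query_ball_point(nodes, radius)
    for i, h in enumerate(hits):
        counts[i] = len(h)
        if len(h) >= min_count:
            values[i] = s[h].mean() / (4.0 * timescale)
    return DiffusionMap(
        (float(x0), float(y0)),
        spacing,
        values.reshape(ny, nx),
        counts.reshape(ny, nx),
        radius,
        timescale,
    )


def msd_curve(tracks: TrajectorySet, max_lag: int) -> pd.DataFrame:
    """Time-and-ensemble-averaged MSD per lag, with SE over pooled displacements."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    per_track = []
    for _, g in tracks.tracks():
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        per_track.append((frames, {f: i for i, f in enumerate(frames)}, xy))
    rows = []
    for lag in range(1, max_lag + 1):
        sqs = []
        for frames, idx, xy in per_track:
            pairs = [(idx[f], idx[f + lag]) for f in frames if f + lag in idx]
            if pairs:
                i0, i1 = np.array(pairs).T
                sqs.append(((xy[i1] - xy[i0]) ** 2).sum(axis=1))
        if not sqs:
            continue
        s = np.concatenate(sqs)
        rows.append(
            (
                lag,
                lag * tracks.frame_interval,
                s.mean(),
                s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
                len(s),
            )
        )
    if not rows:
        raise ValueError("no track long enough for the requested lags")
    return pd.DataFrame(rows, columns=["lag", "lag_s", "msd_um2", "sem_um2", "n"])


@dataclass
class ExplorationArea:
    area_um2: float
    sem_um2: float
    no_plateau: bool


def exploration_area(msd: pd.DataFrame) -> ExplorationArea:
    """Plateau of an MSD curve, read as the confined exploration area.

    The plateau is the mean MSD over the final third of lags.  If the slope
    over that final third exceeds 20% of the initial slope the curve is
    still growing and ``no_plateau`` is set.
    """
    if len(msd) < 6:
        raise ValueError("need at least 6 MSD lags")
    tail = msd.iloc[-(len(msd) // 3):]
    area = float(tail["msd_um2"].mean())
    sem = float(np.sqrt((tail["sem_um2"] ** 2).sum()) / len(tail))
    head = msd.iloc[: max(3, len(msd) // 3)]
    slope0 = np.polyfit(head["lag_s"], head["msd_um2"], 1)[0]
    slope1 = np.polyfit(tail["lag_s"], tail["msd_um2"], 1)[0]
    no_plateau = bool(abs(slope0) > 0 and slope1 > 0.2 * slope0) if slope0 > 0 else False
    return ExplorationArea(area, sem, no_plateau)
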