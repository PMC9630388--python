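"""Auto- and cross-correlation of binned photon-count traces.

Fluorescence correlation spectroscopy works on the normalized correlation

    G(tau) = <dI_a(t) dI_b(t + tau)> / (<I_a> <I_b>),   dI = I - <I>,

computed from photon counts binned on a regular grid.  Two estimators are
provided: a brute-force ``direct_correlate`` that evaluates the definition
at every requested lag (the oracle), and the multi-tau scheme
(``multitau_correlate``) that covers many decades of lag time by
progressively rebinning the trace by factors of two.  Both use symmetric
normalization: the means in the denominator are taken over the same valid
time windows as the numerator, which suppresses bias from slow drifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "direct_correlate",
    "multitau_correlate",
    "average_curves",
]


@dataclass
class PhotonTrace:
    """Binned photon counts for one detection channel.

    Parameters
    ----------
    counts
        Non-negative photon counts per bin.
    bin_width
        Bin width in seconds.
    channel_label
        Free-form channel name (e.g. ``"A"``, ``"585"``).
    """

    counts: np.ndarray
    bin_width: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.counts) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean count rate in Hz."""
        return float(self.counts.mean()) / self.bin_width

    def rebin(self, factor: int) -> "PhotonTrace":
        """Sum consecutive groups of ``factor`` bins (trailing remainder dropped)."""
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        n = (len(self.counts) // factor) * factor
        c = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return PhotonTrace(c, self.bin_width * factor, self.channel_label)


@dataclass
class CorrelationCurve:
    """Normalized correlation amplitudes on a strictly increasing lag grid."""

    lags: np.ndarray  # seconds
    G: np.ndarray
    sem: np.ndarray | None = None
    kind: str = "auto"  # "auto" | "cross"
    channel_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have the same shape")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem < 0):
                raise ValueError("sem must be non-negative")


def _check_pair(a: PhotonTrace, b: PhotonTrace) -> None:
    if not np.isclose(a.bin_width, b.bin_width, rtol=1e-9, atol=0.0):
        raise ValueError("traces must share the same bin width")
    if len(a.counts) != len(b.counts):
        raise ValueError("traces must have the same length")


_N_SEM_BLOCKS = 10


def _correlate_at_lags(
    x: np.ndarray,
    y: np.ndarray,
    lags: np.ndarray,
    mean_a: float | None = None,
    mean_b: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """G and its SE at integer lags.

    By default the normalization means are window-local (symmetric
    normalization).  When ``mean_a``/``mean_b`` are given (e.g. pooled over
    repeated measurements of the same spot) they are used instead, which
    removes the finite-trace normalization bias that window-local means
    introduce when the trace is not much longer than the correlation time.

    The per-lag standard error comes from splitting the lagged products into
    contiguous blocks and taking the SE of the block means (block length far
    exceeds the correlation time for all but the last levels, where the SE
    is an underestimate but still ranks points correctly for weighting).
    """
    n = len(x)
    g = np.empty(len(lags))
    sem = np.empty(len(lags))
    for i, k in enumerate(lags):
        xa = x[: n - k]
        yb = y[k:]
        ma = xa.mean() if mean_a is None else mean_a
        mb = yb.mean() if mean_b is None else mean_b
        if ma == 0.0 or mb == 0.0:
            raise ZeroDivisionError(
                "zero-mean trace window: correlation normalization undefined"
            )
        prod = xa * yb
        g[i] = prod.mean() / (ma * mb) - 1.0
        nb = min(_N_SEM_BLOCKS, len(prod))
        bl = len(prod) // nb
        if bl >= 2:
            bm = prod[: nb * bl].reshape(nb, bl).mean(axis=1)
            sem[i] = bm.std(ddof=1) / np.sqrt(nb) / (ma * mb)
        else:
            sem[i] = 0.0
    return g, sem


def direct_correlate(
    a: PhotonTrace,
    b: PhotonTrace | None = None,
    lags: np.ndarray | None = None,
    mean_a: float | None = None,
    mean_b: float | None = None,
) -> CorrelationCurve:
    """Brute-force normalized correlation at the requested integer lags.

    Parameters
    ----------
    a, b
        Traces of equal length and bin width; ``b=None`` computes the
        autocorrelation of ``a``.
    lags
        Lags in units of bins (positive integers, strictly increasing,
        each smaller than the trace length).  Defaults to ``1..min(64, N//4)``.
    """
    auto = b is None or b is a
    if b is None:
        b = a
    _check_pair(a, b)
    n = len(a.counts)
    if lags is None:
        lags = np.arange(1, min(64, n // 4) + 1)
    lags = np.asarray(lags, dtype=int)
    if len(lags) == 0 or lags.min() < 1 or lags.max() >= n:
        raise ValueError("lags must be in [1, n_bins)")
    if np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be strictly increasing")
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    g, sem = _correlate_at_lags(x, y, lags, mean_a, mean_b)
    return CorrelationCurve(
        lags * a.bin_width,
        g,
        sem=sem,
        kind="auto" if auto else "cross",
        channel_pair=(a.channel_label, b.channel_label),
    )


def multitau_correlate(
    a: PhotonTrace,
    b: PhotonTrace | None = None,
    m_per_level: int = 16,
    n_levels: int | None = None,
    mean_a: float | None = None,
    mean_b: float | None = None,
) -> CorrelationCurve:
    """Multi-tau correlation: ``m_per_level`` lags per level, rebinning by 2.

    Level 0 evaluates lags ``1..m`` on the raw trace; each further level
    rebins both traces pairwise by a factor of two and evaluates lags
    ``m/2+1..m`` in rebinned units, yielding a quasi-logarithmic lag grid.
    Values at level ``l`` are, by construction, the symmetric-normalized
    correlation of the ``2**l``-rebinned traces.
    """
    auto = b is None or b is a
    if b is None:
        b = a
    _check_pair(a, b)
    if m_per_level < 2 or m_per_level % 2:
        raise ValueError("m_per_level must be an even integer >= 2")
    n = len(a.counts)
    m = m_per_level
    if n_levels is None:
        # stop while the rebinned trace still has >= 4*m bins
        n_levels = 1
        length = n // 2
        while length >= 4 * m:
            n_levels += 1
            length //= 2
    if n // 2 ** (n_levels - 1) <= m:
        raise ValueError("trace too short for the requested number of levels")

    xa = a.counts.astype(float)
    xb = b.counts.astype(float)
    all_lags: list[np.ndarray] = []
    all_g: list[np.ndarray] = []
    all_sem: list[np.ndarray] = []
    for level in range(n_levels):
        if level == 0:
            local = np.arange(1, m + 1)
        else:
            nl = (len(xa) // 2) * 2
            xa = xa[:nl].reshape(-1, 2).sum(axis=1)
            xb = xb[:nl].reshape(-1, 2).sum(axis=1)
            local = np.arange(m // 2 + 1, m + 1)
        local = local[local < len(xa)]
        if len(local) == 0:
            break
        scale = float(2**level)
        g, sem = _correlate_at_lags(
            xa,
            xb,
            local,
            None if mean_a is None else mean_a * scale,
            None if mean_b is None else mean_b * scale,
        )
        all_g.append(g)
        all_sem.append(sem)
        all_lags.append(local * (2**level) * a.bin_width)
    return CorrelationCurve(
        np.concatenate(all_lags),
        np.concatenate(all_g),
        sem=np.concatenate(all_sem),
        kind="auto" if auto else "cross",
        channel_pair=(a.channel_label, b.channel_label),
    )


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean and SEM over curves sharing one lag grid."""
    if not curves:
        raise ValueError("need at least one curve")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags, rtol=1e-12):
            raise ValueError("curves must share an identical lag grid")
    gs = np.vstack([c.G for c in curves])
    mean = gs.mean(axis=0)
    if len(curves) > 1:
        sem = gs.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        sem = np.zeros_like(mean)
    return CorrelationCurve(
        lags.copy(),
        mean,
        sem=sem,
        kind=curves[0].kind,
        channel_pair=curves[0].channel_pair,
    )
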