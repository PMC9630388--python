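"""FCS/FCCS model fitting and derived quantities.

The confocal detection volume is modeled as a 3D Gaussian with lateral 1/e²
radius ``w`` and axial-to-lateral ratio ``kappa``.  A single freely diffusing
species with diffusion time ``tau_D`` then produces

    G(tau) = G0 * [1 - T + T exp(-tau/Tt)]
             * (1 + tau/tau_D)^-1 * (1 + tau/(tau_D kappa^2))^-1/2,

where ``T`` and ``Tt`` are the triplet (dark-state) fraction and lifetime and
``G0`` the amplitude; a two-component variant mixes two diffusion times with
fraction ``A``.  The printed model has unit amplitude; a free multiplicative
``G0`` is included here because measured curves are not pre-normalized
(G0 = 1/<N> for an ideal dilute measurement).

Diffusion times convert to coefficients through D = w^2 / (4 tau_D); the
waist can conversely be calibrated from a known (tau_D, D) pair.  For
dual-color cross-correlation, the ratio of the cross amplitude to the other
channel's autocorrelation amplitude estimates the bound fraction of each
species.

All times are seconds, lengths μm, diffusion coefficients μm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = [
    "FocalVolume",
    "FCSFitResult",
    "FCCSResult",
    "eval_fcs_model",
    "fit_fcs",
    "compare_models",
    "calibrate_waist",
    "diffusion_time_to_coefficient",
    "estimate_concentration",
    "fccs_bound_fraction",
]

AVOGADRO = 6.02214076e23
DEFAULT_KAPPA = 5.0


@dataclass
class FocalVolume:
    """Confocal detection volume: lateral 1/e² waist (μm) and axial ratio."""

    waist: float = 0.26
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if not self.waist > 0:
            raise ValueError("waist must be positive")
        if not self.kappa >= 1:
            raise ValueError("kappa must be >= 1")

    @property
    def effective_volume_um3(self) -> float:
        """V_eff = pi^{3/2} w^2 (kappa w), in μm³ (1 μm³ = 1 fL)."""
        return math.pi**1.5 * self.waist**2 * (self.kappa * self.waist)

    @property
    def effective_volume_l(self) -> float:
        return self.effective_volume_um3 * 1e-15


def _diffusion_term(lags: np.ndarray, tau: float, kappa: float) -> np.ndarray:
    return 1.0 / ((1.0 + lags / tau) * np.sqrt(1.0 + lags / (tau * kappa**2)))


def eval_fcs_model(
    lags: np.ndarray,
    model: str = "one",
    *,
    G0: float = 1.0,
    T: float = 0.0,
    Tt: float = 5e-6,
    tau1: float = 1e-3,
    tau2: float | None = None,
    A: float = 1.0,
    kappa: float = DEFAULT_KAPPA,
) -> np.ndarray:
    """Evaluate the one- or two-component triplet-diffusion model.

    ``lags`` in seconds (strictly positive); ``tau1 < tau2`` is the caller's
    convention for the two-component model, where ``A`` is the fraction with
    diffusion time ``tau1``.
    """
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0):
        raise ValueError("lags must be strictly positive")
    if not 0 <= T < 1:
        raise ValueError("triplet fraction T must be in [0, 1)")
    if tau1 <= 0 or (tau2 is not None and tau2 <= 0) or Tt <= 0:
        raise ValueError("diffusion and triplet times must be positive")
    triplet = 1.0 - T + T * np.exp(-lags / Tt)
    if model == "one":
        diff = _diffusion_term(lags, tau1, kappa)
    elif model == "two":
        if tau2 is None:
            raise ValueError("two-component model requires tau2")
        if not 0 <= A <= 1:
            raise ValueError("A must be in [0, 1]")
        diff = A * _diffusion_term(lags, tau1, kappa) + (1 - A) * _diffusion_term(
            lags, tau2, kappa
        )
    else:
        raise ValueError("model must be 'one' or 'two'")
    return G0 * triplet * diff


@dataclass
class FCSFitResult:
    """Fitted parameters of the triplet-diffusion model with uncertainties."""

    model: str
    params: dict
    stderr: dict
    success: bool
    redchi: float
    residuals: np.ndarray
    lags: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def G0(self) -> float:
        return self.params["G0"]

    @property
    def tau1(self) -> float:
        return self.params["tau1"]

    @property
    def tau2(self) -> float | None:
        return self.params.get("tau2")

    def predict(self, lags: np.ndarray | None = None) -> np.ndarray:
        if lags is None:
            lags = self.lags
        p = {k: v for k, v in self.params.items() if k not in ("kappa", "offset")}
        return eval_fcs_model(
            lags, self.model, kappa=self.params["kappa"], **p
        ) + self.params.get("offset", 0.0)


def _initial_tau(curve: CorrelationCurve) -> float:
    """Lag at which G first drops below half of its small-lag amplitude."""
    g0 = np.median(curve.G[: max(3, len(curve.G) // 20)])
    below = np.nonzero(curve.G < 0.5 * g0)[0]
    if g0 <= 0 or len(below) == 0:
        return float(np.sqrt(curve.lags[0] * curve.lags[-1]))
    return float(curve.lags[below[0]])


def fit_fcs(
    curve: CorrelationCurve,
    model: str = "one",
    *,
    kappa: float = DEFAULT_KAPPA,
    init: dict | None = None,
    bounds: dict | None = None,
    fix: dict | None = None,
    max_triplet_lifetime: float = 1e-4,
    fit_offset: bool = True,
) -> FCSFitResult:
    """Weighted least-squares fit of the FCS model to a correlation curve.

    Weights are ``1/sem`` where a per-lag SEM is available (zero-SEM points
    fall back to the median weight), uniform otherwise.  ``fix`` pins
    parameters (e.g. ``{"T": 0}`` for data without photophysics).  The
    triplet lifetime is bounded above (default 100 μs) to keep the triplet
    term from exchanging with slow diffusion.  Two-component fits enforce
    ``tau2 > tau1`` via a ratio parameter and are flagged
    ``"poorly_separated"`` when ``tau2/tau1 < 3``.

    ``fit_offset`` adds a free additive baseline: correlation estimates
    from finite traces sit below the true curve by a near-constant offset
    of order ``2 \\int G \\, d\\tau / T`` (the empirical means in the
    normalization are themselves correlated with the signal), and a free
    baseline absorbs it.  Set ``fit_offset=False`` to fit the bare model.
    """
    if model not in ("one", "two"):
        raise ValueError("model must be 'one' or 'two'")
    n_free = {"one": 4, "two": 6}[model]
    if len(curve.lags) < 3 * n_free:
        raise ValueError("need at least 3x more lag points than free parameters")
    init = dict(init or {})
    fix = dict(fix or {})
    bounds = dict(bounds or {})

    tau_guess = init.get("tau1", _initial_tau(curve))
    g0_guess = init.get("G0", max(float(np.max(curve.G)), 1e-6))
    lag_min, lag_max = curve.lags[0], curve.lags[-1]

    p = lmfit.Parameters()
    p.add("G0", value=g0_guess, min=0.0)
    p.add("offset", value=0.0, vary=fit_offset)
    p.add("T", value=init.get("T", 0.1), min=0.0, max=0.8)
    p.add("Tt", value=init.get("Tt", 5e-6), min=lag_min / 10, max=max_triplet_lifetime)
    if model == "one":
        p.add("tau1", value=tau_guess, min=lag_min / 10, max=lag_max * 10)
    else:
        p.add(
            "tau1",
            value=init.get("tau1", tau_guess / 10),
            min=lag_min / 10,
            max=lag_max * 10,
        )
        ratio0 = init.get("tau_ratio", max(init.get("tau2", tau_guess * 10) / p["tau1"].value, 1.0))
        p.add("tau_ratio", value=ratio0, min=1.0, max=1e7)
        p.add("tau2", expr="tau1 * tau_ratio")
        p.add("A", value=init.get("A", 0.5), min=0.0, max=1.0)
    for name, (lo, hi) in bounds.items():
        p[name].min, p[name].max = lo, hi
    for name, val in fix.items():
        p[name].value = val
        p[name].vary = False
        if name == "T" and val == 0:
            p["Tt"].vary = False

    if curve.sem is not None and np.any(curve.sem > 0):
        w = np.where(curve.sem > 0, 1.0 / np.where(curve.sem > 0, curve.sem, 1.0), 0.0)
        w[w == 0] = np.median(w[w > 0])
    else:
        w = np.ones_like(curve.G)

    def resid(params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        g = eval_fcs_model(
            curve.lags,
            model,
            G0=v["G0"],
            T=v["T"],
            Tt=v["Tt"],
            tau1=v["tau1"],
            tau2=v.get("tau2"),
            A=v.get("A", 1.0),
            kappa=kappa,
        )
        return (g + v["offset"] - curve.G) * w

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    params = {
        "G0": v["G0"],
        "offset": v["offset"],
        "T": v["T"],
        "Tt": v["Tt"],
        "tau1": v["tau1"],
        "kappa": kappa,
    }
    stderr = {k: (out.params[k].stderr if k in out.params else None) for k in params}
    flags: list[str] = []
    if model == "two":
        params["tau2"] = v["tau2"]
        params["A"] = v["A"]
        stderr["tau2"] = out.params["tau2"].stderr
        stderr["A"] = out.params["A"].stderr
        if v["tau_ratio"] < 3:
            flags.append("poorly_separated")
    if not out.success:
        flags.append("non_convergent")
    residuals = resid(out.params) / w
    return FCSFitResult(
        model=model,
        params=params,
        stderr=stderr,
        success=bool(out.success),
        redchi=float(out.redchi),
        residuals=residuals,
        lags=curve.lags.copy(),
        flags=flags,
    )


def _smooth(x: np.ndarray, half_width: int = 2) -> np.ndarray:
    k = 2 * half_width + 1
    return np.convolve(x, np.ones(k) / k, mode="same")


def compare_models(
    curve: CorrelationCurve, *, kappa: float = DEFAULT_KAPPA, fix: dict | None = None
) -> dict:
    """One- vs two-component adequacy report for a correlation curve.

    Fits both models and measures the structure of the one-component
    residuals against the noise floor estimated from the two-component fit:
    ``residual_excess`` is max |boxcar-smoothed one-component residual|
    divided by 3x the robust SD of the two-component residuals.  A value
    above 1 means the one-component residuals leave the noise band, i.e. a
    second diffusive component is required.
    """
    fit1 = fit_fcs(curve, "one", kappa=kappa, fix=fix)
    fit2 = fit_fcs(curve, "two", kappa=kappa, fix=fix)
    noise = 1.4826 * float(np.median(np.abs(fit2.residuals - np.median(fit2.residuals))))
    noise = max(noise, 1e-12)
    excess = float(np.max(np.abs(_smooth(fit1.residuals)))) / (3.0 * noise)
    return {
        "one": fit1,
        "two": fit2,
        "residual_excess": excess,
        "two_component_preferred": excess > 1.0,
    }


def calibrate_waist(tau: float, d: float) -> float:
    """Lateral waist from a known diffusion time and coefficient: w = sqrt(4 D tau)."""
    if tau <= 0 or d <= 0:
        raise ValueError("tau and D must be positive")
    return math.sqrt(4.0 * d * tau)


def diffusion_time_to_coefficient(tau: float, volume: FocalVolume) -> float:
    """D = w^2 / (4 tau), with tau in seconds and D in μm²/s."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return volume.waist**2 / (4.0 * tau)


def estimate_concentration(G0: float, T: float, volume: FocalVolume) -> float:
    """Apparent molar concentration from a fitted amplitude.

    The triplet-corrected mean occupancy is <N> = (1 - T)/G0; dividing by
    Avogadro's number times the effective volume gives molarity.
    """
    if G0 <= 0:
        raise ValueError("G0 must be positive")
    n_mean = (1.0 - T) / G0
    return n_mean / (AVOGADRO * volume.effective_volume_l)


@dataclass
class FCCSResult:
    """Dual-color amplitude ratios and derived bound fractions."""

    G0_auto_a: float
    G0_auto_b: float
    G0_cross: float
    bound_fraction_a: float  # clipped to [0, 1]
    bound_fraction_b: float
    bound_fraction_a_raw: float
    bound_fraction_b_raw: float
    se_a: float | None = None
    se_b: float | None = None


def fccs_bound_fraction(
    auto_a: FCSFitResult, auto_b: FCSFitResult, cross: FCSFitResult
) -> FCCSResult:
    """Bound fractions from FCCS amplitudes.

    For species A and B with double-labeled complexes AB,
    ``G0_cross/G0_auto_b = C_AB/C_A`` (the bound fraction of A) and
    symmetrically for B.  Standard errors are propagated from the amplitude
    SEs in quadrature on the relative scale.
    """
    for f in (auto_a, auto_b, cross):
        if not f.success:
            raise ValueError("all three fits must have converged")
    ga, gb, gx = auto_a.G0, auto_b.G0, cross.G0
    if ga <= 0 or gb <= 0:
        raise ValueError("auto-correlation amplitudes must be positive")
    bf_a = gx / gb
    bf_b = gx / ga

    def _prop(num: FCSFitResult, den: FCSFitResult, value: float) -> float | None:
        # se of value = num.G0/den.G0, valid also at num.G0 = 0
        sn, sd = num.stderr.get("G0"), den.stderr.get("G0")
        if sn is None or sd is None:
            return None
        return math.sqrt((sn / den.G0) ** 2 + (value * sd / den.G0) ** 2)

    return FCCSResult(
        G0_auto_a=ga,
        G0_auto_b=gb,
        G0_cross=gx,
        bound_fraction_a=float(np.clip(bf_a, 0.0, 1.0)),
        bound_fraction_b=float(np.clip(bf_b, 0.0, 1.0)),
        bound_fraction_a_raw=bf_a,
        bound_fraction_b_raw=bf_b,
        se_a=_prop(cross, auto_b, bf_a),
        se_b=_prop(cross, auto_a, bf_b),
    )
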