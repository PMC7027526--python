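"""Spectral features: estimation from spectra and prediction from geometry.

A diffusion spectrum is summarized by its height D_hi (high-frequency
plateau), width f_half (lowest frequency where D crosses D_hi/2), a
single-Lorentzian fit L(f) = D_hi f^2/(f_half^2 + f^2), and its low-frequency
power-law exponent p (D ~ c f^p).

Theory predicts, with D0 the bulk diffusivity:

* height:  D_hi = muOD * D0 (thin fibers), D0 (cylinders);
* width:   f_half = k_c D0/d^2 (cylinder), k_h D0 muOD / a^2 (1-harmonic),
           the D_hi-weighted average of member widths (n-harmonic), and
           k_s (D0/a_max^2) <muOD(x)^2>/<muOD> (stochastic);
* diameter bias: matching the f^2 expansions of the cylinder and 1-harmonic
  spectra gives the apparent diameter d = sqrt(k_c/k_h) * a * muOD^(-1/4).

k_c is exact (dspec_analytic); k_h and k_s are calibrated on simulated
substrate grids by a through-origin regression of estimated widths on the
k=1 predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dspec_analytic import KC
from .dspec_sim import DiffusionSpectrum

__all__ = [
    "SpectralFeatures",
    "K_H",
    "K_S",
    "estimate_height",
    "estimate_width",
    "predict_height",
    "predict_width",
    "fit_lorentzian",
    "lorentzian",
    "fit_power_exponent",
    "derivative_exponent",
    "calibrate_width_constant",
]

#: 1-harmonic (and n-harmonic) width constant, calibrated on the 15-substrate
#: grid (a in {1,2,3} um x lambda in {10..50} um); the small-amplitude limit
#: is 1/pi ~ 0.318.
K_H = 0.34

#: Stochastic-case width constant (local-feature average predictor).
K_S = 0.13

#: Plateau estimation band, Hz.
_HI_BAND = (900.0, 1000.0)


@dataclass
class SpectralFeatures:
    """Feature bundle for one spectrum."""

    D_hi: float
    f_half: float
    lorentzian_fit: tuple = (np.nan, np.nan)  # (D_hi_fit, f_half_fit)
    p_fit: float = np.nan
    p_prefactor: float = np.nan
    metadata: dict = field(default_factory=dict)


def estimate_height(spectrum: DiffusionSpectrum) -> float:
    """Spectral height: mean of D(f) over the 900-1000 Hz band."""
    f = spectrum.frequencies
    if f[-1] < _HI_BAND[1]:
        raise ValueError(f"spectrum must extend to {_HI_BAND[1]:.0f} Hz (got {f[-1]:.0f})")
    mask = (f >= _HI_BAND[0]) & (f <= _HI_BAND[1])
    return float(spectrum.values[mask].mean())


def estimate_width(spectrum: DiffusionSpectrum, D_hi: float | None = None) -> float:
    """Spectral width: lowest frequency where D(f) crosses D_hi/2 (first
    upward crossing, linearly interpolated)."""
    if D_hi is None:
        D_hi = estimate_height(spectrum)
    if D_hi <= 0:
        raise ValueError("D_hi must be positive")
    half = D_hi / 2.0
    v = spectrum.values
    above = np.nonzero(v >= half)[0]
    above = above[above > 0]
    if len(above) == 0:
        raise ValueError("spectrum never reaches half of the spectral height")
    j = int(above[0])
    f = spectrum.frequencies
    return float(f[j - 1] + (half - v[j - 1]) * (f[j] - f[j - 1]) / (v[j] - v[j - 1]))


def predict_height(mu_od, D0: float) -> float:
    """D_hi = muOD * D0; for an ensemble, the mean over members."""
    mu = np.atleast_1d(np.asarray(mu_od, dtype=float))
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("muOD must lie in [0, 1]")
    return float(np.mean(mu) * D0)


def predict_width(case: str, **params) -> float:
    """Predicted spectral width in Hz for one of the model cases.

    cylinder:   d, D0                      -> k_c D0/d^2
    harmonic:   a, mu_od, D0               -> k_h D0 muOD/a^2
    n_harmonic: a_list, mu_od_list, D0     -> D_hi-weighted mean of members
    stochastic: a_max, mu_od_profile, D0   -> k_s (D0/a_max^2) <muOD^2>/<muOD>

    Constants k_c/k_h/k_s can be overridden via keyword.
    """

    def need(*names):
        missing = [n for n in names if n not in params]
        if missing:
            raise ValueError(f"case {case!r} requires parameters {missing}")
        return [params[n] for n in names]

    khz_to_hz = 1e3
    if case == "cylinder":
        d, D0 = need("d", "D0")
        kc = params.get("k_c", KC)
        return kc * D0 / d**2 * khz_to_hz
    if case == "harmonic":
        a, mu, D0 = need("a", "mu_od", "D0")
        kh = params.get("k_h", K_H)
        return kh * D0 * mu / a**2 * khz_to_hz
    if case == "n_harmonic":
        a_list, mu_list, D0 = need("a_list", "mu_od_list", "D0")
        kh = params.get("k_h", K_H)
        a_arr = np.asarray(a_list, dtype=float)
        mu_arr = np.asarray(mu_list, dtype=float)
        heights = mu_arr * D0
        widths = kh * D0 * mu_arr / a_arr**2 * khz_to_hz
        return float(np.sum(heights * widths) / np.sum(heights))
    if case == "stochastic":
        a_max, profile, D0 = need("a_max", "mu_od_profile", "D0")
        ks = params.get("k_s", K_S)
        profile = np.asarray(profile, dtype=float)
        mu = profile.mean()
        if mu == 0:
            raise ValueError("straight fiber has no spectral width")
        return ks * D0 / a_max**2 * float(np.mean(profile**2) / mu) * khz_to_hz
    raise ValueError(f"unknown case {case!r}")


def lorentzian(f, D_hi, f_half):
    """Single-Lorentzian spectrum L(f) = D_hi f^2/(f_half^2 + f^2)."""
    return D_hi * f**2 / (f_half**2 + f**2)


def fit_lorentzian(spectrum: DiffusionSpectrum) -> tuple[float, float]:
    """Least-squares single-Lorentzian fit on the spectrum's grid,
    initialized from the estimated height and width; deterministic."""
    f = spectrum.frequencies
    v = spectrum.values
    d0 = estimate_height(spectrum)
    w0 = estimate_width(spectrum, d0)
    n_below = np.count_nonzero(f < w0)
    n_above = np.count_nonzero(f > w0)
    if len(f) < 10 or n_below < 1 or n_above < 1:
        raise ValueError("need >= 10 points spanning both sides of the half height")
    try:
        popt, _ = optimize.curve_fit(lorentzian, f, v, p0=(d0, w0), maxfev=10_000)
    except RuntimeError as err:
        resid = float(np.sum((lorentzian(f, d0, w0) - v) ** 2))
        raise RuntimeError(f"Lorentzian fit did not converge (residual at init {resid:.3e})") from err
    d_fit, w_fit = float(popt[0]), float(abs(popt[1]))
    return d_fit, w_fit


def fit_power_exponent(
    spectrum: DiffusionSpectrum, f_max_cap_hz: float = 20.0, f_half: float | None = None
) -> tuple[float, float]:
    """Low-frequency power-law fit D(f) ~ c f^p over grid frequencies in
    (0, min(f_half, f_max_cap)]; returns (p_fit, c)."""
    if f_half is None:
        f_half = estimate_width(spectrum)
    f = spectrum.frequencies
    v = spectrum.values
    f_hi = min(f_half, f_max_cap_hz)
    mask = (f > 0) & (f <= f_hi) & (v > 0)
    if np.count_nonzero(mask) < 4:
        raise ValueError(
            f"fewer than 4 usable grid points in (0, {f_hi:.2f}] Hz for the power-law fit"
        )
    slope, intercept = np.polyfit(np.log(f[mask]), np.log(v[mask]), 1)
    return float(slope), float(np.exp(intercept))


def derivative_exponent(spectrum: DiffusionSpectrum, D_hi: float | None = None):
    """Running exponent p(f) = d log(D/D_hi) / d log f by centered finite
    differences; points with non-positive D are masked (NaN)."""
    if D_hi is None:
        D_hi = estimate_height(spectrum)
    f = spectrum.frequencies
    v = spectrum.values
    ok = (f > 0) & (v > 0)
    logf = np.full_like(f, np.nan)
    logd = np.full_like(f, np.nan)
    logf[ok] = np.log(f[ok])
    logd[ok] = np.log(v[ok] / D_hi)
    p = np.full_like(f, np.nan)
    p[1:-1] = (logd[2:] - logd[:-2]) / (logf[2:] - logf[:-2])
    p[~ok] = np.nan  # masked points, not interpolated across
    return f, p


def calibrate_width_constant(predictors_hz, estimated_widths_hz, corr_warn: float = 0.9):
    """Through-origin least-squares slope of estimated widths against the
    k = 1 predictor; returns (k, pearson_r).  The theory has no intercept,
    hence the through-origin form."""
    x = np.asarray(predictors_hz, dtype=float)
    y = np.asarray(estimated_widths_hz, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 substrates for a calibration")
    k = float(np.dot(x, y) / np.dot(x, x))
    r = float(np.corrcoef(x, y)[0, 1])
    if r < corr_warn:
        import warnings

        warnings.warn(f"width calibration correlation {r:.3f} below {corr_warn}", stacklevel=2)
    return k, r
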