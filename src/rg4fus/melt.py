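"""CD spectrum preprocessing and the two-state van't Hoff melt fit.

Spectra (ellipticity in mdeg vs wavelength or temperature) are buffer-
subtracted and smoothed with a means-movement (centered moving-average)
filter. Melts recorded at a single wavelength are fitted to a two-state
unfolding model with sloping folded/unfolded baselines: with X in Kelvin and

    Q = exp((dH/R) * (1/Tm - 1/X))

the observed signal is the population-weighted baseline average

    Y = [(m_f*X + b_f) + (m_u*X + b_u)*Q] / (1 + Q),

so the fraction unfolded Q/(1+Q) is exactly 1/2 at X = Tm. dH is the van't
Hoff unfolding enthalpy (J/mol, > 0) and R = 8.314 J/(mol*K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["Spectrum", "MeltModel", "MeltFitResult", "subtract_blank",
           "means_movement_smooth", "melt_model", "fit_melt",
           "is_parallel_g4"]

R_GAS = 8.314  # J / (mol K)
_KELVIN = 273.15


@dataclass(frozen=True)
class Spectrum:
    """X/Y series (wavelength nm or temperature C vs ellipticity mdeg)."""

    x: np.ndarray
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class MeltModel:
    """Two-state melt parameters; Tm stored in Celsius, dH in J/mol."""

    m_folded: float      # mdeg/K
    b_folded: float      # mdeg
    m_unfolded: float
    b_unfolded: float
    t_m: float           # Celsius
    delta_h: float       # J/mol, > 0

    def __post_init__(self) -> None:
        if self.delta_h <= 0:
            raise ValueError("delta_h must be positive (endothermic unfolding)")


@dataclass(frozen=True)
class MeltFitResult:
    model: MeltModel
    converged: bool
    residual_norm: float
    stderr: dict[str, float]
    message: str = ""


def subtract_blank(spec: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise buffer subtraction; X grids must match to 1e-9."""
    if spec.x.shape != blank.x.shape or not np.allclose(
            spec.x, blank.x, atol=1e-9, rtol=0):
        raise ValueError("spectrum and blank are on different X grids")
    return Spectrum(spec.x, spec.y - blank.y, dict(spec.metadata))


def means_movement_smooth(spec: Spectrum, width: int = 15) -> Spectrum:
    """Means-movement smoothing: centered moving average over ``width`` points.

    At the edges the window shrinks symmetrically to the largest centered
    window that fits, so no padding values are invented. X is unchanged.
    """
    if width % 2 == 0:
        raise ValueError("width must be odd")
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(spec.y)
    if width > 1 and n < 2 * width:
        raise ValueError("series too short for the smoothing width")
    half = width // 2
    y = spec.y
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = y[i - k: i + k + 1].mean()
    return Spectrum(spec.x, out, dict(spec.metadata))


def melt_model(x_celsius, model: MeltModel) -> np.ndarray:
    """Evaluate the two-state melt model at temperature(s) in Celsius."""
    x = np.asarray(x_celsius, dtype=float) + _KELVIN
    tm = model.t_m + _KELVIN
    q = np.exp((model.delta_h / R_GAS) * (1.0 / tm - 1.0 / x))
    folded = model.m_folded * x + model.b_folded
    unfolded = model.m_unfolded * x + model.b_unfolded
    return (folded + unfolded * q) / (1.0 + q)


def _baseline_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2:
        return 0.0, float(y.mean())
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_melt(spec: Spectrum, init: MeltModel | None = None,
             smooth_width: int = 15) -> MeltFitResult:
    """Least-squares fit of the two-state melt model to a melt curve.

    X is temperature in Celsius. Default initialization: Tm at the
    temperature of steepest change of the smoothed curve, dH = 150 kJ/mol,
    baselines from straight-line fits to the first and last 20% of points.
    Curves with no resolvable transition are returned converged=False.
    """
    x_c, y = spec.x, spec.y
    if len(x_c) < 20:
        raise ValueError("melt fit requires at least 20 temperature points")
    x_k = x_c + _KELVIN

    if init is None:
        sm = means_movement_smooth(spec, smooth_width) if len(y) >= 2 * smooth_width else spec
        dy = np.gradient(sm.y, x_c)
        tm0_c = float(x_c[np.argmax(np.abs(dy))])
        n20 = max(2, len(x_c) // 5)
        mf0, bf0 = _baseline_fit(x_k[:n20], y[:n20])
        mu0, bu0 = _baseline_fit(x_k[-n20:], y[-n20:])
        dh0 = 150e3
    else:
        tm0_c = init.t_m
        mf0, bf0 = init.m_folded, init.b_folded
        mu0, bu0 = init.m_unfolded, init.b_unfolded
        dh0 = init.delta_h

    def f(xc, mf, bf, mu, bu, tm_c, dh):
        return melt_model(xc, MeltModel(mf, bf, mu, bu, tm_c, dh))

    names = ["m_folded", "b_folded", "m_unfolded", "b_unfolded", "t_m",
             "delta_h"]
    p0 = [mf0, bf0, mu0, bu0, tm0_c, dh0]
    # Tm constrained to the data range +/- 20 K; dH positive
    lo = [-np.inf, -np.inf, -np.inf, -np.inf, x_c.min() - 20.0, 1.0]
    hi = [np.inf, np.inf, np.inf, np.inf, x_c.max() + 20.0, np.inf]
    p0 = np.clip(p0, lo, hi)

    try:
        popt, pcov = curve_fit(f, x_c, y, p0=p0, bounds=(lo, hi),
                               xtol=1e-10, ftol=1e-10, maxfev=20_000)
        converged = True
        message = ""
    except RuntimeError as exc:
        popt, pcov = np.array(p0), np.full((6, 6), np.nan)
        converged = False
        message = str(exc)

    model = MeltModel(*popt)
    resid = y - melt_model(x_c, model)
    with np.errstate(invalid="ignore"):
        stderr = dict(zip(names, np.sqrt(np.diag(pcov))))
    # a transition pinned to the edge of the allowed range signals no sigmoid
    if converged and not (x_c.min() - 19.9 < model.t_m < x_c.max() + 19.9):
        converged = False
        message = "Tm at bound: no resolvable transition"
    if converged:
        amplitude = abs((model.m_unfolded - model.m_folded) * (model.t_m + _KELVIN)
                        + model.b_unfolded - model.b_folded)
        noise = float(np.std(resid))
        floor = max(3 * noise, 1e-3 * float(np.ptp(y)))
        if amplitude < floor:
            converged = False
            message = "transition amplitude indistinguishable from noise"
    return MeltFitResult(model, converged, float(np.linalg.norm(resid)),
                         stderr, message)


def is_parallel_g4(spec: Spectrum, window_nm: float = 5.0) -> bool:
    """Qualitative parallel-G4 call from a CD spectrum.

    True when the (smoothed, buffer-subtracted) spectrum shows a positive
    band at 265 +/- window nm and a negative band at 240 +/- window nm — the
    signature of a parallel G-quadruplex.
    """
    x, y = spec.x, spec.y
    pos = y[(x >= 265 - window_nm) & (x <= 265 + window_nm)]
    neg = y[(x >= 240 - window_nm) & (x <= 240 + window_nm)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("spectrum does not cover the 240/265 nm bands")
    return bool(pos.max() > 0 and neg.min() < 0)
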