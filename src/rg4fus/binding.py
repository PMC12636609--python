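"""Fluorescence-anisotropy binding isotherm and its least-squares fit.

The model is the quadratic ligand-depletion isotherm: with total protein x
(nM), total labeled RNA Lt (nM, held at 8 nM in the titrations this package
targets) and dissociation constant Kd (nM), the bound fraction is the exact
root of the binding quadratic, and the anisotropy signal is

    y = a0 + dAmax * [(x + Lt + Kd) - sqrt((x + Lt + Kd)^2 - 4*x*Lt)] / (2*Lt)

where dAmax is the baseline-subtracted anisotropy amplitude and a0 an
optional baseline offset (0 for pre-subtracted data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BindingModel", "BindingFitResult", "binding_model", "fit_binding"]


@dataclass(frozen=True)
class BindingModel:
    """Parameters of the ligand-depletion isotherm."""

    delta_a_max: float
    k_d: float          # nM
    l_t: float = 8.0    # nM, total labeled RNA
    a0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("k_d must be positive")
        if self.l_t <= 0:
            raise ValueError("l_t must be positive")


@dataclass(frozen=True)
class BindingFitResult:
    model: BindingModel
    converged: bool
    residual_norm: float
    stderr: dict[str, float]
    message: str = ""


def binding_model(x, model: BindingModel) -> np.ndarray:
    """Evaluate the isotherm at total protein concentration(s) x (nM)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("protein concentration must be non-negative")
    s = x + model.l_t + model.k_d
    disc = s * s - 4.0 * x * model.l_t
    if np.any(disc < 0):
        raise ValueError("negative discriminant: invalid parameters")
    bound_fraction = (s - np.sqrt(disc)) / (2.0 * model.l_t)
    return model.a0 + model.delta_a_max * bound_fraction


def fit_binding(x, y, l_t: float = 8.0, fit_offset: bool = True
                ) -> BindingFitResult:
    """Nonlinear least-squares fit of the binding isotherm to a titration.

    Replicate curves are fitted jointly by pooling their points before the
    call. Initial guesses: Kd at the x of half-maximal signal, dAmax as the
    signal span, a0 as the minimum; Kd and dAmax are constrained positive.
    A degenerate (flat) curve is returned with converged=False rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct protein concentrations")
    if l_t <= 0:
        raise ValueError("l_t must be positive")

    span = float(y.max() - y.min())
    y_half = y.min() + 0.5 * span
    order = np.argsort(x)
    kd0 = float(np.interp(y_half, y[order], x[order])) if span > 0 else 1.0
    kd0 = max(kd0, 1e-6)
    a00 = float(y.min())

    tiny = 1e-12
    if fit_offset:
        def f(xv, damax, kd, a0):
            return binding_model(xv, BindingModel(damax, kd, l_t, a0))
        p0 = [max(span, tiny), kd0, a00]
        bounds = ([tiny, tiny, -np.inf], [np.inf, np.inf, np.inf])
        names = ["delta_a_max", "k_d", "a0"]
    else:
        def f(xv, damax, kd):
            return binding_model(xv, BindingModel(damax, kd, l_t, 0.0))
        p0 = [max(span, tiny), kd0]
        bounds = ([tiny, tiny], [np.inf, np.inf])
        names = ["delta_a_max", "k_d"]

    try:
        popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds,
                               xtol=1e-10, ftol=1e-10, maxfev=10_000)
        converged = True
        message = ""
    except RuntimeError as exc:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
        message = str(exc)

    params = dict(zip(names, popt))
    model = BindingModel(params["delta_a_max"], params["k_d"], l_t,
                         params.get("a0", 0.0))
    resid = y - binding_model(x, model)
    with np.errstate(invalid="ignore"):
        stderr = dict(zip(names, np.sqrt(np.diag(pcov))))
    # an essentially flat curve carries no binding signal
    if converged and model.delta_a_max < 1e-8:
        converged = False
        message = "amplitude collapsed to zero (flat curve?)"
    return BindingFitResult(model, converged, float(np.linalg.norm(resid)),
                            stderr, message)
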