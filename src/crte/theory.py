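"""Exact CRTE/DCRTE values and asymptotic constants for reference models.

The cumulative residual Tsallis entropy of order ``alpha`` is

    eta_alpha(X) = (1/(alpha-1)) * (1 - int_0^inf Fbar(x)**alpha dx),

and its dynamic version conditions on survival past ``t``:

    eta_alpha(X; t) = (1/(alpha-1)) * (1 - int_t^inf (Fbar(x)/Fbar(t))**alpha dx).

For the exponential law with rate ``lam`` the CRTE has the closed form
``(lam*alpha - 1) / (lam*alpha*(alpha-1))`` and, by memorylessness, the
dynamic version equals it for every ``t``.  For Uniform(0, b) the residual
lifetime past ``t`` is Uniform(0, b-t), giving a second analytic oracle.
The Weibull model exercises the numeric quadrature path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np
from scipy import integrate, stats

__all__ = [
    "TheoryModel",
    "exponential_model",
    "uniform_model",
    "weibull_model",
    "get_model",
    "crte_exact",
    "dcrte_exact",
    "sigma_eta_sq_exact",
    "sigma_eta_x_sq_exact",
]


@dataclass(frozen=True)
class TheoryModel:
    """A named lifetime distribution with the derivatives the asymptotic
    bias/variance formulas need.

    ``pdf2`` is the second derivative of the density; for models without
    an analytic form it is supplied by central differences of the pdf.
    """

    name: str
    parameters: Dict[str, float]
    pdf: Callable[[np.ndarray], np.ndarray]
    pdf2: Callable[[np.ndarray], np.ndarray]
    sf: Callable[[np.ndarray], np.ndarray]
    ppf: Callable[[np.ndarray], np.ndarray]
    support: Tuple[float, float]
    rv: object = field(default=None, repr=False)

    @property
    def upper(self) -> float:
        return self.support[1]


def exponential_model(lam: float = 1.0) -> TheoryModel:
    """Exponential distribution with rate ``lam`` (mean ``1/lam``)."""
    if lam <= 0:
        raise ValueError(f"rate must be positive, got {lam}")
    rv = stats.expon(scale=1.0 / lam)
    return TheoryModel(
        name="exponential",
        parameters={"lam": lam},
        pdf=rv.pdf,
        pdf2=lambda x: lam ** 3 * np.exp(-lam * np.asarray(x, dtype=float))
        * (np.asarray(x, dtype=float) >= 0),
        sf=rv.sf,
        ppf=rv.ppf,
        support=(0.0, math.inf),
        rv=rv,
    )


def uniform_model(b: float = 1.0) -> TheoryModel:
    """Uniform distribution on (0, b)."""
    if b <= 0:
        raise ValueError(f"upper endpoint must be positive, got {b}")
    rv = stats.uniform(loc=0.0, scale=b)
    zero2 = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    return TheoryModel(
        name="uniform",
        parameters={"b": b},
        pdf=rv.pdf,
        pdf2=zero2,  # density is flat on the interior of the support
        sf=rv.sf,
        ppf=rv.ppf,
        support=(0.0, b),
        rv=rv,
    )


def weibull_model(k: float = 1.5, scale: float = 1.0) -> TheoryModel:
    """Weibull distribution with shape ``k`` and the given scale.

    The second derivative of the density is obtained by central
    differences; this model is the numeric-only reference.
    """
    if k <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    rv = stats.weibull_min(k, scale=scale)

    def pdf2(x, h=1e-4 * scale):
        x = np.asarray(x, dtype=float)
        return (rv.pdf(x + h) - 2.0 * rv.pdf(x) + rv.pdf(x - h)) / (h * h)

    return TheoryModel(
        name="weibull",
        parameters={"k": k, "scale": scale},
        pdf=rv.pdf,
        pdf2=pdf2,
        sf=rv.sf,
        ppf=rv.ppf,
        support=(0.0, math.inf),
        rv=rv,
    )


def get_model(name: str, **params: float) -> TheoryModel:
    """Build a reference model by name: exponential, uniform or weibull."""
    factories = {
        "exponential": exponential_model,
        "uniform": uniform_model,
        "weibull": weibull_model,
    }
    try:
        return factories[name](**params)
    except KeyError:
        raise KeyError(
            f"unknown model '{name}'; available: {sorted(factories)}"
        ) from None


def _sf_power_integral(model: TheoryModel, power: float, lower: float) -> float:
    """Quadrature of ``int_lower^upper Fbar(x)**power dx``."""
    upper = model.upper
    if math.isinf(upper):
        value, _ = integrate.quad(
            lambda x: model.sf(x) ** power, lower, math.inf, limit=400)
    else:
        value, _ = integrate.quad(
            lambda x: model.sf(x) ** power, lower, upper, limit=400)
    if not math.isfinite(value):
        raise ArithmeticError(
            f"int Fbar^{power} diverges for model '{model.name}'"
        )
    return value


def crte_exact(model: TheoryModel, alpha: float) -> float:
    """Exact CRTE of order ``alpha``; closed form where known."""
    _check_alpha(alpha)
    if model.name == "exponential":
        lam = model.parameters["lam"]
        return (lam * alpha - 1.0) / (lam * alpha * (alpha - 1.0))
    if model.name == "uniform":
        b = model.parameters["b"]
        return (1.0 / (alpha - 1.0)) * (1.0 - b / (alpha + 1.0))
    integral = _sf_power_integral(model, alpha, model.support[0])
    return (1.0 / (alpha - 1.0)) * (1.0 - integral)


def dcrte_exact(model: TheoryModel, alpha: float, t: float) -> float:
    """Exact dynamic CRTE at age ``t``."""
    _check_alpha(alpha)
    sft = float(model.sf(t))
    if sft <= 0.0:
        raise ValueError(
            f"survival at t={t} is zero for model '{model.name}': the "
            "residual lifetime is undefined"
        )
    if model.name == "exponential":
        # memorylessness: residual lifetime has the same law for every t
        return crte_exact(model, alpha)
    if model.name == "uniform":
        b = model.parameters["b"]
        t = max(t, 0.0)
        return (1.0 / (alpha - 1.0)) * (1.0 - (b - t) / (alpha + 1.0))
    integral = _sf_power_integral(model, alpha, max(t, model.support[0]))
    return (1.0 / (alpha - 1.0)) * (1.0 - integral / sft ** alpha)


def sigma_eta_sq_exact(model: TheoryModel, alpha: float, kernel_CK: float,
                       beta_half: float) -> float:
    """Asymptotic variance constant of the standardized CRTE estimator.

    ``sigma_eta^2 = alpha^2 * CK * int_0^inf Fbar^(2*alpha-1) dx
                    / ((alpha-1)^2 * beta_{0.5}^2)``;
    exponential closed form
    ``alpha^2 * CK / ((alpha-1)^2 * beta_{0.5}^2 * lam * (2*alpha-1))``.
    """
    _check_alpha(alpha, require_variance=True)
    front = alpha ** 2 * kernel_CK / ((alpha - 1.0) ** 2 * beta_half ** 2)
    if model.name == "exponential":
        lam = model.parameters["lam"]
        return front / (lam * (2.0 * alpha - 1.0))
    return front * _sf_power_integral(model, 2.0 * alpha - 1.0, model.support[0])


def sigma_eta_x_sq_exact(model: TheoryModel, alpha: float, t: float,
                         kernel_CK: float, beta_half: float) -> float:
    """Asymptotic variance constant of the standardized DCRTE estimator at ``t``.

    ``sigma_eta_x^2 = alpha^2 * CK * [I_{2a-1}(t) + I_a(t)^2 * Fbar(t)]
                      / ((alpha-1)^2 * beta_{0.5}^2 * Fbar(t)^(2*alpha))``
    with ``I_p(t) = int_t^inf Fbar^p dx``.
    """
    _check_alpha(alpha, require_variance=True)
    sft = float(model.sf(t))
    if sft <= 0.0:
        raise ValueError(f"survival at t={t} is zero for model '{model.name}'")
    lower = max(t, model.support[0])
    i_2am1 = _sf_power_integral(model, 2.0 * alpha - 1.0, lower)
    i_a = _sf_power_integral(model, alpha, lower)
    front = alpha ** 2 * kernel_CK / ((alpha - 1.0) ** 2 * beta_half ** 2)
    return front * (i_2am1 + i_a ** 2 * sft) / sft ** (2.0 * alpha)


def _check_alpha(alpha: float, *, require_variance: bool = False) -> None:
    if alpha <= 0 or alpha == 1.0:
        raise ValueError(f"alpha must be positive and != 1, got {alpha}")
    if require_variance and alpha <= 0.5:
        raise ValueError(
            f"alpha={alpha}: the variance theory requires alpha > 1/2 "
            "(the tail integral int Fbar^(2*alpha-1) may diverge)"
        )
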