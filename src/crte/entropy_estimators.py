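"""CRTE and DCRTE kernel estimators with their asymptotic standard errors.

The point estimators plug the kernel survival estimate into the defining
integrals:

    etahat_alpha(X)    = (1/(alpha-1)) * (1 - int_0^inf Fbarhat^alpha dx)
    etahat_alpha(X; t) = (1/(alpha-1)) * (1 - Mhat_alpha(t) / Ahat_alpha(t))

with ``Mhat_alpha(t) = int_t^inf Fbarhat^alpha dx`` and
``Ahat_alpha(t) = Fbarhat(t)**alpha``.  The asymptotic variance theory
holds for ``alpha > 1/2`` (and ``alpha != 1``); point estimation is
allowed for smaller alpha, but standard errors are refused there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy import integrate

from .density_survival import DensityEstimate, Sample, SurvivalEstimate
from .kernels_bandwidths import (
    BandwidthSchedule,
    KernelSpec,
    beta_coefficient,
)
from .theory import TheoryModel

__all__ = [
    "EntropyConfig",
    "EntropyEstimate",
    "UnstableTailError",
    "crte_functional",
    "dcrte_functional",
    "crte_estimate",
    "dcrte_estimate",
    "crte_asymptotic_se",
    "dcrte_asymptotic_se",
    "entropy_bias_theory",
    "mse_theory",
]

SurvivalLike = Union[SurvivalEstimate, Callable[[np.ndarray], np.ndarray]]


class UnstableTailError(ValueError):
    """The DCRTE denominator Fbarhat(t)^alpha is too small to be trusted."""


@dataclass(frozen=True)
class EntropyConfig:
    """Settings shared by the CRTE/DCRTE estimators.

    alpha must be positive and different from 1.  Values at or below 1/2
    trigger a warning: point estimates remain well defined when the
    empirical tail integral converges, but the variance theory (and
    hence the standard error) requires alpha > 1/2.
    """

    alpha: float
    t: Optional[float] = None
    integration_tol: float = 1e-9
    grid_points: int = 2048
    upper_limit_rule: str = "auto"  # {"auto", "fixed"}
    upper_limit: Optional[float] = None
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha == 1.0:
            raise ValueError(f"alpha must be positive and != 1, got {self.alpha}")
        if self.alpha <= 0.5:
            warnings.warn(
                f"alpha={self.alpha} <= 1/2: the point estimate is computed "
                "but no standard error is available (variance theory needs "
                "alpha > 1/2)", UserWarning, stacklevel=2)
        if self.t is not None and self.t < 0:
            raise ValueError(f"t must be non-negative, got {self.t}")
        if self.upper_limit_rule not in ("auto", "fixed"):
            raise ValueError("upper_limit_rule must be 'auto' or 'fixed'")
        if self.upper_limit_rule == "fixed" and self.upper_limit is None:
            raise ValueError("upper_limit required when upper_limit_rule='fixed'")


@dataclass(frozen=True)
class EntropyEstimate:
    """A CRTE/DCRTE point estimate with its asymptotic standard error.

    ``components`` stores (Mhat_alpha(t), Ahat_alpha(t)) for the dynamic
    estimator so the value can be reconstructed as
    ``(1/(alpha-1)) * (1 - Mhat/Ahat)``.
    """

    value: float
    asymptotic_se: Optional[float]
    config: EntropyConfig
    n: int
    b_n: float
    components: Optional[Tuple[float, float]] = None


def _eval_survival(surv: SurvivalLike, t: np.ndarray) -> np.ndarray:
    if isinstance(surv, SurvivalEstimate):
        return surv.evaluate(t)
    return np.asarray(surv(t), dtype=float)


def _simpson_sf_power(surv: SurvivalLike, power: float, lower: float,
                      upper: float, grid_points: int) -> float:
    """Composite-Simpson integral of Fbar^power over [lower, upper]."""
    grid = np.linspace(lower, upper, grid_points + 1)
    vals = np.clip(_eval_survival(surv, grid), 0.0, None) ** power
    return float(integrate.simpson(vals, x=grid))


def _auto_upper(surv: SurvivalLike, alpha: float, start: float,
                tol: float) -> float:
    """Doubling upper-limit rule: extend while Fbar^alpha(U) * U > tol."""
    upper = max(start, 1.0)
    for _ in range(60):
        tail = float(np.clip(_eval_survival(surv, np.array([upper])), 0, None)[0])
        if tail ** alpha * upper <= tol:
            return upper
        upper *= 2.0
    return upper


def crte_functional(surv: SurvivalLike, alpha: float, *,
                    upper: float, grid_points: int = 2048) -> float:
    """CRTE of a survival curve: (1/(alpha-1)) * (1 - int_0^upper Fbar^alpha).

    Shared by the estimator (kernel survival curve) and oracle mode
    (exact model survival injected).
    """
    integral = _simpson_sf_power(surv, alpha, 0.0, upper, grid_points)
    return (1.0 / (alpha - 1.0)) * (1.0 - integral)


def dcrte_functional(surv: SurvivalLike, alpha: float, t: float, *,
                     upper: float, grid_points: int = 2048
                     ) -> Tuple[float, float, float]:
    """Dynamic CRTE of a survival curve at age ``t``.

    Returns ``(value, M_alpha(t), A_alpha(t))`` where
    ``M_alpha(t) = int_t^upper Fbar^alpha`` and ``A_alpha(t) = Fbar(t)^alpha``.
    """
    m_hat = _simpson_sf_power(surv, alpha, t, upper, grid_points)
    sft = float(np.clip(_eval_survival(surv, np.array([t])), 0.0, None)[0])
    a_hat = sft ** alpha
    value = (1.0 / (alpha - 1.0)) * (1.0 - m_hat / a_hat)
    return value, m_hat, a_hat


def _build_survival(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
                    renormalize: bool = False) -> SurvivalEstimate:
    sample.require_nonnegative()
    dens = DensityEstimate(sample=sample, kernel=K, bandwidths=bw)
    return SurvivalEstimate(density=dens, renormalize=renormalize)


def _resolve_upper(cfg: EntropyConfig, surv: SurvivalLike,
                   sample: Sample, bw: BandwidthSchedule) -> float:
    if cfg.upper_limit_rule == "fixed":
        return float(cfg.upper_limit)
    start = float(sample.observations.max()) + 8.0 * float(bw.values[0])
    return _auto_upper(surv, cfg.alpha, start, cfg.integration_tol)


def crte_estimate(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
                  cfg: EntropyConfig, *, renormalize: bool = False
                  ) -> EntropyEstimate:
    """Kernel estimate of the CRTE of order ``cfg.alpha``.

    The integral of Fbarhat^alpha is computed by composite Simpson
    quadrature on ``cfg.grid_points`` panels up to an automatically
    extended upper limit.  When ``cfg.compute_se`` and alpha > 1/2, the
    plug-in asymptotic standard error (kernel survival substituted into
    the variance integral) is attached.
    """
    surv = _build_survival(sample, K, bw, renormalize)
    upper = _resolve_upper(cfg, surv, sample, bw)
    value = crte_functional(surv, cfg.alpha, upper=upper,
                            grid_points=cfg.grid_points)
    if not math.isfinite(value):
        raise ArithmeticError(
            f"the tail integral of Fbarhat^{cfg.alpha} is non-finite; "
            "for alpha <= 1/2 the empirical tail may fail to be integrable"
        )
    se = None
    if cfg.compute_se and cfg.alpha > 0.5:
        se = crte_asymptotic_se(surv, cfg.alpha, bw.n, bw.b_n,
                                surv.density.beta_half, K.CK,
                                upper=upper, grid_points=cfg.grid_points)
    return EntropyEstimate(value=value, asymptotic_se=se, config=cfg,
                           n=bw.n, b_n=bw.b_n)


def dcrte_estimate(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
                   cfg: EntropyConfig, *, renormalize: bool = False
                   ) -> EntropyEstimate:
    """Kernel estimate of the dynamic CRTE at age ``cfg.t``."""
    if cfg.t is None:
        raise ValueError("DCRTE estimation requires cfg.t")
    surv = _build_survival(sample, K, bw, renormalize)
    eps = 1e-6 * surv.total_mass
    sft = float(surv.evaluate(cfg.t))
    if sft <= eps:
        raise UnstableTailError(
            f"Fbarhat({cfg.t}) = {sft:.3g} <= {eps:.3g}: t lies beyond the "
            "data and the alpha-power denominator would amplify noise"
        )
    upper = _resolve_upper(cfg, surv, sample, bw)
    value, m_hat, a_hat = dcrte_functional(surv, cfg.alpha, cfg.t,
                                           upper=upper,
                                           grid_points=cfg.grid_points)
    se = None
    if cfg.compute_se and cfg.alpha > 0.5:
        se = dcrte_asymptotic_se(surv, cfg.alpha, cfg.t, bw.n, bw.b_n,
                                 surv.density.beta_half, K.CK,
                                 upper=upper, grid_points=cfg.grid_points)
    return EntropyEstimate(value=value, asymptotic_se=se, config=cfg,
                           n=bw.n, b_n=bw.b_n, components=(m_hat, a_hat))


def crte_asymptotic_se(sf_source: SurvivalLike, alpha: float, n: int,
                       b_n: float, beta_half: float, CK: float, *,
                       upper: float = None, grid_points: int = 2048) -> float:
    """Asymptotic SE of the CRTE estimator: sqrt(sigma_eta^2 / (n*b_n)).

    ``sigma_eta^2 = alpha^2 * CK * int_0^inf Fbar^(2*alpha-1) dx
                    / ((alpha-1)^2 * beta_{0.5}^2)``.
    ``sf_source`` may be the exact model survival (oracle mode) or the
    kernel estimate (plug-in mode).
    """
    _require_variance_alpha(alpha)
    integral = _tail_integral(sf_source, 2.0 * alpha - 1.0, 0.0, upper,
                              grid_points)
    sigma_sq = alpha ** 2 * CK * integral / ((alpha - 1.0) ** 2 * beta_half ** 2)
    return math.sqrt(sigma_sq / (n * b_n))


def dcrte_asymptotic_se(sf_source: SurvivalLike, alpha: float, t: float,
                        n: int, b_n: float, beta_half: float, CK: float, *,
                        upper: float = None, grid_points: int = 2048) -> float:
    """Asymptotic SE of the DCRTE estimator at age ``t``.

    ``sigma_eta_x^2 = alpha^2*CK*[I_{2a-1}(t) + I_a(t)^2*Fbar(t)]
                      / ((alpha-1)^2 * beta_{0.5}^2 * Fbar(t)^(2*alpha))``.
    """
    _require_variance_alpha(alpha)
    sft = float(np.clip(_eval_survival(sf_source, np.array([t])), 0.0, None)[0])
    if sft <= 0.0:
        raise ValueError(f"Fbar({t}) = 0: the dynamic variance is undefined")
    i_2am1 = _tail_integral(sf_source, 2.0 * alpha - 1.0, t, upper, grid_points)
    i_a = _tail_integral(sf_source, alpha, t, upper, grid_points)
    sigma_sq = (alpha ** 2 * CK * (i_2am1 + i_a ** 2 * sft)
                / ((alpha - 1.0) ** 2 * beta_half ** 2 * sft ** (2.0 * alpha)))
    return math.sqrt(sigma_sq / (n * b_n))


def _tail_integral(surv: SurvivalLike, power: float, lower: float,
                   upper: Optional[float], grid_points: int) -> float:
    if upper is None:
        upper = _auto_upper(surv, power, max(lower, 1.0) * 2.0, 1e-9)
    return _simpson_sf_power(surv, power, lower, upper, grid_points)


def _require_variance_alpha(alpha: float) -> None:
    if alpha <= 0.5 or alpha == 1.0:
        raise ValueError(
            f"alpha={alpha}: asymptotic standard errors require alpha > 1/2 "
            "and alpha != 1"
        )


def entropy_bias_theory(model: TheoryModel, alpha: float, n: int,
                        bw: BandwidthSchedule, K: KernelSpec,
                        t: Optional[float] = None) -> Optional[float]:
    """First-order bias of the CRTE (or, with ``t``, DCRTE) estimator.

    CRTE:  bias ~ -(alpha/(alpha-1)) * b_n^2 * c2 * (beta_{2.5}/(2*beta_{0.5}))
                   * int_0^inf Fbar^(alpha-1)(x) * G(x) dx
    DCRTE: bias ~ (alpha/(alpha-1)) * (beta_{2.5}/(2*beta_{0.5})) * b_n^2 * c2
                   / Fbar^alpha(t) * [ (int_t^inf Fbar^alpha / Fbar(t)) * G(t)
                                       - int_t^inf Fbar^(alpha-1)(x) G(x) dx ]
    with ``G(x) = int_x^inf f''(y) dy``.

    Returns ``None`` (not-applicable flag) when beta_{2.5} diverges,
    i.e. theta >= 2/5: the second-order expansion does not hold for the
    schedule and no finite first-order bias is defined.
    """
    beta_52 = beta_coefficient(bw.theta, 2.5)
    if not beta_52.finite:
        return None
    beta_half = beta_coefficient(bw.theta, 0.5).value
    b_n = bw.b_n
    upper = model.upper if math.isfinite(model.upper) else math.inf

    def tail_f2(x: float) -> float:
        val, _ = integrate.quad(model.pdf2, x, upper, limit=200)
        return val

    front = (alpha / (alpha - 1.0)) * b_n ** 2 * K.c2 * beta_52.value / (2.0 * beta_half)
    if t is None:
        integrand = lambda x: model.sf(x) ** (alpha - 1.0) * tail_f2(x)
        outer, _ = integrate.quad(integrand, 0.0, upper, limit=200)
        return -front * outer
    sft = float(model.sf(t))
    if sft <= 0.0:
        raise ValueError(f"Fbar({t}) = 0: dynamic bias undefined")
    i_a, _ = integrate.quad(lambda x: model.sf(x) ** alpha, t, upper, limit=200)
    outer, _ = integrate.quad(
        lambda x: model.sf(x) ** (alpha - 1.0) * tail_f2(x), t, upper, limit=200)
    return (front / sft ** alpha) * (i_a * tail_f2(t) / sft - outer)


def mse_theory(model: TheoryModel, alpha: float, n: int,
               bw: BandwidthSchedule, K: KernelSpec,
               t: Optional[float] = None) -> Optional[float]:
    """First-order MSE (bias^2 + variance) of the CRTE/DCRTE estimator.

    Returns ``None`` when the bias part is not applicable (divergent
    beta_{2.5}); the variance alone is available through the SE
    functions in that case.
    """
    from .theory import sigma_eta_sq_exact, sigma_eta_x_sq_exact

    bias = entropy_bias_theory(model, alpha, n, bw, K, t=t)
    if bias is None:
        return None
    beta_half = beta_coefficient(bw.theta, 0.5).value
    if t is None:
        sigma_sq = sigma_eta_sq_exact(model, alpha, K.CK, beta_half)
    else:
        sigma_sq = sigma_eta_x_sq_exact(model, alpha, t, K.CK, beta_half)
    return bias ** 2 + sigma_sq / (n * bw.b_n)
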