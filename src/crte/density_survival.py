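"""Recursive kernel density estimation and the plug-in survival estimator.

The recursive (Wegman–Davies type) estimator gives each observation its
own bandwidth from a decreasing schedule ``b_1 >= ... >= b_n``:

    f*_n(x) = (1 / (n * sqrt(b_n))) * sum_j b_j**(-1/2) * K((x - X_j) / b_j).

Under a power-law schedule ``E f*_n ~ beta_{0.5} * f``, so the
asymptotically unbiased estimator is ``fhat_n = f*_n / beta_{0.5}``.
The survival function is estimated by integrating the density upward:
``Fbarhat_n(t) = int_t^inf fhat_n``, which reduces to a weighted sum of
kernel tail masses and is available in closed form for the built-in
kernels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import integrate

from .kernels_bandwidths import (
    BandwidthSchedule,
    KernelSpec,
    beta_coefficient,
    beta_coefficient_empirical,
)
from .theory import TheoryModel

logger = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "DensityEstimate",
    "SurvivalEstimate",
    "density_raw",
    "density",
    "survival",
    "survival_bias_variance_theory",
    "read_sample",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class Sample:
    """A univariate sample of lifetimes from a (presumed) stationary process."""

    observations: np.ndarray
    stationarity_assumed: bool = True
    origin: str = "unspecified"

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        if obs.ndim != 1 or obs.size < 1:
            raise ValueError("observations must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(obs)):
            raise ValueError("observations must all be finite")
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return self.observations.size

    @property
    def n(self) -> int:
        return self.observations.size

    def require_nonnegative(self) -> None:
        """Entropy estimation integrates from 0; negative lifetimes are invalid."""
        if np.any(self.observations < 0):
            raise ValueError(
                "entropy estimation requires non-negative observations"
            )


def read_sample(path, *, origin: Optional[str] = None) -> Sample:
    """Read a single-column CSV or whitespace-delimited text file.

    An optional header row is tolerated; blank and NaN rows are dropped
    with a logged count.
    """
    frame = pd.read_csv(path, sep=r"[,\s]+", engine="python", header=None,
                        comment="#", skip_blank_lines=True)
    col = frame.iloc[:, 0]
    values = pd.to_numeric(col, errors="coerce")
    # a non-numeric first row is treated as a header
    if np.isnan(values.iloc[0]) and isinstance(col.iloc[0], str):
        values = values.iloc[1:]
    dropped = int(values.isna().sum())
    if dropped:
        logger.warning("dropped %d non-numeric/blank rows from %s", dropped, path)
    clean = values.dropna().to_numpy(dtype=float)
    return Sample(observations=clean, origin=origin or str(path))


def _weights(bw: BandwidthSchedule) -> np.ndarray:
    """Per-term weights sqrt(b_j / b_n) used by both density and survival."""
    return np.sqrt(bw.values / bw.b_n)


@dataclass(frozen=True)
class DensityEstimate:
    """The recursive density estimator bound to a sample.

    ``evaluate_raw`` is f*_n; ``evaluate`` is the rescaled fhat_n =
    f*_n / beta_{0.5}.  ``beta_half`` defaults to the asymptotic closed
    form 1/(1 - theta/2); pass ``use_empirical_beta=True`` to use the
    finite-n partial sum instead (then the survival estimator's total
    mass is exactly 1).
    """

    sample: Sample
    kernel: KernelSpec
    bandwidths: BandwidthSchedule
    beta_half: float = field(default=math.nan)
    use_empirical_beta: bool = False

    def __post_init__(self) -> None:
        if len(self.sample) != self.bandwidths.n:
            raise ValueError(
                f"bandwidth schedule length {self.bandwidths.n} does not "
                f"match sample size {len(self.sample)}"
            )
        if math.isnan(self.beta_half):
            if self.use_empirical_beta:
                bh = beta_coefficient_empirical(self.bandwidths, 0.5)
            else:
                bh = beta_coefficient(self.bandwidths.theta, 0.5).value
            object.__setattr__(self, "beta_half", bh)
        if not (math.isfinite(self.beta_half) and self.beta_half > 0):
            raise ValueError(f"beta_half must be positive finite, got {self.beta_half}")

    def evaluate_raw(self, x: ArrayLike) -> ArrayLike:
        """f*_n(x), vectorised over x."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        b = self.bandwidths.values
        u = (xv[:, None] - self.sample.observations[None, :]) / b[None, :]
        terms = self.kernel.evaluate(u) / np.sqrt(b)[None, :]
        out = terms.sum(axis=1) / (len(self.sample) * math.sqrt(self.bandwidths.b_n))
        return float(out[0]) if scalar else out

    def evaluate(self, x: ArrayLike) -> ArrayLike:
        """fhat_n(x) = f*_n(x) / beta_{0.5}."""
        return self.evaluate_raw(x) / self.beta_half


@dataclass(frozen=True)
class SurvivalEstimate:
    """Plug-in survival estimator Fbarhat_n(t) = int_t^inf fhat_n(x) dx.

    Because each kernel integrates to one, the total mass at t = -inf is
    (1/(beta_{0.5} n)) * sum_j sqrt(b_j/b_n), which is 1 only in the
    limit; pass ``renormalize=True`` to divide the curve by it.
    """

    density: DensityEstimate
    renormalize: bool = False

    @property
    def total_mass(self) -> float:
        bw = self.density.bandwidths
        raw = float(np.sum(_weights(bw))) / (self.density.beta_half * bw.n)
        return 1.0 if self.renormalize else raw

    def evaluate(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tv = np.atleast_1d(t)
        dens = self.density
        bw = dens.bandwidths
        b = bw.values
        u = (tv[:, None] - dens.sample.observations[None, :]) / b[None, :]
        tails = dens.kernel.tail(u.ravel()).reshape(u.shape)
        out = tails @ _weights(bw) / (dens.beta_half * bw.n)
        if self.renormalize:
            bw_sum = float(np.sum(_weights(bw))) / (dens.beta_half * bw.n)
            out = out / bw_sum
        # quadrature noise can produce tiny negative tail masses for
        # kernels without a closed-form tail
        out = np.where(out < 0, np.where(out > -1e-12, 0.0, out), out)
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def export_grid(self, points: int = 512) -> Tuple[np.ndarray, np.ndarray]:
        """Evaluation grid spanning the data +- 4 leading bandwidths."""
        obs = self.density.sample.observations
        b1 = float(self.density.bandwidths.values[0])
        t = np.linspace(obs.min() - 4.0 * b1, obs.max() + 4.0 * b1, points)
        return t, self.evaluate(t)


# --- functional wrappers ----------------------------------------------------

def density_raw(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
                x: ArrayLike) -> ArrayLike:
    """Evaluate the raw recursive estimator f*_n at x."""
    return DensityEstimate(sample=sample, kernel=K, bandwidths=bw).evaluate_raw(x)


def density(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
            beta_half: float, x: ArrayLike) -> ArrayLike:
    """Evaluate the rescaled estimator fhat_n = f*_n / beta_{0.5} at x."""
    est = DensityEstimate(sample=sample, kernel=K, bandwidths=bw,
                          beta_half=float(beta_half))
    return est.evaluate(x)


def survival(sample: Sample, K: KernelSpec, bw: BandwidthSchedule,
             beta_half: float, t: ArrayLike) -> ArrayLike:
    """Evaluate the plug-in survival estimator Fbarhat_n at t."""
    est = DensityEstimate(sample=sample, kernel=K, bandwidths=bw,
                          beta_half=float(beta_half))
    return SurvivalEstimate(density=est).evaluate(t)


def survival_bias_variance_theory(model: TheoryModel, t: float, n: int,
                                  bw: BandwidthSchedule, K: KernelSpec
                                  ) -> Tuple[Optional[float], float]:
    """First-order bias and variance of Fbarhat_n(t) under the model.

    bias ~ (beta_{2.5} / (2*beta_{0.5})) * b_n^2 * c2 * int_t^inf f''(x) dx
    var  ~ CK * Fbar(t) / (n * b_n * beta_{0.5}^2)

    The bias is returned as ``None`` when beta_{2.5} diverges
    (theta >= 2/5), in which case the second-order expansion does not
    apply to the schedule.
    """
    beta_half = beta_coefficient(bw.theta, 0.5).value
    beta_52 = beta_coefficient(bw.theta, 2.5)
    b_n = bw.b_n
    if beta_52.finite:
        tail_f2, _ = integrate.quad(model.pdf2, t, model.upper
                                    if math.isfinite(model.upper) else math.inf,
                                    limit=400)
        bias = (beta_52.value / (2.0 * beta_half)) * b_n ** 2 * K.c2 * tail_f2
    else:
        bias = None
    variance = K.CK * float(model.sf(t)) / (n * b_n * beta_half ** 2)
    return bias, variance
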