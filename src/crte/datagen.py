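"""Seeded generation of stationary lifetime sequences.

Two process families share one latent-Gaussian pathway:

* ``iid`` — independent draws from the marginal (the latent series is
  white noise);
* ``gaussian_copula_ar1`` — a stationary Gaussian AR(1) series with
  coefficient ``phi`` and unit stationary variance, pushed through the
  standard normal CDF and the marginal quantile function.

The copula construction preserves the marginal exactly and the output is
strictly stationary.  For a stationary Gaussian process the maximal
correlation between past and future equals the absolute lag correlation,
and measurable transforms cannot increase it, so the generated series is
rho-mixing with ``rho(k) <= |phi|**k -> 0`` geometrically; the iid family
is the ``phi = 0`` special case (``rho(k) = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import signal
from scipy.special import ndtr

from .density_survival import Sample
from .theory import TheoryModel, get_model

__all__ = ["ProcessSpec", "generate", "rho_mixing_bound_ar1"]

_FAMILIES = ("iid", "gaussian_copula_ar1")


@dataclass(frozen=True)
class ProcessSpec:
    """Recipe for a reproducible stationary sequence.

    ``stream`` separates independent replicate streams derived from one
    master seed; replicate ``i`` of a Monte Carlo study uses
    ``stream=i`` so each replicate is individually reproducible.
    """

    family: str
    marginal: str = "exponential"
    marginal_params: Dict[str, float] = field(default_factory=dict)
    phi: float = 0.0
    n: int = 1
    seed: int = 0
    stream: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family '{self.family}'; available: {_FAMILIES}")
        if not (-1.0 < self.phi < 1.0):
            raise ValueError(f"|phi| must be < 1 for stationarity, got {self.phi}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    def model(self) -> TheoryModel:
        return get_model(self.marginal, **self.marginal_params)

    def with_stream(self, stream: int) -> "ProcessSpec":
        return ProcessSpec(family=self.family, marginal=self.marginal,
                           marginal_params=dict(self.marginal_params),
                           phi=self.phi, n=self.n, seed=self.seed,
                           stream=stream)


def _latent_ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) with unit variance; phi = 0 gives white noise."""
    eps = rng.standard_normal(n)
    if phi == 0.0:
        return eps
    innov = eps * np.sqrt(1.0 - phi * phi)
    innov[0] = eps[0]  # start in the stationary N(0,1) law
    z = signal.lfilter([1.0], [1.0, -phi], innov)
    return z


def generate(spec: ProcessSpec) -> Sample:
    """Draw one sample according to ``spec``; fully reproducible from
    (seed, stream)."""
    model = spec.model()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, spec.stream]))
    phi = spec.phi if spec.family == "gaussian_copula_ar1" else 0.0
    z = _latent_ar1(rng, spec.n, phi)
    u = ndtr(z)
    x = np.asarray(model.ppf(u), dtype=float)
    origin = (f"{spec.family}(marginal={spec.marginal}"
              f"{spec.marginal_params or ''}, phi={phi}, "
              f"seed={spec.seed}, stream={spec.stream})")
    return Sample(observations=x, stationarity_assumed=True, origin=origin)


def rho_mixing_bound_ar1(phi: float, k: int) -> float:
    """Upper bound |phi|**k on the rho-mixing coefficient at lag ``k``
    for the Gaussian-copula AR(1) family."""
    if not (-1.0 < phi < 1.0):
        raise ValueError(f"|phi| must be < 1, got {phi}")
    if k < 1:
        raise ValueError(f"lag k must be >= 1, got {k}")
    return abs(phi) ** k
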