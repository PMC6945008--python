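"""Truncation-selection arithmetic shared by all selection schemes.

Standardized selection intensity for a Gaussian criterion, the plot-budget
arithmetic of the trial designs, and the generic breeder's-equation kernel
theta * phi * i * Cov(criterion, target) / sigma(criterion).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import integrate, special, stats

__all__ = [
    "SchemeDesign",
    "selection_intensity",
    "finite_sample_intensity",
    "candidates_tested",
    "candidates_selected",
    "response_kernel",
    "load_design",
]


class SchemeDesign(BaseModel):
    """Trial and selection constants of one recurrent-selection scheme.

    ``replicates`` is the number of field observations (plots) per tested
    mixture or progeny family (M).  ``theta_*`` is 1 or 2 according to whether
    selection applies to one or both sexes; ``phi_*`` is the parent-offspring
    covariance factor of the progeny-family type (1 for half-sib, 1/2 for
    topcross).  ``theta_prime_*`` is the pure-stand counterpart of theta.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    total_plots: int = Field(ge=1)
    replicates: int = Field(ge=1)
    selection_rate: float = Field(gt=0.0, le=1.0)
    theta_1: Literal[1, 2] = 1
    theta_2: Literal[1, 2] = 1
    phi_1: float = 1.0
    phi_2: float = 1.0
    theta_prime_1: Optional[Literal[1, 2]] = None
    theta_prime_2: Optional[Literal[1, 2]] = None

    @model_validator(mode="after")
    def _validate(self) -> "SchemeDesign":
        if self.total_plots < self.replicates:
            raise ValueError("total_plots must be >= replicates")
        for name in ("phi_1", "phi_2"):
            if getattr(self, name) not in (1.0, 0.5):
                raise ValueError(f"{name} must be 1 or 0.5")
        return self

    @property
    def theta_phi_1(self) -> float:
        return self.theta_1 * self.phi_1

    @property
    def theta_phi_2(self) -> float:
        return self.theta_2 * self.phi_2

    def theta_prime(self, species: Literal[1, 2]) -> int:
        """Pure-stand theta, defaulting to the mixture-scheme value."""
        explicit = self.theta_prime_1 if species == 1 else self.theta_prime_2
        if explicit is not None:
            return explicit
        return self.theta_1 if species == 1 else self.theta_2


def selection_intensity(rate: float) -> float:
    """Infinite-population selection intensity i = phi(z_p) / p.

    ``z_p`` is the standard-normal quantile truncating the upper ``rate``
    fraction.  Monotone decreasing in the rate; i(1) = 0.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError("selection rate must be in (0, 1]")
    if rate == 1.0:
        return 0.0
    z = stats.norm.isf(rate)
    return stats.norm.pdf(z) / rate


def finite_sample_intensity(n_tested: int, n_selected: int) -> float:
    """Exact expected intensity when the top k of n Gaussian draws are kept.

    E[mean of top k] = (n/k) * Int z phi(z) P(Binom(n-1, Phi(z)) >= n-k) dz,
    with the binomial tail written as a regularized incomplete beta.  This is
    the order-statistics value the Monte-Carlo oracle realizes; it approaches
    ``selection_intensity(k / n)`` as n grows.
    """
    if not 1 <= n_selected <= n_tested:
        raise ValueError("need 1 <= n_selected <= n_tested")
    n, k = n_tested, n_selected
    if k == n:
        return 0.0

    def integrand(z: float) -> float:
        p_top = special.betainc(n - k, k, stats.norm.cdf(z))
        return z * stats.norm.pdf(z) * p_top

    val, _ = integrate.quad(integrand, -10.0, 10.0, limit=200)
    return n * val / k


def candidates_tested(
    design: SchemeDesign, scheme: Literal["srma", "sgma", "pure"]
) -> int:
    """Candidates tested per species for a given plot budget.

    Each SRMA plot observes one pair-mixture testing one candidate of each
    species, so the full budget serves both species at once.  SGMA and
    pure-stand selection run two parallel processes that split the budget
    equally.
    """
    plots, m = design.total_plots, design.replicates
    if scheme == "srma":
        if plots % m:
            raise ValueError(
                f"{plots} plots not divisible by {m} replicates"
            )
        return plots // m
    if scheme in ("sgma", "pure"):
        if plots % (2 * m):
            raise ValueError(
                f"{plots} plots not divisible by 2 x {m} replicates "
                "(two parallel processes)"
            )
        return plots // (2 * m)
    raise ValueError(f"unknown scheme {scheme!r}")


def candidates_selected(tested: int, rate: float) -> int:
    """Number of selected candidates: round-half-up of tested * rate, >= 1."""
    if tested < 1:
        raise ValueError("tested must be >= 1")
    if not 0.0 < rate <= 1.0:
        raise ValueError("selection rate must be in (0, 1]")
    return max(1, int(math.floor(tested * rate + 0.5)))


def response_kernel(
    intensity: float,
    theta_phi: float,
    criterion_sd: float,
    covariance: float,
) -> float:
    """Breeder's-equation building block theta*phi * i * cov / sigma_I.

    Every expected response in the package is a sum of these terms; the sign
    follows the covariance between the criterion and the target effect.
    """
    if criterion_sd <= 0.0:
        raise ValueError("criterion_sd must be positive")
    return theta_phi * intensity * covariance / criterion_sd


def load_design(path: str | Path) -> SchemeDesign:
    """Read a :class:`SchemeDesign` from a JSON file.

    Accepts either a bare design object or a config with a ``design`` key.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if "design" in payload:
        payload = payload["design"]
    return SchemeDesign.model_validate(payload)
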