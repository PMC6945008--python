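"""Genetic model of two-species mixture performance.

The observed performance of a plot mixing progeny families of candidate *r*
(species 1) and candidate *s* (species 2) is additive in the two species
contributions, each modelled with a direct effect ``v`` of the family on its
own species' contribution, an associate effect ``a`` of the partner family,
a pair-specific direct × associate interaction ``(va)``, and a plot error::

    x1 = u1 + v1r + a2s + (va)1r2s + e1
    x2 = u2 + v2s + a1r + (va)2s1r + e2
    y  = x1 + x2

Equivalently ``y = u1 + u2 + g1r + g2s + d1r2s + eps`` where
``g = v + a`` is the general mixture ability (GMA) of a family,
``d = (va)12 + (va)21`` is the specific mixture ability (SMA) of the pair,
and ``eps = e1 + e2`` the plot error of the mixture performance.

This module holds the variance/correlation parameters of that model, derives
the GMA/SMA variance components, and computes the variances of the linear
selection criteria used by the reciprocal (SRMA) and general (SGMA)
mixture-ability selection schemes, plus the resulting design heritabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, TYPE_CHECKING

from pydantic import BaseModel, ConfigDict, Field, model_validator

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .selection_math import SchemeDesign
    from .srma import IndexWeights

__all__ = [
    "SpeciesGeneticParams",
    "MixtureGeneticParams",
    "DerivedComponents",
    "derive_components",
    "srma_criterion_variance",
    "sgma_criterion_variance",
    "design_heritability",
    "load_params",
]

#: relative tolerance for the eps = e1 + e2 decomposition consistency check
_ERROR_SPLIT_RTOL = 1e-9


class SpeciesGeneticParams(BaseModel):
    """Variance components of one species' mixture-model effects.

    ``var_direct`` and ``var_associate`` are the between-progeny-family
    variances of the direct effect v and associate effect a; ``rho_va`` their
    correlation.  The pure-stand block (``var_pure``, ``eta``, ``omega``,
    ``pure_design_h2``) describes the genetic effect p of a family in pure
    stand: ``eta`` = corr(p, v), ``omega`` = corr(p, a), and
    ``pure_design_h2`` the design heritability sigma_p^2 / sigma_yp^2 of the
    pure-stand progeny trial.  ``eta``/``omega`` stay ``None`` unless
    pure-stand correlative responses are requested.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    var_direct: float = Field(ge=0.0)
    var_associate: float = Field(ge=0.0)
    rho_va: float = Field(default=0.0, ge=-1.0, le=1.0)
    var_pure: float = Field(default=1.0, ge=0.0)
    eta: Optional[float] = Field(default=None, ge=-1.0, le=1.0)
    omega: Optional[float] = Field(default=None, ge=-1.0, le=1.0)
    pure_design_h2: float = Field(default=0.6, gt=0.0, le=1.0)

    @property
    def cov_va(self) -> float:
        """Cov(v, a), zero whenever either variance is zero."""
        return _cov(self.rho_va, self.var_direct, self.var_associate)


class MixtureGeneticParams(BaseModel):
    """Full parameter set of the two-species mixture model.

    Interaction variances ``var_va_12`` (of (va)1r2s, entering species-1's
    contribution) and ``var_va_21`` (of (va)2s1r) are correlated with
    ``rho_va12_va21``.  ``var_plot_error_mixture`` is sigma_eps^2, the plot
    error variance of the observed mixture performance.  Its split into the
    two species-contribution errors (eps = e1 + e2) may be given explicitly
    through ``var_e1``/``var_e2``/``rho_e1_e2``; when omitted, the default
    split sigma_e1^2 = sigma_e2^2 = sigma_eps^2 with corr(e1, e2) = -1/2 is
    used, which reproduces sigma_eps^2 exactly.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    species1: SpeciesGeneticParams
    species2: SpeciesGeneticParams
    var_va_12: float = Field(default=0.0, ge=0.0)
    var_va_21: float = Field(default=0.0, ge=0.0)
    rho_va12_va21: float = Field(default=0.0, ge=-1.0, le=1.0)
    var_plot_error_mixture: float = Field(default=0.0, ge=0.0)
    var_e1: Optional[float] = Field(default=None, ge=0.0)
    var_e2: Optional[float] = Field(default=None, ge=0.0)
    rho_e1_e2: Optional[float] = Field(default=None, ge=-1.0, le=1.0)
    mean_u1: float = 0.0
    mean_u2: float = 0.0
    mean_u1_pure: float = 0.0

    @model_validator(mode="after")
    def _check_error_split(self) -> "MixtureGeneticParams":
        given = [self.var_e1, self.var_e2, self.rho_e1_e2]
        if any(g is not None for g in given) and any(g is None for g in given):
            raise ValueError(
                "var_e1, var_e2 and rho_e1_e2 must be supplied together"
            )
        if all(g is not None for g in given):
            total = (
                self.var_e1
                + self.var_e2
                + 2.0 * self.rho_e1_e2 * math.sqrt(self.var_e1 * self.var_e2)
            )
            ref = max(abs(self.var_plot_error_mixture), 1.0)
            if abs(total - self.var_plot_error_mixture) > _ERROR_SPLIT_RTOL * ref:
                raise ValueError(
                    "error split inconsistent: var_e1 + var_e2 + 2*cov(e1,e2) "
                    f"= {total!r} but var_plot_error_mixture = "
                    f"{self.var_plot_error_mixture!r}"
                )
        return self

    def error_split(self) -> tuple[float, float, float]:
        """Return (sigma_e1^2, sigma_e2^2, Cov(e1, e2)).

        Falls back to the symmetric default split
        sigma_e1^2 = sigma_e2^2 = sigma_eps^2, Cov(e1, e2) = -sigma_eps^2 / 2
        when no explicit split was supplied.
        """
        if self.var_e1 is not None:
            cov = self.rho_e1_e2 * math.sqrt(self.var_e1 * self.var_e2)
            return self.var_e1, self.var_e2, cov
        s = self.var_plot_error_mixture
        return s, s, -0.5 * s


@dataclass(frozen=True)
class DerivedComponents:
    """GMA/SMA variance components derived from :class:`MixtureGeneticParams`.

    ``var_Gx1``/``var_Gx2`` are the genetic variances of the species
    contributions under reciprocal pairing (direct + partner's associate +
    interaction); ``cov_Gx1_Gx2`` their covariance.
    """

    var_gma_1: float
    var_gma_2: float
    var_sma: float
    var_Gx1: float
    var_Gx2: float
    cov_Gx1_Gx2: float
    cov_v1_a1: float
    cov_v2_a2: float
    cov_va12_va21: float


def _cov(rho: float, var_x: float, var_y: float) -> float:
    # degenerate variances force the covariance to zero regardless of rho
    if var_x == 0.0 or var_y == 0.0:
        return 0.0
    return rho * math.sqrt(var_x * var_y)


def derive_components(params: MixtureGeneticParams) -> DerivedComponents:
    """Compute GMA, SMA and species-contribution variance components.

    sigma_g^2 = sigma_v^2 + sigma_a^2 + 2 Cov(v, a) per species,
    sigma_d^2 = sigma_(va)12^2 + sigma_(va)21^2 + 2 Cov((va)12, (va)21),
    sigma_Gx1^2 = sigma_v1^2 + sigma_a2^2 + sigma_(va)12^2 and
    Cov(Gx1, Gx2) = Cov(v1, a1) + Cov(v2, a2) + Cov((va)12, (va)21).
    """
    s1, s2 = params.species1, params.species2
    cov1 = s1.cov_va
    cov2 = s2.cov_va
    cov12 = _cov(params.rho_va12_va21, params.var_va_12, params.var_va_21)
    return DerivedComponents(
        var_gma_1=s1.var_direct + s1.var_associate + 2.0 * cov1,
        var_gma_2=s2.var_direct + s2.var_associate + 2.0 * cov2,
        var_sma=params.var_va_12 + params.var_va_21 + 2.0 * cov12,
        var_Gx1=s1.var_direct + s2.var_associate + params.var_va_12,
        var_Gx2=s2.var_direct + s1.var_associate + params.var_va_21,
        cov_Gx1_Gx2=cov1 + cov2 + cov12,
        cov_v1_a1=cov1,
        cov_v2_a2=cov2,
        cov_va12_va21=cov12,
    )


def srma_criterion_variance(
    params: MixtureGeneticParams,
    weights: "IndexWeights",
    replicates: int,
) -> float:
    """Variance of the SRMA pair index I = a1*x1 + a2*x2 averaged over M plots.

    With weights (1, 1) the index is the observed mixture performance and the
    variance collapses to sigma_g1^2 + sigma_g2^2 + sigma_d^2 + sigma_eps^2/M.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    a1, a2 = weights.alpha_1, weights.alpha_2
    d = derive_components(params)
    ve1, ve2, cov_e = params.error_split()
    genetic = (
        a1 * a1 * d.var_Gx1
        + a2 * a2 * d.var_Gx2
        + 2.0 * a1 * a2 * d.cov_Gx1_Gx2
    )
    error = (a1 * a1 * ve1 + a2 * a2 * ve2 + 2.0 * a1 * a2 * cov_e) / replicates
    var = genetic + error
    if var <= 0.0:
        raise ValueError(
            "degenerate model: SRMA criterion variance is not positive"
        )
    return var


def sgma_criterion_variance(
    params: MixtureGeneticParams,
    weights: "IndexWeights",
    replicates: int,
    focal_species: Literal[1, 2],
) -> float:
    """Variance of the SGMA index for the process selecting ``focal_species``.

    The candidate's family is mixed with a bulk of all partner families, so
    the genetic parts of the two observed contributions are the candidate's
    own direct effect and its associate effect on the bulk.  Weights are
    labelled by species: in the species-1 process ``alpha_1`` weighs the
    candidate's own contribution and ``alpha_2`` the bulk's; in the species-2
    process the roles swap.  With weights (1, 1) the variance collapses to
    sigma_g^2 + sigma_eps^2 / M of the focal species.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sp = params.species1 if focal_species == 1 else params.species2
    if focal_species == 1:
        a_own, a_comp = weights.alpha_1, weights.alpha_2
    else:
        a_own, a_comp = weights.alpha_2, weights.alpha_1
    ve_own, ve_comp, cov_e = params.error_split()
    genetic = (
        a_own * a_own * sp.var_direct
        + a_comp * a_comp * sp.var_associate
        + 2.0 * a_own * a_comp * sp.cov_va
    )
    error = (
        a_own * a_own * ve_own
        + a_comp * a_comp * ve_comp
        + 2.0 * a_own * a_comp * cov_e
    ) / replicates
    var = genetic + error
    if var <= 0.0:
        raise ValueError(
            "degenerate model: SGMA criterion variance is not positive"
        )
    return var


def design_heritability(
    params: MixtureGeneticParams,
    design: "SchemeDesign",
    scheme: Literal["srma", "sgma"],
) -> float:
    """Design heritability of the plain mixture-performance criterion.

    SRMA: (sigma_g1^2 + sigma_g2^2 + sigma_d^2) / sigma_y(pair mean)^2;
    SGMA: sigma_g1^2 / sigma_y(family mean)^2.  Both use the unweighted
    criterion (index weights all one).
    """
    from .srma import IndexWeights  # local import avoids a cycle

    d = derive_components(params)
    ones = IndexWeights(alpha_1=1.0, alpha_2=1.0)
    if scheme == "srma":
        genetic = d.var_gma_1 + d.var_gma_2 + d.var_sma
        total = srma_criterion_variance(params, ones, design.replicates)
    elif scheme == "sgma":
        genetic = d.var_gma_1
        total = sgma_criterion_variance(params, ones, design.replicates, 1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return genetic / total


def load_params(path: str | Path) -> MixtureGeneticParams:
    """Read :class:`MixtureGeneticParams` from a JSON file.

    Keys mirror the field names; unknown keys are rejected so typos such as
    ``rho_va21_va12`` fail loudly instead of being silently dropped.
    """
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("design", None)  # design block handled by selection_math
    return MixtureGeneticParams.model_validate(payload)
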