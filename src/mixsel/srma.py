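"""Reciprocal mixture-ability selection (SRMA).

Pairs of progeny families, one per species, are tested in mixture and the
best pairs selected on a linear index I = alpha_1 * x1 + alpha_2 * x2 of the
observed species contributions.  Expected one-cycle responses are given both
after recombination of the selected candidates (what the next-cycle
populations inherit; interactions are not transmitted because pairings are
re-randomized) and before recombination (the genetic value of the selected
pairs themselves).  The index can be tuned so the before-recombination
contribution responses meet a target ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .model_core import (
    MixtureGeneticParams,
    derive_components,
    srma_criterion_variance,
)
from .selection_math import SchemeDesign, response_kernel, selection_intensity

__all__ = [
    "IndexWeights",
    "ResponseSet",
    "ResponseRatioTarget",
    "srma_responses_after",
    "srma_responses_before",
    "solve_srma_index",
]

logger = logging.getLogger(__name__)


class IndexWeights(BaseModel):
    """Weights of a linear index over the two observed species contributions.

    ``alpha_1`` always weighs the species-1 contribution, ``alpha_2`` the
    species-2 contribution — also in the SGMA processes, where one of the two
    is the bulk of partner families.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    alpha_1: float
    alpha_2: float

    @model_validator(mode="after")
    def _nonzero(self) -> "IndexWeights":
        if self.alpha_1 == 0.0 and self.alpha_2 == 0.0:
            raise ValueError("index weights must not both be zero")
        if not (np.isfinite(self.alpha_1) and np.isfinite(self.alpha_2)):
            raise ValueError("index weights must be finite")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_1, self.alpha_2])


@dataclass(frozen=True)
class ResponseSet:
    """Expected one-cycle responses (trait units).

    ``dG_x1``/``dG_x2`` are the responses of the species contributions,
    ``dG_total`` their sum (the mixture-performance response, by
    construction).  ``by_process`` optionally carries the per-process
    breakdown of the parallel schemes.
    """

    dG_x1: float
    dG_x2: float
    flavor: Literal["before_recombination", "after_recombination"]
    by_process: Optional[dict[str, float]] = field(default=None)

    @property
    def dG_total(self) -> float:
        return self.dG_x1 + self.dG_x2


class ResponseRatioTarget(BaseModel):
    """Desired proportionality (k1, k2) of species-contribution responses."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    k1: float
    k2: float

    @model_validator(mode="after")
    def _nonzero(self) -> "ResponseRatioTarget":
        if self.k1 == 0.0 and self.k2 == 0.0:
            raise ValueError("target ratio must not be (0, 0)")
        return self


def _criterion_sd(
    params: MixtureGeneticParams, weights: IndexWeights, design: SchemeDesign
) -> float:
    return srma_criterion_variance(params, weights, design.replicates) ** 0.5


def srma_responses_after(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights: IndexWeights,
    intensity: float | None = None,
) -> ResponseSet:
    """After-recombination responses of the species contributions.

    Only the heritable direct and associate effects contribute to the
    covariance terms; the pair-specific interactions inflate the criterion
    variance but are not transmitted.  ``intensity`` overrides the
    infinite-population value derived from the design's selection rate (the
    Monte-Carlo oracle uses the finite-sample expectation).
    """
    i = selection_intensity(design.selection_rate) if intensity is None else intensity
    sd = _criterion_sd(params, weights, design)
    s1, s2 = params.species1, params.species2
    a1, a2 = weights.alpha_1, weights.alpha_2
    cov1, cov2 = s1.cov_va, s2.cov_va
    dG_x1 = response_kernel(
        i, design.theta_phi_1, sd, a1 * s1.var_direct + a2 * cov1
    ) + response_kernel(
        i, design.theta_phi_2, sd, a1 * s2.var_associate + a2 * cov2
    )
    dG_x2 = response_kernel(
        i, design.theta_phi_1, sd, a1 * cov1 + a2 * s1.var_associate
    ) + response_kernel(
        i, design.theta_phi_2, sd, a1 * cov2 + a2 * s2.var_direct
    )
    return ResponseSet(dG_x1=dG_x1, dG_x2=dG_x2, flavor="after_recombination")


def srma_responses_before(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights: IndexWeights,
    intensity: float | None = None,
) -> ResponseSet:
    """Before-recombination responses: genetic value of the selected pairs.

    Valid whatever the progeny-family type provided the same selection
    intensity applies to both species (true here: pairs are selected
    jointly).  Uses the full contribution variances including interactions.
    """
    i = selection_intensity(design.selection_rate) if intensity is None else intensity
    sd = _criterion_sd(params, weights, design)
    d = derive_components(params)
    a1, a2 = weights.alpha_1, weights.alpha_2
    dG_x1 = response_kernel(
        i, 1.0, sd, a1 * d.var_Gx1 + a2 * d.cov_Gx1_Gx2
    )
    dG_x2 = response_kernel(
        i, 1.0, sd, a1 * d.cov_Gx1_Gx2 + a2 * d.var_Gx2
    )
    return ResponseSet(dG_x1=dG_x1, dG_x2=dG_x2, flavor="before_recombination")


def solve_srma_index(
    params: MixtureGeneticParams,
    target: ResponseRatioTarget,
) -> IndexWeights:
    """Index weights whose before-recombination responses are c*(k1, k2).

    Solves the 2x2 linear system G @ alpha = (k1, k2) where G is the
    covariance matrix of the genetic species contributions.  The returned
    weights are the raw solution (any joint positive rescaling leaves the
    responses unchanged); negative weights are legitimate and merely logged.
    """
    d = derive_components(params)
    G = np.array(
        [[d.var_Gx1, d.cov_Gx1_Gx2], [d.cov_Gx1_Gx2, d.var_Gx2]]
    )
    k = np.array([target.k1, target.k2])
    det = np.linalg.det(G)
    scale = max(d.var_Gx1 * d.var_Gx2, 1e-300)
    if abs(det) <= 1e-12 * scale:
        raise ValueError(
            "contribution covariance matrix is singular (perfectly "
            "correlated species contributions); target ratio unsolvable"
        )
    alpha = np.linalg.solve(G, k)
    if alpha.min() < 0.0:
        logger.warning(
            "solved SRMA index has a negative weight: alpha = %s", alpha
        )
    return IndexWeights(alpha_1=float(alpha[0]), alpha_2=float(alpha[1]))
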