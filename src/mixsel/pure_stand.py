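"""Correlative responses in mixture from parallel pure-stand selections.

Each species is selected on the pure-stand performance of progeny families
(criterion variance sigma_p^2 / h^2 with h^2 the design heritability of the
pure-stand trial).  Selection drags the mixture effects along through the
covariances Cov(p, v) = eta * sigma_p * sigma_v and
Cov(p, a) = omega * sigma_p * sigma_a, giving the correlative responses of
the species contributions that a next-cycle mixture test would reveal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import MixtureGeneticParams, SpeciesGeneticParams
from .selection_math import SchemeDesign, response_kernel, selection_intensity
from .srma import ResponseSet

__all__ = ["PureStandCriterion", "pure_stand_responses"]


@dataclass(frozen=True)
class PureStandCriterion:
    """Pure-stand selection criterion of one species.

    Parameterized by the genetic variance sigma_p^2 and the design
    heritability h^2 = sigma_p^2 / sigma_yp^2 (the plot-error variance and
    replicate count of the pure-stand trial are absorbed into h^2).
    """

    var_genetic: float
    design_h2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.design_h2 <= 1.0:
            raise ValueError("design_h2 must be in (0, 1]")
        if self.var_genetic < 0.0:
            raise ValueError("var_genetic must be >= 0")

    @classmethod
    def from_trial(
        cls, var_genetic: float, var_plot_error: float, replicates: int
    ) -> "PureStandCriterion":
        """Build from the trial triple (sigma_p^2, sigma_eps_p^2, M')."""
        total = var_genetic + var_plot_error / replicates
        return cls(var_genetic=var_genetic, design_h2=var_genetic / total)

    @property
    def criterion_sd(self) -> float:
        """sigma of the family-mean criterion: sigma_p / sqrt(h^2)."""
        return (self.var_genetic / self.design_h2) ** 0.5


def _process(
    sp: SpeciesGeneticParams,
    theta_prime: int,
    phi: float,
    intensity: float,
) -> tuple[float, float]:
    """(own-contribution, companion-contribution) correlative gains."""
    if sp.eta is None or sp.omega is None:
        raise ValueError(
            "pure-stand responses need eta and omega for both species"
        )
    crit = PureStandCriterion(var_genetic=sp.var_pure, design_h2=sp.pure_design_h2)
    sd_p = crit.var_genetic ** 0.5
    cov_pv = sp.eta * sd_p * sp.var_direct ** 0.5
    cov_pa = sp.omega * sd_p * sp.var_associate ** 0.5
    theta_phi = theta_prime * phi
    gain_own = response_kernel(intensity, theta_phi, crit.criterion_sd, cov_pv)
    gain_comp = response_kernel(intensity, theta_phi, crit.criterion_sd, cov_pa)
    return gain_own, gain_comp


def pure_stand_responses(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    intensity: float | None = None,
) -> ResponseSet:
    """Correlative responses cumulated over the two pure-stand selections.

    Species 1's contribution gains the direct-effect response of its own
    process plus the associate-effect response of the species-2 process
    (and symmetrically).  These responses never involve the direct-associate
    correlations rho_1/rho_2: only Cov(p, v) and Cov(p, a) enter.
    """
    i = selection_intensity(design.selection_rate) if intensity is None else intensity
    g11, g21 = _process(
        params.species1, design.theta_prime(1), design.phi_1, i
    )
    g22, g12 = _process(
        params.species2, design.theta_prime(2), design.phi_2, i
    )
    by_process = {
        "dG_x11": g11,
        "dG_x21": g21,
        "dG_x22": g22,
        "dG_x12": g12,
    }
    return ResponseSet(
        dG_x1=g11 + g12,
        dG_x2=g21 + g22,
        flavor="after_recombination",
        by_process=by_process,
    )
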