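"""Monte-Carlo simulation of one truncation-selection cycle.

Draws synthetic candidate populations with the mixture model's multivariate
normal effect structure, applies the index and truncation selection of each
scheme, and reports realized gains across replicate cycles.  This is the
independent oracle for every closed-form expectation in the package: the
analytic responses are covariance algebra under Gaussian truncation, and the
simulator realizes exactly those assumptions (transmission is represented by
the theta*phi coefficient, not by explicit meiosis, which the expectations
average over).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .model_core import MixtureGeneticParams
from .selection_math import (
    SchemeDesign,
    candidates_selected,
    candidates_tested,
)
from .srma import IndexWeights

__all__ = ["SimulatedCycle", "MonteCarloSummary", "simulate_cycle", "generate_fixture"]

Scheme = Literal["srma", "sgma", "pure"]


@dataclass(frozen=True)
class SimulatedCycle:
    """One realized selection cycle."""

    scheme: Scheme
    replicate: int
    seed: int
    criterion: np.ndarray
    selected: np.ndarray
    gains: dict[str, float]


@dataclass(frozen=True)
class MonteCarloSummary:
    """Replicate means and standard errors of realized gains.

    Keys of ``mean``/``se``: ``dG_x1``, ``dG_x2``, ``dG_total`` (plus
    ``before_*`` counterparts for SRMA) and ``criterion_variance``.
    """

    scheme: Scheme
    n_replicates: int
    n_tested: int
    n_selected: int
    mean: dict[str, float]
    se: dict[str, float]
    cycles: list[SimulatedCycle] = field(repr=False, default_factory=list)


def _rng(seed: int, replicate: int) -> np.random.Generator:
    # counter-based: replicate streams independent of execution order
    return np.random.default_rng([seed, replicate])


def _bvn(
    rng: np.random.Generator, n: int, var_x: float, var_y: float, cov: float
) -> tuple[np.ndarray, np.ndarray]:
    cov_m = np.array([[var_x, cov], [cov, var_y]])
    draws = rng.multivariate_normal([0.0, 0.0], cov_m, size=n, method="svd")
    return draws[:, 0], draws[:, 1]


def _top_k(criterion: np.ndarray, k: int) -> np.ndarray:
    # stable sort on (-criterion, id): ties broken by candidate identifier
    order = np.lexsort((np.arange(criterion.size), -criterion))
    return order[:k]


def _simulate_srma_once(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights: IndexWeights,
    n: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    s1, s2 = params.species1, params.species2
    m = design.replicates
    v1, a1 = _bvn(rng, n, s1.var_direct, s1.var_associate, s1.cov_va)
    v2, a2 = _bvn(rng, n, s2.var_direct, s2.var_associate, s2.cov_va)
    perm = rng.permutation(n)  # random pairing of the two species' candidates
    v2, a2 = v2[perm], a2[perm]
    cov12 = params.rho_va12_va21 * math.sqrt(params.var_va_12 * params.var_va_21)
    va12, va21 = _bvn(rng, n, params.var_va_12, params.var_va_21, cov12)
    ve1, ve2, cov_e = params.error_split()
    e1, e2 = _bvn(rng, n, ve1 / m, ve2 / m, cov_e / m)  # plot-mean errors
    x1 = params.mean_u1 + v1 + a2 + va12 + e1
    x2 = params.mean_u2 + v2 + a1 + va21 + e2
    criterion = weights.alpha_1 * x1 + weights.alpha_2 * x2
    sel = _top_k(criterion, k)
    tp1, tp2 = design.theta_phi_1, design.theta_phi_2
    after_x1 = tp1 * v1[sel].mean() + tp2 * a2[sel].mean()
    after_x2 = tp1 * a1[sel].mean() + tp2 * v2[sel].mean()
    before_x1 = (v1[sel] + a2[sel] + va12[sel]).mean()
    before_x2 = (v2[sel] + a1[sel] + va21[sel]).mean()
    gains = {
        "dG_x1": after_x1,
        "dG_x2": after_x2,
        "dG_total": after_x1 + after_x2,
        "before_dG_x1": before_x1,
        "before_dG_x2": before_x2,
        "before_dG_total": before_x1 + before_x2,
        "criterion_variance": float(np.var(criterion, ddof=1)),
    }
    return criterion, sel, gains


def _simulate_sgma_process(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights: IndexWeights,
    focal: Literal[1, 2],
    n: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Returns (criterion, selected, own gain, companion gain, crit var)."""
    sp = params.species1 if focal == 1 else params.species2
    m = design.replicates
    v, a = _bvn(rng, n, sp.var_direct, sp.var_associate, sp.cov_va)
    ve_own, ve_comp, cov_e = params.error_split()
    if focal == 2:
        ve_own, ve_comp = ve_comp, ve_own
    e_own, e_comp = _bvn(rng, n, ve_own / m, ve_comp / m, cov_e / m)
    u_own = params.mean_u1 if focal == 1 else params.mean_u2
    u_comp = params.mean_u2 if focal == 1 else params.mean_u1
    x_own = u_own + v + e_own
    x_comp = u_comp + a + e_comp
    if focal == 1:
        a_own, a_comp = weights.alpha_1, weights.alpha_2
    else:
        a_own, a_comp = weights.alpha_2, weights.alpha_1
    criterion = a_own * x_own + a_comp * x_comp
    sel = _top_k(criterion, k)
    theta_phi = design.theta_phi_1 if focal == 1 else design.theta_phi_2
    return (
        criterion,
        sel,
        theta_phi * v[sel].mean(),
        theta_phi * a[sel].mean(),
        float(np.var(criterion, ddof=1)),
    )


def _pure_cov_matrix(sp) -> np.ndarray:
    sd_p = sp.var_pure ** 0.5
    sd_v = sp.var_direct ** 0.5
    sd_a = sp.var_associate ** 0.5
    if sp.eta is None or sp.omega is None:
        raise ValueError("pure-stand simulation needs eta and omega")
    cov = np.array(
        [
            [sp.var_pure, sp.eta * sd_p * sd_v, sp.omega * sd_p * sd_a],
            [sp.eta * sd_p * sd_v, sp.var_direct, sp.cov_va],
            [sp.omega * sd_p * sd_a, sp.cov_va, sp.var_associate],
        ]
    )
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-10 * max(1.0, float(np.trace(cov))):
        raise ValueError(
            "correlations (eta, omega, rho_va) do not form a positive "
            "semidefinite joint distribution of (p, v, a); the pairwise "
            "closed forms remain valid but no joint population exists to "
            "simulate"
        )
    return cov


def _simulate_pure_process(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    focal: Literal[1, 2],
    n: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    sp = params.species1 if focal == 1 else params.species2
    cov = _pure_cov_matrix(sp)
    draws = rng.multivariate_normal(np.zeros(3), cov, size=n, method="svd")
    p, v, a = draws[:, 0], draws[:, 1], draws[:, 2]
    noise_var = sp.var_pure * (1.0 / sp.pure_design_h2 - 1.0)
    criterion = p + rng.normal(0.0, noise_var ** 0.5, size=n)
    sel = _top_k(criterion, k)
    phi = design.phi_1 if focal == 1 else design.phi_2
    theta_phi = design.theta_prime(focal) * phi
    return criterion, sel, theta_phi * v[sel].mean(), theta_phi * a[sel].mean()


def simulate_cycle(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    scheme: Scheme,
    weights: Optional[IndexWeights] = None,
    n_replicates: int = 500,
    seed: int = 0,
    weights_2: Optional[IndexWeights] = None,
    keep_cycles: bool = False,
) -> MonteCarloSummary:
    """Simulate ``n_replicates`` independent selection cycles.

    ``weights`` applies to the SRMA pair index or the species-1 SGMA
    process; ``weights_2`` (default: same as ``weights``) to the species-2
    process.  Pure-stand selection ignores the weights.  Replicate r uses the
    stream seeded by (seed, r), so results do not depend on execution order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if weights is None:
        weights = IndexWeights(alpha_1=1.0, alpha_2=1.0)
    if weights_2 is None:
        weights_2 = weights
    n = candidates_tested(design, scheme)
    k = candidates_selected(n, design.selection_rate)
    if k > n:
        raise ValueError("cannot select more candidates than tested")

    records: list[dict[str, float]] = []
    cycles: list[SimulatedCycle] = []
    for rep in range(n_replicates):
        rng = _rng(seed, rep)
        if scheme == "srma":
            criterion, sel, gains = _simulate_srma_once(
                params, design, weights, n, k, rng
            )
        elif scheme == "sgma":
            c1, s1, own1, comp1, var1 = _simulate_sgma_process(
                params, design, weights, 1, n, k, rng
            )
            c2, s2, own2, comp2, var2 = _simulate_sgma_process(
                params, design, weights_2, 2, n, k, rng
            )
            gx1 = own1 + comp2  # direct gain (proc 1) + associate gain (proc 2)
            gx2 = comp1 + own2
            gains = {
                "dG_x1": gx1,
                "dG_x2": gx2,
                "dG_total": gx1 + gx2,
                "dG_x11": own1,
                "dG_x21": comp1,
                "dG_x22": own2,
                "dG_x12": comp2,
                "criterion_variance": var1,
                "criterion_variance_2": var2,
            }
            criterion, sel = c1, s1
        elif scheme == "pure":
            c1, s1, own1, comp1 = _simulate_pure_process(
                params, design, 1, n, k, rng
            )
            c2, s2, own2, comp2 = _simulate_pure_process(
                params, design, 2, n, k, rng
            )
            gx1 = own1 + comp2
            gx2 = comp1 + own2
            gains = {
                "dG_x1": gx1,
                "dG_x2": gx2,
                "dG_total": gx1 + gx2,
                "dG_x11": own1,
                "dG_x21": comp1,
                "dG_x22": own2,
                "dG_x12": comp2,
            }
            criterion, sel = c1, s1
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        records.append(gains)
        if keep_cycles:
            cycles.append(
                SimulatedCycle(
                    scheme=scheme,
                    replicate=rep,
                    seed=seed,
                    criterion=criterion,
                    selected=sel,
                    gains=gains,
                )
            )

    frame = pd.DataFrame.from_records(records)
    mean = frame.mean().to_dict()
    se = (frame.std(ddof=1) / math.sqrt(n_replicates)).to_dict()
    if n_replicates == 1:
        se = {key: float("nan") for key in mean}
    return MonteCarloSummary(
        scheme=scheme,
        n_replicates=n_replicates,
        n_tested=n,
        n_selected=k,
        mean={key: float(val) for key, val in mean.items()},
        se={key: float(val) for key, val in se.items()},
        cycles=cycles,
    )


def generate_fixture(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    scheme: Scheme,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a tidy plot-level trial table for one simulated cycle.

    SRMA rows carry one plot of one pair-mixture (columns ``pair``,
    ``candidate_1``, ``candidate_2``, ``replicate``, ``x1``, ``x2``, ``y``
    with ``y = x1 + x2`` exactly); SGMA rows one plot of one family-vs-bulk
    mixture per process.  Byte-identical under a fixed seed.
    """
    rng = _rng(seed, 0)
    m = design.replicates
    n = candidates_tested(design, scheme)
    if scheme == "srma":
        s1, s2 = params.species1, params.species2
        v1, a1 = _bvn(rng, n, s1.var_direct, s1.var_associate, s1.cov_va)
        v2, a2 = _bvn(rng, n, s2.var_direct, s2.var_associate, s2.cov_va)
        cov12 = params.rho_va12_va21 * math.sqrt(
            params.var_va_12 * params.var_va_21
        )
        va12, va21 = _bvn(rng, n, params.var_va_12, params.var_va_21, cov12)
        ve1, ve2, cov_e = params.error_split()
        rows = []
        for pair in range(n):
            e1, e2 = _bvn(rng, m, ve1, ve2, cov_e)
            for rep in range(m):
                x1 = params.mean_u1 + v1[pair] + a2[pair] + va12[pair] + e1[rep]
                x2 = params.mean_u2 + v2[pair] + a1[pair] + va21[pair] + e2[rep]
                rows.append(
                    {
                        "pair": pair,
                        "candidate_1": pair,
                        "candidate_2": pair,
                        "replicate": rep,
                        "x1": x1,
                        "x2": x2,
                        "y": x1 + x2,
                    }
                )
        return pd.DataFrame(rows)
    if scheme == "sgma":
        rows = []
        for focal in (1, 2):
            sp = params.species1 if focal == 1 else params.species2
            v, a = _bvn(rng, n, sp.var_direct, sp.var_associate, sp.cov_va)
            ve_own, ve_comp, cov_e = params.error_split()
            if focal == 2:
                ve_own, ve_comp = ve_comp, ve_own
            u_own = params.mean_u1 if focal == 1 else params.mean_u2
            u_comp = params.mean_u2 if focal == 1 else params.mean_u1
            for cand in range(n):
                e_own, e_comp = _bvn(rng, m, ve_own, ve_comp, cov_e)
                for rep in range(m):
                    x_focal = u_own + v[cand] + e_own[rep]
                    x_bulk = u_comp + a[cand] + e_comp[rep]
                    rows.append(
                        {
                            "species": focal,
                            "candidate": cand,
                            "replicate": rep,
                            "x_focal": x_focal,
                            "x_bulk": x_bulk,
                            "y": x_focal + x_bulk,
                        }
                    )
        return pd.DataFrame(rows)
    if scheme == "pure":
        rows = []
        for focal in (1, 2):
            sp = params.species1 if focal == 1 else params.species2
            cov = _pure_cov_matrix(sp)
            draws = rng.multivariate_normal(np.zeros(3), cov, size=n, method="svd")
            noise_var = sp.var_pure * (1.0 / sp.pure_design_h2 - 1.0)
            u_pure = params.mean_u1_pure if focal == 1 else 0.0
            for cand in range(n):
                errs = rng.normal(0.0, (noise_var * m) ** 0.5, size=m)
                for rep in range(m):
                    rows.append(
                        {
                            "species": focal,
                            "candidate": cand,
                            "replicate": rep,
                            "yp": u_pure + draws[cand, 0] + errs[rep],
                        }
                    )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scheme {scheme!r}")
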