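"""General mixture-ability selection (SGMA).

Two parallel recurrent selections, one per species: each candidate's progeny
family is tested in mixture with a balanced bulk of all partner-species
families, so the genetic component of the tested performance is the
candidate's GMA.  Each process applies its own linear index to the two
observed contributions; expected responses are cumulated over the processes.
The index pair can be optimized to maximize the cumulated
mixture-performance response subject to a target ratio of the cumulated
species-contribution responses.

Because each process's responses are invariant under positive rescaling of
its own weight pair, an index is parameterized by a single angle t, with
(own, companion) weights (cos t, sin t); the search space of the constrained
optimization is the 2-torus, and both the objective and the constraint
separate into single-angle terms, which the grid-plus-polish optimizer
exploits.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy import optimize

from .model_core import (
    MixtureGeneticParams,
    sgma_criterion_variance,
)
from .selection_math import SchemeDesign, selection_intensity
from .srma import IndexWeights, ResponseRatioTarget, ResponseSet

__all__ = [
    "sgma_process_responses",
    "sgma_cumulated",
    "optimize_sgma_indices",
    "InfeasibleTargetError",
]

#: relative tolerance on the ratio constraint at the optimizer's solution
CONSTRAINT_RTOL = 1e-6


class InfeasibleTargetError(ValueError):
    """No index pair achieves the requested contribution-response ratio."""

    def __init__(self, message: str, closest_ratio: tuple[float, float]):
        super().__init__(message)
        self.closest_ratio = closest_ratio


def _own_companion(weights: IndexWeights, focal: Literal[1, 2]) -> tuple[float, float]:
    if focal == 1:
        return weights.alpha_1, weights.alpha_2
    return weights.alpha_2, weights.alpha_1


def sgma_process_responses(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights: IndexWeights,
    focal_species: Literal[1, 2],
    intensity: float | None = None,
) -> ResponseSet:
    """Expected responses from one SGMA process.

    ``dG_x1``/``dG_x2`` are the gains on the species-1 and species-2
    contributions produced by selecting in ``focal_species``: the focal
    species gains through its direct effect, the companion through the focal
    candidates' associate effect.  With weights (1, 1) the total is the GMA
    response of the focal species.
    """
    i = selection_intensity(design.selection_rate) if intensity is None else intensity
    sd = sgma_criterion_variance(
        params, weights, design.replicates, focal_species
    ) ** 0.5
    sp = params.species1 if focal_species == 1 else params.species2
    theta_phi = design.theta_phi_1 if focal_species == 1 else design.theta_phi_2
    a_own, a_comp = _own_companion(weights, focal_species)
    gain_own = theta_phi * i * (a_own * sp.var_direct + a_comp * sp.cov_va) / sd
    gain_comp = theta_phi * i * (a_own * sp.cov_va + a_comp * sp.var_associate) / sd
    if focal_species == 1:
        dG_x1, dG_x2 = gain_own, gain_comp
    else:
        dG_x1, dG_x2 = gain_comp, gain_own
    return ResponseSet(dG_x1=dG_x1, dG_x2=dG_x2, flavor="after_recombination")


def sgma_cumulated(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    weights_1: IndexWeights,
    weights_2: IndexWeights,
    intensity: float | None = None,
) -> ResponseSet:
    """Responses cumulated over the two parallel SGMA processes.

    Each species' contribution gain sums the direct-effect gain from its own
    process and the associate-effect gain from the companion process;
    processes run at the same pace (same selection rate).
    """
    p1 = sgma_process_responses(params, design, weights_1, 1, intensity)
    p2 = sgma_process_responses(params, design, weights_2, 2, intensity)
    by_process = {
        "dG_x11": p1.dG_x1,
        "dG_x21": p1.dG_x2,
        "dG_x22": p2.dG_x2,
        "dG_x12": p2.dG_x1,
    }
    return ResponseSet(
        dG_x1=p1.dG_x1 + p2.dG_x1,
        dG_x2=p1.dG_x2 + p2.dG_x2,
        flavor="after_recombination",
        by_process=by_process,
    )


# ---------------------------------------------------------------------------
# constrained optimization of the index pair


def _process_curves(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    focal: Literal[1, 2],
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (focal-contribution, companion-contribution) responses.

    Index weights on the (own, companion) basis are (cos t, sin t).
    """
    sp = params.species1 if focal == 1 else params.species2
    theta_phi = design.theta_phi_1 if focal == 1 else design.theta_phi_2
    i = selection_intensity(design.selection_rate)
    ve_own, ve_comp, cov_e = params.error_split()
    if focal == 2:
        ve_own, ve_comp = ve_comp, ve_own
    m = design.replicates
    v00 = sp.var_direct + ve_own / m
    v11 = sp.var_associate + ve_comp / m
    v01 = sp.cov_va + cov_e / m
    c, s = np.cos(t), np.sin(t)
    var_i = c * c * v00 + s * s * v11 + 2.0 * c * s * v01
    sd = np.sqrt(np.maximum(var_i, 0.0))
    cov_own = c * sp.var_direct + s * sp.cov_va
    cov_comp = c * sp.cov_va + s * sp.var_associate
    with np.errstate(divide="ignore", invalid="ignore"):
        g_own = np.where(sd > 0, theta_phi * i * cov_own / sd, np.nan)
        g_comp = np.where(sd > 0, theta_phi * i * cov_comp / sd, np.nan)
    return g_own, g_comp


def _axis_terms(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    target: ResponseRatioTarget,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-angle objective and constraint terms (f1, h1, f2, h2).

    Objective F(t1, t2) = f1(t1) + f2(t2) is the cumulated
    mixture-performance response; constraint H = h1(t1) + h2(t2) = 0 encodes
    k2 * dG_x1 - k1 * dG_x2 = 0 in product form (no division by responses).
    """
    k1, k2 = target.k1, target.k2
    g11, g21 = _process_curves(params, design, 1, t)  # own, companion
    g22, g12 = _process_curves(params, design, 2, t)  # own, companion
    f1, h1 = g11 + g21, k2 * g11 - k1 * g21
    f2, h2 = g12 + g22, k2 * g12 - k1 * g22
    return f1, h1, f2, h2


def _scalar_terms_factory(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    target: ResponseRatioTarget,
    focal: Literal[1, 2],
):
    """Fast scalar (f, h)(t) closures for one process, for the polish stage."""
    sp = params.species1 if focal == 1 else params.species2
    theta_phi = design.theta_phi_1 if focal == 1 else design.theta_phi_2
    i = selection_intensity(design.selection_rate)
    ve_own, ve_comp, cov_e = params.error_split()
    if focal == 2:
        ve_own, ve_comp = ve_comp, ve_own
    m = design.replicates
    v00 = sp.var_direct + ve_own / m
    v11 = sp.var_associate + ve_comp / m
    v01 = sp.cov_va + cov_e / m
    sv, sa, cva = sp.var_direct, sp.var_associate, sp.cov_va
    if focal == 1:
        k_own, k_comp = target.k2, -target.k1
    else:
        k_own, k_comp = -target.k1, target.k2

    def terms(tv: float) -> tuple[float, float]:
        c, s = math.cos(tv), math.sin(tv)
        sd = math.sqrt(max(c * c * v00 + s * s * v11 + 2.0 * c * s * v01, 0.0))
        g_own = theta_phi * i * (c * sv + s * cva) / sd
        g_comp = theta_phi * i * (c * cva + s * sa) / sd
        return g_own + g_comp, k_own * g_own + k_comp * g_comp

    return terms


def _weights_from_angles(t1: float, t2: float) -> tuple[IndexWeights, IndexWeights]:
    w1 = IndexWeights(alpha_1=math.cos(t1), alpha_2=math.sin(t1))
    # species-2 process: own weight is alpha_2, companion weight alpha_1
    w2 = IndexWeights(alpha_1=math.sin(t2), alpha_2=math.cos(t2))
    return w1, w2


def grid_oracle(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    target: ResponseRatioTarget,
    n_angles: int = 721,
) -> float:
    """Brute-force constrained maximum over a dense torus grid.

    For each t1 angle, zero crossings of h2(t2) = -h1(t1) are located on the
    t2 grid and the objective linearly interpolated at the crossing.  Serves
    as the independent check of :func:`optimize_sgma_indices`.
    """
    t = np.linspace(-math.pi, math.pi, n_angles)
    f1, h1, f2, h2 = _axis_terms(params, design, target, t)
    # wrap for periodic crossing detection
    h2w = np.concatenate([h2, h2[:1]])
    f2w = np.concatenate([f2, f2[:1]])
    best = -np.inf
    for i in range(n_angles):
        rhs = -h1[i]
        d = h2w - rhs
        cross = np.nonzero(d[:-1] * d[1:] <= 0.0)[0]
        for j in cross:
            denom = d[j + 1] - d[j]
            frac = 0.0 if denom == 0.0 else -d[j] / denom
            val = f1[i] + f2w[j] + frac * (f2w[j + 1] - f2w[j])
            if val > best:
                best = val
    return float(best)


def optimize_sgma_indices(
    params: MixtureGeneticParams,
    design: SchemeDesign,
    target: ResponseRatioTarget,
    coarse_step_deg: float = 1.0,
) -> tuple[IndexWeights, IndexWeights, ResponseSet]:
    """Index pair maximizing the cumulated response at a target ratio.

    Deterministic two-stage search: a coarse torus grid locates every branch
    of the constraint zero set (which can be disconnected), then a
    derivative-free polish refines the best branches — t2 is solved from t1
    by bracketed root-finding on the constraint and the objective maximized
    over t1 by bounded scalar minimization.  Raises
    :class:`InfeasibleTargetError` when no weight pair achieves the ratio,
    reporting the closest achievable one.
    """
    n = max(8, int(round(360.0 / coarse_step_deg)))
    t = np.linspace(-math.pi, math.pi, n, endpoint=False)
    f1, h1, f2, h2 = _axis_terms(params, design, target, t)

    h_min = h1.min() + h2.min()
    h_max = h1.max() + h2.max()
    if h_min > 0.0 or h_max < 0.0:
        # closest achievable ratio over the coarse grid
        habs = np.abs(h1[:, None] + h2[None, :])
        i0, j0 = np.unravel_index(np.argmin(habs), habs.shape)
        g11, g21 = _process_curves(params, design, 1, t[i0 : i0 + 1])
        g22, g12 = _process_curves(params, design, 2, t[j0 : j0 + 1])
        closest = (float(g11[0] + g12[0]), float(g21[0] + g22[0]))
        raise InfeasibleTargetError(
            f"target ratio ({target.k1}, {target.k2}) is infeasible; "
            f"closest achievable contribution responses {closest}",
            closest,
        )

    terms1 = _scalar_terms_factory(params, design, target, 1)
    terms2 = _scalar_terms_factory(params, design, target, 2)

    # fine 1D grid of h2 for root bracketing during the polish
    n_fine = 4 * n + 1
    t_fine = np.linspace(-math.pi, math.pi, n_fine)
    h2_fine = np.array([terms2(tv)[1] for tv in t_fine])

    def _roots_t2(rhs: float) -> list[float]:
        d = h2_fine - rhs
        out = []
        sign_change = np.nonzero(d[:-1] * d[1:] <= 0.0)[0]
        for j in sign_change:
            lo, hi = t_fine[j], t_fine[j + 1]
            if d[j] == 0.0:
                out.append(float(lo))
                continue
            out.append(
                float(
                    optimize.brentq(
                        lambda x: terms2(x)[1] - rhs, lo, hi, xtol=1e-13
                    )
                )
            )
        return out

    def _neg_best_over_t2(t1v: float) -> tuple[float, float]:
        """(negated objective, best t2) for the best feasible t2 at t1v."""
        f1v, h1v = terms1(t1v)
        best_val, best_t2 = -np.inf, None
        for t2v in _roots_t2(-h1v):
            f2v = terms2(t2v)[0]
            if f1v + f2v > best_val:
                best_val, best_t2 = f1v + f2v, t2v
        if best_t2 is None:
            # large finite penalty: keeps the bounded scalar search numeric
            return 1e6, np.nan
        return -best_val, best_t2

    # coarse scan of the constraint zero set: for each t1 cell take the best
    # interpolated crossing, keep the top few starting cells
    h2w = np.concatenate([h2, h2[:1]])
    f2w = np.concatenate([f2, f2[:1]])
    coarse: list[tuple[float, float]] = []  # (objective approx, t1)
    for i in range(n):
        rhs = -h1[i]
        d = h2w - rhs
        cross = np.nonzero(d[:-1] * d[1:] <= 0.0)[0]
        best_here = -np.inf
        for j in cross:
            denom = d[j + 1] - d[j]
            frac = 0.0 if denom == 0.0 else -d[j] / denom
            val = f1[i] + f2w[j] + frac * (f2w[j + 1] - f2w[j])
            best_here = max(best_here, val)
        if np.isfinite(best_here):
            coarse.append((best_here, t[i]))
    if not coarse:
        raise InfeasibleTargetError(
            "constraint zero set not located on the coarse grid",
            (float("nan"), float("nan")),
        )
    coarse.sort(reverse=True)
    step = 2.0 * math.pi / n

    best_obj, best_pair = -np.inf, None
    seen: list[float] = []
    for approx, t1c in coarse[:6]:
        if any(abs(t1c - s) < 2.0 * step for s in seen):
            continue
        seen.append(t1c)
        res = optimize.minimize_scalar(
            lambda x: _neg_best_over_t2(x)[0],
            bounds=(t1c - 1.5 * step, t1c + 1.5 * step),
            method="bounded",
            options={"xatol": 1e-10},
        )
        neg, t2_best = _neg_best_over_t2(float(res.x))
        if -neg > best_obj:
            best_obj, best_pair = -neg, (float(res.x), t2_best)

    assert best_pair is not None
    w1, w2 = _weights_from_angles(*best_pair)
    responses = sgma_cumulated(params, design, w1, w2)
    resid = target.k2 * responses.dG_x1 - target.k1 * responses.dG_x2
    scale = max(abs(responses.dG_total), 1e-9)
    if abs(resid) > CONSTRAINT_RTOL * scale:
        raise RuntimeError(
            f"optimizer failed to satisfy the ratio constraint "
            f"(residual {resid:.3e} vs scale {scale:.3e})"
        )
    return w1, w2, responses
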