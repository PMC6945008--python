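"""Parameter-grid studies comparing the three selection schemes.

Named presets encode the numerical settings used throughout the package's
worked comparisons: direct-effect variance 1 in both species, mixture
plot-error variance 2, three replicates, 10% selection with the reciprocal
scheme versus 20% with the parallel schemes (equal plot budgets), theta*phi
= 1, interaction variances set to half the partner's associate-effect
variance, and a direct-associate correlation swept from -1 to 1.  The grids
produce tidy tables of expected responses; figure values are qualitative
summaries of those tables, not asserted constants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .model_core import (
    MixtureGeneticParams,
    SpeciesGeneticParams,
    srma_criterion_variance,
)
from .selection_math import SchemeDesign
from .sgma import InfeasibleTargetError, optimize_sgma_indices, sgma_cumulated
from .srma import (
    IndexWeights,
    ResponseRatioTarget,
    solve_srma_index,
    srma_responses_after,
    srma_responses_before,
)
from .pure_stand import pure_stand_responses

__all__ = [
    "GridSpec",
    "preset",
    "list_presets",
    "run_grid",
    "plot_grid",
    "default_designs",
    "make_params",
    "consistent_error_split",
]

logger = logging.getLogger(__name__)

RHO_GRID = [round(x, 3) for x in np.linspace(-1.0, 1.0, 17)]
ONES = IndexWeights(alpha_1=1.0, alpha_2=1.0)
EQUAL_TARGET = ResponseRatioTarget(k1=1.0, k2=1.0)


@dataclass(frozen=True)
class GridSpec:
    """A named parameter grid: axis values crossed over a fixed block."""

    name: str
    axes: dict[str, list[Any]]
    fixed: dict[str, Any] = field(default_factory=dict)


def default_designs(
    total_plots: int = 900, replicates: int = 3
) -> dict[str, SchemeDesign]:
    """Scheme designs under the standard equal-budget comparison.

    The reciprocal scheme tests twice as many candidates per species for the
    same budget, so it selects at 10% where the parallel schemes select at
    20% (same number of selected candidates).
    """
    return {
        "srma": SchemeDesign(
            total_plots=total_plots, replicates=replicates, selection_rate=0.10
        ),
        "sgma": SchemeDesign(
            total_plots=total_plots, replicates=replicates, selection_rate=0.20
        ),
        "pure": SchemeDesign(
            total_plots=total_plots, replicates=replicates, selection_rate=0.20
        ),
    }


def consistent_error_split(
    var_plot_error: float, rho_e: float
) -> tuple[float, float, float]:
    """Equal-variance split of the plot error eps = e1 + e2.

    Returns (var_e1, var_e2, rho_e) with var_e1 = var_e2 chosen so the sum
    reproduces ``var_plot_error`` at the requested error correlation.
    """
    if rho_e <= -1.0:
        raise ValueError("rho_e must be > -1 for a finite split")
    e = var_plot_error / (2.0 + 2.0 * rho_e)
    return e, e, rho_e


def make_params(
    var_associate_1: float,
    var_associate_2: float,
    rho: float,
    var_direct: float = 1.0,
    var_plot_error: float = 2.0,
    rho_e: float | None = None,
    eta: float | None = None,
    omega: float | None = None,
    pure_design_h2: float = 0.6,
    interaction_rule: bool = True,
) -> MixtureGeneticParams:
    """Standard-setting parameter builder.

    ``rho`` sets the direct-associate correlation in both species and the
    correlation between the two interaction effects.  Under the
    ``interaction_rule`` the interaction variances are half the partner's
    associate-effect variance.  ``rho_e`` optionally fixes the correlation
    of the two error components through the equal-variance consistent split.
    """
    sp_kwargs: dict[str, Any] = {}
    if eta is not None:
        sp_kwargs["eta"] = eta
    if omega is not None:
        sp_kwargs["omega"] = omega
    species1 = SpeciesGeneticParams(
        var_direct=var_direct,
        var_associate=var_associate_1,
        rho_va=rho,
        pure_design_h2=pure_design_h2,
        **sp_kwargs,
    )
    species2 = SpeciesGeneticParams(
        var_direct=var_direct,
        var_associate=var_associate_2,
        rho_va=rho,
        pure_design_h2=pure_design_h2,
        **sp_kwargs,
    )
    err_kwargs: dict[str, Any] = {}
    if rho_e is not None:
        ve1, ve2, re = consistent_error_split(var_plot_error, rho_e)
        err_kwargs = {"var_e1": ve1, "var_e2": ve2, "rho_e1_e2": re}
    return MixtureGeneticParams(
        species1=species1,
        species2=species2,
        var_va_12=var_associate_2 / 2.0 if interaction_rule else 0.0,
        var_va_21=var_associate_1 / 2.0 if interaction_rule else 0.0,
        rho_va12_va21=rho,
        var_plot_error_mixture=var_plot_error,
        **err_kwargs,
    )


_SA_PAIRS = [(0.5, 0.1), (1.0, 0.1), (1.0, 0.5)]

_PRESETS: dict[str, GridSpec] = {
    "fig4": GridSpec(
        name="fig4",
        axes={"rho": RHO_GRID, "var_associate": [0.1, 0.5]},
        fixed={"kind": "scheme_comparison"},
    ),
    "fig5": GridSpec(
        name="fig5",
        axes={
            "rho": RHO_GRID,
            "var_associate": [0.1, 0.5],
            "eta": [-0.25, 0.5, 0.75],
            "omega": [-0.5, 0.0, 0.5],
        },
        fixed={"kind": "pure_vs_sgma", "pure_design_h2": 0.6},
    ),
    "fig6": GridSpec(
        name="fig6",
        axes={"rho": RHO_GRID, "sa_pair": _SA_PAIRS},
        fixed={"kind": "contribution_responses"},
    ),
    "fig7": GridSpec(
        name="fig7",
        axes={"rho": RHO_GRID, "sa_pair": _SA_PAIRS},
        fixed={"kind": "srma_index", "rho_e": -0.5},
    ),
    "fig8": GridSpec(
        name="fig8",
        axes={"rho": RHO_GRID, "sa_pair": _SA_PAIRS},
        fixed={"kind": "sgma_index", "rho_e": -0.5},
    ),
    "s2": GridSpec(
        name="s2",
        axes={"rho": RHO_GRID, "sa_pair": _SA_PAIRS},
        fixed={"kind": "srma_index", "rho_e": 0.5},
    ),
    "s3": GridSpec(
        name="s3",
        axes={"rho": RHO_GRID, "sa_pair": _SA_PAIRS},
        fixed={"kind": "sgma_index", "rho_e": 0.5},
    ),
}


def preset(name: str) -> GridSpec:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def list_presets() -> dict[str, GridSpec]:
    return dict(_PRESETS)


def _iter_rows(spec: GridSpec):
    keys = list(spec.axes)
    for combo in itertools.product(*(spec.axes[k] for k in keys)):
        yield dict(zip(keys, combo))


def _row_scheme_comparison(axes: dict, fixed: dict, designs) -> dict:
    sa = axes["var_associate"]
    params = make_params(sa, sa, axes["rho"])
    before = srma_responses_before(params, designs["srma"], ONES)
    after = srma_responses_after(params, designs["srma"], ONES)
    g = sgma_cumulated(params, designs["sgma"], ONES, ONES)
    return {
        "rho": axes["rho"],
        "var_associate": sa,
        "dG_R_before": before.dG_total,
        "dG_R_after": after.dG_total,
        "dG_G": g.dG_total,
        "status": "ok",
    }


def _row_pure_vs_sgma(axes: dict, fixed: dict, designs) -> dict:
    sa = axes["var_associate"]
    params = make_params(
        sa,
        sa,
        axes["rho"],
        eta=axes["eta"],
        omega=axes["omega"],
        pure_design_h2=fixed.get("pure_design_h2", 0.6),
    )
    p = pure_stand_responses(params, designs["pure"])
    g = sgma_cumulated(params, designs["sgma"], ONES, ONES)
    row = {
        "rho": axes["rho"],
        "var_associate": sa,
        "eta": axes["eta"],
        "omega": axes["omega"],
        "dG_P": p.dG_total,
        "dG_G": g.dG_total,
        "status": "ok",
    }
    if g.dG_total > 0.0:
        row["ratio_P_over_G"] = p.dG_total / g.dG_total
    else:  # ratio undefined: mixture response non-positive in the denominator
        row["ratio_P_over_G"] = float("nan")
        row["status"] = "undefined_ratio"
    return row


def _row_contribution_responses(axes: dict, fixed: dict, designs) -> dict:
    sa1, sa2 = axes["sa_pair"]
    params = make_params(sa1, sa2, axes["rho"])
    g = sgma_cumulated(params, designs["sgma"], ONES, ONES)
    r = srma_responses_after(params, designs["srma"], ONES)
    return {
        "rho": axes["rho"],
        "var_associate_1": sa1,
        "var_associate_2": sa2,
        "dG_G": g.dG_total,
        "dG_x1_G": g.dG_x1,
        "dG_x2_G": g.dG_x2,
        "dG_R": r.dG_total,
        "dG_x1_R": r.dG_x1,
        "dG_x2_R": r.dG_x2,
        "status": "ok",
    }


def _row_srma_index(axes: dict, fixed: dict, designs) -> dict:
    sa1, sa2 = axes["sa_pair"]
    params = make_params(sa1, sa2, axes["rho"], rho_e=fixed["rho_e"])
    design = designs["srma"]
    row: dict[str, Any] = {
        "rho": axes["rho"],
        "var_associate_1": sa1,
        "var_associate_2": sa2,
        "var_va_12": sa2 / 2.0,
        "var_va_21": sa1 / 2.0,
    }
    plain_before = srma_responses_before(params, design, ONES)
    plain_after = srma_responses_after(params, design, ONES)
    row["dG_y_before"] = plain_before.dG_total
    row["dG_y_after"] = plain_after.dG_total
    try:
        weights = solve_srma_index(params, EQUAL_TARGET)
    except ValueError as exc:
        row.update(status=f"unsolvable: {exc}")
        return row
    before = srma_responses_before(params, design, weights)
    after = srma_responses_after(params, design, weights)
    row.update(
        alpha_1=weights.alpha_1,
        alpha_2=weights.alpha_2,
        sigma_I=srma_criterion_variance(params, weights, design.replicates)
        ** 0.5,
        dG_before=before.dG_total,
        dG_x1_before=before.dG_x1,
        dG_x2_before=before.dG_x2,
        dG_after=after.dG_total,
        dG_x1_after=after.dG_x1,
        dG_x2_after=after.dG_x2,
        status="ok",
    )
    return row


def _row_sgma_index(axes: dict, fixed: dict, designs) -> dict:
    sa1, sa2 = axes["sa_pair"]
    params = make_params(sa1, sa2, axes["rho"], rho_e=fixed["rho_e"])
    design = designs["sgma"]
    row: dict[str, Any] = {
        "rho": axes["rho"],
        "var_associate_1": sa1,
        "var_associate_2": sa2,
    }
    plain = sgma_cumulated(params, design, ONES, ONES)
    row["dG_y"] = plain.dG_total
    try:
        w1, w2, resp = optimize_sgma_indices(params, design, EQUAL_TARGET)
    except InfeasibleTargetError as exc:
        row.update(status=f"infeasible: {exc}")
        return row
    assert resp.by_process is not None
    row.update(
        alpha_11=w1.alpha_1,
        alpha_21=w1.alpha_2,
        alpha_12=w2.alpha_1,
        alpha_22=w2.alpha_2,
        dG_G=resp.dG_total,
        dG_x1_G=resp.dG_x1,
        dG_x2_G=resp.dG_x2,
        **resp.by_process,
        status="ok",
    )
    return row


_ROW_FNS: dict[str, Callable] = {
    "scheme_comparison": _row_scheme_comparison,
    "pure_vs_sgma": _row_pure_vs_sgma,
    "contribution_responses": _row_contribution_responses,
    "srma_index": _row_srma_index,
    "sgma_index": _row_sgma_index,
}


def run_grid(spec: GridSpec) -> pd.DataFrame:
    """Evaluate a grid spec row by row; deterministic (pure closed forms).

    Rows whose index target cannot be solved carry the failure in the
    ``status`` column and are retained.
    """
    kind = spec.fixed.get("kind")
    if kind not in _ROW_FNS:
        raise ValueError(f"grid spec {spec.name!r} has unknown kind {kind!r}")
    designs = default_designs(
        total_plots=spec.fixed.get("total_plots", 900),
        replicates=spec.fixed.get("replicates", 3),
    )
    fn = _ROW_FNS[kind]
    rows = [fn(axes, spec.fixed, designs) for axes in _iter_rows(spec)]
    return pd.DataFrame(rows)


def plot_grid(
    results: pd.DataFrame, spec: GridSpec, out_dir: str | Path
) -> list[Path]:
    """Line plots of the grid responses against rho, panelled by setting.

    Returns the written file paths; an empty table writes nothing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if results.empty:
        logger.warning("empty results table for %s: no figure written", spec.name)
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = spec.fixed.get("kind")

    if kind == "scheme_comparison":
        panels = sorted(results["var_associate"].unique())
        fig, axs = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4))
        axs = np.atleast_1d(axs)
        for ax, sa in zip(axs, panels):
            sub = results[results["var_associate"] == sa]
            for col, label in [
                ("dG_R_before", "reciprocal, before recomb."),
                ("dG_R_after", "reciprocal, after recomb."),
                ("dG_G", "parallel GMA"),
            ]:
                ax.plot(sub["rho"], sub[col], marker="o", ms=3, label=label)
            ax.set_title(f"associate variance = {sa}")
            ax.set_xlabel("direct-associate correlation")
            ax.set_ylabel("expected mixture response")
        axs[0].legend(fontsize=8)
    elif kind == "pure_vs_sgma":
        panels = sorted(results["var_associate"].unique())
        fig, axs = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4))
        axs = np.atleast_1d(axs)
        for ax, sa in zip(axs, panels):
            sub = results[results["var_associate"] == sa]
            for (eta, omega), grp in sub.groupby(["eta", "omega"]):
                ax.plot(
                    grp["rho"],
                    grp["ratio_P_over_G"],
                    marker="o",
                    ms=2,
                    label=f"eta={eta}, omega={omega}",
                )
            ax.axhline(1.0, color="grey", lw=0.5)
            ax.set_title(f"associate variance = {sa}")
            ax.set_xlabel("direct-associate correlation")
            ax.set_ylabel("pure-stand / GMA response ratio")
        axs[0].legend(fontsize=6)
    else:
        pair_cols = ["var_associate_1", "var_associate_2"]
        panels = sorted(set(map(tuple, results[pair_cols].values)))
        value_cols = [
            c
            for c in results.columns
            if c.startswith("dG") and results[c].dtype.kind == "f"
        ]
        fig, axs = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4))
        axs = np.atleast_1d(axs)
        for ax, pair in zip(axs, panels):
            mask = (results[pair_cols[0]] == pair[0]) & (
                results[pair_cols[1]] == pair[1]
            )
            sub = results[mask]
            for col in value_cols:
                ax.plot(sub["rho"], sub[col], marker="o", ms=2, label=col)
            ax.set_title(f"associate variances = {pair}")
            ax.set_xlabel("direct-associate correlation")
            ax.set_ylabel("expected response")
        axs[0].legend(fontsize=6)

    fig.tight_layout()
    path = out_dir / f"{spec.name}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return [path]
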