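"""Social-dilemma certification, comparative statics, and parameter sweeps.

The equilibrium of the norm-change game under-provides effort: because each
woman's persuasion also protects every other woman's relationship, there is
always a pair of women who would both be better off raising their efforts
together (a social dilemma).  :func:`social_dilemma_certificate` exhibits such
a joint deviation numerically.  :func:`comparative_statics` scales whole
parameter blocks and checks the predicted direction of equilibrium violence,
and :func:`sweep` produces the tidy tables behind the scenario figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model import (
    AltruismSpec,
    AttitudeModel,
    CommunityParams,
    EquilibriumState,
    ScaleFactors,
    men_best_response,
    welfare,
)
from .altruism import solve

__all__ = [
    "DilemmaCertificate",
    "social_dilemma_certificate",
    "uniform_deviation_welfare",
    "ComparativeStaticsReport",
    "ComparativeStaticsError",
    "comparative_statics",
    "sweep",
    "summarize_across_women",
    "SWEEP_COLUMNS",
]

SWEEP_COLUMNS = [
    "scenario",
    "grid_param",
    "grid_value",
    "woman",
    "violence",
    "effort",
    "welfare",
    "exists",
    "converged",
    "seed",
]

# Predicted direction of equilibrium violence in each block scale factor;
# kappa (violence cost) and nu (norm payoffs) are genuinely ambiguous.
ASSERTED_SIGNS = {
    "sigma": "decreasing",
    "alpha": "decreasing",
    "tau": "increasing",
    "gamma": "increasing",
}
SCALE_FACTOR_NAMES = ("sigma", "tau", "gamma", "kappa", "nu", "alpha")
ALTRUISM_PARAM_VARIANTS = {"b": "process", "eta": "empathetic", "rho": "reciprocal"}


@dataclass
class DilemmaCertificate:
    """A joint effort deviation making both named women strictly better off."""

    found: bool
    delta_e1: float
    delta_e2: float
    dW1: float
    dW2: float


def _deviation_welfare_pair(
    state: EquilibriumState,
    p: CommunityParams,
    model: AttitudeModel,
    pair: tuple[tuple[int, int], tuple[int, int]],
    d1: float,
    d2: float,
) -> tuple[float, float]:
    (w1, man_i), (w2, man_j) = pair
    E = state.efforts.copy()
    E[man_i, w1] += d1
    E[man_j, w2] += d2
    a = model.attitudes(E)
    v = men_best_response(a, p)
    W = welfare(E, v, p)
    return float(W[w1] - state.welfare[w1]), float(W[w2] - state.welfare[w2])


def social_dilemma_certificate(
    state: EquilibriumState,
    p: CommunityParams,
    model: AttitudeModel,
    pair: tuple[tuple[int, int], tuple[int, int]],
    *,
    grid: tuple[float, float, int] = (1e-4, 1.0, 50),
) -> DilemmaCertificate:
    """Search for a joint deviation raising both women's welfare.

    ``pair = ((woman1, man_i), (woman2, man_j))`` (0-based indices): woman 1
    raises her effort on man ``i`` and woman 2 her effort on man ``j`` by a
    common increment, with men re-best-responding and all other efforts held
    at equilibrium.  The increment is scanned on a log-spaced grid and refined
    once around the best point.  Existence of such a deviation is the
    operational content of the social dilemma.
    """
    if not (state.exists and state.converged):
        raise ValueError("certificate requires an existing, converged equilibrium")
    lo, hi, num = grid
    deltas = np.geomspace(lo, hi, num)
    best_delta, best_score = None, -np.inf
    for d in deltas:
        dW1, dW2 = _deviation_welfare_pair(state, p, model, pair, d, d)
        score = min(dW1, dW2)
        if score > best_score:
            best_delta, best_score = d, score
    # refine once around the best grid point
    refined = np.geomspace(best_delta / 3.0, best_delta * 3.0, num)
    for d in refined:
        dW1, dW2 = _deviation_welfare_pair(state, p, model, pair, d, d)
        score = min(dW1, dW2)
        if score > best_score:
            best_delta, best_score = d, score
    dW1, dW2 = _deviation_welfare_pair(state, p, model, pair, best_delta, best_delta)
    found = dW1 > 0 and dW2 > 0
    return DilemmaCertificate(found, float(best_delta), float(best_delta), dW1, dW2)


def uniform_deviation_welfare(
    state: EquilibriumState,
    p: CommunityParams,
    model: AttitudeModel,
    delta: float,
) -> NDArray[np.float64]:
    """Welfare of every woman when all efforts rise by ``delta`` above
    equilibrium, with men re-best-responding."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    E = state.efforts + delta
    a = model.attitudes(E)
    v = men_best_response(a, p)
    return welfare(E, v, p)


@dataclass
class ComparativeStaticsReport:
    """Empirical direction of mean equilibrium violence along a scale grid."""

    factor: str
    table: pd.DataFrame  # columns: factor, value, mean_violence
    direction: str  # "decreasing" | "increasing" | "non-monotone" | "constant"
    expected: str | None  # None when the theory makes no directional claim
    holds: bool | None


class ComparativeStaticsError(AssertionError):
    """A predicted monotonicity failed on the supplied grid."""


def _direction(values: NDArray[np.float64]) -> str:
    d = np.diff(values)
    if np.all(d < 0):
        return "decreasing"
    if np.all(d > 0):
        return "increasing"
    if np.allclose(d, 0):
        return "constant"
    return "non-monotone"


def comparative_statics(
    p: CommunityParams,
    model: AttitudeModel,
    factor: str,
    grid,
    *,
    alt: AltruismSpec = AltruismSpec.none(),
    check: bool = True,
    **solver_kwargs,
) -> ComparativeStaticsReport:
    """Recompute the equilibrium under block scalings and report the direction
    of mean violence.

    Violence is predicted to decrease in ``sigma`` (suffering) and ``alpha``
    (effectiveness) and increase in ``tau`` (tolerance) and ``gamma`` (effort
    cost); with ``check=True`` a violated prediction raises
    :class:`ComparativeStaticsError`.  ``kappa`` and ``nu`` are ambiguous and
    only reported.
    """
    if factor not in SCALE_FACTOR_NAMES:
        raise ValueError(f"unknown scale factor {factor!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("comparative statics needs at least two grid points")
    if np.any(grid < 0):
        raise ValueError("grid values must be nonnegative")
    rows = []
    for g in grid:
        sf = ScaleFactors(**{factor: float(g)})
        p_g, model_g = sf.apply(p, model)
        state = solve(p_g, model_g, alt, **solver_kwargs)
        rows.append(
            {
                "factor": factor,
                "value": float(g),
                "mean_violence": float(np.mean(state.violence)),
            }
        )
    table = pd.DataFrame(rows)
    direction = _direction(table["mean_violence"].to_numpy())
    expected = ASSERTED_SIGNS.get(factor)
    holds = None if expected is None else direction == expected
    if check and holds is False:
        raise ComparativeStaticsError(
            f"violence was expected to be {expected} in {factor} "
            f"but the grid shows {direction}"
        )
    return ComparativeStaticsReport(factor, table, direction, expected, holds)


def _per_woman_rows(
    state: EquilibriumState,
    *,
    scenario: str,
    grid_param: str,
    grid_value: float,
    seed,
) -> list[dict]:
    n = state.n
    return [
        {
            "scenario": scenario,
            "grid_param": grid_param,
            "grid_value": float(grid_value),
            "woman": i + 1,
            "violence": float(state.violence[i]),
            "effort": float(state.efforts[:, i].mean()),
            "welfare": float(state.welfare[i]),
            "exists": bool(state.exists),
            "converged": bool(state.converged),
            "seed": seed,
        }
        for i in range(n)
    ]


def sweep(
    p: CommunityParams,
    model: AttitudeModel,
    param: str,
    values,
    *,
    alt: AltruismSpec = AltruismSpec.none(),
    scenario: str = "",
    seed=None,
    **solver_kwargs,
) -> pd.DataFrame:
    """Tidy equilibrium table along one parameter axis.

    ``param`` is either a block scale factor (``sigma``/``tau``/``gamma``/
    ``kappa``/``nu``/``alpha``, applied multiplicatively to the base
    parameters) or an altruism weight (``b``/``eta``/``rho``).  One row per
    (grid value, woman); the ``effort`` column is the woman's mean per-dyad
    effort.  Grid points with no equilibrium appear as rows with
    ``exists=False`` and NaN outcomes rather than being dropped.
    """
    values = np.asarray(values, dtype=float)
    rows: list[dict] = []
    if param in SCALE_FACTOR_NAMES:
        for g in values:
            sf = ScaleFactors(**{param: float(g)})
            p_g, model_g = sf.apply(p, model)
            state = solve(p_g, model_g, alt, **solver_kwargs)
            rows += _per_woman_rows(
                state, scenario=scenario, grid_param=param, grid_value=g, seed=seed
            )
    elif param in ALTRUISM_PARAM_VARIANTS:
        variant = ALTRUISM_PARAM_VARIANTS[param]
        for g in values:
            state = solve(p, model, AltruismSpec(variant, float(g)), **solver_kwargs)
            rows += _per_woman_rows(
                state, scenario=scenario, grid_param=param, grid_value=g, seed=seed
            )
    else:
        raise ValueError(
            f"unknown sweep parameter {param!r}; expected a scale factor "
            f"{SCALE_FACTOR_NAMES} or altruism weight {tuple(ALTRUISM_PARAM_VARIANTS)}"
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def changes_from_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Per-woman outcome changes relative to the smallest grid value.

    For each (scenario, grid_param, woman) the violence, effort and welfare
    columns are re-expressed as differences from their value at the lowest
    grid point of that axis — the quantity the heterogeneous-community
    figures plot (e.g. the drop in violence as altruism rises from zero).
    """
    out = table.copy()
    keys = ["scenario", "grid_param", "woman"]
    for col in ("violence", "effort", "welfare"):
        base = (
            out.sort_values("grid_value").groupby(keys)[col].transform("first")
        )
        out[col] = out[col] - base
    return out


def summarize_across_women(table: pd.DataFrame) -> pd.DataFrame:
    """Min / median / max of each outcome across women at every grid point.

    The aggregation behind the heterogeneous-community figures: lines are
    medians across women, bands the full min-max range.
    """
    agg = (
        table.groupby(["scenario", "grid_param", "grid_value"], sort=True)[
            ["violence", "effort", "welfare"]
        ]
        .agg(["min", "median", "max"])
        .reset_index()
    )
    agg.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in agg.columns
    ]
    return agg
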