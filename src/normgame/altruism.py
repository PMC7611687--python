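"""Welfare-marginal analysis of the three altruism mechanisms.

Each mechanism carries an exact local condition for altruism to raise
women's welfare: promoting intrinsic motivation ``b``, empathy ``eta`` or
reciprocity ``rho`` helps woman ``i`` exactly when her induced marginal
effort cost is outweighed by the benefit flowing back to her from all women's
induced extra effort.  This module evaluates those conditions numerically:
equilibrium sensitivities to the altruism weight are estimated by finite
differences of the exact (closed-form or iterative) equilibrium, and both
sides of each inequality are reported per woman.

The tolerance weights ``tau_ji`` (own-dyad terms weighted by the woman's
tolerance ``t_i``, cross-dyad terms by 1) encode that, at her own optimum, a
woman has already internalised the untolerated share of her own benefit; only
the tolerated share and the externalities remain on the welfare margin.
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
    LinearAttitudeModel,
    _check_compat,
)
from . import equilibrium as eq

__all__ = [
    "EquilibriumExistenceError",
    "tau_weights",
    "solve",
    "equilibrium_derivative",
    "welfare_gradient",
    "proposition_condition",
    "PropositionReport",
]


class EquilibriumExistenceError(RuntimeError):
    """Raised when a required equilibrium does not exist or did not converge."""


def tau_weights(p: CommunityParams) -> NDArray[np.float64]:
    """Matrix ``tau[j, i] = t_i`` if ``j == i`` else 1."""
    tau = np.ones((p.n, p.n))
    np.fill_diagonal(tau, p.t)
    return tau


def solve(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    **solver_kwargs,
) -> EquilibriumState:
    """Equilibrium via the closed form when available, else best-response."""
    if isinstance(model, LinearAttitudeModel) and not solver_kwargs:
        return eq.solve_closed_form(p, model, alt)
    return eq.solve_best_response(p, model, alt, **solver_kwargs)


def _solve_at(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    weight: float,
    **solver_kwargs,
) -> EquilibriumState:
    state = solve(p, model, alt.with_weight(weight), **solver_kwargs)
    if not state.exists:
        raise EquilibriumExistenceError(
            f"no equilibrium exists for {alt.variant} weight {weight:g}"
        )
    if not state.converged:
        raise EquilibriumExistenceError(
            f"solver failed to converge for {alt.variant} weight {weight:g}"
        )
    return state


def _fd_states(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    h: float,
    **solver_kwargs,
) -> tuple[list[EquilibriumState], list[float]]:
    """Evaluation points and quadrature weights for the derivative stencil.

    Central differences when the lower point stays in the admissible range
    (weights must be nonnegative); otherwise the second-order one-sided
    stencil ``(-3 f(x) + 4 f(x+h) - f(x+2h)) / (2h)``.
    """
    if alt.variant == "none":
        raise ValueError("derivative requires an altruism variant, not 'none'")
    theta = alt.weight
    step = h * max(1.0, abs(theta))
    if theta - step >= 0.0:
        pts = [theta - step, theta + step]
        coefs = [-0.5 / step, 0.5 / step]
    else:
        pts = [theta, theta + step, theta + 2 * step]
        coefs = [-1.5 / step, 2.0 / step, -0.5 / step]
    states = [_solve_at(p, model, alt, w, **solver_kwargs) for w in pts]
    return states, coefs


def equilibrium_derivative(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    h: float = 1e-4,
    **solver_kwargs,
) -> NDArray[np.float64]:
    """Finite-difference sensitivity ``de*_ki / d(weight)`` of the equilibrium."""
    states, coefs = _fd_states(p, model, alt, h, **solver_kwargs)
    return sum(c * st.efforts for c, st in zip(coefs, states))


def welfare_gradient(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    h: float = 1e-4,
    **solver_kwargs,
) -> NDArray[np.float64]:
    """Finite-difference derivative ``dW_i / d(weight)`` of equilibrium welfare."""
    states, coefs = _fd_states(p, model, alt, h, **solver_kwargs)
    return sum(c * st.welfare for c, st in zip(coefs, states))


@dataclass
class PropositionReport:
    """Both sides of the welfare-improvement inequality, per woman."""

    variant: str
    weight: float
    lhs: NDArray[np.float64]
    rhs: NDArray[np.float64]

    @property
    def holds(self) -> NDArray[np.bool_]:
        return self.lhs < self.rhs

    @property
    def all_hold(self) -> bool:
        return bool(self.holds.all())

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "woman": np.arange(1, self.lhs.shape[0] + 1),
                "lhs": self.lhs,
                "rhs": self.rhs,
                "holds": self.holds,
            }
        )


def proposition_condition(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    h: float = 1e-4,
    **solver_kwargs,
) -> PropositionReport:
    """Evaluate the variant's welfare-improvement inequality at the point ``alt``.

    The right-hand side is common to all variants: the tolerance-weighted
    marginal benefit woman ``i`` receives from the induced change in all
    efforts,
    ``rhs_i = -sum_k sum_j tau_ji (s_i n_ik / c_i) (da_k/de_kj) (de_kj/dw)``.

    Left-hand sides (marginal costs):

    - process:     ``b sum_k d_ki de_ki/db``
    - empathetic:  ``-eta sum_k sum_{j != i} (s_j n_jk / c_j) (da_k/de_ki) de_ki/deta``
    - reciprocal:  ``-(rho / (1 - n rho)) sum_k q_k de_ki/drho`` with
      ``q_k = sum_j s_j (1 - t_j) (n_jk / c_j) (da_k/de_kj)``; requires
      ``rho < 1/n``.
    """
    _check_compat(p, model)
    if alt.variant == "none":
        raise ValueError("proposition_condition requires an altruism variant")
    if alt.variant == "reciprocal" and alt.weight >= 1.0 / p.n:
        raise EquilibriumExistenceError(
            f"reciprocity weight {alt.weight:g} >= 1/n = {1.0 / p.n:g}: "
            "a subgame-perfect equilibrium may not exist"
        )
    state = _solve_at(p, model, alt, alt.weight, **solver_kwargs)
    P = model.partials(state.efforts)
    dE = equilibrium_derivative(p, model, alt, h, **solver_kwargs)
    tau = tau_weights(p)
    # rhs_i = -(s_i/c_i) sum_k N[i,k] sum_j tau[j,i] P[k,j] dE[k,j]
    G = (P * dE) @ tau
    rhs = -(p.s / p.c) * np.einsum("ik,ki->i", p.N, G)
    w = alt.weight
    if alt.variant == "process":
        lhs = w * (p.D * dE).sum(axis=0)
    elif alt.variant == "empathetic":
        lhs = -w * (eq._empathy_coef(p) * P * dE).sum(axis=0)
    else:  # reciprocal
        M2 = p.N * (p.s * (1.0 - p.t) / p.c)[:, None]  # M2[j, k]
        q = np.einsum("jk,kj->k", M2, P)
        lhs = -(w / (1.0 - p.n * w)) * (q @ dE)
    return PropositionReport(alt.variant, w, lhs, rhs)
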