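"""Subgame-perfect equilibrium of the two-stage norm-change game.

Women anticipate men's violence best responses when choosing efforts, so the
equilibrium reduces to a simultaneous-move game among women with payoff
gradients given by :func:`foc_residual`.  Under a linear attitude model every
variant admits a closed form (:func:`solve_closed_form`); the damped
best-response iteration (:func:`solve_best_response`) handles general
attitude models and serves as an independent cross-check on the closed form.

Existence can genuinely fail for reciprocal altruism: the per-man effort
system ``diag(d_k.) - rho * ones`` must be positive definite, which in the
symmetric unit-cost case requires ``rho < 1/n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import brentq

from .model import (
    AltruismSpec,
    AttitudeModel,
    CommunityParams,
    EquilibriumState,
    LinearAttitudeModel,
    _check_compat,
    _failed_state,
    men_best_response,
    men_utility,
    welfare,
    women_utility,
)

__all__ = [
    "foc_residual",
    "solve_closed_form",
    "solve_best_response",
    "check_uniqueness",
    "reciprocal_system_exists",
    "UniquenessReport",
]

# Relative tolerance for the positive-definiteness existence test.
_PD_TOL = 1e-9


def _marginal_benefit_coef(p: CommunityParams) -> NDArray[np.float64]:
    """``coef[k, i] = s_i (1 - t_i) n_ik / c_i`` multiplying ``-da_k/de_ki``."""
    return (p.N * (p.s * (1.0 - p.t) / p.c)[:, None]).T


def _empathy_coef(p: CommunityParams) -> NDArray[np.float64]:
    """``emp[k, i] = sum_{j != i} s_j n_jk / c_j`` (others' marginal suffering)."""
    M = p.N * (p.s / p.c)[:, None]  # M[j, k] = s_j n_jk / c_j
    return M.sum(axis=0)[:, None] - M.T


def foc_residual(
    E: NDArray[np.float64],
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec = AltruismSpec.none(),
) -> NDArray[np.float64]:
    """First-order condition ``dU_wi/de_ki`` with men playing best responses.

    Entry ``(k, i)`` is woman ``i``'s marginal utility of effort on man ``k``.
    At an interior equilibrium every entry is zero; at a boundary entry
    (``e_ki = 0``) the residual must be nonpositive (complementarity).
    """
    _check_compat(p, model)
    E = model.check_efforts(E)
    P = model.partials(E)
    res = -_marginal_benefit_coef(p) * P - p.D * E
    if alt.variant == "process":
        res = res + alt.weight
    elif alt.variant == "empathetic":
        res = res - alt.weight * _empathy_coef(p) * P
    elif alt.variant == "reciprocal":
        res = res + alt.weight * E.sum(axis=1)[:, None]
    return res


def boundary_residual_norm(
    E: NDArray[np.float64],
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec = AltruismSpec.none(),
    atol: float = 1e-12,
) -> float:
    """Max complementarity violation: |residual| at interior entries, positive
    part of the residual at boundary (zero-effort) entries."""
    res = foc_residual(E, p, model, alt)
    interior = E > atol
    viol = np.where(interior, np.abs(res), np.maximum(res, 0.0))
    return float(viol.max())


def reciprocal_system_exists(p: CommunityParams, rho: float) -> bool:
    """Positive-definiteness existence test for the reciprocal variant.

    For each man ``k`` the stacked first-order conditions form the linear
    system ``(diag(d_k.) - rho * ones) e_k. = base``; an equilibrium exists
    only when every such matrix is positive definite.  With homogeneous unit
    effort costs this reduces to ``rho < 1/n``.
    """
    if rho == 0:
        return True
    n = p.n
    J = np.ones((n, n))
    for k in range(n):
        A = np.diag(p.D[k, :]) - rho * J
        min_eig = np.linalg.eigvalsh(A)[0]
        if min_eig <= _PD_TOL * max(1.0, float(p.D[k, :].max())):
            return False
    return True


def _finalize(
    E: NDArray[np.float64],
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    *,
    method: str,
    iterations: int = 0,
    converged: bool = True,
) -> EquilibriumState:
    a = model.attitudes(E)
    v = men_best_response(a, p)
    return EquilibriumState(
        efforts=E,
        attitudes=a,
        violence=v,
        women_utility=women_utility(E, v, p, alt),
        men_utility=men_utility(v, a, p),
        welfare=welfare(E, v, p),
        exists=True,
        converged=converged,
        iterations=iterations,
        max_foc_residual=boundary_residual_norm(E, p, model, alt),
        method=method,
    )


def _solve_reciprocal_row(
    d_row: NDArray[np.float64], base_row: NDArray[np.float64], rho: float
) -> NDArray[np.float64]:
    """Solve one man's effort system with complementarity (active set)."""
    n = d_row.shape[0]
    active = np.ones(n, dtype=bool)  # entries allowed to be interior
    for _ in range(n + 1):
        idx = np.flatnonzero(active)
        A = np.diag(d_row[idx]) - rho * np.ones((idx.size, idx.size))
        e_sub = np.linalg.solve(A, base_row[idx])
        if np.all(e_sub >= 0):
            e = np.zeros(n)
            e[idx] = e_sub
            return e
        active[idx[e_sub < 0]] = False
        if not active.any():
            return np.zeros(n)
    raise RuntimeError("active-set iteration failed to settle")  # pragma: no cover


def solve_closed_form(
    p: CommunityParams,
    model: LinearAttitudeModel,
    alt: AltruismSpec = AltruismSpec.none(),
) -> EquilibriumState:
    """Exact equilibrium under a linear attitude model.

    Interior candidates (entry ``(k, i)``, ``B = s_i (1-t_i) n_ik f_ki / c_i``):

    - ``none``:        ``e_ki = B / d_ki``
    - ``process``:     ``e_ki = (b + B) / d_ki``
    - ``empathetic``:  ``e_ki = (B + eta * sum_{j != i} s_j n_jk f_ki / c_j) / d_ki``
    - ``reciprocal``:  per man ``k``, solve ``(diag(d_k.) - rho * ones) e = B_k.``

    Negative candidates are projected to zero with a complementarity re-solve.
    For the reciprocal variant a failed positive-definiteness test returns a
    state with ``exists=False``.
    """
    _check_compat(p, model)
    if not isinstance(model, LinearAttitudeModel):
        raise TypeError("solve_closed_form requires a LinearAttitudeModel")
    f = model.slopes
    B = _marginal_benefit_coef(p) * f
    if alt.variant == "none":
        E = np.maximum(B / p.D, 0.0)
    elif alt.variant == "process":
        E = np.maximum((alt.weight + B) / p.D, 0.0)
    elif alt.variant == "empathetic":
        E = np.maximum((B + alt.weight * _empathy_coef(p) * f) / p.D, 0.0)
    elif alt.variant == "reciprocal":
        if not reciprocal_system_exists(p, alt.weight):
            return _failed_state(p.n, method="closed_form")
        E = np.empty((p.n, p.n))
        for k in range(p.n):
            E[k, :] = _solve_reciprocal_row(p.D[k, :], B[k, :], alt.weight)
    else:  # pragma: no cover - AltruismSpec validates variants
        raise ValueError(alt.variant)
    return _finalize(E, p, model, alt, method="closed_form")


def _best_response_linear(
    E: NDArray[np.float64],
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
) -> NDArray[np.float64]:
    """Vectorised per-entry best response when attitude partials are constant."""
    P = model.partials(E)
    m = -_marginal_benefit_coef(p) * P
    if alt.variant == "process":
        m = m + alt.weight
    elif alt.variant == "empathetic":
        m = m - alt.weight * _empathy_coef(p) * P
    if alt.variant == "reciprocal":
        rho = alt.weight
        others = E.sum(axis=1)[:, None] - E
        denom = p.D - rho  # positive whenever the PD existence test passes
        return np.maximum((m + rho * others) / denom, 0.0)
    return np.maximum(m / p.D, 0.0)


def _best_response_entry(
    E: NDArray[np.float64],
    k: int,
    i: int,
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec,
    bound: float,
) -> float:
    """Scalar best response for one entry via root-finding on the FOC."""

    def g(x: float) -> float:
        Ex = E.copy()
        Ex[k, i] = x
        return float(foc_residual(Ex, p, model, alt)[k, i])

    if g(0.0) <= 0.0:
        return 0.0
    hi = max(1.0, 2.0 * E[k, i])
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > bound:
            return bound  # marginal utility never turns negative: diverging
    return float(brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16))


def solve_best_response(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec = AltruismSpec.none(),
    init: NDArray[np.float64] | None = None,
    *,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    divergence_bound: float = 1e8,
) -> EquilibriumState:
    """Damped best-response iteration over women's effort entries.

    Each sweep replaces every entry by the woman's payoff-maximising effort
    given all other entries (projected at zero), then blends old and new
    iterates with weight ``damping``.  Stops when the sweep changes no entry
    by more than ``tol``.  Iterates escaping ``divergence_bound`` — or a
    failed positive-definiteness test for the reciprocal variant — yield
    ``exists=False``.
    """
    _check_compat(p, model)
    if not 0 < damping <= 1:
        raise ValueError("damping must lie in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if alt.variant == "reciprocal" and not reciprocal_system_exists(p, alt.weight):
        return _failed_state(p.n, method="best_response")
    E = (
        np.zeros((p.n, p.n))
        if init is None
        else model.check_efforts(np.asarray(init, dtype=float)).copy()
    )
    fast = model.constant_partials
    for it in range(1, max_iter + 1):
        if fast:
            BR = _best_response_linear(E, p, model, alt)
        else:
            BR = np.empty_like(E)
            for k in range(p.n):
                for i in range(p.n):
                    BR[k, i] = _best_response_entry(
                        E, k, i, p, model, alt, divergence_bound
                    )
        E_new = (1.0 - damping) * E + damping * BR
        diff = float(np.abs(E_new - E).max())
        E = E_new
        if np.abs(E).max() > divergence_bound:
            return _failed_state(p.n, method="best_response", iterations=it)
        if diff < tol:
            return _finalize(
                E, p, model, alt, method="best_response", iterations=it
            )
    return _finalize(
        E, p, model, alt, method="best_response", iterations=max_iter, converged=False
    )


@dataclass
class UniquenessReport:
    """Outcome of a multi-start uniqueness probe."""

    verdict: str  # "unique" | "multiple" | "inconclusive"
    max_pairwise_distance: float
    n_starts: int
    n_converged: int


def check_uniqueness(
    p: CommunityParams,
    model: AttitudeModel,
    alt: AltruismSpec = AltruismSpec.none(),
    *,
    n_starts: int = 10,
    seed: int | None = None,
    init_scale: float = 2.0,
    distance_tol: float = 1e-6,
    **solver_kwargs,
) -> UniquenessReport:
    """Probe equilibrium uniqueness from seeded random initial efforts.

    Runs the iterative solver from ``n_starts`` random starting matrices and
    reports the maximum pairwise distance between converged effort profiles.
    Any non-convergent run makes the verdict ``"inconclusive"``.
    """
    if n_starts < 2:
        raise ValueError("n_starts must be at least 2")
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(n_starts):
        init = rng.uniform(0.0, init_scale, size=(p.n, p.n))
        state = solve_best_response(p, model, alt, init=init, **solver_kwargs)
        if not (state.exists and state.converged):
            return UniquenessReport("inconclusive", np.nan, n_starts, len(states))
        states.append(state.efforts)
    dist = 0.0
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            dist = max(dist, float(np.abs(states[a] - states[b]).max()))
    verdict = "unique" if dist < distance_tol else "multiple"
    return UniquenessReport(verdict, dist, n_starts, n_starts)
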