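"""Core types and payoff functions for the norm-change collective-action game.

A community holds ``n`` couples.  Woman ``i`` suffers violence ``v_i`` from her
partner, man ``i``.  Men hold attitudes to violence ``a_i`` which respond to
persuasion effort by the community's women: ``e_{ji}`` is the effort woman
``i`` directs at man ``j``.  Men reward or sanction each other's violence
through norm payoffs ``n_ij``, so one woman's effort on one man spills over to
every other woman's relationship — the externality that turns violence
prevention into a collective-action problem.

The game has two stages: women simultaneously choose effort matrices, then men
simultaneously choose violence levels.  This module holds the parameter
containers, the attitude-function contract, and the payoff/welfare functions;
:mod:`normgame.equilibrium` solves the game.

Index convention
----------------
Effort matrices are ``(n, n)`` arrays with ``E[j, i]`` = effort of woman ``i``
directed at man ``j``: man ``j``'s attitude depends only on row ``j``.
Matrix parameters follow the same orientation: ``N[i, j]`` is the norm payoff
rate man ``j`` imposes on man ``i`` (``N[i, i]`` his intrinsic payoff rate),
``D[j, i]`` the cost rate of woman ``i``'s effort on man ``j``.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "CommunityParams",
    "AttitudeModel",
    "LinearAttitudeModel",
    "ExponentialAttitudeModel",
    "AltruismSpec",
    "EquilibriumState",
    "ScaleFactors",
    "attitudes",
    "men_best_response",
    "men_utility",
    "women_utility",
    "welfare",
]

ALTRUISM_VARIANTS = ("none", "process", "empathetic", "reciprocal")


def _as_vector(x: ArrayLike, n: int, name: str) -> NDArray[np.float64]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _as_matrix(x: ArrayLike, n: int, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full((n, n), float(arr))
    if arr.shape != (n, n):
        raise ValueError(f"{name} must have shape ({n}, {n}), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr.copy()


@dataclass(frozen=True)
class CommunityParams:
    """All fixed per-couple and pairwise model constants.

    Parameters
    ----------
    n
        Number of couples; the game assumes ``n >= 2``.
    s
        Suffering rate per unit violence, ``s_i > 0`` (length ``n``).
    t
        Tolerance for violence, ``0 <= t_i < 1``.
    c
        Marginal cost of perpetrating violence, ``c_i > 0``.
    N
        Norm payoff rates ``n_ij > 0``; diagonal = intrinsic payoff rates.
    D
        Effort-cost rates; ``D[j, i] > 0`` scales woman ``i``'s quadratic cost
        of effort directed at man ``j``.
    """

    n: int
    s: NDArray[np.float64]
    t: NDArray[np.float64]
    c: NDArray[np.float64]
    N: NDArray[np.float64]
    D: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("the game requires at least two couples (n >= 2)")
        object.__setattr__(self, "s", _as_vector(self.s, self.n, "s"))
        object.__setattr__(self, "t", _as_vector(self.t, self.n, "t"))
        object.__setattr__(self, "c", _as_vector(self.c, self.n, "c"))
        object.__setattr__(self, "N", _as_matrix(self.N, self.n, "N"))
        object.__setattr__(self, "D", _as_matrix(self.D, self.n, "D"))
        if np.any(self.s <= 0):
            raise ValueError("suffering rates s must be strictly positive")
        if np.any(self.c <= 0):
            raise ValueError("violence-cost rates c must be strictly positive")
        if np.any((self.t < 0) | (self.t >= 1)):
            raise ValueError("tolerances t must lie in [0, 1)")
        if np.any(self.N <= 0):
            raise ValueError("norm payoff rates N must be strictly positive")
        if np.any(self.D <= 0):
            raise ValueError("effort-cost rates D must be strictly positive")

    @classmethod
    def homogeneous(
        cls,
        n: int,
        *,
        s: float = 1.0,
        t: float = 0.5,
        c: float = 1.0,
        norm: float = 1.0,
        effort_cost: float = 1.0,
    ) -> "CommunityParams":
        """Community in which every couple shares the same constants."""
        return cls(n=n, s=s, t=t, c=c, N=norm, D=effort_cost)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "s": self.s.tolist(),
            "t": self.t.tolist(),
            "c": self.c.tolist(),
            "N": self.N.tolist(),
            "D": self.D.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityParams":
        return cls(n=int(d["n"]), s=d["s"], t=d["t"], c=d["c"], N=d["N"], D=d["D"])


class AttitudeModel(abc.ABC):
    """Contract for attitude functions ``a_j(e_j1, ..., e_jn)``.

    Each man's attitude depends only on the efforts directed at him (row ``j``
    of the effort matrix) and is strictly decreasing in each of them; the model
    must expose both values and partial derivatives.  Implementations with
    effort-independent partials should set :attr:`constant_partials` so the
    solver can use its fast vectorised path.
    """

    n: int
    constant_partials: bool = False

    @abc.abstractmethod
    def attitudes(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        """Attitude vector ``a`` given the effort matrix."""

    @abc.abstractmethod
    def partials(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        """Matrix ``P`` with ``P[j, i] = da_j/de_ji`` evaluated at ``E``."""

    @abc.abstractmethod
    def with_effectiveness(self, alpha: float) -> "AttitudeModel":
        """Return a copy with every slope multiplied by ``alpha >= 0``."""

    def check_efforts(self, E: ArrayLike) -> NDArray[np.float64]:
        E = np.asarray(E, dtype=float)
        if E.shape != (self.n, self.n):
            raise ValueError(
                f"effort matrix must have shape ({self.n}, {self.n}), got {E.shape}"
            )
        if np.any(E < 0):
            raise ValueError("efforts must be nonnegative")
        return E

    def validate(self) -> None:
        """Check the decreasing/convexity contract; may warn, never raises."""


@dataclass(frozen=True)
class LinearAttitudeModel(AttitudeModel):
    """Attitudes linear in effort: ``a_j(E) = intercept_j - sum_i f[j,i] E[j,i]``.

    The linear form is decreasing but only weakly convex; it is accepted (all
    worked scenarios use it) and :meth:`validate` notes the weak convexity as
    a warning rather than an error.
    """

    intercepts: NDArray[np.float64]
    slopes: NDArray[np.float64]
    constant_partials: bool = field(default=True, init=False, repr=False)

    def __post_init__(self) -> None:
        intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        n = intercepts.shape[0]
        object.__setattr__(self, "intercepts", intercepts.copy())
        object.__setattr__(self, "slopes", _as_matrix(self.slopes, n, "slopes"))
        object.__setattr__(self, "n", n)
        if np.any(self.slopes < 0):
            raise ValueError("slopes f must be nonnegative")

    @classmethod
    def homogeneous(
        cls, n: int, *, intercept: float = 2.0, slope: float = 0.1
    ) -> "LinearAttitudeModel":
        return cls(intercepts=np.full(n, float(intercept)), slopes=slope)

    def attitudes(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        E = self.check_efforts(E)
        return self.intercepts - (self.slopes * E).sum(axis=1)

    def partials(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        return -self.slopes

    def with_effectiveness(self, alpha: float) -> "LinearAttitudeModel":
        if alpha < 0:
            raise ValueError("effectiveness scale alpha must be nonnegative")
        return replace(self, slopes=self.slopes * float(alpha))

    def validate(self) -> None:
        warnings.warn(
            "linear attitude model is weakly, not strictly, convex in efforts",
            UserWarning,
            stacklevel=2,
        )

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "intercepts": self.intercepts.tolist(),
            "slopes": self.slopes.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearAttitudeModel":
        return cls(intercepts=d["intercepts"], slopes=d["slopes"])


@dataclass(frozen=True)
class ExponentialAttitudeModel(AttitudeModel):
    """Strictly convex alternative: ``a_j(E) = intercept_j * exp(-sum_i f[j,i] E[j,i])``.

    Strictly decreasing and strictly convex for positive intercepts and
    slopes, with effort-dependent partials; used to exercise the generic
    (scalar root-finding) solver path.
    """

    intercepts: NDArray[np.float64]
    slopes: NDArray[np.float64]
    constant_partials: bool = field(default=False, init=False, repr=False)

    def __post_init__(self) -> None:
        intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        n = intercepts.shape[0]
        object.__setattr__(self, "intercepts", intercepts.copy())
        object.__setattr__(self, "slopes", _as_matrix(self.slopes, n, "slopes"))
        object.__setattr__(self, "n", n)
        if np.any(self.intercepts <= 0) or np.any(self.slopes < 0):
            raise ValueError("intercepts must be positive and slopes nonnegative")

    def attitudes(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        E = self.check_efforts(E)
        return self.intercepts * np.exp(-(self.slopes * E).sum(axis=1))

    def partials(self, E: NDArray[np.float64]) -> NDArray[np.float64]:
        return -self.slopes * self.attitudes(E)[:, None]

    def with_effectiveness(self, alpha: float) -> "ExponentialAttitudeModel":
        if alpha < 0:
            raise ValueError("effectiveness scale alpha must be nonnegative")
        return replace(self, slopes=self.slopes * float(alpha))


@dataclass(frozen=True)
class AltruismSpec:
    """Which altruistic utility variant is active, and its weight.

    Variants: ``none`` (baseline), ``process`` (intrinsic per-unit benefit
    ``b`` of exerting effort), ``empathetic`` (weight ``eta`` on other women's
    suffering), ``reciprocal`` (weight ``rho`` on matching other women's
    efforts).
    """

    variant: str = "none"
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in ALTRUISM_VARIANTS:
            raise ValueError(
                f"unknown altruism variant {self.variant!r}; "
                f"expected one of {ALTRUISM_VARIANTS}"
            )
        if self.weight < 0:
            raise ValueError("altruism weight must be nonnegative")
        if self.variant == "none" and self.weight != 0:
            object.__setattr__(self, "weight", 0.0)

    @classmethod
    def none(cls) -> "AltruismSpec":
        return cls("none", 0.0)

    @classmethod
    def process(cls, b: float) -> "AltruismSpec":
        return cls("process", b)

    @classmethod
    def empathetic(cls, eta: float) -> "AltruismSpec":
        return cls("empathetic", eta)

    @classmethod
    def reciprocal(cls, rho: float) -> "AltruismSpec":
        return cls("reciprocal", rho)

    def with_weight(self, weight: float) -> "AltruismSpec":
        return AltruismSpec(self.variant, weight)


@dataclass
class EquilibriumState:
    """Solved (or failed) equilibrium of the two-stage game.

    ``exists=False`` marks detected non-existence (e.g. reciprocity at or
    beyond 1/n); ``converged=False`` marks an iterative solve that stopped at
    the iteration cap.  Outcome arrays are NaN when no equilibrium exists.
    """

    efforts: NDArray[np.float64]
    attitudes: NDArray[np.float64]
    violence: NDArray[np.float64]
    women_utility: NDArray[np.float64]
    men_utility: NDArray[np.float64]
    welfare: NDArray[np.float64]
    exists: bool = True
    converged: bool = True
    iterations: int = 0
    max_foc_residual: float = np.nan
    method: str = ""

    @property
    def n(self) -> int:
        return self.efforts.shape[0]

    def per_woman_table(self):
        """Tidy per-woman summary (violence, mean per-dyad effort, payoffs)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "woman": np.arange(1, self.n + 1),
                "violence": self.violence,
                "effort": self.efforts.mean(axis=0),
                "utility": self.women_utility,
                "welfare": self.welfare,
            }
        )


def _failed_state(n: int, method: str, iterations: int = 0) -> EquilibriumState:
    nan_v = np.full(n, np.nan)
    nan_m = np.full((n, n), np.nan)
    return EquilibriumState(
        efforts=nan_m,
        attitudes=nan_v,
        violence=nan_v,
        women_utility=nan_v,
        men_utility=nan_v,
        welfare=nan_v,
        exists=False,
        converged=False,
        iterations=iterations,
        method=method,
    )


@dataclass(frozen=True)
class ScaleFactors:
    """Multiplicative scalings of whole parameter blocks.

    ``sigma`` scales suffering ``s``, ``tau`` tolerance ``t``, ``gamma``
    effort costs ``D``, ``kappa`` violence costs ``c``, ``nu`` norm payoffs
    ``N``, and ``alpha`` the attitude slopes.  ``tau`` and ``alpha`` may be
    zero (zero tolerance / zero effectiveness are legal parameter values); the
    others must stay strictly positive to preserve parameter signs.
    """

    sigma: float = 1.0
    tau: float = 1.0
    gamma: float = 1.0
    kappa: float = 1.0
    nu: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma", "gamma", "kappa", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"scale factor {name} must be strictly positive")
        for name in ("tau", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"scale factor {name} must be nonnegative")

    def apply(
        self, p: CommunityParams, model: AttitudeModel
    ) -> tuple[CommunityParams, AttitudeModel]:
        t_new = p.t * self.tau
        if np.any(t_new >= 1):
            raise ValueError("tau scaling pushes some tolerance t_i to 1 or beyond")
        p_new = CommunityParams(
            n=p.n,
            s=p.s * self.sigma,
            t=t_new,
            c=p.c * self.kappa,
            N=p.N * self.nu,
            D=p.D * self.gamma,
        )
        return p_new, model.with_effectiveness(self.alpha)


def _check_compat(p: CommunityParams, model: AttitudeModel) -> None:
    if model.n != p.n:
        raise ValueError(
            f"attitude model is for {model.n} couples but parameters have {p.n}"
        )


def attitudes(model: AttitudeModel, E: ArrayLike) -> NDArray[np.float64]:
    """Attitude vector ``a_j(E)`` for every man ``j``."""
    return model.attitudes(np.asarray(E, dtype=float))


def men_best_response(a: ArrayLike, p: CommunityParams) -> NDArray[np.float64]:
    """Violence levels maximising each man's payoff given attitudes.

    ``v_i = (1/c_i) (n_ii a_i + sum_{j != i} n_ij a_j)`` — the unique interior
    maximiser of the quadratic stage-two payoff.
    """
    a = _as_vector(a, p.n, "attitudes")
    return (p.N @ a) / p.c


def men_utility(
    v: ArrayLike, a: ArrayLike, p: CommunityParams
) -> NDArray[np.float64]:
    """Stage-two payoff ``U_hi = (sum_j n_ij a_j) v_i - c_i v_i^2 / 2``."""
    v = np.broadcast_to(np.asarray(v, dtype=float), (p.n,))
    a = _as_vector(a, p.n, "attitudes")
    return (p.N @ a) * v - 0.5 * p.c * v**2


def women_utility(
    E: ArrayLike,
    v: ArrayLike,
    p: CommunityParams,
    alt: AltruismSpec = AltruismSpec.none(),
) -> NDArray[np.float64]:
    """Per-woman utility under the active altruism variant.

    Baseline: ``-s_i (1 - t_i) v_i - (1/2) sum_k d_ki e_ki^2``.  The process
    variant adds ``b sum_k e_ki``; the empathetic variant adds
    ``-eta sum_{j != i} s_j v_j``; the reciprocal variant adds
    ``rho sum_k sum_{j != i} e_ki e_kj + (rho/2) sum_k e_ki^2``.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (p.n, p.n):
        raise ValueError(f"effort matrix must have shape ({p.n}, {p.n})")
    v = np.broadcast_to(np.asarray(v, dtype=float), (p.n,))
    u = -p.s * (1.0 - p.t) * v - 0.5 * (p.D * E**2).sum(axis=0)
    w = alt.weight
    if alt.variant == "none":
        pass
    elif alt.variant == "process":
        u = u + w * E.sum(axis=0)
    elif alt.variant == "empathetic":
        sv = p.s * v
        u = u - w * (sv.sum() - sv)
    elif alt.variant == "reciprocal":
        rowsum = E.sum(axis=1)
        u = u + w * (E * rowsum[:, None]).sum(axis=0) - 0.5 * w * (E**2).sum(axis=0)
    return u


def welfare(E: ArrayLike, v: ArrayLike, p: CommunityParams) -> NDArray[np.float64]:
    """Normative welfare ``W_i = -s_i v_i - (1/2) sum_k d_ki e_ki^2``.

    Equals baseline utility with tolerance forced to zero (adaptive
    preferences are not credited); altruism terms never enter welfare.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (p.n, p.n):
        raise ValueError(f"effort matrix must have shape ({p.n}, {p.n})")
    v = np.broadcast_to(np.asarray(v, dtype=float), (p.n,))
    return -p.s * v - 0.5 * (p.D * E**2).sum(axis=0)
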