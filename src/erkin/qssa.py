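"""Algebraic quasi-steady-state reduction of polynomial ODE systems.

The reduction operator works on a *split system*: the state is partitioned
into retained variables ``x1`` and eliminated (fast) variables ``x2`` with
dynamics ``f1`` and ``f2``.  Where the Jacobian ``D2 f2`` is invertible, the
zero set of ``f2`` (the quasi-steady-state variety) is an invariant manifold
of the auxiliary system::

    dx1/dt = f1(x, theta)
    dx2/dt = -D2f2(x, theta)^{-1} D1f2(x, theta) f1(x, theta)

and on that variety the retained block reproduces the reduced model obtained
by solving ``f2 = 0`` for ``x2``.  This module implements the operator
generically (with finite-difference Jacobians as a fallback) plus the two
ERK-specific eliminated subsystems, one per conservation-law substitution
for the free enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .models import ExperimentDesign, FullParams

__all__ = [
    "SplitSystem",
    "SingularJacobianError",
    "erk_f2",
    "erk_split_system",
    "solve_complexes",
    "d2_rank_check",
    "qss_reduced_rhs",
    "variety_residual",
    "reduction_error",
]

Substitution = Literal["conservation_E", "conservation_S"]


class SingularJacobianError(np.linalg.LinAlgError):
    """Raised when ``D2 f2`` is numerically singular at the requested point."""


def _fd_jacobian(f, x_block, other_args, rel_step=1e-6):
    """Central finite differences of ``f`` w.r.t. its first argument."""
    x_block = np.asarray(x_block, dtype=float)
    f0 = np.asarray(f(x_block, *other_args), dtype=float)
    jac = np.empty((len(f0), len(x_block)))
    for j in range(len(x_block)):
        h = rel_step * max(1.0, abs(x_block[j]))
        xp = x_block.copy()
        xm = x_block.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (
            np.asarray(f(xp, *other_args)) - np.asarray(f(xm, *other_args))
        ) / (2.0 * h)
    return jac


@dataclass
class SplitSystem:
    """A system split into retained (``x1``) and eliminated (``x2``) blocks.

    ``f1(x1, x2, theta)`` and ``f2(x1, x2, theta)`` return the two rate
    blocks; ``d1f2`` and ``d2f2`` evaluate the Jacobians of ``f2`` with
    respect to ``x1`` and ``x2``.  When the analytic Jacobians are not
    supplied they default to central finite differences with step
    ``1e-6 * max(1, |x|)`` per coordinate.
    """

    f1: Callable
    f2: Callable
    n1: int
    n2: int
    d1f2: Callable | None = None
    d2f2: Callable | None = None

    def __post_init__(self) -> None:
        if self.d1f2 is None:
            self.d1f2 = lambda x1, x2, th: _fd_jacobian(
                lambda a, b, t: self.f2(a, b, t), x1, (x2, th)
            )
        if self.d2f2 is None:
            self.d2f2 = lambda x1, x2, th: _fd_jacobian(
                lambda b, a, t: self.f2(a, b, t), x2, (x1, th)
            )

    def split(self, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if len(x) != self.n1 + self.n2:
            raise ValueError(
                f"state has length {len(x)}, expected {self.n1 + self.n2}"
            )
        return x[: self.n1], x[self.n1 :]


# --- ERK-specific split systems -------------------------------------------
#
# Retained variables x1 = (S0, S1, S2); eliminated x2 = (C1, C2).  The free
# enzyme E is removed first using one of the two conservation laws:
#   conservation_E:  E = E_tot - C1 - C2          (Rational-model path)
#   conservation_S:  E = E_tot - S_tot + S0+S1+S2 (Linear-model path)


def _enzyme(substitution, x1, x2, params, design):
    S0, S1, S2 = x1
    C1, C2 = x2
    if substitution == "conservation_E":
        return design.E_tot - C1 - C2
    if substitution == "conservation_S":
        return design.E_tot - design.S_tot + S0 + S1 + S2
    raise ValueError(f"unknown substitution {substitution!r}")


def erk_f2(
    substitution: Substitution,
    state: Sequence[float],
    params: FullParams,
    design: ExperimentDesign,
) -> np.ndarray:
    """Eliminated-block rates ``(dC1/dt, dC2/dt)`` for the chosen substitution.

    ``state`` is the five-vector ``(S0, S1, S2, C1, C2)``.
    """
    x = np.asarray(state, dtype=float)
    x1, x2 = x[:3], x[3:]
    E = _enzyme(substitution, x1, x2, params, design)
    S0, S1, _ = x1
    C1, C2 = x2
    p = params
    return np.array(
        [
            p.kf1 * E * S0 - (p.kr1 + p.kc1) * C1,
            p.kc1 * C1 + p.kf2 * E * S1 - (p.kr2 + p.kc2) * C2,
        ]
    )


def erk_split_system(
    substitution: Substitution, design: ExperimentDesign
) -> SplitSystem:
    """Build the ERK split system for one conservation-law substitution.

    Jacobians are analytic.  For ``conservation_S`` the matrix ``D2 f2`` is
    lower-triangular with diagonal ``(-(kr1+kc1), -(kr2+kc2))``, hence
    invertible whenever the network is non-degenerate; for ``conservation_E``
    it additionally involves the substrate concentrations.
    """

    def f1(x1, x2, p):
        E = _enzyme(substitution, x1, x2, p, design)
        S0, S1, _ = x1
        C1, C2 = x2
        return np.array(
            [
                -p.kf1 * E * S0 + p.kr1 * C1,
                -p.kf2 * E * S1 + p.kr2 * C2,
                p.kc2 * C2,
            ]
        )

    def f2(x1, x2, p):
        return erk_f2(substitution, np.concatenate([x1, x2]), p, design)

    if substitution == "conservation_E":

        def d1f2(x1, x2, p):
            E = _enzyme(substitution, x1, x2, p, design)
            return np.array(
                [[p.kf1 * E, 0.0, 0.0], [0.0, p.kf2 * E, 0.0]]
            )

        def d2f2(x1, x2, p):
            S0, S1, _ = x1
            return np.array(
                [
                    [-p.kf1 * S0 - (p.kr1 + p.kc1), -p.kf1 * S0],
                    [-p.kf2 * S1 + p.kc1, -p.kf2 * S1 - (p.kr2 + p.kc2)],
                ]
            )

    else:

        def d1f2(x1, x2, p):
            E = _enzyme(substitution, x1, x2, p, design)
            S0, S1, _ = x1
            return np.array(
                [
                    [p.kf1 * (E + S0), p.kf1 * S0, p.kf1 * S0],
                    [p.kf2 * S1, p.kf2 * (E + S1), p.kf2 * S1],
                ]
            )

        def d2f2(x1, x2, p):
            return np.array(
                [
                    [-(p.kr1 + p.kc1), 0.0],
                    [p.kc1, -(p.kr2 + p.kc2)],
                ]
            )

    return SplitSystem(f1=f1, f2=f2, n1=3, n2=2, d1f2=d1f2, d2f2=d2f2)


def solve_complexes(
    substitution: Substitution,
    x1: Sequence[float],
    params: FullParams,
    design: ExperimentDesign,
) -> np.ndarray:
    """Solve ``f2 = 0`` for the complex concentrations ``(C1, C2)``.

    Both eliminated subsystems are linear in ``(C1, C2)`` at fixed substrate
    state, so the quasi-steady-state complexes come from a 2x2 solve.
    """
    S0, S1, S2 = np.asarray(x1, dtype=float)
    p = params
    if substitution == "conservation_S":
        E = design.E_tot - design.S_tot + S0 + S1 + S2
        C1 = p.kf1 * E * S0 / (p.kr1 + p.kc1)
        C2 = (p.kc1 * C1 + p.kf2 * E * S1) / (p.kr2 + p.kc2)
        return np.array([C1, C2])
    A = np.array(
        [
            [-p.kf1 * S0 - (p.kr1 + p.kc1), -p.kf1 * S0],
            [p.kc1 - p.kf2 * S1, -p.kf2 * S1 - (p.kr2 + p.kc2)],
        ]
    )
    b = np.array([-p.kf1 * design.E_tot * S0, -p.kf2 * design.E_tot * S1])
    return np.linalg.solve(A, b)


def d2_rank_check(
    system: SplitSystem,
    point: Sequence[float],
    params,
    rank_tol: float = 1e-12,
) -> bool:
    """Whether ``D2 f2`` is invertible at ``point``.

    The test is scale-free: ``|det| > rank_tol * prod(row infinity-norms)``,
    with the convention that a matrix with an exactly zero row fails.
    """
    x1, x2 = system.split(point)
    J = np.asarray(system.d2f2(x1, x2, params), dtype=float)
    row_norms = np.max(np.abs(J), axis=1)
    if np.any(row_norms == 0):
        return False
    return bool(abs(np.linalg.det(J)) > rank_tol * float(np.prod(row_norms)))


def qss_reduced_rhs(system: SplitSystem, x: Sequence[float], params) -> np.ndarray:
    """Rates of the reduction's auxiliary system at the full state ``x``.

    Returns the concatenation of ``f1`` and the induced eliminated-variable
    dynamics ``-D2f2^{-1} D1f2 f1``.  Raises :class:`SingularJacobianError`
    when ``D2 f2`` is not invertible at ``x``.
    """
    x1, x2 = system.split(x)
    if not d2_rank_check(system, x, params):
        raise SingularJacobianError("D2 f2 singular at the requested state")
    r1 = np.asarray(system.f1(x1, x2, params), dtype=float)
    D1 = np.asarray(system.d1f2(x1, x2, params), dtype=float)
    D2 = np.asarray(system.d2f2(x1, x2, params), dtype=float)
    r2 = -np.linalg.solve(D2, D1 @ r1)
    return np.concatenate([r1, r2])


def variety_residual(
    trajectory: np.ndarray, system: SplitSystem, params
) -> float:
    """Max-norm of ``f2`` along a trajectory of the auxiliary system.

    A small residual certifies numerically that the quasi-steady-state
    variety is invariant for the reduced dynamics (it is, exactly, whenever
    the initial condition lies on it).
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    worst = 0.0
    for x in traj:
        x1, x2 = system.split(x)
        worst = max(worst, float(np.max(np.abs(system.f2(x1, x2, params)))))
    return worst


def reduction_error(
    full_traj: np.ndarray, reduced_traj: np.ndarray, times: Sequence[float]
) -> np.ndarray:
    """Per-species sup-norm difference between two trajectories.

    Both inputs must be sampled at the same ``times`` and have the same
    number of columns (species); the result has one entry per species.
    Non-negative, zero on identical inputs, symmetric in its arguments.
    """
    a = np.asarray(full_traj, dtype=float)
    b = np.asarray(reduced_traj, dtype=float)
    t = np.asarray(times, dtype=float)
    if a.shape != b.shape or a.shape[0] != len(t):
        raise ValueError(
            f"trajectory shapes {a.shape} and {b.shape} must match and have "
            f"{len(t)} rows"
        )
    return np.max(np.abs(a - b), axis=0)
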