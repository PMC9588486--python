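"""Mass-action models of dual ERK phosphorylation by MEK.

Three nested model layers are provided:

* the **Full model** — six species ``(S0, C1, C2, S1, S2, E)`` following the
  mass-action mechanism ``S0 + E <-> C1 -> C2 <-> S1 + E``, ``C2 -> S2 + E``,
  with six rate constants;
* the **Rational model** — three substrate species ``(S0, S1, S2)`` obtained
  from the Full model by a quasi-steady-state elimination of the complexes,
  with Michaelis–Menten-type rational rates;
* the **Linear model** — the same three species with linear rates, valid when
  the saturation coefficients ``gamma_i`` are small; it admits a closed-form
  solution.

Units are micromolar (concentrations) and minutes (time) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FULL_SPECIES",
    "SUBSTRATE_SPECIES",
    "FullParams",
    "ReducedParams",
    "ExperimentDesign",
    "DegenerateNetworkError",
    "IntegrationError",
    "full_rhs",
    "conserved_quantities",
    "reduced_from_full",
    "michaelis_menten",
    "rational_rhs",
    "linear_rhs",
    "linear_solution",
    "simulate",
]

#: Ordering of state components for the Full model.
FULL_SPECIES = ("S0", "C1", "C2", "S1", "S2", "E")
#: Ordering of state components for the reduced (Rational/Linear) models.
SUBSTRATE_SPECIES = ("S0", "S1", "S2")


class DegenerateNetworkError(ValueError):
    """Raised when ``k_r_i + k_c_i = 0``: the complex ``C_i`` can never unbind
    or react, so the network is degenerate and no reduction exists."""


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class FullParams:
    """Rate constants of the Full model.

    ``kf1, kf2`` are bimolecular binding rates (1/(uM*min)); ``kr1, kr2`` are
    unbinding rates and ``kc1, kc2`` catalytic rates (1/min).
    """

    kf1: float
    kr1: float
    kc1: float
    kf2: float
    kr2: float
    kc2: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("rate constants must be finite and non-negative")
        if self.kr1 + self.kc1 <= 0 or self.kr2 + self.kc2 <= 0:
            raise DegenerateNetworkError(
                "need k_r_i + k_c_i > 0 for both complexes"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.kf1, self.kr1, self.kc1, self.kf2, self.kr2, self.kc2]
        )


@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced models.

    ``kappa1, kappa2`` (1/min) are the kinetic efficiencies of the two
    phosphorylation steps, ``pi`` in [0, 1] is the processivity — the
    probability that both phosphate groups are added during a single enzyme
    encounter — and ``gamma1, gamma2`` (1/uM) are the saturation coefficients
    of the Rational model (ignored by the Linear model).
    """

    kappa1: float
    kappa2: float
    pi: float
    gamma1: float = 0.0
    gamma2: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("kappa_i must be non-negative")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma_i must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.kappa1, self.kappa2, self.pi, self.gamma1, self.gamma2]
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Measurement design: sampling times (min), replicate count and totals.

    ``S_tot`` is total substrate and ``E_tot`` total enzyme (uM); both are
    fixed by the initial condition ``S0(0) = S_tot``, ``E(0) = E_tot`` with
    every other species starting at zero.
    """

    times: tuple
    replicates: int
    S_tot: float = 5.0
    E_tot: float = 0.65
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.S_tot <= 0 or self.E_tot < 0:
            raise ValueError("need S_tot > 0 and E_tot >= 0")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_obs(self) -> int:
        """Total number of scalar observations, 3 * l * r."""
        return 3 * self.n_times * self.replicates

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def full_x0(self) -> np.ndarray:
        """Initial state of the Full model, (S_tot, 0, 0, 0, 0, E_tot)."""
        return np.array([self.S_tot, 0.0, 0.0, 0.0, 0.0, self.E_tot])

    def substrate_x0(self) -> np.ndarray:
        """Initial state of the reduced models, (S_tot, 0, 0)."""
        return np.array([self.S_tot, 0.0, 0.0])


def full_rhs(state: Sequence[float], params: FullParams) -> np.ndarray:
    """Time-derivatives of the Full model at ``state = (S0,C1,C2,S1,S2,E)``."""
    S0, C1, C2, S1, S2, E = np.asarray(state, dtype=float)
    p = params
    bind1 = p.kf1 * E * S0
    bind2 = p.kf2 * E * S1
    dS0 = -bind1 + p.kr1 * C1
    dC1 = bind1 - (p.kr1 + p.kc1) * C1
    dC2 = p.kc1 * C1 - (p.kr2 + p.kc2) * C2 + bind2
    dS1 = -bind2 + p.kr2 * C2
    dS2 = p.kc2 * C2
    dE = -bind1 + p.kr1 * C1 - bind2 + (p.kr2 + p.kc2) * C2
    return np.array([dS0, dC1, dC2, dS1, dS2, dE])


def conserved_quantities(state: Sequence[float]) -> tuple[float, float]:
    """Return ``(S_tot, E_tot)`` implied by a Full-model state.

    Substrate in any form, ``S0+S1+S2+C1+C2``, and enzyme in any form,
    ``E+C1+C2``, are both constant along trajectories.
    """
    S0, C1, C2, S1, S2, E = np.asarray(state, dtype=float)
    return float(S0 + S1 + S2 + C1 + C2), float(E + C1 + C2)


def michaelis_menten(params: FullParams) -> tuple[float, float]:
    """Michaelis–Menten constants ``k_Mi = (k_ci + k_ri) / k_fi`` in uM."""
    if params.kf1 == 0 or params.kf2 == 0:
        raise ZeroDivisionError("k_Mi undefined when k_fi = 0")
    return (
        (params.kc1 + params.kr1) / params.kf1,
        (params.kc2 + params.kr2) / params.kf2,
    )


def reduced_from_full(params: FullParams, E_tot: float) -> ReducedParams:
    """Map Full-model rate constants to reduced-model parameters.

    The map follows from the exact quasi-steady-state elimination of the
    complexes (setting the complex dynamics to zero and solving the resulting
    linear system for ``C1, C2``)::

        kappa_i = E_tot * k_fi * k_ci / (k_ci + k_ri)
        pi      = k_c2 / (k_c2 + k_r2)
        gamma1  = k_f1 * (k_c1 + k_c2 + k_r2) / ((k_c1 + k_r1)(k_c2 + k_r2))
        gamma2  = k_f2 / (k_c2 + k_r2)  =  1 / k_M2

    equivalently ``gamma1 = (1/k_M1) * (k_c1 + k_c2 + k_r2)/(k_c2 + k_r2)``.
    The ``k_r2`` term in ``gamma1``'s numerator accounts for the processive
    feed of the second complex by the first; simplified forms that drop it
    appear in the literature and coincide only when ``k_r2 << k_c1 + k_c2``.
    """
    p = params
    if p.kr1 + p.kc1 <= 0 or p.kr2 + p.kc2 <= 0:
        raise DegenerateNetworkError("need k_r_i + k_c_i > 0")
    kappa1 = E_tot * p.kf1 * p.kc1 / (p.kc1 + p.kr1)
    kappa2 = E_tot * p.kf2 * p.kc2 / (p.kc2 + p.kr2)
    pi = p.kc2 / (p.kc2 + p.kr2)
    gamma1 = p.kf1 * (p.kc1 + p.kc2 + p.kr2) / ((p.kc1 + p.kr1) * (p.kc2 + p.kr2))
    gamma2 = p.kf2 / (p.kc2 + p.kr2)
    return ReducedParams(kappa1, kappa2, pi, gamma1, gamma2)


def rational_rhs(state: Sequence[float], params: ReducedParams) -> np.ndarray:
    """Rational-model rates at ``state = (S0, S1, S2)``.

    All three rates share the saturation denominator
    ``gamma1*S0 + gamma2*S1 + 1``; they sum to zero, so ``S0+S1+S2`` is
    conserved.
    """
    S0, S1, S2 = np.asarray(state, dtype=float)
    p = params
    den = p.gamma1 * S0 + p.gamma2 * S1 + 1.0
    dS0 = -p.kappa1 * S0 / den
    dS1 = (-p.kappa2 * S1 + (1.0 - p.pi) * p.kappa1 * S0) / den
    dS2 = (p.pi * p.kappa1 * S0 + p.kappa2 * S1) / den
    return np.array([dS0, dS1, dS2])


def linear_rhs(state: Sequence[float], params: ReducedParams) -> np.ndarray:
    """Linear-model rates: the Rational model with ``gamma1 = gamma2 = 0``."""
    S0, S1, S2 = np.asarray(state, dtype=float)
    p = params
    dS0 = -p.kappa1 * S0
    dS1 = -p.kappa2 * S1 + (1.0 - p.pi) * p.kappa1 * S0
    dS2 = p.pi * p.kappa1 * S0 + p.kappa2 * S1
    return np.array([dS0, dS1, dS2])


def _exp_diff_quotient(kappa1: float, kappa2: float, t: np.ndarray) -> np.ndarray:
    """Stable evaluation of ``(exp(-k2 t) - exp(-k1 t)) / (k1 - k2)``.

    Written as ``exp(-k1 t) * expm1((k1 - k2) t) / (k1 - k2)``; near the
    diagonal ``k1 = k2`` the difference quotient is replaced by its series,
    which is where the naive two-branch formula loses all precision.
    """
    d = kappa1 - kappa2
    tiny = 1e-9 * max(kappa1, kappa2, 1.0)
    base = np.exp(-kappa1 * t)
    if abs(d) < tiny:
        dt = d * t
        return base * t * (1.0 + dt / 2.0 + dt * dt / 6.0)
    return base * np.expm1(d * t) / d


def linear_solution(
    t: float | Sequence[float], params: ReducedParams, S_tot: float
) -> np.ndarray:
    """Closed-form Linear-model solution from ``(S_tot, 0, 0)``.

    ``S0(t) = S_tot exp(-kappa1 t)``;
    ``S1(t) = S_tot kappa1 (1-pi) (exp(-kappa2 t) - exp(-kappa1 t)) /
    (kappa1 - kappa2)`` with the degenerate limit
    ``S_tot kappa1 (1-pi) t exp(-kappa1 t)`` at ``kappa1 = kappa2``;
    ``S2 = S_tot - S0 - S1``.  Continuous in the parameters across the
    ``kappa1 = kappa2`` locus.

    Returns an array of shape ``(3,)`` for scalar ``t`` or ``(len(t), 3)``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    p = params
    S0 = S_tot * np.exp(-p.kappa1 * t_arr)
    S1 = S_tot * p.kappa1 * (1.0 - p.pi) * _exp_diff_quotient(
        p.kappa1, p.kappa2, t_arr
    )
    S2 = S_tot - S0 - S1
    out = np.column_stack([S0, S1, S2])
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def simulate(
    rhs: Callable[[Sequence[float], object], np.ndarray],
    params: object,
    x0: Sequence[float],
    times: Sequence[float],
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> np.ndarray:
    """Integrate ``dx/dt = rhs(x, params)`` from t=0, sampled at ``times``.

    Uses an adaptive explicit Runge–Kutta method (the systems here are
    non-stiff at the experimental parameter magnitudes).  Returns an array of
    shape ``(len(times), len(x0))``.  Raises :class:`IntegrationError` with
    the failing time if the step size underflows.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    if t[0] < 0:
        raise ValueError("times must be non-negative")
    sol = solve_ivp(
        lambda _t, x: rhs(x, params),
        (0.0, float(t[-1])),
        np.asarray(x0, dtype=float),
        t_eval=t,
        method="RK45",
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationError(
            f"integration failed near t = {t_fail:g}: {sol.message}", t_fail
        )
    return sol.y.T
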