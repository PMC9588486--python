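"""Structural and practical identifiability of the ERK models.

The model prediction map sends a parameter vector to the noise-free
observable data — the three substrate states at the design's time points,
tiled over replicates.  Under i.i.d. additive Gaussian noise the maximum
likelihood estimate is the least-squares fit, and the likelihood-ratio
confidence region at significance level alpha,

    U_delta(z*) = { theta : -log psi(theta, z*) < delta },

is exactly the preimage under the prediction map of the open Euclidean ball
of radius ``rho = sqrt(rss + 2 sigma^2 * (-log k*))`` around the data point.
Practical identifiability is the boundedness of this region.  The critical
value ``-log k*`` is calibrated either by parametric-bootstrap simulation of
likelihood ratios (:func:`algorithm1_neg_log_kstar`) or by the Wilks
chi-squared asymptote (:func:`wilks_neg_log_kstar`).

Structural identifiability of the Linear model is witnessed constructively:
:func:`recover_linear_params` inverts the prediction map from the values of
``S0`` and ``S1`` at any three distinct positive time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .models import (
    ExperimentDesign,
    FullParams,
    IntegrationError,
    ReducedParams,
    full_rhs,
    linear_solution,
    rational_rhs,
    simulate,
)

__all__ = [
    "Model",
    "MODELS",
    "get_model",
    "TimeCourseData",
    "MLEResult",
    "ConfidenceSpec",
    "RegionSample",
    "prediction_map",
    "mle_fit",
    "estimate_sigma",
    "neg_log_likelihood",
    "algorithm1_neg_log_kstar",
    "wilks_neg_log_kstar",
    "confidence_spec",
    "region_membership",
    "algorithm2_marginal_region",
    "boundedness_assessment",
    "recover_linear_params",
    "InconsistentDataError",
]


class InconsistentDataError(ValueError):
    """Raised when data handed to an exact inversion is not model-generated."""


# --------------------------------------------------------------------------
# Model registry


@dataclass(frozen=True)
class Model:
    """A named observable model: parameter vector -> (3, l) trajectory."""

    name: str
    param_names: tuple
    default_bounds: tuple
    _traj: Callable = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def trajectory(self, theta: Sequence[float], design: ExperimentDesign) -> np.ndarray:
        """Noise-free (3, l) array of (S0, S1, S2) at the design times."""
        return self._traj(np.asarray(theta, dtype=float), design)


def _linear_traj(theta, design):
    p = ReducedParams(theta[0], theta[1], theta[2])
    return linear_solution(design.times_array(), p, design.S_tot).T


def _rational_traj(theta, design):
    p = ReducedParams(*theta)
    traj = simulate(
        rational_rhs, p, design.substrate_x0(), design.times_array(),
        rel_tol=1e-8, abs_tol=1e-10,
    )
    return traj.T


def _full_traj(theta, design):
    p = FullParams(*theta)
    traj = simulate(
        full_rhs, p, design.full_x0(), design.times_array(),
        rel_tol=1e-8, abs_tol=1e-10,
    )
    # observables are the plain substrate states (S0, S1, S2)
    return traj[:, [0, 3, 4]].T


MODELS: dict[str, Model] = {
    "linear": Model(
        "linear",
        ("kappa1", "kappa2", "pi"),
        ((0.0, 10.0), (0.0, 10.0), (0.0, 1.0)),
        _linear_traj,
    ),
    "rational": Model(
        "rational",
        ("kappa1", "kappa2", "pi", "gamma1", "gamma2"),
        ((0.0, 10.0), (0.0, 10.0), (0.0, 1.0), (0.0, 1000.0), (0.0, 1000.0)),
        _rational_traj,
    ),
    "full": Model(
        "full",
        ("kf1", "kr1", "kc1", "kf2", "kr2", "kc2"),
        ((0.0, 10.0),) * 6,
        _full_traj,
    ),
}


def get_model(model: str | Model) -> Model:
    if isinstance(model, Model):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise KeyError(
            f"unknown model {model!r}; choose from {sorted(MODELS)}"
        ) from None


# --------------------------------------------------------------------------
# Data containers


@dataclass
class TimeCourseData:
    """Measured concentrations, shape (3 species, l times, r replicates)."""

    values: np.ndarray
    design: ExperimentDesign

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (3, self.design.n_times, self.design.replicates)
        if v.shape != expected:
            raise ValueError(f"values shape {v.shape}, expected {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        self.values = v

    def flat(self) -> np.ndarray:
        """Flatten to the prediction-map order: per replicate, the (3, l)
        block raveled species-major, replicates concatenated."""
        return np.concatenate(
            [self.values[:, :, j].ravel() for j in range(self.design.replicates)]
        )

    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=2)


@dataclass
class MLEResult:
    theta_hat: np.ndarray
    rss: float
    sigma_hat: float
    n_starts_used: int
    at_bounds: bool = False


@dataclass
class ConfidenceSpec:
    """Geometry of the likelihood-ratio confidence region for one data set.

    ``delta`` thresholds the negative log-likelihood; ``rho`` is the radius
    of the equivalent data-space ball; both encode the same region.
    """

    alpha: float
    neg_log_kstar: float
    delta: float
    rho: float
    sigma: float
    rss: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.neg_log_kstar < 0:
            raise ValueError("-log k* must be >= 0")
        if self.rho < 0 or not np.isfinite(self.rho):
            raise ValueError("invalid rho")


@dataclass
class RegionSample:
    """Discrete approximation of a confidence region from Algorithm 2."""

    accepted: np.ndarray          # (n_accepted, n_params)
    bounds: Mapping[str, tuple]   # per-parameter (lo, hi)
    marginal_pair: tuple
    n_proposed: int
    param_names: tuple

    def marginal(self) -> np.ndarray:
        idx = [self.param_names.index(p) for p in self.marginal_pair]
        if len(self.accepted) == 0:
            return np.empty((0, 2))
        return self.accepted[:, idx]


# --------------------------------------------------------------------------
# Prediction map, likelihood and MLE


def prediction_map(
    theta: Sequence[float], design: ExperimentDesign, model: str | Model
) -> np.ndarray:
    """Flat noise-free data vector of length ``3 * l * r``.

    The (3, l) trajectory block (species-major, times within species) is
    repeated once per replicate.
    """
    m = get_model(model)
    block = m.trajectory(theta, design).ravel()
    return np.tile(block, design.replicates)


def neg_log_likelihood(
    theta: Sequence[float],
    z: TimeCourseData,
    sigma: float,
    model: str | Model,
) -> float:
    """Gaussian negative log-likelihood at noise level ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = z.design.n_obs
    rss = _rss(np.asarray(theta, dtype=float), z, get_model(model))
    return 0.5 * n * np.log(2.0 * np.pi * sigma**2) + rss / (2.0 * sigma**2)


def _rss(theta: np.ndarray, z: TimeCourseData, model: Model) -> float:
    pred = model.trajectory(theta, z.design)
    return float(np.sum((z.values - pred[:, :, None]) ** 2))


def _spread(z: TimeCourseData) -> float:
    """Sum of squares of replicates about the replicate mean (theta-free)."""
    mean = z.replicate_mean()
    return float(np.sum((z.values - mean[:, :, None]) ** 2))


def mle_fit(
    z: TimeCourseData,
    model: str | Model,
    bounds: Sequence[tuple] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: Sequence[Sequence[float]] = (),
) -> MLEResult:
    """Multi-start least-squares maximum likelihood fit.

    Minimises ``||z - prediction_map(theta)||^2`` over the bounds box.  The
    replicate dimension is collapsed exactly: the total RSS equals
    ``r * ||mean - trajectory||^2`` plus a theta-independent spread term, so
    each local fit works on the replicate mean.  Starts are a seeded Latin
    hypercube over the box, plus any ``extra_starts``.  Deterministic for a
    fixed seed.
    """
    m = get_model(model)
    if bounds is None:
        bounds = m.default_bounds
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    mean = z.replicate_mean()
    r = z.design.replicates
    spread = _spread(z)
    sqrt_r = np.sqrt(r)

    def resid(theta):
        try:
            pred = m.trajectory(theta, z.design)
        except IntegrationError:
            return np.full(mean.size, 1e6)
        return (sqrt_r * (mean - pred)).ravel()

    sampler = qmc.LatinHypercube(d=m.n_params, seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lo, hi)
    starts = list(starts) + [np.asarray(s, dtype=float) for s in extra_starts]

    best = None
    n_used = 0
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:
            continue
        n_used += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no optimisation start converged")

    rss = 2.0 * best.cost + spread
    theta_hat = best.x
    eps = 1e-6 * np.maximum(1.0, hi - lo)
    at_bounds = bool(np.any(theta_hat <= lo + eps) or np.any(theta_hat >= hi - eps))
    sigma_hat = float(np.sqrt(rss / z.design.n_obs))
    return MLEResult(theta_hat, float(rss), sigma_hat, n_used, at_bounds)


def estimate_sigma(
    z: TimeCourseData, theta_hat: Sequence[float], model: str | Model
) -> float:
    """ML noise estimate: ``sqrt(rss / (3 l r))`` about the fitted trajectory."""
    rss = _rss(np.asarray(theta_hat, dtype=float), z, get_model(model))
    return float(np.sqrt(rss / z.design.n_obs))


# --------------------------------------------------------------------------
# Critical values and the confidence region


def wilks_neg_log_kstar(alpha: float, dof: int) -> float:
    """Asymptotic critical value: chi-squared(1 - alpha; dof) / 2."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, dof) / 2.0)


def algorithm1_neg_log_kstar(
    theta_hat: Sequence[float],
    sigma: float,
    design: ExperimentDesign,
    model: str | Model,
    alpha: float = 0.05,
    n_sim: int = 500,
    seed: int = 0,
    n_starts: int = 5,
    bounds: Sequence[tuple] | None = None,
) -> float:
    """Parametric-bootstrap estimate of ``-log k*``.

    Simulates ``n_sim`` data sets from the fitted model with noise ``sigma``,
    refits each, and returns the empirical ``(1 - alpha)``-quantile of the
    negative log likelihood ratio ``-log Lambda = (rss(theta_hat) -
    rss(refit)) / (2 sigma^2)`` (sigma held fixed).  Quantiles interpolate
    linearly between order statistics.  Failed refits are dropped with a
    warning.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    m = get_model(model)
    theta_hat = np.asarray(theta_hat, dtype=float)
    truth = m.trajectory(theta_hat, design)
    rng = np.random.default_rng(seed)
    stats_out = []
    n_failed = 0
    for i in range(n_sim):
        noise = sigma * rng.standard_normal(
            (3, design.n_times, design.replicates)
        )
        z_hat = TimeCourseData(truth[:, :, None] + noise, design)
        try:
            fit = mle_fit(
                z_hat, m, bounds=bounds, n_starts=n_starts - 1,
                seed=seed + 1 + i, extra_starts=[theta_hat],
            )
        except RuntimeError:
            n_failed += 1
            continue
        rss_null = _rss(theta_hat, z_hat, m)
        stats_out.append(max(0.0, (rss_null - fit.rss) / (2.0 * sigma**2)))
    if n_failed:
        warnings.warn(f"{n_failed}/{n_sim} bootstrap refits failed; dropped")
    if not stats_out:
        raise RuntimeError("all bootstrap refits failed")
    return float(np.quantile(np.asarray(stats_out), 1.0 - alpha))


def confidence_spec(
    z: TimeCourseData,
    theta_hat: Sequence[float],
    sigma: float,
    neg_log_kstar: float,
    model: str | Model,
    alpha: float = 0.05,
) -> ConfidenceSpec:
    """Assemble the region geometry: ``delta`` threshold and ball radius
    ``rho = sqrt(rss + 2 sigma^2 (-log k*))``."""
    rss = _rss(np.asarray(theta_hat, dtype=float), z, get_model(model))
    rho_sq = rss + 2.0 * sigma**2 * neg_log_kstar
    if rho_sq < 0:
        raise ValueError("rho^2 negative; check -log k*")
    delta = neg_log_likelihood(theta_hat, z, sigma, model) + neg_log_kstar
    return ConfidenceSpec(
        alpha=alpha,
        neg_log_kstar=float(neg_log_kstar),
        delta=float(delta),
        rho=float(np.sqrt(rho_sq)),
        sigma=float(sigma),
        rss=float(rss),
    )


def region_membership(
    theta_prime: Sequence[float],
    z: TimeCourseData,
    spec: ConfidenceSpec,
    model: str | Model,
) -> bool:
    """Whether ``theta'`` lies in the confidence region (strict inequality).

    Equivalent formulations ``-log psi(theta') < delta`` and
    ``||z - phi(theta')|| < rho`` are algebraically identical; the residual
    form is used.  A failed integration counts as non-membership (with a
    warning): a conservative convention.
    """
    try:
        rss = _rss(np.asarray(theta_prime, dtype=float), z, get_model(model))
    except IntegrationError as err:
        warnings.warn(f"integration failed during membership test: {err}")
        return False
    return rss < spec.rho**2


def algorithm2_marginal_region(
    z: TimeCourseData,
    model: str | Model,
    bounds: Mapping[str, tuple],
    marginal_pair: tuple,
    n_samples: int,
    spec: ConfidenceSpec,
    seed: int = 0,
    scheme: str = "uniform",
) -> RegionSample:
    """Sample the bounds box, keep confidence-region members.

    ``bounds`` maps every model parameter to ``(lo, hi)``; a parameter with
    ``lo == hi`` is held fixed.  ``scheme`` is ``"uniform"`` (seeded uniform
    proposals, the default) or ``"grid"`` (a full factorial grid over the
    non-fixed parameters, approximately ``n_samples`` points).  The result
    records all accepted full parameter vectors; :meth:`RegionSample.marginal`
    projects them onto the named pair.
    """
    m = get_model(model)
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    for p in marginal_pair:
        if p not in m.param_names:
            raise KeyError(f"unknown parameter {p!r} for model {m.name}")
    lo = np.array([bounds[p][0] for p in m.param_names], dtype=float)
    hi = np.array([bounds[p][1] for p in m.param_names], dtype=float)
    if np.any(hi < lo):
        raise ValueError("each bound must satisfy lo <= hi")
    free = hi > lo

    if scheme == "uniform":
        rng = np.random.default_rng(seed)
        proposals = lo + (hi - lo) * rng.random((n_samples, m.n_params))
    elif scheme == "grid":
        n_free = int(np.sum(free))
        per_axis = max(2, int(round(n_samples ** (1.0 / max(n_free, 1)))))
        axes = [
            np.linspace(lo[i], hi[i], per_axis) if free[i] else np.array([lo[i]])
            for i in range(m.n_params)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        proposals = np.column_stack([g.ravel() for g in mesh])
    else:
        raise ValueError("scheme must be 'uniform' or 'grid'")

    accepted = [
        th for th in proposals if region_membership(th, z, spec, m)
    ]
    accepted_arr = (
        np.array(accepted) if accepted else np.empty((0, m.n_params))
    )
    return RegionSample(
        accepted=accepted_arr,
        bounds={p: tuple(bounds[p]) for p in m.param_names},
        marginal_pair=tuple(marginal_pair),
        n_proposed=len(proposals),
        param_names=m.param_names,
    )


def boundedness_assessment(
    region: RegionSample, margin_frac: float = 0.02
) -> str:
    """Classify a region sample as ``bounded``, ``boundary-contact`` or
    ``empty``.

    ``boundary-contact`` means some accepted point lies within
    ``margin_frac * (hi - lo)`` of a proposal bound in one of the
    marginalised coordinates — the sampled region presses against the edge
    of the proposal box, so boundedness cannot be asserted within it.
    """
    if len(region.accepted) == 0:
        return "empty"
    pts = region.marginal()
    for j, name in enumerate(region.marginal_pair):
        lo, hi = region.bounds[name]
        if hi <= lo:
            continue
        margin = margin_frac * (hi - lo)
        if np.any(pts[:, j] <= lo + margin) or np.any(pts[:, j] >= hi - margin):
            return "boundary-contact"
    return "bounded"


# --------------------------------------------------------------------------
# Constructive structural identifiability of the Linear model


def _s1_shape(t: np.ndarray, kappa1: float, kappa2: float) -> np.ndarray:
    """The S1 time profile up to its amplitude: the exponential difference
    quotient, stable across kappa1 = kappa2."""
    d = kappa1 - kappa2
    tiny = 1e-12 * max(kappa1, kappa2, 1.0)
    base = np.exp(-kappa1 * t)
    if abs(d) < tiny:
        return base * t
    return base * np.expm1(d * t) / d


def recover_linear_params(
    y0: Sequence[float],
    y1: Sequence[float],
    t1: float,
    t2: float,
    t3: float,
    S_tot: float,
    tol: float = 1e-6,
) -> ReducedParams:
    """Invert the Linear model from exact observations at three times.

    ``y0`` and ``y1`` hold ``S0`` and ``S1`` at ``(t1, t2, t3)``.  The decay
    rate comes from ``kappa1 = -log(y0/S_tot)/t`` (cross-checked over all
    three times); ``kappa2`` solves the amplitude-free ratio equation
    ``y1(ta) h(tb; kappa2) = y1(tb) h(ta; kappa2)`` where ``h`` is the S1
    shape function, and the processivity follows from the amplitude.  The
    third time point validates the solution; raises
    :class:`InconsistentDataError` when the data are not model-generated and
    :class:`ValueError` in the degenerate cases (``kappa1 = 0`` leaves ``pi``
    undetermined; ``pi = 1`` leaves ``kappa2`` undetermined).
    """
    ts = np.array([t1, t2, t3], dtype=float)
    if len(set(ts.tolist())) != 3 or np.any(ts <= 0):
        raise ValueError("t1, t2, t3 must be distinct and positive")
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    if y0.shape != (3,) or y1.shape != (3,):
        raise ValueError("y0 and y1 must each hold three values")
    if np.any(y0 <= 0) or np.any(y0 >= S_tot):
        raise ValueError("S0 observations must lie strictly in (0, S_tot)")

    k1_est = -np.log(y0 / S_tot) / ts
    k1 = float(np.mean(k1_est))
    if np.max(np.abs(k1_est - k1)) > tol * max(k1, 1.0):
        raise InconsistentDataError(
            f"kappa1 estimates disagree: {k1_est.tolist()}"
        )
    if k1 <= 0:
        raise ValueError("kappa1 = 0: S1 vanishes identically, pi undetermined")

    amp_scale = S_tot * k1
    if np.all(np.abs(y1) <= 1e-14 * amp_scale):
        raise ValueError("S1 is identically zero (pi = 1): kappa2 undetermined")

    ta, tb, tc = ts
    ya, yb, yc = y1

    def ratio_eq(k2: float) -> float:
        return ya * _s1_shape(np.array([tb]), k1, k2)[0] - yb * _s1_shape(
            np.array([ta]), k1, k2
        )[0]

    # bracket roots of the ratio equation on a log grid
    grid = np.concatenate([[1e-8], np.geomspace(1e-6, 1e3, 181)])
    vals = np.array([ratio_eq(k) for k in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                float(optimize.brentq(ratio_eq, grid[i], grid[i + 1],
                                      xtol=1e-14, rtol=1e-15))
            )
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise InconsistentDataError("no kappa2 solves the S1 ratio equation")

    best = None
    for k2 in roots:
        ha = _s1_shape(np.array([ta]), k1, k2)[0]
        if ha == 0.0:
            continue
        one_minus_pi = ya / (amp_scale * ha)
        if not -1e-9 <= one_minus_pi <= 1.0 + 1e-9:
            continue
        pi = float(np.clip(1.0 - one_minus_pi, 0.0, 1.0))
        # validate against the held-out third time point
        pred_c = amp_scale * (1.0 - pi) * _s1_shape(np.array([tc]), k1, k2)[0]
        err = abs(pred_c - yc)
        if best is None or err < best[0]:
            best = (err, k2, pi)
    if best is None or best[0] > tol * max(amp_scale, 1.0):
        raise InconsistentDataError(
            "S1 observations inconsistent with the Linear model"
        )
    _, k2, pi = best

    # polish (kappa2, pi) against all three S1 equations
    def resid(v):
        kk2, ppi = v
        shapes = _s1_shape(ts, k1, kk2)
        return amp_scale * (1.0 - ppi) * shapes - y1

    sol = optimize.least_squares(
        resid, [k2, pi], xtol=3e-16, ftol=3e-16, gtol=3e-16
    )
    k2, pi = float(sol.x[0]), float(np.clip(sol.x[1], 0.0, 1.0))
    return ReducedParams(k1, k2, pi)
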