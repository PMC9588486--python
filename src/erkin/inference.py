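"""Bayesian inference of reduced-model parameters from time courses.

The statistical model: each measurement of each substrate state is the
model trajectory plus independent Gaussian noise with a single standard
deviation ``sigma``, which is inferred jointly with the kinetic parameters.
Priors are uniform boxes — ``kappa_i ~ U(0, 10) 1/min``, ``pi ~ U(0, 1)``,
``sigma ~ U(0, 10) uM`` (and, experimentally, ``gamma_i ~ U(0, 1000) 1/uM``
for the Rational model, whose posterior is prior-sensitive).

Sampling uses an adaptive random-walk Metropolis scheme with several
independent chains; per-coordinate proposal scales adapt toward a target
acceptance rate during warm-up only, so the post-warm-up kernel is a valid
fixed Metropolis kernel.  A diagnostics gate (split-R-hat, effective sample
size) must pass before a posterior cloud is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .identifiability import TimeCourseData, get_model, neg_log_likelihood
from .models import ExperimentDesign, IntegrationError

__all__ = [
    "PriorSpec",
    "PosteriorCloud",
    "NonConvergenceError",
    "log_prior",
    "log_posterior",
    "sample_posterior",
    "diagnostics",
    "marginalize",
]


class NonConvergenceError(RuntimeError):
    """MCMC diagnostics failed after the retry budget."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over open intervals."""

    kappa_bounds: tuple = (0.0, 10.0)
    sigma_bounds: tuple = (0.0, 10.0)
    pi_bounds: tuple = (0.0, 1.0)
    gamma_bounds: tuple = (0.0, 1000.0)

    def box(self, model: str = "linear") -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) arrays for the sampled vector: model params then sigma."""
        m = get_model(model)
        pairs = []
        for name in m.param_names:
            if name.startswith("kappa"):
                pairs.append(self.kappa_bounds)
            elif name == "pi":
                pairs.append(self.pi_bounds)
            elif name.startswith("gamma"):
                pairs.append(self.gamma_bounds)
            else:  # full-model rate constants reuse the kappa box
                pairs.append(self.kappa_bounds)
        pairs.append(self.sigma_bounds)
        lo = np.array([p[0] for p in pairs])
        hi = np.array([p[1] for p in pairs])
        return lo, hi


@dataclass
class PosteriorCloud:
    """Pooled post-warm-up MCMC draws for one MEK variant.

    ``samples`` has one row per draw; columns are the model parameters
    followed by ``sigma``.  ``chains`` keeps the unpooled (chain, draw, dim)
    array for diagnostics.
    """

    samples: np.ndarray
    param_names: tuple
    variant: str
    seed: int
    n_chains: int
    diagnostics: Mapping = field(default_factory=dict)
    chains: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("need at least one sample")


def log_prior(theta: Sequence[float], prior: PriorSpec, model: str = "linear") -> float:
    """0 inside the open prior box, -inf outside (boundary excluded)."""
    theta = np.asarray(theta, dtype=float)
    lo, hi = prior.box(model)
    if theta.shape != lo.shape:
        raise ValueError(f"theta has shape {theta.shape}, expected {lo.shape}")
    if np.all(theta > lo) and np.all(theta < hi):
        return 0.0
    return -np.inf


def log_posterior(
    theta: Sequence[float],
    z: TimeCourseData,
    design: ExperimentDesign,
    model: str,
    prior: PriorSpec,
) -> float:
    """Unnormalised log posterior; ``theta`` is model params plus sigma."""
    lp = log_prior(theta, prior, model)
    if not np.isfinite(lp):
        return -np.inf
    theta = np.asarray(theta, dtype=float)
    try:
        nll = neg_log_likelihood(theta[:-1], z, theta[-1], model)
    except IntegrationError as err:
        warnings.warn(f"integration failed in posterior evaluation: {err}")
        return -np.inf
    return lp - nll


def diagnostics(chains: np.ndarray, param_names: Sequence[str] | None = None) -> dict:
    """Split-R-hat and effective sample size per coordinate.

    ``chains`` has shape (n_chains, n_draws, dim) with n_chains >= 2.  The
    gate passes when every rank-normalised split-R-hat is below 1.05 and
    every bulk ESS exceeds 100.
    """
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[0] < 2:
        raise ValueError("chains must be (n_chains >= 2, n_draws, dim)")
    dim = chains.shape[2]
    names = list(param_names) if param_names else [f"p{i}" for i in range(dim)]
    rhat = np.array([float(az.rhat(chains[:, :, i])) for i in range(dim)])
    ess = np.array([float(az.ess(chains[:, :, i])) for i in range(dim)])
    report = {
        "rhat": dict(zip(names, rhat.tolist())),
        "ess": dict(zip(names, ess.tolist())),
        "max_rhat": float(np.max(rhat)),
        "min_ess": float(np.min(ess)),
        "passed": bool(np.all(rhat < 1.05) and np.all(ess > 100.0)),
    }
    return report


def _run_chain(log_post, x0, scales, n_warmup, n_keep, thin, rng):
    """One adaptive random-walk Metropolis chain.

    Per-coordinate Gaussian proposals; log-scales adapt by Robbins–Monro
    toward 44% acceptance during warm-up, then freeze.
    """
    x = np.array(x0, dtype=float)
    lp = log_post(x)
    log_s = np.log(np.asarray(scales, dtype=float))
    dim = len(x)
    kept = np.empty((n_keep, dim))
    n_sweeps = n_warmup + n_keep * thin
    accepts = 0
    j = 0
    for sweep in range(n_sweeps):
        for i in range(dim):  # one full component-wise sweep per iteration
            prop = x.copy()
            prop[i] += np.exp(log_s[i]) * rng.standard_normal()
            lp_prop = log_post(prop)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
                accepts += 1
            if sweep < n_warmup:
                step = 1.0 / (1.0 + sweep / 10.0)
                log_s[i] += step * ((1.0 if accept else 0.0) - 0.44)
        if sweep >= n_warmup and (sweep - n_warmup + 1) % thin == 0:
            kept[j] = x
            j += 1
    return kept, accepts / (n_sweeps * dim)


def sample_posterior(
    z: TimeCourseData,
    design: ExperimentDesign,
    model: str,
    prior: PriorSpec,
    n_samples: int = 500,
    n_chains: int = 4,
    seed: int = 0,
    variant: str = "",
    n_warmup: int = 2000,
    thin: int = 5,
    max_retries: int = 2,
) -> PosteriorCloud:
    """Draw ``n_samples`` post-warm-up samples per chain and pool them.

    Chains start from overdispersed points in the central 80% of the prior
    box.  If the diagnostics gate fails, warm-up and kept lengths double, up
    to ``max_retries`` times; a final failure raises
    :class:`NonConvergenceError`.  Deterministic for a fixed seed.
    """
    if n_chains < 2:
        raise ValueError("need n_chains >= 2 for convergence diagnostics")
    m = get_model(model)
    lo, hi = prior.box(model)
    names = tuple(m.param_names) + ("sigma",)

    def log_post(theta):
        return log_posterior(theta, z, design, model, prior)

    report: dict = {}
    for attempt in range(max_retries + 1):
        factor = 2**attempt
        warm = n_warmup * factor
        keep = n_samples  # pooled size is part of the contract; lengthen warmup/thin instead
        thin_eff = thin * factor
        rng = np.random.default_rng([seed, attempt])
        chains = []
        rates = []
        for c in range(n_chains):
            crng = np.random.default_rng([seed, attempt, c])
            x0 = lo + (hi - lo) * (0.1 + 0.8 * crng.random(len(lo)))
            scales = 0.05 * (hi - lo)
            kept, rate = _run_chain(
                log_post, x0, scales, warm, keep, thin_eff, crng
            )
            chains.append(kept)
            rates.append(rate)
        chains = np.stack(chains)  # (n_chains, keep, dim)
        report = diagnostics(chains, names)
        report["acceptance"] = [float(r) for r in rates]
        if report["passed"]:
            break
    else:
        raise NonConvergenceError(
            f"diagnostics failed after {max_retries + 1} attempts: "
            f"max R-hat {report.get('max_rhat')}, min ESS {report.get('min_ess')}"
        )

    pooled = chains.reshape(-1, chains.shape[2])
    return PosteriorCloud(
        samples=pooled,
        param_names=names,
        variant=variant,
        seed=seed,
        n_chains=n_chains,
        diagnostics=report,
        chains=chains,
    )


def marginalize(cloud: PosteriorCloud, keep: Sequence[str]) -> np.ndarray:
    """Project the pooled samples onto the named coordinates (in order)."""
    idx = []
    for name in keep:
        if name not in cloud.param_names:
            raise KeyError(f"unknown parameter {name!r}")
        idx.append(cloud.param_names.index(name))
    return cloud.samples[:, idx]
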