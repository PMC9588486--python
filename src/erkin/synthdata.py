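"""Synthetic time courses and posterior-like point clouds.

The generators reproduce the statistical structure of the ERK
phosphorylation experiments: 0.65 uM activated MEK added to 5 uM
unphosphorylated ERK; three measured phosphorylation states at seven time
points; 11 replicates for wild-type MEK, 6 for the phosphomimetic SSDD
variant (on a shifted time grid) and 5 for each activating mutant (Y130C,
F53S, E203K); i.i.d. additive Gaussian noise with a single standard
deviation.  Negative synthetic measurements are kept — the Gaussian noise
model assigns them positive likelihood, and clamping would bias fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .identifiability import TimeCourseData, get_model
from .models import ExperimentDesign, FullParams, ReducedParams, full_rhs, simulate

__all__ = [
    "VariantScenario",
    "WT_TIMES",
    "SSDD_TIMES",
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_SIGMA",
    "default_designs",
    "default_scenario",
    "generate_timecourse",
    "generate_posterior_like_cloud",
    "make_variant_suite",
]

WT_TIMES = (0.5, 2.0, 3.25, 3.75, 5.0, 10.0, 20.0)
SSDD_TIMES = (1.0, 2.0, 3.25, 5.0, 10.0, 20.0, 40.0)

#: Demo truth for the Linear model: inside the prior box, visible dynamics
#: over the 20-minute window.
DEFAULT_TRUE_PARAMS = ReducedParams(kappa1=0.5, kappa2=1.5, pi=0.3)
DEFAULT_SIGMA = 0.1  # uM


@dataclass
class VariantScenario:
    """A named data-generating condition: design, true parameters, noise."""

    label: str
    design: ExperimentDesign
    true_params: FullParams | ReducedParams
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def default_designs() -> dict[str, ExperimentDesign]:
    """The five measurement designs, keyed by MEK-variant label."""
    designs = {
        "wild-type": ExperimentDesign(WT_TIMES, 11, label="wild-type"),
        "SSDD": ExperimentDesign(SSDD_TIMES, 6, label="SSDD"),
    }
    for mutant in ("Y130C", "F53S", "E203K"):
        designs[mutant] = ExperimentDesign(WT_TIMES, 5, label=mutant)
    return designs


def default_scenario(label: str = "wild-type") -> VariantScenario:
    """Demo scenario: the named design with the default Linear truth."""
    return VariantScenario(
        label=label,
        design=default_designs()[label],
        true_params=DEFAULT_TRUE_PARAMS,
        sigma=DEFAULT_SIGMA,
    )


def generate_timecourse(
    scenario: VariantScenario,
    model: str = "linear",
    seed: int = 0,
    compound_outputs: bool = False,
) -> TimeCourseData:
    """Simulate one noisy data set for a scenario.

    The noise-free trajectory of the named model at the design's times gets
    i.i.d. ``N(0, sigma^2)`` noise per species, time and replicate.
    ``compound_outputs`` (Full model only) observes the physically measured
    channels ``S0 + C1``, ``S1 + C2`` and ``S2`` instead of the bare
    substrate states.  Deterministic for a fixed seed.
    """
    design = scenario.design
    if compound_outputs:
        if model != "full":
            raise ValueError("compound outputs only exist for the full model")
        if not isinstance(scenario.true_params, FullParams):
            raise TypeError("full model needs FullParams truth")
        states = simulate(
            full_rhs, scenario.true_params, design.full_x0(),
            design.times_array(),
        )
        # (S0 + C1, S1 + C2, S2)
        clean = np.vstack(
            [states[:, 0] + states[:, 1], states[:, 3] + states[:, 2], states[:, 4]]
        )
    else:
        m = get_model(model)
        theta = np.asarray(scenario.true_params.as_array(), dtype=float)
        if model == "linear":
            theta = theta[:3]
        clean = m.trajectory(theta, design)
    rng = np.random.default_rng(seed)
    noise = scenario.sigma * rng.standard_normal(
        (3, design.n_times, design.replicates)
    )
    return TimeCourseData(clean[:, :, None] + noise, design)


def generate_posterior_like_cloud(
    modes: Sequence[tuple],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` points from a Gaussian mixture in R^3.

    ``modes`` lists ``(center, covariance, weight)`` triples; weights must
    sum to one and covariances be positive definite.  Used as a stand-in for
    posterior samples when exercising the topological pipeline.
    """
    centers = [np.asarray(c, dtype=float) for c, _, _ in modes]
    covs = [np.atleast_2d(np.asarray(c, dtype=float)) for _, c, _ in modes]
    weights = np.array([w for _, _, w in modes], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    if np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative")
    for cov in covs:
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("covariances must be positive definite") from err
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    parts = [
        rng.multivariate_normal(c, cov, size=k, method="cholesky")
        for c, cov, k in zip(centers, covs, counts)
        if k > 0
    ]
    cloud = np.vstack(parts)
    return cloud[rng.permutation(len(cloud))]


def make_variant_suite(seed: int = 0, n: int = 2000) -> dict[str, np.ndarray]:
    """Five labelled point clouds standing in for per-variant posteriors.

    Clouds live in the (kappa1, kappa2, pi) prior box.  Wild-type and the
    three activating mutants share a common unimodal shape with mildly
    perturbed spreads and different locations (location does not affect the
    density barcode); SSDD carries a deliberately distinct density profile —
    its mass concentrates on a tight closed ridge (a ring in the
    (kappa1, kappa2) plane, the shape of a correlated non-identifiability),
    which creates a prominent persistent 1-cycle absent from the unimodal
    clouds — so it is the designated topological outlier of the suite.
    """
    rng = np.random.default_rng(seed)
    base_sd = np.array([0.06, 0.09, 0.04])
    clouds: dict[str, np.ndarray] = {}
    centers = {
        "wild-type": (0.5, 1.5, 0.30),
        "Y130C": (0.7, 1.2, 0.35),
        "F53S": (0.4, 1.8, 0.25),
        "E203K": (0.6, 1.0, 0.40),
    }
    for i, (label, center) in enumerate(centers.items()):
        jitter = 1.0 + 0.15 * rng.standard_normal(3)
        sd = base_sd * np.abs(jitter)
        cov = np.diag(sd**2)
        clouds[label] = generate_posterior_like_cloud(
            [(center, cov, 1.0)], n, seed=int(rng.integers(2**31))
        )
    # ring of 16 tight modes in the (kappa1, kappa2) plane
    n_modes = 16
    angles = 2.0 * np.pi * np.arange(n_modes) / n_modes
    ring_cov = np.diag([0.02**2, 0.02**2, 0.03**2])
    modes = [
        (
            (0.55 + 0.15 * np.cos(a), 1.4 + 0.15 * np.sin(a), 0.32),
            ring_cov,
            1.0 / n_modes,
        )
        for a in angles
    ]
    clouds["SSDD"] = generate_posterior_like_cloud(
        modes, n, seed=int(rng.integers(2**31))
    )
    return clouds
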