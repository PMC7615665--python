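"""Two-cohort synthetic data with a planted sparse partial-correlation network.

Latent scores are drawn from a zero-mean Gaussian whose precision matrix
carries the planted conditional-independence structure; each margin is then
pushed through a fixed strictly monotone warp onto its bounded, skewed scale.
Because the warps are monotone, rank-based statistics of the generated
columns coincide with those of the latent Gaussian, which gives every
downstream stage a ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._rand import substreams
from .data_io import CohortTable
from .schema import (
    AGE_COLUMNS,
    PRESET_N,
    SEX_COLUMN,
    VariableSchema,
    cohort_schema,
)

__all__ = [
    "PlantedNetwork",
    "CohortSimConfig",
    "default_planted_network",
    "simulate_cohort",
    "cohort_preset",
    "write_truth_sidecar",
]

SCENARIOS = ("paper_like", "dense", "null")

#: base age (years) per covariate block used when generating covariates
_BASE_AGES = {"age_trait": 9.0, "age_stressor_dysregulation": 9.5, "age_depression": 16.0}


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth precision matrix and its implied partial correlations."""

    precision: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        theta = np.asarray(self.precision, dtype=float)
        if theta.shape != (len(self.labels), len(self.labels)):
            raise ValueError("precision shape must match labels")
        if not np.allclose(theta, theta.T, atol=1e-12):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(theta).min() <= 1e-10:
            raise ValueError("precision must be positive definite")

    @property
    def partials(self) -> np.ndarray:
        """Implied partial-correlation matrix: rho_ij = -theta_ij/sqrt(theta_ii theta_jj)."""
        theta = self.precision
        d = np.sqrt(np.diag(theta))
        rho = -theta / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return rho

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def rho_of(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.partials[i, j])


# planted partial correlations for the paper_like scenario; every pair not
# listed here is exactly conditionally independent -- in particular all 21
# trait x depression pairs
_PAPER_LIKE_EDGES: dict[tuple[str, str], float] = {
    # trait--trait (11 of 21 nonzero)
    ("hyperactive_impulsive", "inattentive"): 0.35,
    ("general_cognitive", "learning"): 0.30,
    ("autistic", "hyperactive_impulsive"): 0.25,
    ("autistic", "pragmatic"): 0.25,
    ("speech_syntax", "pragmatic"): 0.30,
    ("autistic", "speech_syntax"): 0.15,
    ("inattentive", "general_cognitive"): -0.15,
    ("general_cognitive", "speech_syntax"): 0.15,
    ("speech_syntax", "learning"): 0.15,
    ("inattentive", "learning"): -0.15,
    ("hyperactive_impulsive", "pragmatic"): 0.15,
    # trait--stressor/dysregulation (6 of 21 nonzero)
    ("general_cognitive", "academic"): 0.30,
    ("learning", "academic"): 0.25,
    ("hyperactive_impulsive", "dysregulation"): 0.30,
    ("autistic", "peer_problems"): 0.25,
    ("inattentive", "academic"): -0.15,
    ("autistic", "dysregulation"): 0.15,
    # within stressor block
    ("dysregulation", "peer_problems"): 0.15,
    # stressor/dysregulation--depression
    ("dysregulation", "dep_childhood"): 0.22,
    ("peer_problems", "dep_childhood"): 0.18,
    ("academic", "dep_adolescence"): -0.15,
    # depression waves
    ("dep_childhood", "dep_adolescence"): 0.30,
    ("dep_adolescence", "dep_adulthood"): 0.25,
}


def default_planted_network(
    scenario: str, schema: VariableSchema | None = None
) -> PlantedNetwork:
    """Build the planted ground-truth network for a named scenario.

    ``paper_like`` has nonzero edges within traits, between traits and the
    stressor/dysregulation block, between that block and childhood
    depression, and along the depression waves -- with exactly zero direct
    trait-depression edges.  ``dense`` connects everything weakly; ``null``
    is the empty network (identity precision).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    schema = schema or cohort_schema("cohort_A")
    labels = schema.names
    p = len(labels)
    rho = np.zeros((p, p))
    if scenario == "paper_like":
        for (a, b), v in _PAPER_LIKE_EDGES.items():
            i, j = labels.index(a), labels.index(b)
            rho[i, j] = rho[j, i] = v
    elif scenario == "dense":
        rho[:] = 0.05
        np.fill_diagonal(rho, 0.0)
    theta = np.eye(p) - rho  # unit diagonal, so implied partials equal rho exactly
    return PlantedNetwork(precision=theta, labels=labels)


@dataclass(frozen=True)
class CohortSimConfig:
    """Knobs for one simulated cohort."""

    n_individuals: int
    seed: int
    missing_rate: float = 0.15
    mar_strength: float = 1.0
    all_trait_missing_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 50:
            raise ValueError("n_individuals must be >= 50")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.all_trait_missing_frac < 1:
            raise ValueError("all_trait_missing_frac must be in [0, 1)")


def skew_warp(u: np.ndarray, skew: float) -> np.ndarray:
    """Strictly monotone warp of uniforms: exponential-quantile skewing.

    ``skew > 0`` concentrates mass near the low end of the scale (right-skewed
    scores), ``skew < 0`` the opposite, ``skew = 0`` is the identity.
    """
    if abs(skew) < 1e-12:
        return u
    return np.expm1(skew * u) / np.expm1(skew)


def _mar_probabilities(
    eta: np.ndarray, target_rate: float
) -> np.ndarray:
    """Per-row missingness probabilities with the intercept solved so the
    realized mean equals the target rate exactly (in expectation)."""

    def mean_rate(b: float) -> float:
        return float(special.expit(b + eta).mean()) - target_rate

    b = optimize.brentq(mean_rate, -30.0, 30.0)
    return special.expit(b + eta)


def simulate_cohort(
    net: PlantedNetwork, schema: VariableSchema, cfg: CohortSimConfig
) -> CohortTable:
    """Simulate one cohort table from the planted network.

    Steps: latent Gaussian draws with covariance inverse to the planted
    precision; monotone marginal warps onto each variable's bounded scale;
    age/sex covariates; missing-at-random masking driven by sex and age
    only; optionally a fraction of rows with the whole trait block missing.
    """
    if tuple(net.labels) != schema.names:
        raise ValueError("network labels must match the schema")
    n, p = cfg.n_individuals, len(schema.names)
    rng_latent, rng_cov, rng_miss, rng_block = substreams(cfg.seed, 4)

    sigma = net.covariance
    d = np.sqrt(np.diag(sigma))
    sigma_corr = sigma / np.outer(d, d)  # unit-variance latents; partials unchanged
    z = rng_latent.multivariate_normal(
        np.zeros(p), sigma_corr, size=n, method="cholesky"
    )
    u = special.ndtr(z)

    values = pd.DataFrame(index=range(n), columns=list(schema.names), dtype=float)
    for j, var in enumerate(schema.variables):
        v = skew_warp(u[:, j], var.skew_target)
        values[var.name] = var.score_min + (var.score_max - var.score_min) * v

    sex = rng_cov.integers(0, 2, size=n).astype(float)
    covariates = pd.DataFrame({SEX_COLUMN: sex})
    for col in AGE_COLUMNS:
        covariates[col] = _BASE_AGES[col] + rng_cov.uniform(-0.5, 0.5, size=n)
    covariates = covariates[list(AGE_COLUMNS) + [SEX_COLUMN]]

    if cfg.missing_rate > 0:
        for var in schema.variables:
            age = covariates[schema.age_column(var.name)].to_numpy()
            z_age = (age - age.mean()) / age.std()
            eta = cfg.mar_strength * (0.8 * (sex - 0.5) + 0.6 * z_age)
            prob = _mar_probabilities(eta, cfg.missing_rate)
            masked = rng_miss.uniform(size=n) < prob
            values.loc[masked, var.name] = np.nan

    if cfg.all_trait_missing_frac > 0:
        k = int(round(cfg.all_trait_missing_frac * n))
        rows = rng_block.choice(n, size=k, replace=False)
        values.loc[rows, list(schema.trait_names)] = np.nan

    return CohortTable(
        values=values,
        covariates=covariates,
        schema=schema,
        cohort_id=schema.cohort_id,
        family_id=None,
    )


def cohort_preset(
    name: str,
    seed: int,
    scenario: str = "paper_like",
    n_individuals: int | None = None,
    **cfg_kwargs,
) -> tuple[CohortTable, PlantedNetwork]:
    """Named two-cohort presets mirroring the study sample sizes."""
    schema = cohort_schema(name)
    net = default_planted_network(scenario, schema)
    cfg = CohortSimConfig(
        n_individuals=n_individuals or PRESET_N[name], seed=seed, **cfg_kwargs
    )
    return simulate_cohort(net, schema, cfg), net


def write_truth_sidecar(net: PlantedNetwork, path) -> None:
    """JSON sidecar recording the planted partial correlations for harnesses."""
    rho = net.partials
    payload = {
        "labels": list(net.labels),
        "rho_true": [[round(float(x), 12) for x in row] for row in rho],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
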