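"""Edge-level inference: Bayes factors, classification, replication, summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import BetaDraws, PosteriorDraws, PriorSpec
from .schema import Pair

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeDecision",
    "ReplicationSummary",
    "NetworkSummary",
    "MediationEstimate",
    "savage_dickey_bf",
    "classify_edges",
    "replicate",
    "network_density",
    "adjacency_similarity",
    "mediation_index",
    "decisions_to_frame",
    "replication_to_frame",
]

ASSOCIATED = "associated"
INDEPENDENT = "independent"
AMBIGUOUS = "ambiguous"

REPLICATED_ASSOCIATION = "replicated_association"
REPLICATED_INDEPENDENCE = "replicated_independence"
DISCORDANT = "discordant"
UNREPLICATED = "unreplicated"

#: floor/ceiling keeping Bayes factors finite in reports
BF_FLOOR = 1e-4
BF_CEILING = 1e4

#: default mediation triples (exposure, mediator, outcome)
DEFAULT_MEDIATION_TRIPLES = (
    ("hyperactive_impulsive", "dysregulation", "dep_childhood"),
    ("autistic", "peer_problems", "dep_childhood"),
)


@dataclass(frozen=True)
class EdgeDecision:
    """Three-way verdict for one pair: associated / independent / ambiguous."""

    pair: Pair
    bf01: float
    bf10: float
    rho_mean: float
    rho_cri: tuple[float, float]
    status: str


@dataclass(frozen=True)
class ReplicationSummary:
    """Cross-cohort agreement for one pair."""

    pair: Pair
    status_a: str
    status_b: str
    sign_a: int
    sign_b: int
    replication: str


@dataclass(frozen=True)
class NetworkSummary:
    """Density of supported edges over a declared pair set."""

    pair_set: str
    n_supported: int
    n_possible: int
    density_pct: float


@dataclass(frozen=True)
class MediationEstimate:
    """Posterior of the indirect-effect index ab = beta(M<-X) * beta(Y<-M)."""

    triple: tuple[str, str, str]
    ab_mean: float
    ab_cri: tuple[float, float]
    draws: np.ndarray


def savage_dickey_bf(
    prior: PriorSpec, rho_draws: np.ndarray, method: str = "kde"
) -> tuple[float, float]:
    """Bayes factors for rho = 0 via the Savage-Dickey density ratio.

    ``bf01`` is the posterior density of rho at zero (Gaussian kernel
    estimate over the pooled draws, Silverman bandwidth; ``method='normal'``
    swaps in a normal approximation as a cross-check) divided by the
    analytic scaled-Beta prior density at zero.  ``bf10`` is the reciprocal.
    Values are clipped to [1e-4, 1e4].
    """
    rho_draws = np.asarray(rho_draws, dtype=float)
    if rho_draws.size < 1000:
        logger.warning("savage_dickey_bf: only %d draws", rho_draws.size)
    if method == "kde":
        if rho_draws.std() == 0:
            post0 = np.inf if rho_draws[0] == 0 else 0.0
        else:
            post0 = float(stats.gaussian_kde(rho_draws, bw_method="silverman")(0.0)[0])
    elif method == "normal":
        post0 = float(stats.norm.pdf(0.0, rho_draws.mean(), rho_draws.std(ddof=1)))
    else:
        raise ValueError(f"unknown method {method!r}; expected 'kde' or 'normal'")
    prior0 = prior.pdf_at_zero()
    if post0 <= 0 or not np.isfinite(post0):
        if post0 <= 0:
            logger.info("posterior density at 0 vanished; reporting the BF floor")
        bf01 = BF_FLOOR if post0 <= 0 else BF_CEILING
    else:
        bf01 = post0 / prior0
    bf01 = float(np.clip(bf01, BF_FLOOR, BF_CEILING))
    return bf01, 1.0 / bf01


def _status(bf01: float, bf10: float, threshold: float) -> str:
    if bf10 >= threshold:
        return ASSOCIATED
    if bf01 >= threshold:
        return INDEPENDENT
    return AMBIGUOUS


def classify_edges(
    draws: PosteriorDraws,
    prior: PriorSpec | None = None,
    threshold: float = 3.0,
    pairs: tuple[Pair, ...] | None = None,
    method: str = "kde",
) -> list[EdgeDecision]:
    """Per-pair Bayes factors, posterior mean, central 95% CrI, and status."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    prior = prior or draws.prior
    if pairs is None:
        labels = draws.labels
        pairs = tuple(
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        )
    out = []
    for a, b in pairs:
        d = draws.edge_draws(a, b)
        bf01, bf10 = savage_dickey_bf(prior, d, method=method)
        lo, hi = np.percentile(d, [2.5, 97.5])
        out.append(
            EdgeDecision(
                pair=(a, b),
                bf01=bf01,
                bf10=bf10,
                rho_mean=float(d.mean()),
                rho_cri=(float(lo), float(hi)),
                status=_status(bf01, bf10, threshold),
            )
        )
    return out


def replicate(
    decisions_a: list[EdgeDecision], decisions_b: list[EdgeDecision]
) -> list[ReplicationSummary]:
    """Cross-cohort replication status per pair.

    Association replicates only when both cohorts support it with matching
    sign; independence replicates when both cohorts support it; an
    associated-vs-independent split (or sign-conflicting associations) is
    discordant; anything involving an ambiguous verdict is unreplicated.
    """
    by_pair_b = {d.pair: d for d in decisions_b}
    if {d.pair for d in decisions_a} != set(by_pair_b):
        raise ValueError("cohorts carry different pair sets")
    out = []
    for da in decisions_a:
        db = by_pair_b[da.pair]
        sa = int(np.sign(da.rho_mean))
        sb = int(np.sign(db.rho_mean))
        if da.status == ASSOCIATED and db.status == ASSOCIATED:
            repl = REPLICATED_ASSOCIATION if sa == sb else DISCORDANT
        elif da.status == INDEPENDENT and db.status == INDEPENDENT:
            repl = REPLICATED_INDEPENDENCE
        elif {da.status, db.status} == {ASSOCIATED, INDEPENDENT}:
            repl = DISCORDANT
        else:
            repl = UNREPLICATED
        out.append(
            ReplicationSummary(
                pair=da.pair, status_a=da.status, status_b=db.status,
                sign_a=sa, sign_b=sb, replication=repl,
            )
        )
    return out


def _rounded_pct(k: int, n: int) -> float:
    """Percentage rounded to the nearest integer, keeping one decimal when the
    value sits near the .5 rounding boundary (mirroring mixed 52% / 9.5%
    reporting styles)."""
    pct = 100.0 * k / n
    frac = pct - np.floor(pct)
    if abs(frac - 0.5) < 0.05:
        return round(pct, 1)
    return float(round(pct))


def network_density(
    decisions, pair_set: tuple[Pair, ...], pair_set_name: str = "", supported_status: str | None = None
) -> NetworkSummary:
    """Supported edges over possible edges within a pair set, as a percentage.

    Accepts per-cohort decisions (counting ``associated``) or replication
    summaries (counting ``replicated_association``).
    """
    if not pair_set:
        raise ValueError("pair_set must be nonempty")
    wanted = {frozenset(p) for p in pair_set}
    n_supported = 0
    for d in decisions:
        if frozenset(d.pair) not in wanted:
            continue
        if isinstance(d, ReplicationSummary):
            hit = d.replication == (supported_status or REPLICATED_ASSOCIATION)
        else:
            hit = d.status == (supported_status or ASSOCIATED)
        n_supported += int(hit)
    n_possible = len(pair_set)
    return NetworkSummary(
        pair_set=pair_set_name,
        n_supported=n_supported,
        n_possible=n_possible,
        density_pct=_rounded_pct(n_supported, n_possible),
    )


def adjacency_similarity(
    rho_a: np.ndarray,
    rho_b: np.ndarray,
    labels: tuple[str, ...],
    pair_set: tuple[Pair, ...],
) -> float:
    """Pearson r of the two cohorts' posterior-mean edge weights over a pair set."""
    if len(pair_set) < 3:
        raise ValueError("need at least 3 pairs to correlate adjacency matrices")
    idx = {name: i for i, name in enumerate(labels)}
    va = np.array([rho_a[idx[a], idx[b]] for a, b in pair_set])
    vb = np.array([rho_b[idx[a], idx[b]] for a, b in pair_set])
    return float(stats.pearsonr(va, vb).statistic)


def mediation_index(
    beta: BetaDraws, x: str, m: str, y: str
) -> MediationEstimate:
    """Index of mediation ab = beta(M<-X) * beta(Y<-M), per posterior draw."""
    if len({x, m, y}) != 3:
        raise ValueError("x, m, y must be distinct nodes")
    ab = beta.coef_draws(m, x) * beta.coef_draws(y, m)
    lo, hi = np.percentile(ab, [2.5, 97.5])
    return MediationEstimate(
        triple=(x, m, y), ab_mean=float(ab.mean()), ab_cri=(float(lo), float(hi)), draws=ab
    )


def decisions_to_frame(decisions: list[EdgeDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "var_a": [d.pair[0] for d in decisions],
            "var_b": [d.pair[1] for d in decisions],
            "bf01": [d.bf01 for d in decisions],
            "bf10": [d.bf10 for d in decisions],
            "rho_mean": [d.rho_mean for d in decisions],
            "cri_low": [d.rho_cri[0] for d in decisions],
            "cri_high": [d.rho_cri[1] for d in decisions],
            "status": [d.status for d in decisions],
        }
    )


def replication_to_frame(summaries: list[ReplicationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "var_a": [r.pair[0] for r in summaries],
            "var_b": [r.pair[1] for r in summaries],
            "status_a": [r.status_a for r in summaries],
            "status_b": [r.status_b for r in summaries],
            "sign_a": [r.sign_a for r in summaries],
            "sign_b": [r.sign_b for r in summaries],
            "replication": [r.replication for r in summaries],
        }
    )
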