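"""End-to-end study pipeline: per-cohort estimation, replication, reporting."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import __version__
from ._rand import substream_seeds
from .community import CommunityResult, spinglass_consensus
from .data_io import CohortTable, apply_exclusions, completers_filter, load_cohort
from .edges import (
    ASSOCIATED,
    DEFAULT_MEDIATION_TRIPLES,
    REPLICATED_ASSOCIATION,
    EdgeDecision,
    MediationEstimate,
    NetworkSummary,
    ReplicationSummary,
    adjacency_similarity,
    classify_edges,
    decisions_to_frame,
    mediation_index,
    network_density,
    replicate,
    replication_to_frame,
)
from .ggm import (
    NodePredictability,
    PosteriorDraws,
    PriorSpec,
    bayesian_r2,
    beta_from_draws,
    convergence_report,
    pool_imputations,
    sample_posterior,
)
from .preprocess import (
    ImputationConfig,
    impute,
    npn_transform,
    residualize,
    write_zero_order_tsv,
    zero_order_screen,
)
from .report import (
    FigureSpec,
    average_absolute_adjacency,
    compute_layout,
    plot_network,
    triangular_matrix,
)
from .schema import cohort_schema, pair_sets
from .synthetic import cohort_preset

logger = logging.getLogger(__name__)

SENSITIVITY_CONDITIONS = ("prior_0.1", "prior_0.4", "completers_70", "residualize_age_sex")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one full two-cohort run."""

    cohort_a_path: str | None = None  # None -> synthetic preset
    cohort_b_path: str | None = None
    scenario: str = "paper_like"
    n_a: int | None = None
    n_b: int | None = None
    missing_rate: float = 0.1
    mar_strength: float = 1.0
    m: int = 50
    impute_max_iter: int = 5
    prior_scale: float = 0.2
    n_draws: int = 10_000
    burn_in: int = 500
    chains: int = 2
    bf_threshold: float = 3.0
    one_per_family: bool = False
    completers_min_frac: float | None = None
    residualize_age_sex: bool = False
    n_spinglass: int = 5000
    sensitivity: tuple[str, ...] = ()
    seed: int = 0
    outdir: str = "ndnet_run"
    make_figures: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload.get("sensitivity"):
            payload["sensitivity"] = tuple(payload["sensitivity"])
        return cls(**payload)

    def small(self) -> "RunConfig":
        """Desk-scale variant for smoke tests."""
        return replace(
            self, n_a=500, n_b=1000, m=2, n_draws=1200, burn_in=200,
            n_spinglass=50,
        )


@dataclass
class CohortResult:
    """All per-cohort artifacts of the primary pipeline."""

    cohort_id: str
    n_included: int
    decisions_traits: list[EdgeDecision]
    decisions_full: list[EdgeDecision]
    draws_traits: PosteriorDraws
    draws_full: PosteriorDraws
    zero_order: list
    mediation: list[MediationEstimate]
    predictability: list[NodePredictability]
    community: CommunityResult
    rhat_max: float


@dataclass
class RunResult:
    config: RunConfig
    cohorts: dict[str, CohortResult]
    replication_full: list[ReplicationSummary]
    replication_traits: list[ReplicationSummary]
    densities: dict[str, NetworkSummary]
    adjacency_r: dict[str, float]
    manifest: dict


def _prepare_cohort(name: str, path: str | None, cfg: RunConfig, seed: int) -> CohortTable:
    if path is not None:
        table = load_cohort(path, cohort_schema(name))
    else:
        n = cfg.n_a if name == "cohort_A" else cfg.n_b
        table, _ = cohort_preset(
            name,
            seed=seed,
            scenario=cfg.scenario,
            n_individuals=n,
            missing_rate=cfg.missing_rate,
            mar_strength=cfg.mar_strength,
        )
    table = apply_exclusions(table, one_per_family=cfg.one_per_family, seed=seed)
    if cfg.completers_min_frac is not None:
        table = completers_filter(table, cfg.completers_min_frac)
    return table


def _analyze_cohort(table: CohortTable, cfg: RunConfig, seed: int) -> CohortResult:
    schema = table.schema
    prior = PriorSpec(cfg.prior_scale)
    seeds = substream_seeds(seed, 4 + cfg.m)
    imp = impute(table, ImputationConfig(m=cfg.m, max_iter=cfg.impute_max_iter, seed=seeds[0]))

    age_of = {v.name: schema.age_column(v.name) for v in schema.variables}
    transformed = []
    for d in imp.datasets:
        t = npn_transform(d)
        if cfg.residualize_age_sex:
            cov_ok = table.covariates.notna().all(axis=1).to_numpy()
            t = residualize(t.loc[cov_ok].reset_index(drop=True),
                            table.covariates.loc[cov_ok].reset_index(drop=True), age_of)
            t = npn_transform(t)  # restore exact unit-SD standardization
        transformed.append(t)

    draws_per = max(cfg.n_draws // cfg.m, 200)
    trait_cols = list(schema.trait_names)
    per_traits, per_full = [], []
    for k, t in enumerate(transformed):
        per_traits.append(
            sample_posterior(t[trait_cols], prior, n_draws=draws_per,
                             seed=seeds[4 + k], burn_in=cfg.burn_in, chains=cfg.chains)
        )
        per_full.append(
            sample_posterior(t, prior, n_draws=draws_per,
                             seed=seeds[4 + k] + 1, burn_in=cfg.burn_in, chains=cfg.chains)
        )
    draws_traits = pool_imputations(per_traits)
    draws_full = pool_imputations(per_full)

    decisions_traits = classify_edges(draws_traits, prior, threshold=cfg.bf_threshold)
    decisions_full = classify_edges(draws_full, prior, threshold=cfg.bf_threshold)

    ps = pair_sets(schema)
    zero = zero_order_screen(imp, ps.trait_depression, alpha=0.05)

    betas = beta_from_draws(draws_full)
    mediation = [mediation_index(betas, *triple) for triple in DEFAULT_MEDIATION_TRIPLES]
    predictability = [bayesian_r2(draws_full, node) for node in schema.depression_names]

    supported = [
        (d.pair[0], d.pair[1], d.rho_mean)
        for d in decisions_full
        if d.status == ASSOCIATED
    ]
    community = spinglass_consensus(
        schema.names, supported, n_iter=cfg.n_spinglass, seed=seeds[1]
    )
    conv = convergence_report(draws_full)
    return CohortResult(
        cohort_id=table.cohort_id,
        n_included=table.n,
        decisions_traits=decisions_traits,
        decisions_full=decisions_full,
        draws_traits=draws_traits,
        draws_full=draws_full,
        zero_order=zero,
        mediation=mediation,
        predictability=predictability,
        community=community,
        rhat_max=max(conv.rhat.values()),
    )


def run_primary(cfg: RunConfig) -> RunResult:
    """The full two-cohort pipeline; writes all outputs under ``cfg.outdir``."""
    os.makedirs(cfg.outdir, exist_ok=True)
    timings: dict[str, float] = {}
    cohort_seeds = dict(zip(("cohort_A", "cohort_B"), substream_seeds(cfg.seed, 2)))

    cohorts: dict[str, CohortResult] = {}
    for name, path in (("cohort_A", cfg.cohort_a_path), ("cohort_B", cfg.cohort_b_path)):
        t0 = time.perf_counter()
        try:
            table = _prepare_cohort(name, path, cfg, cohort_seeds[name])
            cohorts[name] = _analyze_cohort(table, cfg, cohort_seeds[name])
        except Exception:
            logger.exception("pipeline failed during cohort stage %r", name)
            raise
        timings[f"cohort:{name}"] = time.perf_counter() - t0
        logger.info("finished %s in %.1fs", name, timings[f"cohort:{name}"])

    a, b = cohorts["cohort_A"], cohorts["cohort_B"]
    replication_full = replicate(a.decisions_full, b.decisions_full)
    replication_traits = replicate(a.decisions_traits, b.decisions_traits)

    ps = pair_sets()
    densities = {
        "trait_trait": network_density(replication_traits, ps.trait_trait, "trait_trait"),
        "trait_trait_independent": network_density(
            replication_traits, ps.trait_trait, "trait_trait",
            supported_status="replicated_independence"),
        "trait_stressor": network_density(replication_full, ps.trait_stressor, "trait_stressor"),
        "trait_depression": network_density(
            replication_full, ps.trait_depression, "trait_depression"),
        "trait_depression_independent": network_density(
            replication_full, ps.trait_depression, "trait_depression",
            supported_status="replicated_independence"),
        "stressor_depression": network_density(
            replication_full, ps.stressor_depression, "stressor_depression"),
    }

    rho_a, rho_b = a.draws_full.rho_mean(), b.draws_full.rho_mean()
    labels = a.draws_full.labels
    repl_pairs = tuple(
        r.pair for r in replication_full if r.replication == REPLICATED_ASSOCIATION
    )
    adjacency_r = {"all_pairs": adjacency_similarity(rho_a, rho_b, labels, ps.all_pairs)}
    if len(repl_pairs) >= 3:
        adjacency_r["replicated"] = adjacency_similarity(rho_a, rho_b, labels, repl_pairs)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "cohort_seeds": cohort_seeds,
        "n_included": {k: c.n_included for k, c in cohorts.items()},
        "rhat_max": {k: c.rhat_max for k, c in cohorts.items()},
        "timings_s": timings,
    }
    result = RunResult(
        config=cfg,
        cohorts=cohorts,
        replication_full=replication_full,
        replication_traits=replication_traits,
        densities=densities,
        adjacency_r=adjacency_r,
        manifest=manifest,
    )
    _write_outputs(result)
    return result


def _write_outputs(res: RunResult) -> None:
    out = res.config.outdir
    for name, c in res.cohorts.items():
        decisions_to_frame(c.decisions_full).to_csv(
            os.path.join(out, f"edges_full_{name}.tsv"), sep="\t", index=False)
        decisions_to_frame(c.decisions_traits).to_csv(
            os.path.join(out, f"edges_traits_{name}.tsv"), sep="\t", index=False)
        write_zero_order_tsv(c.zero_order, os.path.join(out, f"zero_order_{name}.tsv"))
        c.community.to_json(os.path.join(out, f"community_{name}.json"))
        c.community.co_membership_csv(os.path.join(out, f"co_membership_{name}.csv"))
        np.savetxt(os.path.join(out, f"rho_mean_{name}.csv"),
                   c.draws_full.rho_mean(), delimiter=",",
                   header=",".join(c.draws_full.labels), comments="")
    replication_to_frame(res.replication_full).to_csv(
        os.path.join(out, "replication_full.tsv"), sep="\t", index=False)
    replication_to_frame(res.replication_traits).to_csv(
        os.path.join(out, "replication_traits.tsv"), sep="\t", index=False)

    summary = {
        "densities": {k: asdict(v) for k, v in res.densities.items()},
        "adjacency_similarity_r": res.adjacency_r,
        "mediation": {
            name: [
                {"triple": m.triple, "ab_mean": m.ab_mean, "ab_cri": m.ab_cri}
                for m in c.mediation
            ]
            for name, c in res.cohorts.items()
        },
        "bayesian_r2": {
            name: [asdict(p) for p in c.predictability] for name, c in res.cohorts.items()
        },
        "community_modal_frequency": {
            name: c.community.modal_frequency for name, c in res.cohorts.items()
        },
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(res.manifest, fh, indent=1)

    if res.config.make_figures:
        a, b = res.cohorts["cohort_A"], res.cohorts["cohort_B"]
        labels = a.draws_full.labels
        schema = cohort_schema("cohort_A")
        block_of = {v.name: v.block for v in schema.variables}
        spec = FigureSpec()
        avg = average_absolute_adjacency(a.draws_full.rho_mean(), b.draws_full.rho_mean())
        layout = compute_layout(labels, avg, spec.layout_seed)
        for name, c in res.cohorts.items():
            plot_network(
                c.decisions_full, labels, spec,
                os.path.join(out, f"network_{name}.png"),
                layout=layout, block_of=block_of, title=name,
            )
        triangular_matrix(
            res.replication_full, a.decisions_full, b.decisions_full, labels,
            tsv_path=os.path.join(out, "triangular_matrix.tsv"),
            image_path=os.path.join(out, "triangular_matrix.png"),
        )


def run_sensitivity(cfg: RunConfig, primary: RunResult | None = None) -> dict[str, RunResult]:
    """One re-run per sensitivity condition plus a per-pair comparison table.

    Every condition reuses the primary configuration and seed, varying only
    its own element.
    """
    import pandas as pd

    conditions = cfg.sensitivity or SENSITIVITY_CONDITIONS
    unknown = set(conditions) - set(SENSITIVITY_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown sensitivity condition(s) {sorted(unknown)}")
    if primary is None:
        primary = run_primary(cfg)
    results: dict[str, RunResult] = {}
    for cond in conditions:
        sub = replace(cfg, outdir=os.path.join(cfg.outdir, f"sensitivity_{cond}"),
                      sensitivity=())
        if cond == "prior_0.1":
            sub = replace(sub, prior_scale=0.1)
        elif cond == "prior_0.4":
            sub = replace(sub, prior_scale=0.4)
        elif cond == "completers_70":
            sub = replace(sub, completers_min_frac=0.70)
        elif cond == "residualize_age_sex":
            sub = replace(sub, residualize_age_sex=True)
        results[cond] = run_primary(sub)

    primary_status = {r.pair: r.replication for r in primary.replication_full}
    rows = []
    for cond, res in results.items():
        for r in res.replication_full:
            rows.append(
                {
                    "condition": cond,
                    "var_a": r.pair[0],
                    "var_b": r.pair[1],
                    "replication": r.replication,
                    "primary": primary_status[r.pair],
                    "changed": r.replication != primary_status[r.pair],
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(cfg.outdir, "sensitivity_comparison.tsv"),
                 sep="\t", index=False)
    return results
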