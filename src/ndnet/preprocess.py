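"""Multiple imputation, nonparanormal transform, residualization, zero-order screen."""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from ._rand import substream_seeds
from .data_io import CohortTable
from .schema import Pair

__all__ = [
    "ImputationConfig",
    "ImputedSet",
    "ZeroOrderResult",
    "impute",
    "npn_shrunken",
    "npn_transform",
    "residualize",
    "zero_order_screen",
    "write_zero_order_tsv",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations configuration; m completed datasets are produced."""

    m: int = 50
    max_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class ImputedSet:
    """m complete copies of the scored variables, observed cells untouched."""

    datasets: list[pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def write_csvs(self, directory) -> list[str]:
        os.makedirs(directory, exist_ok=True)
        paths = []
        for i, d in enumerate(self.datasets):
            path = os.path.join(directory, f"imputed_{i:03d}.csv")
            d.to_csv(path, index=False)
            paths.append(path)
        return paths


def impute(table: CohortTable, cfg: ImputationConfig) -> ImputedSet:
    """Chained-equation imputation producing ``cfg.m`` completed datasets.

    Each variable is imputed conditional on all other scored variables plus
    the age and sex covariates, using Bayesian linear regression draws
    (``sample_posterior=True``), so the m completions differ in their
    imputed cells while observed cells are identical across datasets.
    """
    if (table.observed_trait_counts() == 0).any():
        raise ValueError(
            "table contains rows with all traits missing; run apply_exclusions first"
        )
    empty = [c for c in table.values.columns if table.values[c].notna().sum() == 0]
    if empty:
        raise ValueError(f"column(s) with zero observed values: {empty}")

    var_cols = list(table.values.columns)
    design = pd.concat([table.values, table.covariates], axis=1)
    observed = table.values.notna().to_numpy()

    datasets: list[pd.DataFrame] = []
    if not design.isna().to_numpy().any():
        datasets = [table.values.copy() for _ in range(cfg.m)]
    else:
        for rs in substream_seeds(cfg.seed, cfg.m):
            imp = IterativeImputer(
                max_iter=cfg.max_iter,
                sample_posterior=True,
                random_state=rs,
                keep_empty_features=True,
            )
            full = imp.fit_transform(design.to_numpy())
            comp = pd.DataFrame(full[:, : len(var_cols)], columns=var_cols)
            # guard: imputation must never alter observed cells
            comp_vals = comp.to_numpy()
            comp_vals[observed] = table.values.to_numpy()[observed]
            datasets.append(pd.DataFrame(comp_vals, columns=var_cols))
    return ImputedSet(
        datasets=datasets,
        provenance={"cohort_id": table.cohort_id, "m": cfg.m, "seed": cfg.seed,
                    "max_iter": cfg.max_iter},
    )


def npn_shrunken(column: np.ndarray) -> np.ndarray:
    """Nonparanormal transform of one complete column via the shrunken ECDF.

    Ranks (average for ties) are shrunk to u_i = rank_i / (n + 1), mapped
    through the standard-normal quantile function, then mean-centered and
    rescaled to unit sample standard deviation.  The map is strictly rank
    preserving, so any strictly increasing transform of the input yields an
    identical output.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("column must be 1-D with n >= 2")
    if np.isnan(x).any():
        raise ValueError("column contains missing values; transform runs per imputed dataset")
    if np.ptp(x) == 0:
        raise ValueError("constant column: ranks are degenerate")
    u = stats.rankdata(x, method="average") / (x.size + 1)
    z = ndtri(u)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate column after rank transform")
    return z / sd


def npn_transform(dataset: pd.DataFrame) -> pd.DataFrame:
    """Apply the shrunken-ECDF nonparanormal transform column-wise."""
    return pd.DataFrame(
        {c: npn_shrunken(dataset[c].to_numpy()) for c in dataset.columns},
        columns=dataset.columns,
    )


def residualize(
    dataset: pd.DataFrame,
    covariates: pd.DataFrame,
    age_column_of: dict[str, str],
) -> pd.DataFrame:
    """Replace each column by re-standardized OLS residuals on age and sex.

    ``age_column_of`` maps each variable name to the covariate column that
    holds its block-matched age at collection.
    """
    out = {}
    sex = covariates["sex"].to_numpy(dtype=float)
    for name in dataset.columns:
        age = covariates[age_column_of[name]].to_numpy(dtype=float)
        design = np.column_stack([np.ones_like(age), age, sex])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"collinear covariates when residualizing {name!r}")
        y = dataset[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sd = resid.std(ddof=1)
        if sd < 1e-10:
            raise ValueError(f"residuals of {name!r} are constant")
        out[name] = (resid - resid.mean()) / sd
    return pd.DataFrame(out, columns=dataset.columns)


@dataclass(frozen=True)
class ZeroOrderResult:
    """Pooled unadjusted Pearson correlation for one variable pair."""

    pair: Pair
    r_pooled: float
    p_pooled: float
    significant: bool
    threshold: float


def zero_order_screen(
    imp: ImputedSet, pairs: tuple[Pair, ...], alpha: float = 0.05
) -> list[ZeroOrderResult]:
    """Pearson correlations pooled across imputations on the Fisher-z scale.

    Per-dataset correlations are Fisher-transformed, combined with Rubin's
    rules (within-variance 1/(n-3), between-variance across the m datasets),
    and tested two-sided; significance uses the Bonferroni threshold
    alpha / len(pairs).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = imp.m
    n = len(imp.datasets[0])
    threshold = alpha / len(pairs)
    out: list[ZeroOrderResult] = []
    for a, b in pairs:
        zs = np.array(
            [np.arctanh(stats.pearsonr(d[a], d[b]).statistic) for d in imp.datasets]
        )
        qbar = zs.mean()
        w = 1.0 / (n - 3)
        if m > 1:
            bvar = zs.var(ddof=1)
            total = w + (1 + 1 / m) * bvar
            if bvar > 0:
                df = (m - 1) * (1 + w / ((1 + 1 / m) * bvar)) ** 2
                p = 2 * stats.t.sf(abs(qbar) / math.sqrt(total), df)
            else:
                p = 2 * stats.norm.sf(abs(qbar) / math.sqrt(total))
        else:
            total = w
            p = 2 * stats.norm.sf(abs(qbar) / math.sqrt(total))
        out.append(
            ZeroOrderResult(
                pair=(a, b),
                r_pooled=float(np.tanh(qbar)),
                p_pooled=float(p),
                significant=bool(p < threshold),
                threshold=threshold,
            )
        )
    return out


def write_zero_order_tsv(results: list[ZeroOrderResult], path) -> None:
    rows = [
        {
            "var_a": r.pair[0],
            "var_b": r.pair[1],
            "r": r.r_pooled,
            "p": r.p_pooled,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
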