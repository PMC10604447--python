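"""Seasonal community statistics for vOTU abundance/activity matrices.

Implements the downstream statistics of the virome analysis: seasonal
occupancy sets, Bray–Curtis dissimilarity and PERMANOVA on a distance
matrix, per-vOTU differential activity across months (one-way ANOVA with
eta-squared effect size, Storey q-values, Tukey–Kramer post hoc pairs), and
z-score temporal profiles grouped by host ecological strategy.

Matrices are pandas DataFrames with vOTUs as rows and samples as columns;
sample metadata is a DataFrame indexed by sample id with at least ``month``
and ``season`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PermanovaResult",
    "DifferentialActivityResult",
    "ZScoreProfile",
    "season_occupancy",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "storey_qvalues",
    "differential_activity",
    "zscore_profiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


@dataclass
class DifferentialActivityResult:
    votu_id: str
    f_statistic: float
    eta_squared: float
    p_value: float
    q_value: float = np.nan
    seasonal: bool = False
    significant_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    peak_month: str | None = None
    host_strategy: str = "none"


@dataclass
class ZScoreProfile:
    votu_id: str
    month_means: pd.Series
    z_scores: pd.Series
    strategy: str = "unassigned"


def season_occupancy(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-vOTU core / season-specific occupancy from a presence pattern.

    Presence is RPKM > 0. A vOTU is *core* when present in ≥1 sample of every
    season, and *season-specific* when present only in samples of a single
    season (recorded in ``specific_season``).
    """
    seasons = meta.loc[matrix.columns, "season"]
    season_levels = sorted(seasons.unique())
    for s in season_levels:
        if (seasons == s).sum() == 0:
            raise ValueError(f"season {s!r} has no samples")
    present = matrix.gt(0)
    rows = []
    for votu, row in present.iterrows():
        seasons_present = sorted(seasons[row[row].index].unique())
        rows.append(
            {
                "votu_id": votu,
                "n_seasons_present": len(seasons_present),
                "core": len(seasons_present) == len(season_levels),
                "specific_season": seasons_present[0] if len(seasons_present) == 1 else "",
            }
        )
    return pd.DataFrame(rows).set_index("votu_id")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) for non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Bray–Curtis matrix from a vOTU × sample table."""
    samples = matrix.columns
    n = len(samples)
    out = np.zeros((n, n))
    values = matrix.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(values[:, i], values[:, j])
    return pd.DataFrame(out, index=samples, columns=samples)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame | np.ndarray,
    grouping: Sequence,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F is computed from among/within sums of squared distances
    (Anderson's formulation); the p-value counts permuted pseudo-F values at
    least as large as the observed one, with the +1 correction. Label
    permutations are unrestricted and driven by ``seed``.
    """
    d = np.asarray(dist, dtype=float)
    _, codes = np.unique(np.asarray(grouping), return_inverse=True)
    groups, counts = np.unique(codes, return_counts=True)
    n = d.shape[0]
    if len(groups) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    if len(codes) != n:
        raise ValueError("grouping length must match distance matrix size")
    d2 = d**2
    ss_total, ss_within = _permanova_ss(d2, codes, groups)
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    with np.errstate(divide="ignore"):  # zero within-group SS -> F = inf
        f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # vectorized permutations: indicator tensor (perm, group, sample)
    perms = np.empty((n_permutations, n), dtype=np.int64)
    for i in range(n_permutations):
        perms[i] = rng.permutation(codes)
    indicators = np.stack([(perms == g).astype(float) for g in groups], axis=1)
    within_pergroup = np.einsum("pgi,ij,pgj->pg", indicators, d2, indicators) / 2.0
    ss_within_perm = (within_pergroup / counts[None, :]).sum(axis=1)
    ss_among_perm = ss_total - ss_within_perm
    with np.errstate(divide="ignore"):
        f_perm = (ss_among_perm / df_among) / (ss_within_perm / df_within)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_permutations)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p_value=float(p),
                           n_permutations=n_permutations)


def storey_qvalues(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
    pi0: float | None = None,
    smoother: bool = False,
) -> np.ndarray:
    """Storey q-values with a plateau (or spline-smoother) π0 estimate.

    By default π0 is the plateau estimate at λ = 0.5:
    ``#{p > λ} / (m (1 − λ))`` capped at 1. With ``smoother=True``, π0 is a
    cubic-spline fit of the plateau estimates over ``lambda_grid`` evaluated
    at the largest λ. Forcing ``pi0=1`` reduces the procedure to
    Benjamini–Hochberg exactly. q-values are monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if smoother:
            grid = np.asarray(lambda_grid if lambda_grid is not None
                              else np.arange(0.05, 0.96, 0.05))
            estimates = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
            from scipy.interpolate import CubicSpline

            pi0 = float(CubicSpline(grid, estimates)(grid[-1]))
        else:
            lam = 0.5 if lambda_grid is None else float(lambda_grid[0])
            pi0 = float((p > lam).sum() / (m * (1 - lam)))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _eta_squared(groups: list[np.ndarray]) -> float:
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_total = float(((all_values - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    return ss_between / ss_total if ss_total > 0 else 0.0


def differential_activity(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    effect_min: float = 0.3,
    q_max: float = 0.05,
    log_transform: bool = False,
    host_strategies: Mapping[str, str] | None = None,
    tukey_alpha: float = 0.05,
) -> list[DifferentialActivityResult]:
    """Differential activity of vOTUs across months.

    Per vOTU: one-way ANOVA of (metatranscriptome) RPKM across months with
    eta-squared effect size; Storey q-values across all tested vOTUs; a vOTU
    is flagged *seasonal* when q ≤ ``q_max`` and eta² > ``effect_min``.
    Tukey–Kramer pairwise month comparisons (Kramer's unequal-n correction,
    as implemented by statsmodels) are run for vOTUs passing the q cutoff;
    ``peak_month`` is the month with the highest z-scored mean. vOTUs with
    zero variance across samples are excluded and logged.
    """
    months = meta.loc[matrix.columns, "month"]
    month_levels = list(dict.fromkeys(months))
    if len(month_levels) < 2:
        raise ValueError("need at least two months")
    values = np.log10(matrix + 1) if log_transform else matrix

    results: list[DifferentialActivityResult] = []
    for votu, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            logger.info("vOTU %s has zero variance; excluded from ANOVA", votu)
            continue
        groups = [x[(months == mth).to_numpy()] for mth in month_levels]
        if any(len(g) < 2 for g in groups):
            raise ValueError("every month needs >=2 samples")
        f, p = sps.f_oneway(*groups)
        results.append(
            DifferentialActivityResult(
                votu_id=str(votu),
                f_statistic=float(f),
                eta_squared=_eta_squared(groups),
                p_value=float(p),
            )
        )
    if not results:
        return results

    q = storey_qvalues([r.p_value for r in results])
    month_codes = months.to_numpy()
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.seasonal = (r.q_value <= q_max) and (r.eta_squared > effect_min)
        if r.q_value <= q_max:
            x = values.loc[r.votu_id].to_numpy(dtype=float)
            tukey = pairwise_tukeyhsd(x, month_codes, alpha=tukey_alpha)
            pairs = list(combinations(tukey.groupsunique, 2))
            for (g1, g2), reject, p_adj in zip(pairs, tukey.reject, tukey.pvalues):
                if reject:
                    r.significant_pairs.append((str(g1), str(g2), float(p_adj)))
        if r.seasonal:
            means = pd.Series(
                {mth: values.loc[r.votu_id][(months == mth).to_numpy()].mean()
                 for mth in month_levels}
            )
            sd = means.std(ddof=1)
            z = (means - means.mean()) / sd if sd > 0 else means * 0.0
            r.peak_month = str(z.idxmax())
            if host_strategies is not None:
                r.host_strategy = host_strategies.get(r.votu_id, "none")
    return results


def zscore_profiles(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    strategies: Mapping[str, str] | None = None,
) -> dict[str, list[ZScoreProfile]]:
    """Per-vOTU monthly mean RPKM transformed to z-scores, grouped by strategy.

    z = (month mean − grand mean of month means) / sd of month means; when
    the sd is 0 all z-scores are 0. vOTUs without a host strategy go to the
    ``unassigned`` group.
    """
    months = meta.loc[matrix.columns, "month"]
    month_levels = list(dict.fromkeys(months))
    grouped: dict[str, list[ZScoreProfile]] = {}
    for votu, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        means = pd.Series(
            {mth: x[(months == mth).to_numpy()].mean() for mth in month_levels}
        )
        sd = means.std(ddof=1)
        z = (means - means.mean()) / sd if sd > 0 else means * 0.0
        strategy = (strategies or {}).get(str(votu), "unassigned")
        if strategy in ("none", ""):
            strategy = "unassigned"
        grouped.setdefault(strategy, []).append(
            ZScoreProfile(votu_id=str(votu), month_means=means, z_scores=z, strategy=strategy)
        )
    return grouped
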