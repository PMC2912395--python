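"""Permutation tests of class-membership association with covariates.

Hard class labels (argmax membership) are compared against one covariate at
a time: continuous covariates use the midrank Kruskal-Wallis statistic with
tie correction, categorical covariates the Pearson chi-square statistic of
the class x level contingency table.  The permutation p-value uses the
add-one convention p = (1 + #{permuted >= observed}) / (B + 1), so p is
never exactly zero and remains a valid p-value.  Complete cases only: a
sample missing the covariate is excluded from that covariate's test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermTestResult",
    "kruskal_wallis_stat",
    "chi_square_stat",
    "permutation_test",
    "association_table",
]


@dataclass
class PermTestResult:
    covariate: str
    statistic_kind: str          # "kruskal-wallis" | "chi-square"
    observed: float
    p_value: float
    n_permutations: int
    n_used: int
    asymptotic_p: float = np.nan  # chi-square reference; diagnostic only


def kruskal_wallis_stat(groups, x) -> float:
    """Midrank Kruskal-Wallis statistic with tie correction.

    ``groups`` are class labels, ``x`` continuous values.  All-identical
    values give 0 by convention; fewer than 2 non-empty groups is an error.
    """
    groups = np.asarray(groups)
    x = np.asarray(x, dtype=float)
    samples = [x[groups == g] for g in np.unique(groups)]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if np.all(x == x[0]):
        return 0.0
    try:
        stat, _ = stats.kruskal(*samples)
    except ValueError:  # scipy rejects all-identical input
        return 0.0
    return float(stat)


def chi_square_stat(groups, x) -> float:
    """Pearson chi-square statistic sum (O-E)^2/E of the groups x levels
    contingency table; levels with a zero margin are dropped by
    construction.  A margin with fewer than 2 levels is degenerate."""
    table = pd.crosstab(pd.Series(np.asarray(groups)), pd.Series(np.asarray(x)))
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate margin: need >= 2 levels on each side")
    stat = stats.chi2_contingency(table.to_numpy(), correction=False).statistic
    return float(stat)


def _kw_null_stats(g_codes, ranks, tie_corr, B, rng) -> np.ndarray:
    """KW statistics for B permutations of the (fixed multiset of) midranks.

    Permuting the covariate is equivalent to permuting its midranks, so the
    tie correction and group sizes are permutation-invariant and computed
    once.  Identical in value to ``kruskal_wallis_stat``."""
    n = len(ranks)
    n_groups = g_codes.max() + 1
    sizes = np.bincount(g_codes, minlength=n_groups).astype(float)
    out = np.empty(B)
    for b in range(B):
        r = rng.permutation(ranks)
        sums = np.bincount(g_codes, weights=r, minlength=n_groups)
        h = 12.0 / (n * (n + 1)) * (sums ** 2 / sizes).sum() - 3.0 * (n + 1)
        out[b] = h / tie_corr if tie_corr > 0 else 0.0
    return out


def _chi2_null_stats(g_codes, v_codes, n_groups, n_levels, B, rng) -> np.ndarray:
    """Chi-square statistics for B permutations of the covariate codes.

    Both margins are fixed under permutation, so the expected table is
    precomputed; only the observed counts are re-tallied.  Identical in
    value to ``chi_square_stat``."""
    n = len(g_codes)
    row = np.bincount(g_codes, minlength=n_groups).astype(float)
    col = np.bincount(v_codes, minlength=n_levels).astype(float)
    E = np.outer(row, col).ravel() / n
    ok = E > 0
    out = np.empty(B)
    for b in range(B):
        perm = rng.permutation(v_codes)
        O = np.bincount(g_codes * n_levels + perm, minlength=n_groups * n_levels)
        out[b] = (((O[ok] - E[ok]) ** 2) / E[ok]).sum()
    return out


def permutation_test(
    classes,
    covariate,
    B: int = 10_000,
    seed: int = 0,
    kind: str | None = None,
) -> PermTestResult:
    """Permutation association test between class labels and one covariate.

    The covariate is permuted across samples B times while the class labels
    stay fixed; ``kind`` ("continuous" / "categorical") overrides dtype-based
    statistic choice.  Missing covariate values are dropped first.
    Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    classes = pd.Series(np.asarray(classes))
    cov = pd.Series(covariate).reset_index(drop=True)
    keep = cov.notna().to_numpy()
    g = classes.to_numpy()[keep]
    v = cov.to_numpy()[keep]
    if kind is None:
        kind = "continuous" if pd.api.types.is_numeric_dtype(cov) else "categorical"
    rng = np.random.default_rng(seed)
    g_codes = pd.factorize(g, sort=True)[0]
    n_groups = g_codes.max() + 1
    if kind == "continuous":
        x = v.astype(float)
        observed = kruskal_wallis_stat(g, x)
        stat_name = "kruskal-wallis"
        df = n_groups - 1
        n = len(x)
        ranks = stats.rankdata(x)
        _, counts = np.unique(x, return_counts=True)
        tie_corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
        null = _kw_null_stats(g_codes, ranks, tie_corr, B, rng)
    else:
        observed = chi_square_stat(g, v)
        stat_name = "chi-square"
        v_codes = pd.factorize(v, sort=True)[0]
        n_levels = v_codes.max() + 1
        df = (n_groups - 1) * (n_levels - 1)
        null = _chi2_null_stats(g_codes, v_codes, n_groups, n_levels, B, rng)
    count = int((null >= observed - 1e-12).sum())
    p = (1 + count) / (B + 1)
    asym = float(stats.chi2.sf(observed, df)) if df > 0 else np.nan
    return PermTestResult(
        covariate=getattr(covariate, "name", "") or "",
        statistic_kind=stat_name,
        observed=float(observed),
        p_value=float(p),
        n_permutations=B,
        n_used=int(keep.sum()),
        asymptotic_p=asym,
    )


def association_table(
    labels: pd.Series,
    covariates: pd.DataFrame,
    columns: list[str] | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the permutation test for each requested covariate column and
    return a tidy table (one row per covariate)."""
    columns = list(columns) if columns is not None else list(covariates.columns)
    rows = []
    for i, col in enumerate(columns):
        try:
            res = permutation_test(
                labels.loc[covariates.index], covariates[col], B=B, seed=seed + i
            )
            row = {
                "covariate": col,
                "statistic_kind": res.statistic_kind,
                "statistic": res.observed,
                "perm_p": res.p_value,
                "asymptotic_p": res.asymptotic_p,
                "n_used": res.n_used,
                "B": res.n_permutations,
            }
        except ValueError:  # degenerate margin / single class
            row = {
                "covariate": col,
                "statistic_kind": "degenerate",
                "statistic": np.nan,
                "perm_p": np.nan,
                "asymptotic_p": np.nan,
                "n_used": int(covariates[col].notna().sum()),
                "B": B,
            }
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
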