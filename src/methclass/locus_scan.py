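"""Array-wide locus-by-locus association scans on beta values.

Each CpG is regressed on a covariate of interest (optionally adjusted)
under a quasi-binomial model: logit link, variance phi * mu * (1 - mu) with
the scale phi estimated by Pearson chi-square / (n - p).  Fractional
responses in [0, 1] are handled natively — no transformation of beta.
Inference on the covariate coefficient uses a t reference with n - p
degrees of freedom, the quasi-likelihood convention.  Multiplicity is
addressed with q-values: the null proportion pi0 is estimated on a lambda
grid with a cubic-smoother extrapolation to lambda = 1, and
q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BetaMatrix

__all__ = [
    "LocusFit",
    "ScanResult",
    "SignTrend",
    "fit_locus_glm",
    "scan",
    "storey_qvalues",
    "sign_trend",
]


@dataclass
class LocusFit:
    locus_id: str
    coefficient: float
    se: float
    t: float
    p: float
    dispersion: float
    n_used: int
    converged: bool = True

    @property
    def flagged(self) -> bool:
        return not self.converged or not np.isfinite(self.p)


@dataclass
class ScanResult:
    """One fitted model per locus plus array-wide FDR quantities."""

    table: pd.DataFrame  # locus_id index: coefficient, se, t, p, q, dispersion, n_used, converged
    pi0: float
    target: str
    adjust: tuple[str, ...] = ()

    @property
    def n_loci(self) -> int:
        return len(self.table)

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


@dataclass
class SignTrend:
    n_negative: int
    n_positive: int
    n_zero: int
    sign_test_p: float
    table: pd.DataFrame = field(repr=False)


def fit_locus_glm(
    beta_values, design, target_index: int = 1, locus_id: str = "",
    max_iter: int = 100, tol: float = 1e-10,
) -> LocusFit:
    """Quasi-binomial fit of one locus; inference on one design column.

    IRLS under mean mu = logistic(X b) and variance phi * mu * (1 - mu);
    phi is the Pearson chi-square divided by n - p, and the covariate's
    coefficient is tested against a t reference with n - p degrees of
    freedom.  ``design`` must include an intercept column; ``target_index``
    selects the coefficient reported (default: the first non-intercept
    column).  Requires at least p + 2 complete cases; beta values of exactly
    0 or 1 are admitted.  Separation or non-convergence yields a flagged
    LocusFit (NaN statistics) rather than an exception; a saturated fit
    (zero residual dispersion) keeps its coefficient but has missing
    inference.
    """
    y = np.asarray(beta_values, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {n}")
    if y.min() < 0 or y.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    flagged = LocusFit(locus_id, np.nan, np.nan, np.nan, np.nan, np.nan, n, False)

    # IRLS from the mean-model start
    mu0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    eta = np.full(n, np.log(mu0 / (1 - mu0)))
    beta_hat = None
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / W
        WX = X * W[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        except np.linalg.LinAlgError:
            return flagged
        if not np.all(np.isfinite(new)):
            return flagged
        if beta_hat is not None and np.max(np.abs(new - beta_hat)) < tol:
            beta_hat = new
            converged = True
            break
        beta_hat = new
        eta = X @ beta_hat
    if not converged or np.max(np.abs(eta)) > 30.0:  # separation guard
        return flagged

    eta = X @ beta_hat
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = np.clip(mu * (1.0 - mu), 1e-12, None)
    pearson = float(np.sum((y - mu) ** 2 / W))
    phi = pearson / (n - p)
    coef = float(beta_hat[target_index])
    if phi <= 0:
        # saturated: estimate is exact, inference undefined
        return LocusFit(locus_id, coef, np.nan, np.nan, np.nan, 0.0, n, True)
    cov = phi * np.linalg.inv(X.T @ (X * W[:, None]))
    se = float(np.sqrt(cov[target_index, target_index]))
    tval = coef / se
    pval = float(2.0 * stats.t.sf(abs(tval), df=n - p))
    return LocusFit(locus_id, coef, se, tval, pval, phi, n, True)


def _build_design(
    covariates: pd.DataFrame, target: str, adjust: tuple[str, ...]
) -> tuple[pd.DataFrame, int]:
    """Intercept + target + dummy-coded adjusters; returns (design, target col)."""
    cols = {"intercept": pd.Series(1.0, index=covariates.index)}
    tgt = covariates[target]
    if tgt.dtype == object or isinstance(tgt.dtype, pd.CategoricalDtype):
        levels = sorted(tgt.dropna().unique())
        if len(levels) < 2:
            raise ValueError(f"degenerate covariate {target!r}")
        # binary-code against the first level; multi-level targets scan the
        # first contrast
        cols[target] = (tgt == levels[1]).astype(float).where(tgt.notna())
    else:
        vals = tgt.astype(float)
        if vals.dropna().nunique() < 2:
            raise ValueError(f"degenerate covariate {target!r}")
        cols[target] = vals
    for name in adjust:
        c = covariates[name]
        if c.dtype == object or isinstance(c.dtype, pd.CategoricalDtype):
            levels = sorted(c.dropna().unique())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (c == lev).astype(float).where(c.notna())
        else:
            cols[name] = c.astype(float)
    return pd.DataFrame(cols), 1


def scan(
    beta: BetaMatrix,
    covariates: pd.DataFrame,
    target: str,
    adjust: tuple[str, ...] = (),
    pi0_method: str = "smoother",
) -> ScanResult:
    """Fit every locus against ``target`` (complete cases per locus) and
    attach q-values computed over the non-flagged p-values."""
    if target not in covariates.columns:
        raise KeyError(f"covariate {target!r} not found")
    design, tgt_idx = _build_design(covariates.loc[beta.sample_ids], target, adjust)
    X = design.to_numpy(dtype=float)
    vals = beta.to_numpy()
    rows = []
    for j, locus in enumerate(beta.locus_ids):
        fit = fit_locus_glm(vals[:, j], X, target_index=tgt_idx, locus_id=locus)
        rows.append(
            (locus, fit.coefficient, fit.se, fit.t, fit.p, fit.dispersion,
             fit.n_used, fit.converged)
        )
    table = pd.DataFrame(
        rows,
        columns=["locus_id", "coefficient", "se", "t", "p", "dispersion",
                 "n_used", "converged"],
    ).set_index("locus_id")
    usable = table["p"].notna() & table["converged"]
    if not usable.any():
        raise RuntimeError("all locus fits flagged; nothing to scan")
    qvals, pi0 = storey_qvalues(
        table.loc[usable, "p"].to_numpy(), pi0_method=pi0_method
    )
    table["q"] = np.nan
    table.loc[usable, "q"] = qvals
    return ScanResult(table=table, pi0=pi0, target=target, adjust=tuple(adjust))


def storey_qvalues(
    pvals,
    lambdas=None,
    pi0_method: str = "smoother",
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
    0.05..0.95; a cubic least-squares smoother is evaluated at lambda = 1
    and clamped to (0, 1].  ``pi0_method='fixed'`` with ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values exactly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need a 1-D array of at least 2 p-values")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is not None or pi0_method == "fixed":
        pi0_hat = 1.0 if pi0 is None else float(pi0)
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        lam = np.asarray(lambdas, dtype=float)
        pi0_grid = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
        coef = np.polyfit(lam, pi0_grid, deg=3)
        pi0_hat = float(np.polyval(coef, 1.0))
    pi0_hat = float(np.clip(pi0_hat, 1e-8, 1.0))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0_hat * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0_hat


def sign_trend(result: ScanResult) -> SignTrend:
    """Directional summary of the scan's coefficient signs.

    Counts negative / positive / exactly-zero coefficients among non-flagged
    fits and runs a two-sided binomial sign test of sign symmetry; the table
    holds the per-locus (coefficient, p) pairs for volcano-style plotting.
    """
    ok = result.table["converged"] & result.table["coefficient"].notna()
    if not ok.any():
        raise ValueError("no usable fits")
    sub = result.table.loc[ok, ["coefficient", "p"]]
    coefs = sub["coefficient"].to_numpy()
    n_neg = int((coefs < 0).sum())
    n_pos = int((coefs > 0).sum())
    n_zero = int((coefs == 0).sum())
    n_signed = n_neg + n_pos
    if n_signed:
        sign_p = float(stats.binomtest(n_pos, n_signed, 0.5).pvalue)
    else:
        sign_p = 1.0
    return SignTrend(n_neg, n_pos, n_zero, sign_p, sub.copy())
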