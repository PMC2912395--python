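"""Ridge-penalized multinomial logistic regression of class membership.

Class membership (one label per sample, one class held out as referent) is
modeled with multinomial logit probabilities; all non-intercept
coefficients share a ridge (L2) penalty, shrinking a covariate's
coefficients across outcome levels toward zero.  Continuous covariates are
standardized internally before penalization (shared shrinkage is only
meaningful on a common scale) and back-transformed for reporting.  The
tuning parameter is selected by minimizing BIC, where the model dimension
is the effective degrees of freedom trace[H (H + 2*lambda*P)^(-1)] of the
ridge hat operator (H = unpenalized information at the estimate, P the
non-intercept indicator).  Wald tests use the inverse penalized information
as the coefficient covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RidgeMultinomialFit",
    "ProbabilityCurve",
    "build_design",
    "fit_ridge_multinomial",
    "select_lambda_bic",
    "wald_tests",
    "membership_curves",
    "default_referent",
]

_TRANSFORMS = {"identity": lambda v: v, "sqrt": np.sqrt, "log1p": np.log1p}


@dataclass
class RidgeMultinomialFit:
    coef: pd.DataFrame            # (classes minus referent) x (intercept + covariates), original scale
    coef_std: np.ndarray          # same layout on the standardized fitting scale
    referent: object
    class_labels: list
    lambda_: float
    loglik: float                 # unpenalized log-likelihood at the estimate
    penalized_loglik: float
    df_eff: float
    bic: float
    n_used: int
    columns: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    x_range: pd.DataFrame = field(repr=False, default=None)
    cov_std: np.ndarray = field(repr=False, default=None)
    trace: list[float] = field(default_factory=list, repr=False)

    @property
    def nonreferent_labels(self) -> list:
        return [c for c in self.class_labels if c != self.referent]

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        """Class probabilities (all classes, referent included)."""
        Xs, idx = self._standardize(X)
        eta = Xs @ self.coef_std.T        # n x (K-1)
        full = np.zeros((eta.shape[0], len(self.class_labels)))
        j = 0
        for k, lab in enumerate(self.class_labels):
            if lab == self.referent:
                continue
            full[:, k] = eta[:, j]
            j += 1
        full -= full.max(axis=1, keepdims=True)
        p = np.exp(full)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=idx, columns=self.class_labels)

    def _standardize(self, X) -> tuple[np.ndarray, pd.Index | None]:
        idx = X.index if isinstance(X, pd.DataFrame) else None
        arr = (
            X[self.columns[1:]].to_numpy(dtype=float)
            if isinstance(X, pd.DataFrame)
            else np.asarray(X, dtype=float)
        )
        arr = (arr - self.x_mean) / self.x_sd
        return np.column_stack([np.ones(arr.shape[0]), arr]), idx


@dataclass
class ProbabilityCurve:
    covariate: str
    grid: np.ndarray
    probabilities: pd.DataFrame   # classes x grid points, columns sum to 1
    reference: dict


def default_referent(classes) -> object:
    """The median-size class: order class labels by (count, label) and take
    the middle one — neither the largest nor the smallest class."""
    counts = pd.Series(classes).value_counts()
    ordered = sorted(counts.index, key=lambda c: (counts[c], str(c)))
    return ordered[len(ordered) // 2]


def build_design(
    covariates: pd.DataFrame,
    columns: list[str],
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Numeric design frame (no intercept): continuous columns optionally
    transformed (identity / sqrt / log1p), categoricals dummy-coded against
    their first sorted level.  Rows with any missing value are dropped."""
    transforms = transforms or {}
    out = {}
    for col in columns:
        c = covariates[col]
        if pd.api.types.is_numeric_dtype(c):
            t = transforms.get(col, "identity")
            vals = _TRANSFORMS[t](c.astype(float))
            name = col if t == "identity" else f"{t}({col})"
            out[name] = vals
        else:
            levels = sorted(c.dropna().unique())
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (c == lev).astype(float).where(c.notna())
    return pd.DataFrame(out, index=covariates.index).dropna()


def _neg_loglik_grad_hess(
    theta: np.ndarray, X: np.ndarray, Y: np.ndarray, lam: float, pen: np.ndarray,
    want_hess: bool = True,
):
    """Penalized negative log-likelihood, gradient, (optional) Hessian.

    theta: (K-1) x P coefficients for non-referent classes (referent row
    implicitly zero); Y: n x (K-1) indicators; pen: P-vector penalty
    indicator (0 for intercept)."""
    n, P = X.shape
    Km1 = theta.shape[0]
    eta = X @ theta.T                          # n x (K-1)
    M = np.column_stack([np.zeros(n), eta])    # referent first, coefficient 0
    mx = M.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(M - mx).sum(axis=1))
    ll = float((eta * Y).sum() - lse.sum())
    pi = np.exp(M - lse[:, None])[:, 1:]       # n x (K-1), non-referent probs
    nll = -ll + lam * float((theta ** 2 * pen[None, :]).sum())
    grad = (pi - Y).T @ X + 2.0 * lam * theta * pen[None, :]
    if not want_hess:
        return nll, grad, None, ll
    H = np.empty((Km1, P, Km1, P))
    for k in range(Km1):
        for l in range(k, Km1):
            if k == l:
                w = pi[:, k] * (1.0 - pi[:, k])
            else:
                w = -pi[:, k] * pi[:, l]
            block = X.T @ (X * w[:, None])
            H[k, :, l, :] = block
            H[l, :, k, :] = block
    Hm = H.reshape(Km1 * P, Km1 * P)
    Hm += 2.0 * lam * np.diag(np.tile(pen, Km1))
    return nll, grad, Hm, ll


def fit_ridge_multinomial(
    classes,
    X: pd.DataFrame,
    lam: float = 0.0,
    referent=None,
    max_iter: int = 200,
    grad_tol: float = 1e-8,
) -> RidgeMultinomialFit:
    """Damped-Newton fit of the ridge multinomial model.

    ``X`` is a numeric design frame without intercept; ``classes`` one label
    per row of X.  Intercepts are never penalized.  Convergence requires the
    penalized-gradient norm to fall below ``grad_tol``; at lambda = 0 a
    singular Hessian (complete separation) raises with advice to penalize.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = pd.Series(np.asarray(classes), index=X.index if isinstance(X, pd.DataFrame) else None)
    keep = y.notna()
    if isinstance(X, pd.DataFrame):
        keep &= X.notna().all(axis=1)
        Xv = X.loc[keep].to_numpy(dtype=float)
        cols = list(X.columns)
    else:
        Xv = np.asarray(X, dtype=float)[keep.to_numpy()]
        cols = [f"x{j}" for j in range(Xv.shape[1])]
    yv = y[keep].to_numpy()
    labels = sorted(pd.unique(yv), key=str)
    if len(labels) < 2:
        raise ValueError("need at least 2 classes present")
    if referent is None:
        referent = default_referent(yv)
    if referent not in labels:
        raise ValueError(f"referent {referent!r} not among class labels")
    n, p = Xv.shape

    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = np.column_stack([np.ones(n), (Xv - mean) / sd])
    P = p + 1
    nonref = [c for c in labels if c != referent]
    Y = np.column_stack([(yv == c).astype(float) for c in nonref])
    pen = np.array([0.0] + [1.0] * p)
    Km1 = len(nonref)

    theta = np.zeros((Km1, P))
    trace: list[float] = []
    nll, grad, H, ll = _neg_loglik_grad_hess(theta, Xs, Y, lam, pen)
    for it in range(max_iter):
        gnorm = np.linalg.norm(grad)
        trace.append(-nll)
        if gnorm < grad_tol:
            break
        try:
            step = np.linalg.solve(H, grad.ravel()).reshape(Km1, P)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "singular information matrix (possible separation); "
                "use lambda > 0"
            ) from e
        t = 1.0
        for _ in range(50):
            cand = theta - t * step
            nll_new, grad_new, H_new, ll_new = _neg_loglik_grad_hess(
                cand, Xs, Y, lam, pen
            )
            if nll_new <= nll + 1e-12:
                theta, nll, grad, H, ll = cand, nll_new, grad_new, H_new, ll_new
                break
            t *= 0.5
        else:
            raise RuntimeError(
                f"line search failed at iteration {it}; trace={trace[-5:]}"
            )
    else:
        if np.linalg.norm(grad) >= grad_tol:
            raise RuntimeError(
                f"Newton did not converge in {max_iter} iterations; "
                f"final gradient norm {np.linalg.norm(grad):.3g}"
            )

    # unpenalized information at the estimate and effective df
    _, _, H_unpen, _ = _neg_loglik_grad_hess(theta, Xs, Y, 0.0, pen)
    H_pen = H_unpen + 2.0 * lam * np.diag(np.tile(pen, Km1))
    df_eff = float(np.trace(np.linalg.solve(H_pen, H_unpen)))
    bic = -2.0 * ll + df_eff * np.log(n)
    cov_std = np.linalg.inv(H_pen)

    # back-transform to the original covariate scale
    coef_orig = np.empty_like(theta)
    coef_orig[:, 1:] = theta[:, 1:] / sd[None, :]
    coef_orig[:, 0] = theta[:, 0] - (theta[:, 1:] * (mean / sd)[None, :]).sum(axis=1)
    columns = ["intercept"] + cols
    coef = pd.DataFrame(coef_orig, index=pd.Index(nonref, name="class"), columns=columns)
    x_range = pd.DataFrame({"min": Xv.min(axis=0), "max": Xv.max(axis=0)}, index=cols)
    return RidgeMultinomialFit(
        coef=coef,
        coef_std=theta,
        referent=referent,
        class_labels=labels,
        lambda_=float(lam),
        loglik=float(ll),
        penalized_loglik=float(-nll),
        df_eff=df_eff,
        bic=float(bic),
        n_used=n,
        columns=columns,
        x_mean=mean,
        x_sd=sd,
        x_range=x_range,
        cov_std=cov_std,
        trace=trace,
    )


def select_lambda_bic(
    classes, X: pd.DataFrame, lambda_grid, referent=None
) -> tuple[float, dict[float, RidgeMultinomialFit]]:
    """Fit every lambda on the grid; return (BIC-minimizing lambda, fits).
    Ties go to the larger lambda (stronger shrinkage)."""
    grid = sorted(float(l) for l in lambda_grid)
    if not grid:
        raise ValueError("empty lambda grid")
    fits: dict[float, RidgeMultinomialFit] = {}
    best_lam, best_bic = None, np.inf
    for lam in grid:
        fit = fit_ridge_multinomial(classes, X, lam=lam, referent=referent)
        fits[lam] = fit
        if fit.bic <= best_bic:
            best_bic, best_lam = fit.bic, lam
    return best_lam, fits


def wald_tests(fit: RidgeMultinomialFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overall (per covariate, chi-square with K-1 df) and per-class Wald
    tests, computed on the standardized fitting scale from the penalized
    information.  Returns (overall table, per-class table)."""
    Km1, P = fit.coef_std.shape
    cov = fit.cov_std
    if cov is None:
        raise ValueError("fit lacks a coefficient covariance")
    overall_rows = []
    class_rows = []
    for j, name in enumerate(fit.columns):
        if name == "intercept":
            continue
        idx = [k * P + j for k in range(Km1)]
        v = fit.coef_std[:, j]
        block = cov[np.ix_(idx, idx)]
        try:
            stat = float(v @ np.linalg.solve(block, v))
        except np.linalg.LinAlgError as e:
            raise RuntimeError("non-invertible covariance block") from e
        overall_rows.append(
            {
                "covariate": name,
                "wald_chi2": stat,
                "df": Km1,
                "p": float(stats.chi2.sf(stat, Km1)),
            }
        )
        for k, lab in enumerate(fit.nonreferent_labels):
            se = np.sqrt(cov[k * P + j, k * P + j])
            z = fit.coef_std[k, j] / se if se > 0 else np.nan
            class_rows.append(
                {
                    "covariate": name,
                    "class": lab,
                    "coef_std": fit.coef_std[k, j],
                    "se_std": se,
                    "z": z,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                }
            )
    return (
        pd.DataFrame(overall_rows).set_index("covariate"),
        pd.DataFrame(class_rows).set_index(["covariate", "class"]),
    )


def membership_curves(
    fit: RidgeMultinomialFit,
    covariate: str,
    grid,
    reference: dict,
    transform: str | None = None,
) -> ProbabilityCurve:
    """Class-membership probabilities along a covariate grid, all other
    design columns held at ``reference`` values.  ``transform`` applies one
    of identity/sqrt/log1p to the grid before it enters the design (the
    returned grid stays on the raw scale).  Grid values outside the training
    range warn but still evaluate."""
    design_cols = fit.columns[1:]
    if covariate not in design_cols:
        raise KeyError(f"{covariate!r} is not a design column of this fit")
    grid = np.asarray(grid, dtype=float)
    gvals = _TRANSFORMS[transform or "identity"](grid)
    lo, hi = fit.x_range.loc[covariate, ["min", "max"]]
    if gvals.min() < lo - 1e-12 or gvals.max() > hi + 1e-12:
        warnings.warn(
            f"grid for {covariate!r} extends outside the fitted range "
            f"[{lo:.3g}, {hi:.3g}]", RuntimeWarning,
        )
    rows = []
    for g in gvals:
        row = {c: reference[c] for c in design_cols if c != covariate}
        missing = [c for c in design_cols if c != covariate and c not in reference]
        if missing:
            raise ValueError(f"reference values missing for {missing}")
        row[covariate] = g
        rows.append([row[c] for c in design_cols])
    Xg = pd.DataFrame(rows, columns=design_cols)
    probs = fit.predict_proba(Xg)
    table = probs.T
    table.columns = grid
    return ProbabilityCurve(covariate, grid, table, dict(reference))
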