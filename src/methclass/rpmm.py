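"""Recursively partitioned beta-mixture clustering of methylation profiles.

Samples are split recursively by a two-component mixture of independent
per-locus Beta distributions, fit with a fuzzy EM: E-step responsibilities
are proportional to mixing weight times the product over loci of beta
densities (in log space); the M-step re-estimates the mixing weight and the
per-locus shape pairs by weighted maximum likelihood (Newton iteration on
the digamma system, initialized at method-of-moments).  A split is accepted
iff the two-component BIC beats the one-component BIC at that node; free
parameters are 2 per locus per component plus one mixing weight, and the
effective sample size is the total membership weight reaching the node.
Terminal nodes are the methylation classes; every sample carries fuzzy
membership weights that multiply down the tree.

Split initialization is deterministic (no seed needed): samples are
bipartitioned by the first principal coordinate of their pairwise Manhattan
distances, so refitting the same matrix reproduces the same tree exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, polygamma

from .datatypes import BetaMatrix

__all__ = [
    "BetaNodeParams",
    "RPMMModel",
    "beta_mle_weighted",
    "em_two_class",
    "fit_rpmm",
    "class_profiles",
    "classify",
]

CLAMP_EPS = 1e-6
_SHAPE_MIN, _SHAPE_MAX = 1e-3, 1e6
_CONC_CAP = 1e4  # concentration cap for degenerate (zero-variance) loci


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, CLAMP_EPS, 1.0 - CLAMP_EPS)


# ---------------------------------------------------------------------------
# weighted beta maximum likelihood
# ---------------------------------------------------------------------------

def _mom_shapes(m: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments shapes from weighted mean/variance, concentration
    capped for (near-)degenerate loci."""
    m = np.clip(m, 1e-4, 1 - 1e-4)
    vmax = m * (1 - m)
    v = np.clip(v, vmax / (1.0 + _CONC_CAP), vmax * 0.999)
    conc = vmax / v - 1.0
    conc = np.clip(conc, 1e-2, _CONC_CAP)
    return np.clip(m * conc, _SHAPE_MIN, _SHAPE_MAX), np.clip(
        (1 - m) * conc, _SHAPE_MIN, _SHAPE_MAX
    )


def _beta_mle_vector(
    S1: np.ndarray, S2: np.ndarray, U: float | np.ndarray,
    m: np.ndarray, v: np.ndarray, max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton solve of the weighted beta score equations.

    S1 = sum w log x, S2 = sum w log(1-x) per locus; U = sum w.  The system
    psi(a) - psi(a+b) = S1/U, psi(b) - psi(a+b) = S2/U is solved per locus
    with step-damping to keep shapes positive.
    """
    a, b = _mom_shapes(m, v)
    U = np.broadcast_to(np.asarray(U, dtype=float), a.shape)
    t1, t2 = np.where(U > 0, S1 / np.maximum(U, 1e-300), 0.0), np.where(
        U > 0, S2 / np.maximum(U, 1e-300), 0.0
    )
    active = U > 0
    for _ in range(max_iter):
        ga = digamma(a) - digamma(a + b) - t1
        gb = digamma(b) - digamma(a + b) - t2
        if not np.any(active & ((np.abs(ga) > tol) | (np.abs(gb) > tol))):
            break
        pa, pb, pab = polygamma(1, a), polygamma(1, b), polygamma(1, a + b)
        h11, h22, h12 = pa - pab, pb - pab, -pab
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = -(h22 * ga - h12 * gb) / det
        db = -(h11 * gb - h12 * ga) / det
        # damp steps that would leave the positive orthant
        scale = np.ones_like(a)
        bad_a = da < -0.95 * a
        bad_b = db < -0.95 * b
        scale = np.where(bad_a, np.minimum(scale, -0.95 * a / np.where(da == 0, 1, da)), scale)
        scale = np.where(bad_b, np.minimum(scale, -0.95 * b / np.where(db == 0, 1, db)), scale)
        a = np.where(active, np.clip(a + scale * da, _SHAPE_MIN, _SHAPE_MAX), a)
        b = np.where(active, np.clip(b + scale * db, _SHAPE_MIN, _SHAPE_MAX), b)
    bad = ~np.isfinite(a) | ~np.isfinite(b)
    if np.any(bad):
        ma, mb = _mom_shapes(m, v)
        a, b = np.where(bad, ma, a), np.where(bad, mb, b)
    return a, b


def beta_mle_weighted(x, w=None) -> tuple[float, float]:
    """Weighted maximum-likelihood beta shapes for one locus.

    Values are clamped away from {0, 1}; all-equal (degenerate) input yields
    capped-concentration shapes with a warning.  Zero-weight observations do
    not influence the estimate.
    """
    x = _clamp(np.asarray(x, dtype=float))
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if w.min() < 0:
        raise ValueError("weights must be non-negative")
    U = w.sum()
    if U <= 0:
        raise ValueError("total weight must be positive")
    m = float(w @ x / U)
    v = float(w @ (x - m) ** 2 / U)
    if v <= m * (1 - m) / (1.0 + _CONC_CAP):
        warnings.warn("degenerate locus: concentration capped", RuntimeWarning)
        a, b = _mom_shapes(np.array([m]), np.array([v]))
        return float(a[0]), float(b[0])
    S1, S2 = float(w @ np.log(x)), float(w @ np.log1p(-x))
    a, b = _beta_mle_vector(
        np.array([S1]), np.array([S2]), np.array([U]),
        np.array([m]), np.array([v]),
    )
    return float(a[0]), float(b[0])


# ---------------------------------------------------------------------------
# two-class fuzzy EM
# ---------------------------------------------------------------------------

@dataclass
class BetaNodeParams:
    """Per-locus beta shapes plus bookkeeping for one tree node."""

    a: np.ndarray
    b: np.ndarray
    weight: float          # expected fraction of root samples at this node
    loglik: float = np.nan
    bic: float = np.nan


@dataclass
class EMResult:
    children: tuple[BetaNodeParams, BetaNodeParams]
    mixing: np.ndarray          # length 2, sums to 1
    responsibilities: np.ndarray  # n x 2, rows sum to 1
    loglik: float
    trace: list[float]
    converged: bool


def _log_density_matrix(LX, L1X, a, b) -> np.ndarray:
    """n-vector of log prod_j Beta(x_ij; a_j, b_j)."""
    return LX @ (a - 1.0) + L1X @ (b - 1.0) - betaln(a, b).sum()


def _weighted_node_mle(LX, L1X, X, u) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted per-locus beta MLE for one component; returns (a, b, loglik)."""
    U = float(u.sum())
    S1, S2 = u @ LX, u @ L1X
    m = u @ X / U
    v = u @ (X ** 2) / U - m ** 2
    a, b = _beta_mle_vector(S1, S2, U, m, np.maximum(v, 0.0))
    ll = float((a - 1.0) @ S1 + (b - 1.0) @ S2 - U * betaln(a, b).sum())
    return a, b, ll


def _init_split(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Deterministic initial responsibilities: bipartition by the first
    principal coordinate of pairwise Manhattan distances."""
    n = X.shape[0]
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    D2 = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    coord = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    # fix the eigenvector's arbitrary sign by a sample-order-invariant rule
    # so the left/right children do not depend on row order
    orient = float(coord @ X.sum(axis=1))
    if orient < 0 or (orient == 0 and coord.sum() < 0):
        coord = -coord
    # weighted median split; deterministic sign convention
    order = np.argsort(coord, kind="mergesort")
    cum = np.cumsum(w[order])
    half = cum[-1] / 2.0
    left = np.zeros(n, dtype=bool)
    left[order[cum <= half]] = True
    if left.sum() in (0, n):
        left[:] = False
        left[order[: n // 2]] = True
    r = np.where(left, 0.9, 0.1)
    return np.column_stack([r, 1.0 - r])


def em_two_class(
    data: np.ndarray | BetaMatrix,
    parent_weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> EMResult:
    """Fuzzy two-component beta-mixture EM at one tree node.

    ``parent_weights`` are each sample's membership weight at the node (the
    fuzzy analogue of node membership); the fitted log-likelihood is the
    weight-adjusted observed-data likelihood.  The likelihood trace is
    checked to be non-decreasing (within numerical slack) every iteration —
    a violation indicates an implementation defect and raises.
    """
    X = data.to_numpy() if isinstance(data, BetaMatrix) else np.asarray(data, float)
    X = _clamp(X)
    n, J = X.shape
    w = np.ones(n) if parent_weights is None else np.asarray(parent_weights, float)
    if w.shape != (n,) or w.min() < 0:
        raise ValueError("parent_weights must be non-negative, one per sample")
    LX, L1X = np.log(X), np.log1p(-X)
    r = _init_split(X, w)
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    a = np.zeros((2, J))
    bshape = np.zeros((2, J))
    eta = np.array([0.5, 0.5])
    for _ in range(max_iter):
        # M-step
        for c in (0, 1):
            u = w * r[:, c]
            a[c], bshape[c], _ = _weighted_node_mle(LX, L1X, X, np.maximum(u, 1e-12))
        eta = (w @ r) / max(w.sum(), 1e-300)
        eta = np.clip(eta, 1e-12, None)
        eta /= eta.sum()
        # E-step
        logf = np.column_stack(
            [np.log(eta[c]) + _log_density_matrix(LX, L1X, a[c], bshape[c]) for c in (0, 1)]
        )
        mx = logf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logf - mx).sum(axis=1))
        r_new = np.exp(logf - lse[:, None])
        ll = float(w @ lse)
        trace.append(ll)
        if ll < ll_prev - max(1e-6, 1e-8 * abs(ll_prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased: {ll_prev:.8f} -> {ll:.8f}"
            )
        delta = np.max(np.abs(r_new - r))
        r = r_new
        if delta < tol and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    total_w = float(w.sum())
    children = tuple(
        BetaNodeParams(a[c].copy(), bshape[c].copy(), float(eta[c]), np.nan, np.nan)
        for c in (0, 1)
    )
    return EMResult(children, eta.copy(), r, ll_prev, trace, converged)


# ---------------------------------------------------------------------------
# recursive partitioning
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    params: BetaNodeParams
    depth: int
    children: tuple["TreeNode", "TreeNode"] | None = None
    mixing: np.ndarray | None = None      # split proportions if internal
    class_index: int | None = None        # terminal class (0-based)
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_terminal(self) -> bool:
        return self.children is None


@dataclass
class RPMMModel:
    """Fitted recursive beta-mixture: split tree, terminal classes in
    depth-first order, fuzzy membership matrix W (rows sum to 1), and hard
    labels (argmax, ties to the lower class index)."""

    root: TreeNode
    classes: list[TreeNode]
    W: pd.DataFrame
    labels: pd.Series
    locus_ids: list[str]
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_weights(self) -> np.ndarray:
        return self.W.to_numpy().mean(axis=0)

    def tree_summary(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            tag = (
                f"class {node.class_index + 1}" if node.is_terminal else "split"
            )
            lines.append(
                "  " * indent
                + f"[depth {node.depth}] {tag}: weight={node.params.weight:.4f} "
                f"BIC={node.params.bic:.1f}"
            )
            if node.children:
                for ch in node.children:
                    walk(ch, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _node_fit(LX, L1X, X, w, n_root: float) -> BetaNodeParams:
    a, b, ll = _weighted_node_mle(LX, L1X, X, np.maximum(w, 1e-12))
    n_eff = float(w.sum())
    k = 2 * X.shape[1]
    bic = -2.0 * ll + k * np.log(max(n_eff, 1e-300))
    return BetaNodeParams(a, b, n_eff / n_root, ll, bic)


def fit_rpmm(
    beta: BetaMatrix,
    min_node_size: int = 5,
    max_depth: int = 4,
    tol: float = 1e-6,
    max_iter: int = 200,
    impute_missing: bool = False,
) -> RPMMModel:
    """Fit the recursive two-class beta-mixture to a beta matrix.

    Splitting stops at ``max_depth``, when a node's effective size drops
    below ``2 * min_node_size``, when a child would fall below
    ``min_node_size``, or when the two-component BIC does not beat the
    one-component BIC.  Missing values are only admitted with
    ``impute_missing=True`` (per-locus weighted-mean imputation, flagged in
    the diagnostics).
    """
    X = beta.to_numpy()
    if X.size == 0:
        raise ValueError("empty beta matrix")
    imputed = False
    if np.isnan(X).any():
        if not impute_missing:
            raise ValueError("missing beta values; pass impute_missing=True")
        col_mean = np.nanmean(X, axis=0)
        ii, jj = np.where(np.isnan(X))
        X = X.copy()
        X[ii, jj] = col_mean[jj]
        imputed = True
    X = _clamp(X)
    n, J = X.shape
    LX, L1X = np.log(X), np.log1p(-X)
    diagnostics: list[dict] = []
    classes: list[TreeNode] = []
    memberships: list[np.ndarray] = []

    def grow(w: np.ndarray, depth: int) -> TreeNode:
        params = _node_fit(LX, L1X, X, w, float(n))
        node = TreeNode(params=params, depth=depth)
        n_eff = float(w.sum())
        reason = None
        if depth >= max_depth:
            reason = "max_depth"
        elif n_eff < 2 * min_node_size:
            reason = "min_node_size"
        if reason is None:
            em = em_two_class(X, w, tol=tol, max_iter=max_iter)
            child_w = w[:, None] * em.responsibilities
            child_n = child_w.sum(axis=0)
            k2 = 4 * J + 1
            bic2 = -2.0 * em.loglik + k2 * np.log(max(n_eff, 1e-300))
            diag = {
                "depth": depth,
                "n_eff": n_eff,
                "bic_one": params.bic,
                "bic_two": bic2,
                "em_converged": em.converged,
                "em_iterations": len(em.trace),
                "child_sizes": child_n.tolist(),
            }
            if bic2 < params.bic and child_n.min() >= min_node_size:
                diag["accepted"] = True
                diagnostics.append(diag)
                left = grow(child_w[:, 0], depth + 1)
                right = grow(child_w[:, 1], depth + 1)
                node.children = (left, right)
                node.mixing = em.mixing
                # stash fitted component params on the children for classify()
                left.split_component = em.children[0]     # type: ignore[attr-defined]
                right.split_component = em.children[1]    # type: ignore[attr-defined]
                node.diagnostics = diag
                return node
            diag["accepted"] = False
            diagnostics.append(diag)
        node.class_index = len(classes)
        classes.append(node)
        memberships.append(w)
        return node

    root = grow(np.ones(n), 0)
    W = np.column_stack(memberships) if memberships else np.ones((n, 1))
    W = W / W.sum(axis=1, keepdims=True)
    names = [f"class{k + 1}" for k in range(W.shape[1])]
    Wf = pd.DataFrame(W, index=beta.values.index, columns=names)
    labels = pd.Series(
        np.argmax(W, axis=1) + 1, index=beta.values.index, name="class"
    )
    if imputed:
        diagnostics.insert(0, {"imputed_missing": True})
    return RPMMModel(root, classes, Wf, labels, beta.locus_ids, diagnostics)


def class_profiles(model: RPMMModel, beta: BetaMatrix) -> pd.DataFrame:
    """Membership-weighted mean beta per class per locus (classes x loci)."""
    X = beta.to_numpy()
    W = model.W.to_numpy()
    denom = W.sum(axis=0)
    prof = (W.T @ np.nan_to_num(X, nan=0.0))
    # renormalize for missing cells locus by locus
    counts = W.T @ (~np.isnan(X)).astype(float)
    prof = prof / np.maximum(counts, 1e-300)
    return pd.DataFrame(prof, index=model.W.columns, columns=beta.locus_ids)


def classify(model: RPMMModel, new_beta: BetaMatrix) -> pd.DataFrame:
    """Posterior class memberships for new samples under the fitted tree.

    Descends every split using its stored two-component parameters, so
    classifying the training matrix reproduces the training memberships.
    """
    missing = [l for l in model.locus_ids if l not in new_beta.values.columns]
    if missing:
        raise ValueError(f"loci missing from input: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    X = _clamp(new_beta.select_loci(model.locus_ids).to_numpy())
    n = X.shape[0]
    if n == 0:
        return pd.DataFrame(
            np.zeros((0, model.n_classes)), columns=model.W.columns
        )
    LX, L1X = np.log(X), np.log1p(-X)
    out = np.zeros((n, model.n_classes))

    def walk(node: TreeNode, w: np.ndarray) -> None:
        if node.is_terminal:
            out[:, node.class_index] = w
            return
        left, right = node.children
        comp_l = left.split_component   # type: ignore[attr-defined]
        comp_r = right.split_component  # type: ignore[attr-defined]
        logf = np.column_stack([
            np.log(node.mixing[0]) + _log_density_matrix(LX, L1X, comp_l.a, comp_l.b),
            np.log(node.mixing[1]) + _log_density_matrix(LX, L1X, comp_r.a, comp_r.b),
        ])
        mx = logf.max(axis=1, keepdims=True)
        r = np.exp(logf - mx)
        r /= r.sum(axis=1, keepdims=True)
        walk(left, w * r[:, 0])
        walk(right, w * r[:, 1])

    walk(model.root, np.ones(n))
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=new_beta.values.index, columns=model.W.columns)
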