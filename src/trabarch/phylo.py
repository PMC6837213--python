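"""Phylogenetic machinery: trees, Brownian covariance, Pagel's lambda,
and residual-randomization permutation (RRPP) linear models.

The comparative analyses assume trait evolution by Brownian motion on a
time-calibrated tree, giving tip covariance ``C[i, j]`` equal to the shared
root-to-MRCA path length.  Phylogenetic signal is modulated by Pagel's
lambda, which multiplies the off-diagonal entries of ``C``; lambda is
estimated by maximising the Gaussian (GLS) likelihood and, following the
study design, estimates falling outside ``[0, 1]`` are clamped to the
nearest bound.

Hypothesis tests use RRPP: data are whitened by ``C^(-1/2)``, the observed
F statistic is computed by OLS on the whitened data, and its null
distribution is built by permuting reduced-model residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "LambdaFit",
    "RRPPFit",
    "read_newick",
    "vcv",
    "lambda_transform",
    "fit_lambda_gls",
    "inverse_sqrt",
    "rrpp_fit",
    "group_design",
    "rrpp_pairwise",
]


@dataclass
class Phylogeny:
    """A rooted, branch-length-bearing tree (dendropy-backed)."""

    tree: "object"  # dendropy.Tree
    tip_labels: list[str]
    ultrametric: bool

    def __len__(self) -> int:
        return len(self.tip_labels)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.tree.as_string(schema="newick"))


@dataclass
class PhyloCovariance:
    """Brownian-motion tip covariance with its tip ordering."""

    C: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.tip_order)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape must match tip count")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("covariance must be symmetric")

    def reorder(self, tips: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tips]
        return PhyloCovariance(self.C[np.ix_(idx, idx)], list(tips))


@dataclass
class LambdaFit:
    """Result of a lambda-optimised GLS fit."""

    lambda_raw: float
    lambda_used: float
    log_lik: float
    beta: np.ndarray
    sigma2: float
    trace: list[tuple[float, float]] = field(default_factory=list)
    method: str = "ML"


@dataclass
class RRPPFit:
    """Permutation linear-model result."""

    F: float
    R2: float
    p: float
    coefficients: np.ndarray
    n_perm: int
    seed: int
    df_effect: int
    df_resid: int
    perm_F: np.ndarray = field(default_factory=lambda: np.empty(0))
    perm_Y: np.ndarray | None = None
    X_full: np.ndarray | None = None
    yt: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Tree I/O and covariance


def _as_phylogeny(tree) -> Phylogeny:
    import dendropy

    if isinstance(tree, Phylogeny):
        return tree
    if isinstance(tree, str) and ";" in tree:
        try:
            t = dendropy.Tree.get(data=tree, schema="newick")
        except Exception as exc:
            raise ValueError(f"invalid newick (duplicate tips or malformed): {exc}") from exc
        return _wrap_tree(t)
    raise TypeError(f"cannot interpret {type(tree)} as a phylogeny")


def _wrap_tree(t) -> Phylogeny:
    labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dups}")
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
    depths = _tip_depths(t)
    height = max(depths.values())
    ultra = (max(depths.values()) - min(depths.values())) <= 1e-6 * max(height, 1e-12)
    return Phylogeny(tree=t, tip_labels=labels, ultrametric=ultra)


def _tip_depths(t) -> dict[str, float]:
    depths = {}
    node_depth = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node_depth[node]
    return depths


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    import dendropy

    t = dendropy.Tree.get(path=str(path), schema="newick")
    return _wrap_tree(t)


def vcv(tree: Phylogeny | str) -> PhyloCovariance:
    """Brownian covariance: C[i, j] = shared root-to-MRCA path length."""
    phy = _as_phylogeny(tree)
    t = phy.tree
    labels = phy.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    node_depth = {t.seed_node: 0.0}
    # postorder: each internal node's depth is the shared path length of
    # every pair of tips whose MRCA it is
    leafsets: dict = {}
    for node in t.preorder_node_iter():
        if node is not t.seed_node:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node.taxon.label]]
            C[leafsets[node][0], leafsets[node][0]] = node_depth[node]
        else:
            children = [leafsets[ch] for ch in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = node_depth[node]
            leafsets[node] = [i for ch in children for i in ch]
    return PhyloCovariance(C, labels)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariance by lambda (Pagel's transform).

    Valid for lambda in [0, 1]; out-of-range values must be clamped by the
    caller (the fit applies the clamping rule, not the transform).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = C.C * lam
    np.fill_diagonal(out, np.diag(C.C))
    return PhyloCovariance(out, list(C.tip_order))


# ---------------------------------------------------------------------------
# Lambda estimation


def _gls_loglik(y: np.ndarray, X: np.ndarray, C: np.ndarray, method: str) -> tuple[float, np.ndarray, float]:
    n, p = X.shape
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(p, np.nan), np.nan
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtX = Xi.T @ Xi
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    r = yi - Xi @ beta
    rss = float(r @ r)
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:  # REML
        sigma2 = rss / (n - p)
        sign, logdet_xx = np.linalg.slogdet(XtX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdet + logdet_xx + (n - p))
    return float(ll), beta, float(sigma2)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def fit_lambda_gls(
    y: np.ndarray,
    X: np.ndarray,
    tree: Phylogeny | PhyloCovariance,
    method: str = "ML",
    bounds: tuple[float, float] = (-0.5, 1.5),
    tol: float = 1e-6,
) -> LambdaFit:
    """Estimate Pagel's lambda by maximising the GLS likelihood.

    The unconstrained optimum over ``bounds`` is found by bounded scalar
    minimisation; the usable lambda is then clamped to [0, 1] (negative
    estimates become 0, estimates above 1 become 1), and the returned
    coefficients refer to the clamped covariance.  ``method`` selects the
    ML (default, consistent with the ordination steps) or REML criterion.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size:
        raise ValueError("y and X row counts differ")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    if n < p + 2:
        raise ValueError(f"need at least p+2={p+2} observations, got {n}")
    cov = tree if isinstance(tree, PhyloCovariance) else vcv(tree)
    C = cov.C
    trace: list[tuple[float, float]] = []

    def nll(lam: float) -> float:
        ll, _, _ = _gls_loglik(y, X, _lambda_cov(C, lam), method)
        trace.append((float(lam), ll))
        return -ll

    res = optimize.minimize_scalar(nll, bounds=bounds, method="bounded", options={"xatol": tol})
    # guard against local dips: take the best lambda ever probed
    probed = max(trace, key=lambda t: t[1])
    lam_raw = res.x if -res.fun >= probed[1] else probed[0]
    lam_used = float(np.clip(lam_raw, 0.0, 1.0))
    ll, beta, sigma2 = _gls_loglik(y, X, _lambda_cov(C, lam_used), method)
    return LambdaFit(
        lambda_raw=float(lam_raw), lambda_used=lam_used, log_lik=ll,
        beta=beta, sigma2=sigma2, trace=trace, method=method,
    )


# ---------------------------------------------------------------------------
# RRPP


def inverse_sqrt(C: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    Eigenvalues below ``rtol``·max are treated as rank deficiency and raise
    rather than being pseudo-inverted.
    """
    C = np.asarray(C, dtype=float)
    evals, evecs = np.linalg.eigh(C)
    if evals[-1] <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    if evals[0] < rtol * evals[-1]:
        raise np.linalg.LinAlgError(
            f"covariance is numerically singular (condition {evals[-1]/max(evals[0],1e-300):.2e})"
        )
    return (evecs * evals**-0.5) @ evecs.T


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.solve(X.T @ X, X.T)


def rrpp_fit(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    C_lambda: PhyloCovariance | np.ndarray | None,
    n_perm: int = 999,
    seed: int = 0,
) -> RRPPFit:
    """Residual-randomization permutation test of full vs reduced model.

    ``y`` and the designs are whitened by the inverse square root of the
    (lambda-scaled) phylogenetic covariance; pass ``None`` or the identity
    for a non-phylogenetic test.  The observed F compares the OLS fits of
    the two whitened models; the null distribution permutes reduced-model
    residuals (seeded) and re-adds them to the reduced fit.  The p-value
    counts the observed statistic (``p >= 1/(n_perm+1)``).  R² is the
    effect sum of squares over the reduced-model sum of squares.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float).ravel()
    Xf = np.atleast_2d(np.asarray(X_full, dtype=float))
    Xr = np.atleast_2d(np.asarray(X_reduced, dtype=float))
    if Xf.shape[0] != y.size:
        Xf = Xf.T
    if Xr.shape[0] != y.size:
        Xr = Xr.T
    n = y.size
    if C_lambda is None:
        P = np.eye(n)
    else:
        Cmat = C_lambda.C if isinstance(C_lambda, PhyloCovariance) else np.asarray(C_lambda)
        P = inverse_sqrt(Cmat)
    yt, Xft, Xrt = P @ y, P @ Xf, P @ Xr
    if np.allclose(yt, yt[0]):
        raise ValueError("response is constant after transformation")
    Hf, Hr = _hat(Xft), _hat(Xrt)
    df_f = np.linalg.matrix_rank(Xft)
    df_r = np.linalg.matrix_rank(Xrt)
    df_effect = df_f - df_r
    df_resid = n - df_f
    if df_effect < 1 or df_resid < 1:
        raise ValueError("degenerate degrees of freedom")
    fitted_r = Hr @ yt
    resid_r = yt - fitted_r
    Rf = np.eye(n) - Hf

    def f_stat(Y: np.ndarray) -> np.ndarray:
        # Y: (m, n) rows of responses
        rss_f = np.einsum("ij,ij->i", Y @ Rf, Y)
        rss_r = np.einsum("ij,ij->i", Y @ (np.eye(n) - Hr), Y)
        return ((rss_r - rss_f) / df_effect) / (rss_f / df_resid)

    F_obs = float(f_stat(yt[None, :])[0])
    rss_f = float(yt @ Rf @ yt)
    rss_r = float(resid_r @ resid_r)
    R2 = (rss_r - rss_f) / rss_r if rss_r > 0 else 0.0
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y_perm = fitted_r[None, :] + resid_r[perms]
    F_perm = f_stat(Y_perm)
    p = (1 + int(np.count_nonzero(F_perm >= F_obs))) / (n_perm + 1)
    beta = np.linalg.solve(Xft.T @ Xft, Xft.T @ yt)
    return RRPPFit(
        F=F_obs, R2=float(R2), p=float(p), coefficients=beta,
        n_perm=n_perm, seed=seed, df_effect=df_effect, df_resid=df_resid,
        perm_F=F_perm, perm_Y=Y_perm, X_full=Xft, yt=yt,
    )


def group_design(
    groups: np.ndarray | list,
    covariate: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Build full/reduced design matrices for a one-way (AN(C)OVA) model.

    Returns ``(X_full, X_reduced, predict_rows, levels)``: the full design
    is intercept + treatment-coded group dummies (+ covariate); the reduced
    design drops the dummies.  ``predict_rows`` has one row per group level
    with the covariate, if any, held at its overall mean — multiplying by
    fitted coefficients gives least-squares group means.
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    n = groups.size
    dummies = np.stack([(groups == g).astype(float) for g in levels[1:]], axis=1) if len(levels) > 1 else np.empty((n, 0))
    cols = [np.ones(n), *dummies.T]
    red_cols = [np.ones(n)]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float).ravel()
        cols.append(cov)
        red_cols.append(cov)
    X_full = np.column_stack(cols)
    X_reduced = np.column_stack(red_cols)
    k = len(levels)
    pred = np.zeros((k, X_full.shape[1]))
    pred[:, 0] = 1.0
    for i in range(1, k):
        pred[i, i] = 1.0
    if covariate is not None:
        pred[:, -1] = float(np.mean(covariate))
    return X_full, X_reduced, pred, levels


def rrpp_pairwise(
    fit: RRPPFit,
    groups: np.ndarray | list,
    predict_rows: np.ndarray,
    levels: list | None = None,
) -> list[dict]:
    """Pairwise distances between group least-squares means with
    permutation p-values from the omnibus schedule.

    LS means are ``predict_rows @ beta`` (see :func:`group_design`), with
    coefficients re-estimated for every stored permutation of the omnibus
    fit, so the pairwise tests share the omnibus null resampling.  Groups
    with fewer than 2 members are flagged with a missing p-value.
    """
    if fit.perm_Y is None or fit.X_full is None or fit.yt is None:
        raise ValueError("fit was not run with permutation storage")
    groups = np.asarray(groups)
    if levels is None:
        levels = sorted(set(groups.tolist()))
    Xft = fit.X_full
    XtXi = np.linalg.inv(Xft.T @ Xft)
    proj = XtXi @ Xft.T  # beta = proj @ y
    obs = predict_rows @ (proj @ fit.yt)
    perm_means = fit.perm_Y @ proj.T @ predict_rows.T
    counts = {g: int(np.count_nonzero(groups == g)) for g in levels}
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            d_obs = abs(obs[a] - obs[b])
            if counts[levels[a]] < 2 or counts[levels[b]] < 2:
                rows.append({"group_a": levels[a], "group_b": levels[b],
                             "distance": float(d_obs), "p": float("nan"),
                             "flag": "group with < 2 members"})
                continue
            d_perm = np.abs(perm_means[:, a] - perm_means[:, b])
            p = (1 + int(np.count_nonzero(d_perm >= d_obs))) / (len(d_perm) + 1)
            rows.append({"group_a": levels[a], "group_b": levels[b],
                         "distance": float(d_obs), "p": float(p), "flag": ""})
    return rows
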