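"""Comparative inference chain for trabecular parameters vs locomotor type.

The chain mirrors a standard phylogenetically informed workflow:

1. estimate each specimen's body mass (BMsp, natural log grams) from the
   total volume of its VOI through a lambda-optimised ln-ln phylogenetic
   regression of species mean mass on species mean TV;
2. screen each parameter for correlation with BMsp (RRPP regression on the
   lambda-rescaled tree); significantly size-correlated parameters are
   analysed by ANCOVA with BMsp as covariate, the rest by ANOVA;
3. pairwise contrasts between locomotor types reuse the omnibus
   permutation schedule;
4. inter-limb ratios (humeral head / femoral head; humeral trochlea /
   femoral lateral condyle) and per-group descriptive summaries;
5. phylogenetic PCA (GLS mean, evolutionary covariance, correlation mode)
   and a two-block partial least squares between locomotor type and a
   Brownian representation of the phylogeny.

Conspecific specimens are averaged to species values before any
phylogenetic fit; specimen-level values remain in descriptive tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import (
    LambdaFit,
    Phylogeny,
    PhyloCovariance,
    RRPPFit,
    fit_lambda_gls,
    group_design,
    inverse_sqrt,
    lambda_transform,
    rrpp_fit,
    rrpp_pairwise,
    vcv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ANCOVAResult",
    "PPCAResult",
    "PLSResult",
    "estimate_specimen_mass",
    "size_screen",
    "interlimb_ratios",
    "descriptive_stats",
    "phylogenetic_pca",
    "phylo_two_block_pls",
    "species_means",
]

#: Inter-limb ratio pairing: numerator VOI / denominator VOI.
RATIO_PAIRS = {
    "proximal": ("humeral_head", "femoral_head"),
    "distal": ("humeral_trochlea", "femoral_lateral_condyle"),
}


@dataclass
class ANCOVAResult:
    """Size screen + omnibus AN(C)OVA outcome for one parameter/VOI."""

    parameter: str
    voi_type: str
    size_correlated: bool
    size_p: float
    lambda_used: float
    lambda_raw: float
    F: float
    R2: float
    p: float
    model: str  # "ANOVA" or "ANCOVA"
    pairwise: list[dict]
    size_residuals: pd.Series | None = None


@dataclass
class PPCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: np.ndarray
    mode: str = "correlation"


@dataclass
class PLSResult:
    rPLS: float
    p: float
    n_perm: int
    seed: int
    block2_kind: str = "phylo_sqrt_C"


def species_means(df: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Average conspecific specimens to species rows (numeric columns)."""
    if value_cols is None:
        value_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    return df.groupby("species", as_index=True)[value_cols].mean()


def estimate_specimen_mass(
    tv: pd.Series,
    species: pd.Series,
    species_mass: dict[str, float] | pd.Series,
    tree: Phylogeny,
    lambda_method: str = "REML",
) -> tuple[pd.Series, LambdaFit]:
    """Estimate per-specimen body mass (ln g) from VOI total volume.

    Fits ln(species mean mass) ~ ln(species mean TV) by lambda-optimised
    GLS at species level, then predicts every specimen from its own TV.
    Returns the ln-gram predictions (indexed like ``tv``) and the fit.
    """
    tv = pd.Series(np.asarray(tv, dtype=float), index=tv.index if hasattr(tv, "index") else None)
    if (tv <= 0).any():
        raise ValueError("TV must be positive for log-log regression")
    species = pd.Series(species)
    mass = pd.Series(species_mass, dtype=float)
    sp_tv = pd.DataFrame({"species": species.values, "tv": tv.values}).groupby("species")["tv"].mean()
    missing_mass = sorted(set(sp_tv.index) - set(mass.index))
    if missing_mass:
        raise ValueError(f"species missing a mass entry: {missing_mass}")
    missing_tip = sorted(set(sp_tv.index) - set(tree.tip_labels))
    if missing_tip:
        raise ValueError(f"species missing from the tree: {missing_tip}")
    order = [t for t in tree.tip_labels if t in sp_tv.index]
    y = np.log(mass.loc[order].values)
    x = np.log(sp_tv.loc[order].values)
    X = np.column_stack([np.ones_like(x), x])
    cov = vcv(tree).reorder(order)
    fit = fit_lambda_gls(y, X, cov, method=lambda_method)
    pred = fit.beta[0] + fit.beta[1] * np.log(tv.values)
    return pd.Series(pred, index=tv.index, name="BMsp"), fit


def _species_table(
    values: pd.Series, bmsp: pd.Series, types: pd.Series, species: pd.Series
) -> pd.DataFrame:
    df = pd.DataFrame({
        "species": species.values, "value": np.asarray(values, dtype=float),
        "bmsp": np.asarray(bmsp, dtype=float), "type": types.values,
    })
    n0 = len(df)
    df = df.dropna(subset=["value", "bmsp"])
    if len(df) < n0:
        logger.info("size_screen: dropped %d incomplete case(s)", n0 - len(df))
    sp = df.groupby("species").agg(value=("value", "mean"), bmsp=("bmsp", "mean"), type=("type", "first"))
    return sp


def size_screen(
    values: pd.Series,
    bmsp: pd.Series,
    types: pd.Series,
    species: pd.Series,
    tree: Phylogeny,
    parameter: str = "",
    voi_type: str = "",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    lambda_method: str = "REML",
) -> ANCOVAResult:
    """Size screen, AN(C)OVA routing, omnibus test and pairwise contrasts.

    Step 1 regresses the parameter on BMsp (RRPP on the lambda-rescaled
    covariance, lambda estimated under the same regression); a significant
    slope (p < alpha) routes the parameter to ANCOVA (type effect over
    BMsp-only reduced model), otherwise to ANOVA.  The omnibus and pairwise
    tests use a lambda estimated under the model actually tested (type +
    optional covariate), so a clustered group effect is not mistaken for
    phylogenetic signal.  Residuals of the size regression are kept for
    plotting ("sc" panels).  All fits act on species means.
    """
    sp = _species_table(values, bmsp, types, species)
    present = set(sp["type"])
    expected = set(types.unique())
    absent = sorted(expected - present)
    if absent:
        raise ValueError(f"locomotor type(s) with no data: {absent}")
    order = [t for t in tree.tip_labels if t in sp.index]
    sp = sp.loc[order]
    y = sp["value"].values
    x_bm = sp["bmsp"].values
    cov = vcv(tree).reorder(order)
    n = len(y)
    X_size = np.column_stack([np.ones(n), x_bm])
    X_int = np.ones((n, 1))
    lam_size = fit_lambda_gls(y, X_size, cov, method=lambda_method)
    size_fit = rrpp_fit(y, X_size, X_int, lambda_transform(cov, lam_size.lambda_used),
                        n_perm=n_perm, seed=seed)
    size_correlated = bool(size_fit.p < alpha)
    # residuals of the size regression, for visualization
    P = inverse_sqrt(lambda_transform(cov, lam_size.lambda_used).C)
    resid = y - X_size @ np.linalg.solve((P @ X_size).T @ (P @ X_size), (P @ X_size).T @ (P @ y))
    covariate = x_bm if size_correlated else None
    X_full, X_reduced, pred_rows, levels = group_design(sp["type"].values, covariate)
    lam_fit = fit_lambda_gls(y, X_full, cov, method=lambda_method)
    C_lam = lambda_transform(cov, lam_fit.lambda_used)
    omni = rrpp_fit(y, X_full, X_reduced, C_lam, n_perm=n_perm, seed=seed + 1)
    pairwise = rrpp_pairwise(omni, sp["type"].values, pred_rows, levels)
    return ANCOVAResult(
        parameter=parameter, voi_type=voi_type,
        size_correlated=size_correlated, size_p=float(size_fit.p),
        lambda_used=lam_fit.lambda_used, lambda_raw=lam_fit.lambda_raw,
        F=omni.F, R2=omni.R2, p=omni.p,
        model="ANCOVA" if size_correlated else "ANOVA",
        pairwise=pairwise,
        size_residuals=pd.Series(resid, index=sp.index, name=f"sc_{parameter}"),
    )


def interlimb_ratios(
    metrics: pd.DataFrame,
    parameters: list[str],
    voi_col: str = "voi_type",
    id_col: str = "specimen_id",
) -> pd.DataFrame:
    """Per-specimen inter-limb ratios of trabecular parameters.

    Proximal: humeral head / femoral head; distal: humeral trochlea /
    femoral lateral condyle.  Specimens missing one member of a pair are
    skipped (logged); zero denominators yield missing values (logged).
    """
    rows = []
    for region, (num_voi, den_voi) in RATIO_PAIRS.items():
        num = metrics[metrics[voi_col] == num_voi].set_index(id_col)
        den = metrics[metrics[voi_col] == den_voi].set_index(id_col)
        shared = num.index.intersection(den.index)
        skipped = sorted(set(num.index).symmetric_difference(den.index))
        if skipped:
            logger.info("interlimb_ratios %s: skipped specimen(s) missing one VOI: %s", region, skipped)
        for spec in shared:
            row: dict = {"specimen_id": spec, "region": region}
            if "species" in metrics.columns:
                row["species"] = num.loc[spec, "species"]
            for p in parameters:
                d = float(den.loc[spec, p])
                if d == 0:
                    logger.info("interlimb_ratios: zero denominator for %s/%s/%s", spec, region, p)
                    row[p] = np.nan
                else:
                    row[p] = float(num.loc[spec, p]) / d
            rows.append(row)
    return pd.DataFrame(rows)


def descriptive_stats(values: pd.Series, groups: pd.Series, parameter: str = "") -> pd.DataFrame:
    """Mean, sample sd, min and max per group plus a pooled row.

    Values are returned at full precision; round only at output (the
    summary tables print 2 decimals).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": groups.values}).dropna()
    rows = []
    for g, sub in df.groupby("group"):
        v = sub["value"].values
        rows.append({
            "parameter": parameter, "group": g, "n": len(v),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            "min": float(np.min(v)), "max": float(np.max(v)),
        })
    v = df["value"].values
    rows.append({
        "parameter": parameter, "group": "all", "n": len(v),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
        "min": float(np.min(v)), "max": float(np.max(v)),
    })
    return pd.DataFrame(rows)


def phylogenetic_pca(
    X: pd.DataFrame,
    tree: Phylogeny,
    mode: str = "correlation",
) -> PPCAResult:
    """Phylogenetic PCA on species-by-variable data.

    Removes the GLS (phylogenetic) mean, forms the evolutionary covariance
    ``R = (X − 1a)' C⁻¹ (X − 1a)/(n − 1)``, converts it to a correlation
    matrix in the default mode (the variables mix units), and
    eigen-decomposes.  Scores are the centred (and scaled, in correlation
    mode) data projected on the eigenvectors.
    """
    order = [t for t in tree.tip_labels if t in X.index]
    if len(order) != len(X):
        missing = sorted(set(X.index) - set(tree.tip_labels))
        raise ValueError(f"species missing from the tree: {missing}")
    Xv = X.loc[order].values.astype(float)
    names = list(X.columns)
    n, p = Xv.shape
    C = vcv(tree).reorder(order).C
    Ci = np.linalg.inv(C)
    one = np.ones((n, 1))
    a = np.linalg.solve(one.T @ Ci @ one, one.T @ Ci @ Xv)  # GLS mean, (1, p)
    Xc = Xv - one @ a
    R = Xc.T @ Ci @ Xc / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R))
        if np.any(d <= 0):
            bad = [names[i] for i in range(p) if d[i] <= 0]
            raise ValueError(f"zero evolutionary variance in variable(s): {bad}")
        R_use = R / np.outer(d, d)
        Xc_use = Xc / d
    else:
        R_use = R
        Xc_use = Xc
    rank = np.linalg.matrix_rank(R_use)
    if rank < p:
        corr = np.abs(R_use - np.eye(p))
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValueError(
            f"rank-deficient trait covariance (rank {rank} < {p}); most "
            f"collinear pair: {names[i]!r} / {names[j]!r}"
        )
    evals, evecs = np.linalg.eigh(R_use)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    # deterministic sign: largest-magnitude loading positive
    for k in range(p):
        jmax = np.argmax(np.abs(evecs[:, k]))
        if evecs[jmax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Xc_use @ evecs
    comp = [f"pPC{i+1}" for i in range(p)]
    return PPCAResult(
        scores=pd.DataFrame(scores, index=order, columns=comp),
        loadings=pd.DataFrame(evecs, index=names, columns=comp),
        percent_variance=100.0 * evals / evals.sum(),
        mode=mode,
    )


def phylo_two_block_pls(
    block1: pd.DataFrame | np.ndarray,
    block2: pd.DataFrame | np.ndarray | None,
    tree: Phylogeny,
    tip_order: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Two-block partial least squares under Brownian motion.

    With two trait blocks, both are GLS-centred and whitened by
    ``C^(-1/2)`` (the standard BM treatment), and rPLS is the correlation
    of the first singular-score pair of their cross-covariance.

    When ``block2`` is None the statistic instead measures how strongly
    block1 (here, locomotor type) aggregates on the tree: block2 becomes
    the leading principal-coordinate axes of the Brownian covariance
    (truncated at 95% of trace) and no whitening is applied — whitening
    would reinject the phylogeny into both blocks and void the test.  The
    p-value permutes the rows of block2 (seeded), counting the observed
    statistic.
    """
    if tip_order is None:
        if isinstance(block1, pd.DataFrame):
            tip_order = [t for t in tree.tip_labels if t in block1.index]
        else:
            tip_order = list(tree.tip_labels)
    C = vcv(tree).reorder(tip_order).C
    n = len(tip_order)
    B1 = block1.loc[tip_order].values.astype(float) if isinstance(block1, pd.DataFrame) else np.asarray(block1, dtype=float)
    if block2 is None:
        # phylogeny representation: leading principal coordinates of the
        # (double-centred) Brownian covariance, truncated at 95% of trace.
        # A full-rank representation would let the SVD correlate any block1
        # perfectly (rPLS degenerates to 1), so the rank must stay < n - 1.
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ C @ J
        evals, evecs = np.linalg.eigh(G)
        order_ = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order_], 0, None), evecs[:, order_]
        cum = np.cumsum(evals) / evals.sum()
        k = min(int(np.searchsorted(cum, 0.95) + 1), n - 2)
        B2 = evecs[:, :k] * np.sqrt(evals[:k])
        kind = "phylo_pcoa95"
        whiten = False
    else:
        B2 = block2.loc[tip_order].values.astype(float) if isinstance(block2, pd.DataFrame) else np.asarray(block2, dtype=float)
        kind = "user"
        whiten = True
    if B1.ndim == 1:
        B1 = B1[:, None]
    if B2.ndim == 1:
        B2 = B2[:, None]
    for name, B in (("block1", B1), ("block2", B2)):
        if np.allclose(B, B[0]):
            raise ValueError(f"{name} is constant")
    one = np.ones((n, 1))
    if whiten:
        P = inverse_sqrt(C)
        Ci = P @ P

        def prep(B: np.ndarray) -> np.ndarray:
            a = np.linalg.solve(one.T @ Ci @ one, one.T @ Ci @ B)
            return P @ (B - one @ a)
    else:

        def prep(B: np.ndarray) -> np.ndarray:
            return B - B.mean(axis=0, keepdims=True)

    T1 = prep(B1)

    def r_pls(B2_rows: np.ndarray) -> float:
        T2 = prep(B2_rows)
        S = T1.T @ T2 / (n - 1)
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        s1 = T1 @ U[:, 0]
        s2 = T2 @ Vt[0, :]
        denom = np.sqrt((s1 @ s1) * (s2 @ s2))
        if denom == 0:
            return 0.0
        return float(abs(s1 @ s2) / denom)

    r_obs = r_pls(B2)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r_pls(B2[perm]) >= r_obs:
            count += 1
    return PLSResult(rPLS=r_obs, p=count / (n_perm + 1), n_perm=n_perm, seed=seed, block2_kind=kind)
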