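"""Calibration experiments for the inferential machinery.

These experiments characterise the statistical behaviour of the pipeline
under known conditions: the type-I error of the RRPP permutation test on
null phylogenetic data, the separation of Pagel's lambda estimates between
Brownian and independent data, and the end-to-end recovery of the
synthetic study's configured effects (natatorial bone-fraction shift,
ANOVA/ANCOVA routing, lambda).  They are used by both the test suite and
the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparative as CP
from . import phylo as P
from . import synthetic as S

__all__ = [
    "rrpp_type_one_rate",
    "lambda_recovery_rates",
    "StudyRecovery",
    "study_recovery",
]


def rrpp_type_one_rate(
    n_datasets: int = 500,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the RRPP group test on null data.

    Each dataset simulates a trait under Brownian motion (lambda = 1, no
    group effect) on a 29-tip tree with the study's clustered four-type
    assignment; the test uses the correct covariance.  A calibrated test
    rejects at close to ``alpha``.
    """
    tree = S.simulate_tree(29, seed=seed)
    cov = P.vcv(tree)
    types = S._assign_types(tree, {"fossorial": 7, "generalized": 9,
                                   "natatorial": 6, "scansorial": 7})
    order = cov.tip_order
    groups = np.array([types[t] for t in order])
    Xf, Xr, _, _ = P.group_design(groups)
    rejections = 0
    for i in range(n_datasets):
        y = S.simulate_traits(tree, lam=1.0, sigma2=1.0, seed=seed * 100003 + i)
        fit = P.rrpp_fit(y.loc[order].values, Xf, Xr, cov,
                         n_perm=n_perm, seed=seed * 7 + i)
        rejections += fit.p < alpha
    return rejections / n_datasets


def lambda_recovery_rates(
    n_rep: int = 50,
    n_tips: int = 128,
    seed: int = 0,
) -> tuple[float, float]:
    """(high, low): fraction of BM replicates with lambda >= 0.9 and of
    iid replicates with lambda <= 0.1, intercept-only model."""
    tree = S.simulate_tree(n_tips, seed=seed)
    cov = P.vcv(tree)
    rng = np.random.default_rng(seed + 1)
    ones = np.ones((n_tips, 1))
    hi = lo = 0
    for rep in range(n_rep):
        y_bm = S.simulate_traits(tree, lam=1.0, sigma2=1.0, seed=seed * 1009 + rep)
        fit = P.fit_lambda_gls(y_bm.loc[cov.tip_order].values, ones, cov)
        hi += fit.lambda_used >= 0.9
        y_iid = rng.standard_normal(n_tips)
        fit = P.fit_lambda_gls(y_iid, ones, cov)
        lo += fit.lambda_used <= 0.1
    return hi / n_rep, lo / n_rep


@dataclass
class StudyRecovery:
    """End-to-end recovery summary over synthetic-study replicates."""

    n_rep: int
    natatorial_power: float  # >= 2 of 3 natatorial pairwise contrasts significant
    omnibus_power: float  # omnibus type test significant for BV/TV
    routing_accuracy: float  # BVTV -> ANOVA and BS -> ANCOVA
    lambda_hat_mean: float  # mean lambda estimate for the no-effect DA trait
    lambda_true: float


def study_recovery(n_rep: int = 50, seed: int = 0, alpha: float = 0.05) -> StudyRecovery:
    """Run the comparative chain on replicate synthetic studies.

    Per replicate: estimate BMsp from humeral-head TV, then size-screen
    BV/TV (configured +2 sd natatorial effect, no size effect) and BS
    (configured size effect, no group effect).  The natatorial effect
    counts as detected when a majority (at least two of three) of the
    natatorial pairwise contrasts is significant; the omnibus rejection
    rate is reported alongside.  Routing is correct when BV/TV takes the
    ANOVA route and BS the ANCOVA route.  Lambda recovery is tracked on
    DA, which carries no effects.
    """
    detected = routed = omni = 0
    lambda_hats = []
    cfg0 = S.StudyConfig()
    for rep in range(n_rep):
        study = S.make_synthetic_study(S.StudyConfig(seed=seed + 1000 * rep))
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        type_map = study.specimens.drop_duplicates("species").set_index("species")["habit"]
        types = hh["species"].map(type_map)
        bmsp, _ = CP.estimate_specimen_mass(hh["TV"], hh["species"],
                                            study.species_mass, study.tree)
        res_bvtv = CP.size_screen(hh["BVTV"], bmsp, types, hh["species"],
                                  study.tree, parameter="BVTV", seed=seed + rep)
        res_bs = CP.size_screen(hh["BS"], bmsp, types, hh["species"],
                                study.tree, parameter="BS", seed=seed + rep)
        res_da = CP.size_screen(hh["DA"], bmsp, types, hh["species"],
                                study.tree, parameter="DA", seed=seed + rep)
        nata = [r for r in res_bvtv.pairwise
                if "natatorial" in (r["group_a"], r["group_b"])]
        n_sig = sum(r["p"] < alpha for r in nata)
        detected += n_sig >= 2
        omni += res_bvtv.p < alpha
        routed += (res_bvtv.model == "ANOVA") and (res_bs.model == "ANCOVA")
        lambda_hats.append(res_da.lambda_used)
    return StudyRecovery(
        n_rep=n_rep,
        natatorial_power=detected / n_rep,
        omnibus_power=omni / n_rep,
        routing_accuracy=routed / n_rep,
        lambda_hat_mean=float(np.mean(lambda_hats)),
        lambda_true=cfg0.lam,
    )
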