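"""Body-mass estimation, AN(C)OVA routing, ratios, ordination and PLS."""

import numpy as np
import pandas as pd
import pytest

import dendropy

from trabarch import comparative as CP
from trabarch import phylo as P
from trabarch import synthetic as S
from trabarch.phylo import _wrap_tree


@pytest.fixture(scope="module")
def study():
    return S.make_synthetic_study(S.StudyConfig(seed=7))


@pytest.fixture(scope="module")
def species_types(study):
    return study.specimens.drop_duplicates("species").set_index("species")["habit"]


def star_tree(n: int, labels=None):
    labels = labels or [f"t{i}" for i in range(n)]
    nwk = "(" + ",".join(f"{l}:1.0" for l in labels) + ");"
    return _wrap_tree(dendropy.Tree.get(data=nwk, schema="newick"))


class TestBodyMass:
    def test_exact_line_reproduced(self, study):
        """Data on ln(mass) = 2 + 1·ln(TV) are interpolated exactly."""
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        sp_tv = hh.groupby("species")["TV"].mean()
        mass = np.exp(2.0 + 1.0 * np.log(sp_tv))
        # give every specimen its species-mean TV so predictions sit on the line
        hh2 = hh.copy()
        hh2["TV"] = hh2["species"].map(sp_tv)
        bmsp, fit = CP.estimate_specimen_mass(hh2["TV"], hh2["species"], mass, study.tree)
        assert np.allclose(bmsp.values, 2.0 + np.log(hh2["TV"].values), atol=1e-8)
        assert fit.beta[1] == pytest.approx(1.0, abs=1e-8)

    def test_equal_tv_equal_bmsp(self, study):
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        hh2 = pd.concat([hh, hh.iloc[[0]]], ignore_index=True)
        bmsp, _ = CP.estimate_specimen_mass(hh2["TV"], hh2["species"], study.species_mass, study.tree)
        assert bmsp.iloc[0] == bmsp.iloc[-1]

    def test_allometric_slope_recovered(self):
        """Slope-1 allometry with BM noise in the response is recovered
        within 2 standard errors over replicates."""
        slopes = []
        for rep in range(10):
            tree = S.simulate_tree(29, seed=300 + rep)
            ln_tv = S.simulate_traits(tree, lam=1.0, sigma2=0.5, seed=400 + rep,
                                      baseline=4.3)
            resid = S.simulate_traits(tree, lam=1.0, sigma2=0.1, seed=500 + rep)
            mass = np.exp(2.0 + 1.0 * ln_tv + resid)
            tv = pd.Series(np.exp(ln_tv.values), index=range(len(ln_tv)))
            species = pd.Series(ln_tv.index, index=tv.index)
            _, fit = CP.estimate_specimen_mass(tv, species, mass, tree)
            slopes.append(fit.beta[1])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.0) < 2 * max(se, 0.02)

    def test_negative_tv_rejected(self, study):
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        bad = hh.copy()
        bad.loc[0, "TV"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            CP.estimate_specimen_mass(bad["TV"], bad["species"], study.species_mass, study.tree)

    def test_missing_species_named(self, study):
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        mass = study.species_mass.drop(hh["species"].iloc[0])
        with pytest.raises(ValueError, match=hh["species"].iloc[0]):
            CP.estimate_specimen_mass(hh["TV"], hh["species"], mass, study.tree)


def _screen(study, param, alpha=0.05, seed=0):
    hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
    types = hh["species"].map(
        study.specimens.drop_duplicates("species").set_index("species")["habit"])
    bmsp, _ = CP.estimate_specimen_mass(hh["TV"], hh["species"], study.species_mass, study.tree)
    return CP.size_screen(hh[param], bmsp, types, hh["species"], study.tree,
                          parameter=param, alpha=alpha, seed=seed)


class TestSizeScreen:
    def test_size_coupled_parameter_routes_to_ancova(self, study):
        res = _screen(study, "BS")
        assert res.size_correlated
        assert res.model == "ANCOVA"

    def test_group_effect_detected_by_anova_route(self, study):
        res = _screen(study, "BVTV")
        assert res.model == "ANOVA"
        assert res.p < 0.05
        nata = [r for r in res.pairwise
                if "natatorial" in (r["group_a"], r["group_b"])]
        assert sum(r["p"] < 0.05 for r in nata) >= 2

    def test_alpha_forces_routing(self, study):
        assert _screen(study, "DA", alpha=1.0).model == "ANCOVA"
        assert _screen(study, "DA", alpha=0.0).model == "ANOVA"

    def test_residuals_exported_for_plotting(self, study):
        res = _screen(study, "BS")
        assert res.size_residuals is not None
        assert res.size_residuals.abs().sum() > 0

    def test_missing_type_rejected(self, study):
        hh = study.metrics[study.metrics.voi_type == "humeral_head"].reset_index(drop=True)
        types = hh["species"].map(
            study.specimens.drop_duplicates("species").set_index("species")["habit"]).copy()
        bmsp, _ = CP.estimate_specimen_mass(hh["TV"], hh["species"], study.species_mass, study.tree)
        values = hh["DA"].copy()
        values[types == "natatorial"] = np.nan  # all natatorial rows dropped
        with pytest.raises(ValueError, match="natatorial"):
            CP.size_screen(values, bmsp, types, hh["species"], study.tree)


class TestRatios:
    def test_identical_metrics_give_unit_ratio(self, study):
        m = study.metrics.copy()
        for par in ("DA", "BVTV"):
            m[par] = 0.5
        out = CP.interlimb_ratios(m, ["DA", "BVTV"])
        assert np.allclose(out["DA"], 1.0)
        assert np.allclose(out["BVTV"], 1.0)

    def test_ratio_arithmetic(self):
        m = pd.DataFrame([
            {"specimen_id": "s1", "voi_type": "humeral_head", "DA": 0.50},
            {"specimen_id": "s1", "voi_type": "femoral_head", "DA": 0.58},
        ])
        out = CP.interlimb_ratios(m, ["DA"])
        assert out.loc[out.region == "proximal", "DA"].iloc[0] == pytest.approx(0.862, abs=1e-3)

    def test_missing_member_skipped(self):
        m = pd.DataFrame([
            {"specimen_id": "s1", "voi_type": "humeral_head", "DA": 0.5},
            {"specimen_id": "s2", "voi_type": "humeral_head", "DA": 0.5},
            {"specimen_id": "s2", "voi_type": "femoral_head", "DA": 0.5},
        ])
        out = CP.interlimb_ratios(m, ["DA"])
        assert set(out["specimen_id"]) == {"s2"}

    def test_zero_denominator_gives_missing(self):
        m = pd.DataFrame([
            {"specimen_id": "s1", "voi_type": "humeral_head", "DA": 0.5},
            {"specimen_id": "s1", "voi_type": "femoral_head", "DA": 0.0},
        ])
        out = CP.interlimb_ratios(m, ["DA"])
        assert np.isnan(out["DA"].iloc[0])


class TestDescriptive:
    def test_known_stats(self):
        out = CP.descriptive_stats(pd.Series([9.0, 10.0, 11.0]),
                                   pd.Series(["a", "a", "a"]), "x")
        row = out[out.group == "a"].iloc[0]
        assert row["mean"] == 10.0
        assert row["sd"] == pytest.approx(1.0)
        assert (row["min"], row["max"]) == (9.0, 11.0)

    def test_single_value_degenerate(self):
        out = CP.descriptive_stats(pd.Series([5.0]), pd.Series(["a"]), "x")
        row = out[out.group == "a"].iloc[0]
        assert np.isnan(row["sd"])
        assert row["min"] == row["max"] == 5.0

    def test_pooled_row_present(self):
        out = CP.descriptive_stats(pd.Series([1.0, 2.0, 3.0, 4.0]),
                                   pd.Series(["a", "a", "b", "b"]), "x")
        assert "all" in set(out.group)
        assert out[out.group == "all"].iloc[0]["n"] == 4


class TestPPCA:
    def test_star_tree_matches_ordinary_pca(self):
        rng = np.random.default_rng(4)
        st = star_tree(12)
        X = pd.DataFrame(rng.standard_normal((12, 4)),
                         index=st.tip_labels, columns=list("abcd"))
        pp = CP.phylogenetic_pca(X, st)
        Z = (X - X.mean()) / X.std(ddof=1)
        ev, evec = np.linalg.eigh(np.cov(Z.values.T, ddof=1))
        idx = np.argsort(ev)[::-1]
        ev, evec = ev[idx], evec[:, idx]
        for k in range(4):
            j = np.argmax(np.abs(evec[:, k]))
            if evec[j, k] < 0:
                evec[:, k] = -evec[:, k]
        assert np.allclose(pp.loadings.values, evec, atol=1e-8)
        assert np.allclose(pp.scores.loc[X.index].values, Z.values @ evec, atol=1e-8)
        assert np.allclose(pp.percent_variance, 100 * ev / ev.sum(), atol=1e-8)

    def test_duplicated_variable_rejected(self, study, species_types):
        sp = CP.species_means(
            study.metrics[study.metrics.voi_type == "humeral_head"],
            ["DA", "BVTV"])
        sp["DA2"] = sp["DA"]
        with pytest.raises(ValueError, match="rank|collinear"):
            CP.phylogenetic_pca(sp, study.tree)

    def test_percent_variance_sums_to_100(self, study):
        sp = CP.species_means(
            study.metrics[study.metrics.voi_type == "humeral_head"],
            ["DA", "BVTV", "TbTh", "TbSp"])
        pp = CP.phylogenetic_pca(sp, study.tree)
        assert pp.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_scores_translation_invariant(self, study):
        sp = CP.species_means(
            study.metrics[study.metrics.voi_type == "humeral_head"],
            ["DA", "BVTV", "TbTh"])
        p1 = CP.phylogenetic_pca(sp, study.tree)
        p2 = CP.phylogenetic_pca(sp + 100.0, study.tree)
        assert np.allclose(p1.scores.values, p2.scores.values, atol=1e-8)


class TestPLS:
    def test_self_correlation_is_one(self, study, species_types):
        d = pd.get_dummies(species_types).astype(float)
        res = CP.phylo_two_block_pls(d, d, study.tree, n_perm=99, seed=0)
        assert res.rPLS == pytest.approx(1.0, abs=1e-9)

    def test_clustered_types_aggregate_on_tree(self, study, species_types):
        d = pd.get_dummies(species_types).astype(float)
        res = CP.phylo_two_block_pls(d, None, study.tree, n_perm=499, seed=1)
        assert res.rPLS > 0.8
        assert res.p < 0.05

    def test_null_p_spread_roughly_uniform(self, study, species_types):
        d = pd.get_dummies(species_types).astype(float)
        ps = []
        for s in range(12):
            shuffled = d.sample(frac=1, random_state=100 + s).set_index(d.index)
            ps.append(CP.phylo_two_block_pls(shuffled, None, study.tree,
                                             n_perm=99, seed=s).p)
        assert min(ps) < 0.35
        assert max(ps) > 0.65

    def test_rpls_invariant_to_orthogonal_rotation(self, study, species_types):
        rng = np.random.default_rng(3)
        d = pd.get_dummies(species_types).astype(float)
        B2 = pd.DataFrame(rng.standard_normal((len(d), 4)), index=d.index)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        B2rot = pd.DataFrame(B2.values @ Q, index=d.index)
        r1 = CP.phylo_two_block_pls(d, B2, study.tree, n_perm=99, seed=2).rPLS
        r2 = CP.phylo_two_block_pls(d, B2rot, study.tree, n_perm=99, seed=2).rPLS
        assert r1 == pytest.approx(r2, rel=1e-8)

    def test_constant_block_rejected(self, study, species_types):
        d = pd.get_dummies(species_types).astype(float)
        const = pd.DataFrame(np.ones((len(d), 2)), index=d.index)
        with pytest.raises(ValueError, match="constant"):
            CP.phylo_two_block_pls(d, const, study.tree, n_perm=99, seed=0)
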