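"""Run the comparative inference chain on the synthetic study.

Reads the study bundle written by 01_simulate_study.py (regenerating it if
absent), then for the humeral-head VOI: estimates specimen body mass
(BMsp) from TV, screens every trabecular parameter for size correlation,
routes each to a phylogenetic ANOVA or ANCOVA with pairwise contrasts,
and produces the descriptive group summaries, inter-limb ratios,
phylogenetic PCA over all VOIs + BMsp, and the locomotor-type vs
phylogeny two-block PLS.

Outputs under results/comparative/: descriptive_stats.csv, ancova_summary.csv,
pairwise.csv, ratios.csv, ppca_scores.csv, ppca_loadings.csv, pls.json,
boxplot_bvtv.svg, scatter_ppca.svg.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("svg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from trabarch import comparative as CP
from trabarch import phylo as P
from trabarch import synthetic as S

ROOT = Path(__file__).resolve().parents[1]
PARAMS = ["DA", "ConnD", "BVTV", "TbTh", "TbSp", "BS"]


def load_study(study_dir: Path, seed: int):
    if not (study_dir / "metrics.csv").exists():
        S.make_synthetic_study(S.StudyConfig(seed=seed), out_dir=study_dir)
    metrics = pd.read_csv(study_dir / "metrics.csv")
    specimens = pd.read_csv(study_dir / "specimens.csv")
    mass = pd.read_csv(study_dir / "species_mass.csv").set_index("species")["mass_g"]
    tree = P.read_newick(study_dir / "tree.nwk")
    return metrics, specimens, mass, tree


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "synthetic_study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "comparative")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    metrics, specimens, mass, tree = load_study(args.study, args.seed)
    type_map = specimens.drop_duplicates("species").set_index("species")["habit"]
    hh = metrics[metrics.voi_type == "humeral_head"].reset_index(drop=True)
    types = hh["species"].map(type_map)

    bmsp, mass_fit = CP.estimate_specimen_mass(hh["TV"], hh["species"], mass, tree)
    print(f"BMsp allometry: ln(mass) = {mass_fit.beta[0]:.3f} + "
          f"{mass_fit.beta[1]:.3f} ln(TV), lambda = {mass_fit.lambda_used:.3f}")

    desc, summary, pairwise = [], [], []
    residuals = {}
    for par in PARAMS:
        desc.append(CP.descriptive_stats(hh[par], types, par))
        res = CP.size_screen(hh[par], bmsp, types, hh["species"], tree,
                             parameter=par, voi_type="humeral_head", seed=args.seed)
        summary.append({
            "parameter": par, "SC": res.size_correlated, "model": res.model,
            "lambda": round(res.lambda_used, 3), "F": round(res.F, 3),
            "R2": round(res.R2, 3), "p": res.p,
        })
        for row in res.pairwise:
            pairwise.append({"parameter": par, **row})
        residuals[par] = res.size_residuals
        marker = "*" if res.p < 0.05 else " "
        print(f"  {par:6s} {res.model:6s} lambda={res.lambda_used:.2f} "
              f"F={res.F:6.2f} p={res.p:.3f}{marker}")

    pd.concat(desc).to_csv(out / "descriptive_stats.csv", index=False, float_format="%.4g")
    pd.DataFrame(summary).to_csv(out / "ancova_summary.csv", index=False)
    pd.DataFrame(pairwise).to_csv(out / "pairwise.csv", index=False, float_format="%.4g")

    ratios = CP.interlimb_ratios(metrics, PARAMS)
    ratios.to_csv(out / "ratios.csv", index=False, float_format="%.4g")

    # phylogenetic PCA over all VOIs plus BMsp
    sp_bmsp = pd.DataFrame({"species": hh["species"], "bmsp": bmsp}).groupby("species")["bmsp"].mean()
    blocks = []
    for voi in sorted(metrics.voi_type.unique()):
        sub = CP.species_means(metrics[metrics.voi_type == voi], PARAMS)
        sub.columns = [f"{voi}_{p}" for p in PARAMS]
        blocks.append(sub)
    X = pd.concat(blocks, axis=1)
    X["BMsp"] = sp_bmsp
    pp = CP.phylogenetic_pca(X, tree)
    pp.scores.to_csv(out / "ppca_scores.csv", float_format="%.5g")
    pp.loadings.to_csv(out / "ppca_loadings.csv", float_format="%.5g")
    cum3 = pp.percent_variance[:3].sum()
    print(f"pPCA: pPC1-3 explain {cum3:.1f}% "
          f"({', '.join(f'{v:.1f}%' for v in pp.percent_variance[:3])}); "
          f"BMsp loading on pPC1 = {pp.loadings.loc['BMsp', 'pPC1']:.2f}")

    dummies = pd.get_dummies(type_map).astype(float)
    pls = CP.phylo_two_block_pls(dummies, None, tree, n_perm=999, seed=args.seed)
    (out / "pls.json").write_text(json.dumps(
        {"rPLS": pls.rPLS, "p": pls.p, "n_perm": pls.n_perm,
         "block2": pls.block2_kind}, indent=2))
    print(f"two-block PLS (types vs phylogeny): rPLS = {pls.rPLS:.3f}, p = {pls.p:.4f}")

    # figures: BV/TV by locomotor type; pPC1 vs pPC2
    fig, ax = plt.subplots(figsize=(5, 4))
    order = sorted(types.unique())
    ax.boxplot([hh.loc[types == g, "BVTV"] for g in order], tick_labels=order)
    ax.set_ylabel("BV/TV")
    fig.tight_layout()
    fig.savefig(out / "boxplot_bvtv.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in order:
        sp = [s for s in pp.scores.index if type_map[s] == g]
        ax.scatter(pp.scores.loc[sp, "pPC1"], pp.scores.loc[sp, "pPC2"], label=g, s=18)
    ax.set_xlabel("pPC1")
    ax.set_ylabel("pPC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "scatter_ppca.svg")
    plt.close(fig)
    print(f"wrote tables and figures to {out}")


if __name__ == "__main__":
    main()
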