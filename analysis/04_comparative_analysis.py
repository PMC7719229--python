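"""Associate NHEJ state with genome size, growth rate and G-C content.

Runs the comparative battery: Wilcoxon rank-sum comparisons (tips as
independent points), Pagel's lambda and Blomberg's K for phylogenetic signal,
phylogenetic ANOVA across the five NHEJ states, Pagel's correlated-evolution
LRT for NHEJ vs binarized size and growth rate, and phylogenetic logistic
regression with VIF screening and AIC model choice.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nhejevo.correlated import binarize, correlated_evolution
from nhejevo.phyloglm import phyloglm_model_choice, vif
from nhejevo.resampling import wilcoxon_compare
from nhejevo.signal import blomberg_k, pagel_lambda, phylo_anova
from nhejevo.trees import read_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--nsim", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = read_newick(str(args.data / "tree.nwk"))
    tree = tree.midpoint_root().resolve_polytomies(eps=1e-6)
    traits = pd.read_csv(args.data / "traits.tsv", sep="\t", index_col="genome_id")
    states = pd.read_csv(args.data / "states.tsv", sep="\t",
                         index_col="genome_id")["state"]
    log_gs = np.log10(traits["genome_size_bp"].astype(float))
    log_gr = np.log10(traits["rrna_copies"].astype(float))
    gc = traits["gc_content"]

    # ------------------------------------------------ tip-level comparisons
    conv = states == "conventional_plus"
    minus = states == "NHEJ_minus"
    rows = []
    for name, values in [("log10_gs", log_gs), ("log10_rrna", log_gr), ("gc", gc)]:
        w, p = wilcoxon_compare(values[conv], values[minus])
        rows.append({"trait": name, "w": w, "p": p,
                     "median_conventional": values[conv].median(),
                     "median_minus": values[minus].median()})
    wx = pd.DataFrame(rows)
    wx.to_csv(args.out / "wilcoxon_comparisons.tsv", sep="\t", index=False)
    print("conventional NHEJ+ vs NHEJ- (Wilcoxon rank-sum):")
    print(wx.round(4).to_string(index=False))

    # ------------------------------------------------- phylogenetic signal
    rows = []
    for name, values in [("log10_gs", log_gs), ("log10_rrna", log_gr)]:
        lam, ll, p_lam = pagel_lambda(tree, values)
        K, p_k = blomberg_k(tree, values, n_perm=args.nsim, seed=args.seed)
        rows.append({"trait": name, "lambda": lam, "lambda_p": p_lam,
                     "blomberg_k": K, "k_p": p_k})
    sig = pd.DataFrame(rows)
    sig.to_csv(args.out / "phylogenetic_signal.tsv", sep="\t", index=False)
    print("\nphylogenetic signal:")
    print(sig.round(4).to_string(index=False))

    # ---------------------------------------------------------- phyloANOVA
    rows = []
    for name, values in [("log10_gs", log_gs), ("log10_rrna", log_gr)]:
        res = phylo_anova(tree, values, states, n_sim=args.nsim, seed=args.seed)
        res.pairwise.assign(trait=name).to_csv(
            args.out / f"phyloanova_posthoc_{name}.tsv", sep="\t", index=False)
        rows.append({"trait": name, "F": res.f_statistic, "p_phylo": res.p_phylo})
    pa = pd.DataFrame(rows)
    pa.to_csv(args.out / "phyloanova.tsv", sep="\t", index=False)
    print("\nphylogenetic ANOVA across the five NHEJ states:")
    print(pa.round(4).to_string(index=False))

    # --------------------------------------- correlated evolution (2-state)
    two_state = states[states.isin(["NHEJ_minus", "conventional_plus"])]
    sub = tree.prune_to_taxa(set(two_state.index))
    nhej01 = (two_state == "conventional_plus").astype(int)
    rows = []
    for name, values in [("genome_size", log_gs), ("growth_rate", log_gr)]:
        codes, thr = binarize(values.loc[two_state.index], rule="mean")
        res = correlated_evolution(sub, nhej01, codes, seed=args.seed)
        rows.append({"pair": f"NHEJ~{name}", "threshold": thr,
                     "loglik_independent": res.loglik_independent,
                     "loglik_dependent": res.loglik_dependent,
                     "lr": res.lr, "df": res.df, "p": res.p_value})
    ce = pd.DataFrame(rows)
    ce.to_csv(args.out / "correlated_evolution.tsv", sep="\t", index=False)
    print("\ncorrelated evolution (dependent vs independent, ML LRT):")
    print(ce.round(4).to_string(index=False))

    # ------------------------------------- phylogenetic logistic regression
    X = pd.DataFrame({"gs": log_gs.loc[two_state.index],
                      "gr": log_gr.loc[two_state.index]})
    v = vif(X)
    print(f"\nVIF: {v.round(4).to_dict()}")
    table = phyloglm_model_choice(sub, nhej01, X, [["gs"], ["gr"], ["gs", "gr"]])
    table.insert(1, "vif_max", v.max())
    table.to_csv(args.out / "phyloglm_models.tsv", sep="\t", index=False)
    print("phylogenetic logistic regression, models ranked by AIC:")
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
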