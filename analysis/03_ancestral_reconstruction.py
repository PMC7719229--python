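"""Reconstruct the evolutionary history of NHEJ on the species tree.

Midpoint-roots and binarizes the tree, collapses the five NHEJ states to the
four-state reconstruction alphabet, compares ER/SYM/ARD rate structures by
AIC weight, samples the rate matrix from its posterior, simulates stochastic
maps (one per posterior draw), summarizes transition counts / time in state /
node posteriors, calls node states at pp > 0.7, applies the four-criterion
primary-gain caller, and reconstructs genome size ancestrally under Brownian
motion.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nhejevo.ancestral import brownian_ancestral
from nhejevo.classify import FOUR_STATES, collapse_to_four
from nhejevo.mk import aic_weights, fit_mk_models, sample_q_posterior
from nhejevo.simmap import (call_node_states, find_primary_gains,
                            stochastic_map, summarize_maps)
from nhejevo.trees import read_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--nmaps", type=int, default=500,
                    help="posterior Q draws; one stochastic map per draw")
    ap.add_argument("--threshold", type=float, default=0.7)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = read_newick(str(args.data / "tree.nwk"))
    tree = tree.midpoint_root().resolve_polytomies(eps=1e-6)
    states5 = pd.read_csv(args.data / "states.tsv", sep="\t",
                          index_col="genome_id")["state"]
    codes = states5.map(lambda s: FOUR_STATES.index(collapse_to_four(s)))

    fits = fit_mk_models(tree, codes, k=4, seed=args.seed,
                         state_names=list(FOUR_STATES))
    weights = aic_weights([fits[m] for m in ("ER", "SYM", "ARD")])
    model_table = pd.DataFrame({
        "model": ["ER", "SYM", "ARD"],
        "loglik": [fits[m].loglik for m in ("ER", "SYM", "ARD")],
        "n_params": [fits[m].n_params for m in ("ER", "SYM", "ARD")],
        "aic": [fits[m].aic for m in ("ER", "SYM", "ARD")],
        "aic_weight": weights,
    })
    model_table.to_csv(args.out / "mk_model_selection.tsv", sep="\t", index=False)
    best = model_table.loc[model_table.aic.idxmin(), "model"]
    print("rate-structure comparison:")
    print(model_table.round(3).to_string(index=False))
    print(f"best structure by AIC weight: {best}")

    post = sample_q_posterior(tree, codes, structure=best,
                              n_samples=args.nmaps, seed=args.seed,
                              mle=fits[best])
    rng = np.random.default_rng(args.seed + 1)
    maps = [stochastic_map(tree, codes, post.generator(i), "fitzjohn", rng=rng)
            for i in range(post.n_samples)]
    summ = summarize_maps(maps, state_names=list(FOUR_STATES))

    trans = pd.DataFrame(summ.mean_transition_counts,
                         index=FOUR_STATES, columns=FOUR_STATES)
    trans.to_csv(args.out / "transition_counts_mean.tsv", sep="\t")
    pd.Series(summ.time_in_state, index=FOUR_STATES, name="expected_time")\
        .rename_axis("state").to_frame()\
        .to_csv(args.out / "time_in_state.tsv", sep="\t")
    summ.node_posteriors.rename_axis("node_id")\
        .rename(columns=dict(enumerate(FOUR_STATES)))\
        .to_csv(args.out / "node_posteriors.tsv", sep="\t")
    with open(args.out / "map_archive.jsonl", "w") as fh:
        for m in maps[:50]:  # a browsable sample of full histories
            fh.write(json.dumps({str(k): v for k, v in m.segments.items()}) + "\n")

    print(f"\nmean state changes per map: {summ.mean_transition_counts.sum():.1f}")
    print("expected time in state (fraction of tree length):")
    frac = summ.time_in_state / summ.time_in_state.sum()
    print(pd.Series(frac, index=FOUR_STATES).round(3).to_string())

    calls = call_node_states(summ, threshold=args.threshold)
    gains = find_primary_gains(
        tree, calls, summ.node_posteriors,
        absent_state=FOUR_STATES.index("NHEJ_minus"),
        gain_states=(FOUR_STATES.index("Ku_only"), FOUR_STATES.index("LigD_only")),
        full_state=FOUR_STATES.index("NHEJ_plus"),
        tip_states=codes, min_desc=3, pp_threshold=args.threshold)
    gain_table = pd.DataFrame(
        [{"node_id": g.node_id, "gained_state": FOUR_STATES[g.gained_state],
          "n_descendant_tips": g.n_descendant_tips, "pp": g.pp_at_node}
         for g in gains])
    gain_table.to_csv(args.out / "primary_gains.tsv", sep="\t", index=False)
    called_frac = (calls.drop([t for t in tree.tip_indices()]) >= 0).mean()
    print(f"\nnodes with a state call at pp > {args.threshold}: {called_frac:.1%}")
    print(f"primary gains called: {len(gain_table)}")

    traits = pd.read_csv(args.data / "traits.tsv", sep="\t", index_col="genome_id")
    log_gs = np.log10(traits["genome_size_bp"].astype(float))
    anc = brownian_ancestral(tree, log_gs)
    anc.rename_axis("node_id").to_csv(args.out / "ancestral_log10_gs.tsv", sep="\t")
    print(f"root log10 genome size estimate: {anc.loc[tree.root, 'estimate']:.3f} "
          f"(+/- {np.sqrt(anc.loc[tree.root, 'variance']):.3f})")


if __name__ == "__main__":
    main()
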