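"""Classify genomes into NHEJ states from domain evidence and summarize.

Reads the synthetic study, applies the E-value filter and the five-state
decision rules, tabulates Ku/LigD copy numbers, classifies the ku--ligD
neighborhood of conventional genomes, and tests per-phylum enrichment of
conventional and nonconventional NHEJ.
"""

import argparse
from pathlib import Path

import pandas as pd

from nhejevo.classify import (assign_states, copy_numbers, neighborhood_table,
                              parse_domain_table, phylum_enrichment)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--evalue-threshold", type=float, default=1e-4)
    ap.add_argument("--window", type=int, default=10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = pd.read_csv(args.data / "states.tsv", sep="\t",
                        index_col="genome_id")["state"]
    hits = parse_domain_table(args.data / "domain_hits.tsv",
                              evalue_threshold=args.evalue_threshold)
    states = assign_states(hits, genome_ids=truth.index)
    states.rename_axis("genome_id").to_frame().to_csv(
        args.out / "nhej_states.tsv", sep="\t")
    agree = (states.loc[truth.index] == truth).mean()
    print("state composition (called):")
    print(states.value_counts().to_string())
    print(f"agreement with generating truth: {agree:.1%}")

    cn = copy_numbers(hits)
    cn.to_csv(args.out / "copy_numbers.tsv", sep="\t", index=False)
    multi_ku = (cn["ku_proteins"] > 1).mean()
    print(f"genomes with >1 Ku protein among hit-bearing genomes: {multi_ku:.1%}")

    genes = pd.read_csv(args.data / "genes.tsv", sep="\t")
    traits = pd.read_csv(args.data / "traits.tsv", sep="\t", index_col="genome_id")
    sizes = {g: {"chr": int(traits.loc[g, "cds_count"])} for g in traits.index}
    nb = neighborhood_table(genes, states, window=args.window,
                            replicon_sizes_by_genome=sizes)
    nb.to_csv(args.out / "neighborhood.tsv", sep="\t", index=False)
    if len(nb):
        print("ku--ligD neighborhood of conventional genomes:")
        print(nb["category"].value_counts(normalize=True).round(3).to_string())

    rows = []
    for focal in ("conventional_plus", "nonconventional_plus"):
        enr = phylum_enrichment(states, traits["phylum"], focal)
        enr.insert(0, "focal_state", focal)
        rows.append(enr)
    enrichment = pd.concat(rows, ignore_index=True)
    enrichment.to_csv(args.out / "phylum_enrichment.tsv", sep="\t", index=False)
    top = enrichment.sort_values("p_value").head(3)
    print("strongest enrichment signals:")
    print(top[["focal_state", "phylum", "odds_ratio", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
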