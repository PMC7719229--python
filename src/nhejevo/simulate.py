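"""Synthetic-data generator with known ground truth.

Emulates every input the pipeline consumes: a Yule species phylogeny, NHEJ
states evolved on it under an Mk model, per-genome domain-hit tables strictly
consistent with each state (plus above-threshold decoy hits that exercise the
E-value filter), gene tables with ku/ligD placed at controlled rank
distances, and genome metadata with configurable state-dependent shifts in
genome size, rRNA copy number and G-C content.  Everything is reproducible
from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FIVE_STATES, FOUR_STATES
from .simmap import StochasticMap
from .trees import Phylogeny

__all__ = [
    "SimulationConfig",
    "default_nhej_generator",
    "simulate_tree",
    "simulate_mk_history",
    "simulate_correlated_pair",
    "simulate_brownian",
    "generate_genome_tables",
    "simulate_all",
]


def default_nhej_generator() -> np.ndarray:
    """Default 4-state generator on (NHEJ-, Ku_only, LigD_only, NHEJ+).

    Rates encode the biology the generator emulates: losses outpace gains,
    the LigD-first route dominates sequential acquisition, direct gains and
    losses of the whole machinery occur, and the Ku-only state is rarely
    entered.  Units are transitions per unit branch length.
    """
    q = np.array([
        #  -     Ku    LigD   +
        [0.0, 0.05, 0.45, 0.30],   # from NHEJ-
        [0.60, 0.0, 0.00, 0.35],   # from Ku_only
        [0.55, 0.00, 0.0, 0.50],   # from LigD_only
        [0.70, 0.05, 0.25, 0.0],   # from NHEJ+
    ])
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs."""

    n_tips: int = 500
    birth_rate: float = 1.0
    mk_Q: np.ndarray = field(default_factory=default_nhej_generator)
    root_state: int = 0                      # eubacterial ancestor: NHEJ-
    tree_height: float = 4.0                 # rescale the Yule tree to this depth
    p_conventional_given_plus: float = 0.7   # 920 of ~1300 NHEJ+ are conventional

    # trait model (per five-state NHEJ category)
    log10_size_mean: dict = field(default_factory=lambda: {
        "NHEJ_minus": 6.46,            # ~2.9 Mb
        "Ku_only": 6.50,
        "LigD_only": 6.55,
        "conventional_plus": 6.73,     # ~5.4 Mb
        "nonconventional_plus": 6.60,
    })
    log10_size_sd: float = 0.15
    rrna_mean: dict = field(default_factory=lambda: {
        "NHEJ_minus": 4.0, "Ku_only": 3.5, "LigD_only": 3.5,
        "conventional_plus": 3.0, "nonconventional_plus": 3.2,
    })
    rrna_sd: float = 1.2
    gc_mean: dict = field(default_factory=lambda: {
        "NHEJ_minus": 0.50, "Ku_only": 0.52, "LigD_only": 0.52,
        "conventional_plus": 0.56, "nonconventional_plus": 0.54,
    })
    gc_sd: float = 0.05
    genes_per_bp: float = 1.0 / 1000.0

    # domain-hit architecture
    evalue_threshold: float = 1e-4
    p_single_ku: float = 0.84           # remainder carry 2-8 copies
    p_extra_lig: float = 0.66
    p_extra_pol: float = 0.37
    p_extra_pe: float = 0.08
    domain_noise: float = 0.3           # mean decoy (above-threshold) hits/genome

    # ku--ligD neighborhood placement for conventional genomes
    neighborhood_window: int = 10
    p_operonic: float = 0.60
    p_proximal_opposite: float = 0.15

    # phylum labels (for enrichment tests)
    phyla: tuple = ("PhylumA", "PhylumB", "PhylumC", "PhylumD", "PhylumE", "PhylumF")
    p_conventional_in_first_phylum: float = 0.4

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["mk_Q"] = np.asarray(self.mk_Q).tolist()
        return d


# ------------------------------------------------------------------- the tree


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed=None,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree: ultrametric, with exponential waiting times."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    start = [0.0, 0.0, 0.0]     # birth time of the lineage leading to each node
    active = [1, 2]
    t = 0.0
    split_time = {}
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        split_time[node] = t
        for _ in range(2):
            parent.append(node)
            start.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    blen = np.zeros(len(parent))
    labels: list[str | None] = [None] * len(parent)
    tip_counter = 0
    for node in range(1, len(parent)):
        end = split_time.get(node, t_end)
        blen[node] = end - start[node]
    for node in active:
        tip_counter += 1
        labels[node] = f"t{tip_counter}"
    return Phylogeny(parent, blen, labels, rooted=True)


# ------------------------------------------------------------ trait histories


def simulate_mk_history(tree: Phylogeny, Q: np.ndarray, root_state: int | None = None,
                        root_prior=None, seed=None,
                        rng: np.random.Generator | None = None):
    """Exact Gillespie simulation of a discrete character along the tree.

    Returns (tip_states, history): integer states per tip label and the full
    true character history as a :class:`StochasticMap` for recovery tests.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    if root_state is None:
        pi = (np.full(k, 1.0 / k) if root_prior is None
              else np.asarray(root_prior, dtype=float))
        node_states[tree.root] = int(rng.choice(k, p=pi / pi.sum()))
    else:
        node_states[tree.root] = int(root_state)
    segments: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        node = int(node)
        if node == tree.root:
            continue
        s = int(node_states[tree.parent[node]])
        t_total = float(tree.blen[node])
        elapsed = 0.0
        segs: list[tuple[int, float]] = []
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                segs.append((s, t_total - elapsed))
                break
            wait = rng.exponential(1.0 / out_rate)
            if elapsed + wait >= t_total:
                segs.append((s, t_total - elapsed))
                break
            segs.append((s, wait))
            elapsed += wait
            probs = Q[s].copy()
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        # merge the dwell bookkeeping: consecutive entries always differ in state
        merged: list[tuple[int, float]] = []
        for st, dw in segs:
            if merged and merged[-1][0] == st:
                merged[-1] = (st, merged[-1][1] + dw)
            else:
                merged.append((st, dw))
        segments[node] = merged
        node_states[node] = s
    tip_states = pd.Series(
        {tree.labels[i]: int(node_states[i]) for i in tree.tip_indices()},
        name="state",
    )
    history = StochasticMap(tree=tree, node_states=node_states,
                            segments=segments, k=k)
    return tip_states, history


_DOUBLE_JUMPS = [(0, 3), (3, 0), (1, 2), (2, 1)]


def simulate_correlated_pair(tree: Phylogeny, dependent_Q: np.ndarray, seed=None,
                             root_prior=None,
                             rng: np.random.Generator | None = None):
    """Forward-simulate two binary traits under a product-space generator.

    ``dependent_Q`` lives on (00, 01, 10, 11); simultaneous double
    transitions must have rate zero.
    """
    Q = np.asarray(dependent_Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValueError("dependent generator must be 4x4")
    for i, j in _DOUBLE_JUMPS:
        if Q[i, j] != 0.0:
            raise ValueError("double transitions (00<->11, 01<->10) must have rate 0")
    states, _ = simulate_mk_history(tree, Q, root_prior=root_prior, seed=seed, rng=rng)
    a = (states // 2).rename("trait_a")
    b = (states % 2).rename("trait_b")
    return a, b


def simulate_brownian(tree: Phylogeny, sigma2: float, root: float = 0.0,
                      seed=None, lam: float | None = None,
                      rng: np.random.Generator | None = None) -> pd.Series:
    """Brownian tip values; optional Pagel-lambda rescaling of shared history.

    The lambda transform multiplies every branch by lambda and stretches each
    terminal branch so root-to-tip depths are preserved, which reproduces the
    lambda-scaled covariance exactly.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    blen = tree.blen.astype(float).copy()
    if lam is not None:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        depths = tree.depths()
        blen = blen * lam
        for t in tree.tip_indices():
            blen[t] += (1.0 - lam) * depths[t]
    x = np.zeros(tree.n_nodes)
    x[tree.root] = root
    for node in tree.preorder():
        node = int(node)
        p = tree.parent[node]
        if p < 0:
            continue
        x[node] = x[p] + rng.normal(0.0, np.sqrt(sigma2 * blen[node]))
    return pd.Series({tree.labels[i]: x[i] for i in tree.tip_indices()},
                     name="value")


# -------------------------------------------------------------- genome tables


def _hit(rows, genome, protein, domain, evalue, frm, to):
    rows.append({"genome_id": genome, "protein_id": protein, "domain": domain,
                 "evalue": evalue, "ali_from": frm, "ali_to": to})


def _good_evalue(rng) -> float:
    return float(10.0 ** -rng.uniform(5.0, 30.0))


def generate_genome_tables(states: pd.Series, config: SimulationConfig, seed=None,
                           rng: np.random.Generator | None = None):
    """Domain hits, gene tables and trait metadata consistent with each state.

    Returns (domain_hits, genes, traits, truth) where ``truth`` records the
    generating neighborhood category per conventional genome.  Decoy hits are
    generated strictly above the E-value threshold so default parsing removes
    them.  Gene tables list the NHEJ genes plus flanking filler genes; ranks
    live on a circular replicon of ``cds_count`` genes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hit_rows: list[dict] = []
    gene_rows: list[dict] = []
    trait_rows: list[dict] = []
    truth_neighborhood: dict[str, str] = {}

    for genome, state in states.items():
        if state not in FIVE_STATES:
            raise ValueError(f"unknown state {state!r} for genome {genome}")
        pcount = 0

        def protein():
            nonlocal pcount
            pcount += 1
            return f"{genome}_p{pcount}"

        has_ku = state in ("Ku_only", "conventional_plus", "nonconventional_plus")
        ku_proteins = []
        if has_ku:
            n_ku = 1 if rng.uniform() < config.p_single_ku else int(rng.integers(2, 9))
            for _ in range(n_ku):
                pid = protein()
                ku_proteins.append(pid)
                _hit(hit_rows, genome, pid, "Ku", _good_evalue(rng), 1, 280)

        lig_protein = None
        if state == "conventional_plus":
            lig_protein = protein()
            _hit(hit_rows, genome, lig_protein, "LIG", _good_evalue(rng), 1, 310)
            _hit(hit_rows, genome, lig_protein, "POL", _good_evalue(rng), 320, 610)
            _hit(hit_rows, genome, lig_protein, "PE", _good_evalue(rng), 620, 760)
            if rng.uniform() < config.p_extra_lig:
                _hit(hit_rows, genome, protein(), "LIG", _good_evalue(rng), 1, 300)
            if rng.uniform() < config.p_extra_pol:
                _hit(hit_rows, genome, protein(), "POL", _good_evalue(rng), 1, 290)
            if rng.uniform() < config.p_extra_pe:
                _hit(hit_rows, genome, protein(), "PE", _good_evalue(rng), 1, 140)
        elif state == "nonconventional_plus":
            subcase = int(rng.integers(5))
            lig_protein = protein()
            _hit(hit_rows, genome, lig_protein, "LIG", _good_evalue(rng), 1, 300)
            if subcase == 0:      # all three domains on three proteins
                _hit(hit_rows, genome, protein(), "POL", _good_evalue(rng), 1, 290)
                _hit(hit_rows, genome, protein(), "PE", _good_evalue(rng), 1, 140)
            elif subcase == 1:    # LIG+POL on one protein
                _hit(hit_rows, genome, lig_protein, "POL", _good_evalue(rng), 320, 600)
            elif subcase == 2:    # LIG and POL on different proteins
                _hit(hit_rows, genome, protein(), "POL", _good_evalue(rng), 1, 290)
            elif subcase == 3:    # LIG+PE on one protein
                _hit(hit_rows, genome, lig_protein, "PE", _good_evalue(rng), 320, 460)
            # subcase 4: LIG alone
        elif state == "LigD_only":
            lig_protein = protein()
            _hit(hit_rows, genome, lig_protein, "LIG", _good_evalue(rng), 1, 310)
            if rng.uniform() < 0.1:  # most LigD-only genomes lack POL/PE
                _hit(hit_rows, genome, lig_protein, "POL", _good_evalue(rng), 320, 610)
                _hit(hit_rows, genome, lig_protein, "PE", _good_evalue(rng), 620, 760)
        elif state == "Ku_only":
            if rng.uniform() < 0.3:  # stray POL/PE fragments never confer LigD
                _hit(hit_rows, genome, protein(), "POL", _good_evalue(rng), 1, 280)
        elif state == "NHEJ_minus":
            if rng.uniform() < 0.3:
                dom = "POL" if rng.uniform() < 0.5 else "PE"
                _hit(hit_rows, genome, protein(), dom, _good_evalue(rng), 1, 200)

        # decoys: above the reporting threshold, removed by default parsing
        for _ in range(rng.poisson(config.domain_noise)):
            dom = ["Ku", "LIG", "POL", "PE"][int(rng.integers(4))]
            ev = float(config.evalue_threshold * 10.0 ** rng.uniform(0.5, 3.0))
            _hit(hit_rows, genome, protein(), dom, ev, 1, 150)

        # ---- traits -----------------------------------------------------
        log_size = rng.normal(config.log10_size_mean[state], config.log10_size_sd)
        size_bp = int(round(10.0 ** log_size))
        cds = max(int(round(size_bp * config.genes_per_bp)), 200)
        rrna = max(1, int(round(rng.normal(config.rrna_mean[state], config.rrna_sd))))
        gc = float(np.clip(rng.normal(config.gc_mean[state], config.gc_sd), 0.2, 0.8))
        if state == "conventional_plus" and rng.uniform() < config.p_conventional_in_first_phylum:
            phylum = config.phyla[0]
        else:
            phylum = config.phyla[int(rng.integers(len(config.phyla)))]
        trait_rows.append({"genome_id": genome, "genome_size_bp": size_bp,
                           "gc_content": gc, "rrna_copies": rrna,
                           "cds_count": cds, "phylum": phylum, "state": state})

        # ---- gene table -------------------------------------------------
        def add_gene(rank, strand, role):
            rank = int(rank % cds)
            gene_rows.append({
                "genome_id": genome, "replicon_id": "chr", "rank": rank,
                "start": rank * 1000 + 1, "end": rank * 1000 + 900,
                "strand": strand, "role": role,
            })

        strands = np.array(["+", "-"])
        if has_ku:
            ku_rank = int(rng.integers(50, cds - 50))
            ku_strand = strands[int(rng.integers(2))]
            add_gene(ku_rank, ku_strand, "ku")
        if lig_protein is not None:
            w = config.neighborhood_window
            if state == "conventional_plus":
                u = rng.uniform()
                if u < config.p_operonic:
                    delta, lig_strand, cat = int(rng.integers(1, w + 1)), ku_strand, "operonic"
                elif u < config.p_operonic + config.p_proximal_opposite:
                    delta = int(rng.integers(1, w + 1))
                    lig_strand = "-" if ku_strand == "+" else "+"
                    cat = "proximal_opposite_strand"
                else:
                    delta = int(rng.integers(w + 1, min(cds // 2, 200)))
                    lig_strand = strands[int(rng.integers(2))]
                    cat = "distant"
                sign = 1 if rng.uniform() < 0.5 else -1
                add_gene(ku_rank + sign * delta, lig_strand, "ligD")
                truth_neighborhood[genome] = cat
            else:
                add_gene(int(rng.integers(50, cds - 50)),
                         strands[int(rng.integers(2))], "ligD")
        # a little filler context
        for off in (2, 3):
            base = ku_rank if has_ku else int(rng.integers(50, cds - 50))
            add_gene(base + off * 17, strands[int(rng.integers(2))], "other")

    hits = pd.DataFrame(hit_rows, columns=["genome_id", "protein_id", "domain",
                                           "evalue", "ali_from", "ali_to"])
    genes = pd.DataFrame(gene_rows, columns=["genome_id", "replicon_id", "rank",
                                             "start", "end", "strand", "role"])
    traits = pd.DataFrame(trait_rows).set_index("genome_id")
    return hits, genes, traits, truth_neighborhood


# --------------------------------------------------------------- full bundles


def simulate_all(config: SimulationConfig, outdir, seed: int):
    """Generate and write one complete synthetic study to ``outdir``.

    Files: tree.nwk, states.tsv (five-state truth), domain_hits.tsv,
    genes.tsv, traits.tsv, truth.json.  Returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng_tree, rng_mk, rng_tables, rng_split = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    tree = simulate_tree(config.n_tips, config.birth_rate, rng=rng_tree)
    tree = tree.scale(config.tree_height / tree.height())
    tip4, history = simulate_mk_history(tree, config.mk_Q,
                                        root_state=config.root_state, rng=rng_mk)
    five = {}
    for label, s4 in tip4.items():
        name = FOUR_STATES[s4]
        if name == "NHEJ_plus":
            five[label] = ("conventional_plus"
                           if rng_split.uniform() < config.p_conventional_given_plus
                           else "nonconventional_plus")
        else:
            five[label] = name
    states5 = pd.Series(five, name="state")
    hits, genes, traits, nb_truth = generate_genome_tables(states5, config,
                                                           rng=rng_tables)

    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    states5.rename_axis("genome_id").to_frame().to_csv(outdir / "states.tsv", sep="\t")
    hits.to_csv(outdir / "domain_hits.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    traits.to_csv(outdir / "traits.tsv", sep="\t")
    truth = {
        "config": config.to_jsonable(),
        "seed": seed,
        "tip_states_four": {k: int(v) for k, v in tip4.items()},
        "node_states_true": [int(s) for s in history.node_states],
        "neighborhood": nb_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return tree, states5, tip4, history, hits, genes, traits, nb_truth
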