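"""NHEJ state classification from protein-domain evidence.

Bacterial NHEJ needs two proteins: the end-binding Ku and the three-domain
ligase LigD (ligase LIG, polymerase POL, phosphoesterase PE).  Genomes are
assigned one of five states from per-genome domain-hit tables:

* ``conventional_plus`` -- Ku plus at least one protein carrying LIG, POL and
  PE together (the canonical LigD);
* ``nonconventional_plus`` -- Ku plus LIG somewhere, but no single
  three-domain protein (fragmented or partial LigD architectures);
* ``Ku_only`` -- Ku present, no LIG anywhere (POL/PE fragments do not count
  as a ligase);
* ``LigD_only`` -- LIG present without Ku;
* ``NHEJ_minus`` -- neither Ku nor LIG (POL and/or PE alone stay negative).

LIG is the diagnostic domain for "LigD present" throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "FIVE_STATES",
    "FOUR_STATES",
    "collapse_to_four",
    "parse_domain_table",
    "assign_state",
    "assign_states",
    "copy_numbers",
    "neighborhood",
    "neighborhood_table",
    "phylum_enrichment",
]

DOMAINS = ("Ku", "LIG", "POL", "PE")

FIVE_STATES = (
    "NHEJ_minus",
    "Ku_only",
    "LigD_only",
    "conventional_plus",
    "nonconventional_plus",
)

# Reconstruction alphabet: conventional and nonconventional collapse to NHEJ_plus.
FOUR_STATES = ("NHEJ_minus", "Ku_only", "LigD_only", "NHEJ_plus")

_COLLAPSE = {
    "NHEJ_minus": "NHEJ_minus",
    "Ku_only": "Ku_only",
    "LigD_only": "LigD_only",
    "conventional_plus": "NHEJ_plus",
    "nonconventional_plus": "NHEJ_plus",
}

DEFAULT_EVALUE_THRESHOLD = 1e-4

_DOMAIN_COLUMNS = ["genome_id", "protein_id", "domain", "evalue", "ali_from", "ali_to"]


def collapse_to_four(state: str) -> str:
    return _COLLAPSE[state]


def parse_domain_table(path, evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD) -> pd.DataFrame:
    """Read a domain-hit TSV and drop hits above the E-value threshold.

    Expected columns: genome_id, protein_id, domain, evalue, ali_from, ali_to.
    Repeated (genome, protein, domain) rows with distinct coordinates are kept
    (multi-domain proteins).  Unknown domain tokens and non-numeric E-values
    raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "protein_id": str,
                                            "domain": str})
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table misses columns: {', '.join(missing)}")
    bad = sorted(set(df["domain"]) - set(DOMAINS))
    if bad:
        raise ValueError(f"unknown domain tokens: {', '.join(map(str, bad))}")
    ev = pd.to_numeric(df["evalue"], errors="coerce")
    if ev.isna().any():
        rows = df.index[ev.isna()].tolist()[:5]
        raise ValueError(f"non-numeric evalue in rows {rows}")
    df = df.assign(evalue=ev)
    keep = df["evalue"] <= evalue_threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("parse_domain_table: dropped %d hits above E-value %.3g",
                    dropped, evalue_threshold)
    return df.loc[keep].reset_index(drop=True)


def assign_state(hits: pd.DataFrame) -> str:
    """Five-state NHEJ call for the hits of a single genome (may be empty)."""
    if len(hits) and hits["genome_id"].nunique() > 1:
        raise ValueError("assign_state expects hits from a single genome")
    doms = hits["domain"] if len(hits) else pd.Series([], dtype=str)
    has_ku = bool((doms == "Ku").any())
    has_lig = bool((doms == "LIG").any())
    conventional = False
    if has_lig:
        per_protein = hits.groupby("protein_id")["domain"].agg(set)
        conventional = any({"LIG", "POL", "PE"} <= s for s in per_protein)
    if has_ku and conventional:
        return "conventional_plus"
    if has_ku and has_lig:
        return "nonconventional_plus"
    if has_ku:
        return "Ku_only"
    if has_lig:
        return "LigD_only"
    return "NHEJ_minus"


def assign_states(hits: pd.DataFrame, genome_ids=None) -> pd.Series:
    """Per-genome five-state calls; genomes without hits become NHEJ_minus."""
    out = {}
    if genome_ids is not None:
        for g in genome_ids:
            out[g] = "NHEJ_minus"
    for g, sub in hits.groupby("genome_id"):
        out[g] = assign_state(sub)
    return pd.Series(out, name="state").sort_index()


def copy_numbers(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-genome Ku protein count and total LIG/POL/PE hit counts."""
    genomes = sorted(hits["genome_id"].unique()) if len(hits) else []
    rows = []
    for g in genomes:
        sub = hits[hits["genome_id"] == g]
        ku = sub.loc[sub["domain"] == "Ku", "protein_id"].nunique()
        row = {"genome_id": g, "ku_proteins": ku}
        for d in ("LIG", "POL", "PE"):
            row[f"{d}_hits"] = int((sub["domain"] == d).sum())
        rows.append(row)
    cols = ["genome_id", "ku_proteins", "LIG_hits", "POL_hits", "PE_hits"]
    return pd.DataFrame(rows, columns=cols)


def _rank_delta(r1: int, r2: int, replicon_size: int | None) -> int:
    d = abs(int(r1) - int(r2))
    if replicon_size:
        d = min(d, replicon_size - d)
    return d


def neighborhood(genes: pd.DataFrame, window: int = 10,
                 replicon_sizes: dict | None = None) -> str:
    """Classify the ku--ligD arrangement of one conventional-NHEJ genome.

    Over all (ku, ligD) pairs sharing a replicon, the pair with the smallest
    gene-rank distance decides (ties prefer a same-strand pair); the window is
    inclusive.  ``replicon_sizes`` (replicon id -> gene count) makes rank
    distances circular.  Pairs never sharing a replicon are ``distant``.
    """
    ku = genes[genes["role"] == "ku"]
    ligd = genes[genes["role"] == "ligD"]
    if ku.empty or ligd.empty:
        raise ValueError("neighborhood needs at least one ku and one ligD record")
    best: tuple[int, int] | None = None  # (delta, not-same-strand)
    for _, krow in ku.iterrows():
        for _, lrow in ligd.iterrows():
            if krow["replicon_id"] != lrow["replicon_id"]:
                continue
            size = replicon_sizes.get(krow["replicon_id"]) if replicon_sizes else None
            delta = _rank_delta(krow["rank"], lrow["rank"], size)
            same = int(krow["strand"] != lrow["strand"])  # 0 when same strand
            key = (delta, same)
            if best is None or key < best:
                best = key
    if best is None:
        return "distant"
    delta, opposite = best
    if delta <= window:
        return "operonic" if not opposite else "proximal_opposite_strand"
    return "distant"


def neighborhood_table(genes: pd.DataFrame, states: pd.Series, window: int = 10,
                       replicon_sizes_by_genome: dict | None = None) -> pd.DataFrame:
    """Neighborhood calls for every conventional-NHEJ genome in a gene table."""
    rows = []
    for g, sub in genes.groupby("genome_id"):
        if states.get(g) != "conventional_plus":
            continue
        sizes = (replicon_sizes_by_genome or {}).get(g)
        rows.append({"genome_id": g,
                     "category": neighborhood(sub, window=window,
                                              replicon_sizes=sizes)})
    return pd.DataFrame(rows, columns=["genome_id", "category"])


def phylum_enrichment(states: pd.Series, taxonomy: pd.Series, focal_state: str,
                      background: str = "all") -> pd.DataFrame:
    """Per-phylum enrichment of a focal NHEJ state (two-sided Fisher exact).

    The 2x2 table per phylum P is [[a, b], [c, d]] with a = genomes in P with
    the focal state, b = in P without, c/d the same outside P.  The raw odds
    ratio ad/bc is reported alongside a Haldane-corrected version (0.5 added
    to every cell) when any cell is zero.  ``background`` = "all" uses every
    genome; "nhej_plus" restricts the comparison to NHEJ+ genomes.
    """
    genomes = states.index.intersection(taxonomy.index)
    st = states.loc[genomes]
    tax = taxonomy.loc[genomes]
    if background == "nhej_plus":
        mask = st.isin(["conventional_plus", "nonconventional_plus"])
        st, tax = st[mask], tax[mask]
    elif background != "all":
        raise ValueError("background must be 'all' or 'nhej_plus'")
    focal = st == focal_state
    rows = []
    for phylum in sorted(tax.unique()):
        in_p = tax == phylum
        a = int((focal & in_p).sum())
        b = int((~focal & in_p).sum())
        c = int((focal & ~in_p).sum())
        d = int((~focal & ~in_p).sum())
        if a + b == 0:
            logger.warning("phylum %s has no genomes; skipped", phylum)
            continue
        if b * c > 0:
            odds = a * d / (b * c)
        else:
            odds = np.inf if a * d > 0 else 0.0
        odds_corr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "phylum": phylum, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds,
            "odds_ratio_corrected": odds_corr if min(a, b, c, d) == 0 else odds,
            "p_value": p,
        })
    return pd.DataFrame(rows)
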