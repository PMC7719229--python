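import io

import numpy as np
import pandas as pd
import pytest

from nhejevo.classify import (FIVE_STATES, assign_state, assign_states,
                              copy_numbers, neighborhood, parse_domain_table,
                              phylum_enrichment)

from _oracles import fisher_p_by_enumeration


def hits_df(rows):
    out = []
    for i, (protein, domain) in enumerate(rows):
        out.append({"genome_id": "g1", "protein_id": protein, "domain": domain,
                    "evalue": 1e-10, "ali_from": 1 + 300 * i, "ali_to": 200 + 300 * i})
    return pd.DataFrame(out, columns=["genome_id", "protein_id", "domain",
                                      "evalue", "ali_from", "ali_to"])


def to_tsv(df):
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf


class TestParseDomainTable:
    def test_filters_above_threshold(self):
        df = hits_df([("p1", "Ku"), ("p2", "LIG"), ("p2", "POL"), ("p2", "PE")])
        extra = hits_df([("p3", "LIG")]).assign(evalue=1e-3)
        parsed = parse_domain_table(to_tsv(pd.concat([df, extra])))
        assert len(parsed) == 4

    def test_empty_file_with_header(self):
        parsed = parse_domain_table(to_tsv(hits_df([])))
        assert parsed.empty

    def test_multi_domain_duplicates_kept(self):
        df = hits_df([("p1", "LIG"), ("p1", "LIG")])
        assert len(parse_domain_table(to_tsv(df))) == 2

    def test_unknown_domain_raises(self):
        df = hits_df([("p1", "Ku")]).assign(domain="KU")
        with pytest.raises(ValueError, match="domain"):
            parse_domain_table(to_tsv(df))

    def test_non_numeric_evalue_raises(self):
        df = hits_df([("p1", "Ku")]).astype({"evalue": object})
        df.loc[0, "evalue"] = "tiny"
        with pytest.raises(ValueError, match="evalue"):
            parse_domain_table(to_tsv(df))


class TestAssignState:
    @pytest.mark.parametrize("rows,expected", [
        ([("p1", "Ku"), ("p2", "LIG"), ("p2", "POL"), ("p2", "PE")], "conventional_plus"),
        ([("p1", "POL"), ("p2", "PE")], "NHEJ_minus"),
        ([("p1", "Ku"), ("p2", "LIG"), ("p3", "POL")], "nonconventional_plus"),
        ([], "NHEJ_minus"),
        ([("p1", "Ku"), ("p2", "POL")], "Ku_only"),
        ([("p1", "LIG"), ("p1", "POL"), ("p1", "PE")], "LigD_only"),
        ([("p1", "Ku"), ("p2", "LIG"), ("p2", "POL"), ("p2", "PE"),
          ("p3", "LIG")], "conventional_plus"),  # fragments never demote
    ])
    def test_decision_procedure(self, rows, expected):
        assert assign_state(hits_df(rows)) == expected

    def test_states_partition_genomes(self):
        from nhejevo.simulate import SimulationConfig, generate_genome_tables

        rng = np.random.default_rng(0)
        states = pd.Series(rng.choice(FIVE_STATES, size=120),
                           index=[f"g{i}" for i in range(120)])
        hits, _, _, _ = generate_genome_tables(states, SimulationConfig(), seed=0)
        called = assign_states(hits[hits.evalue <= 1e-4], genome_ids=states.index)
        assert called.value_counts().sum() == 120


class TestCopyNumbers:
    def test_distinct_ku_proteins_counted(self):
        df = hits_df([("p1", "Ku"), ("p2", "Ku"), ("p3", "Ku"), ("p4", "Ku")])
        assert copy_numbers(df).loc[0, "ku_proteins"] == 4

    def test_empty_genome_all_zero(self):
        out = copy_numbers(hits_df([]))
        assert out.empty

    def test_repeated_lig_hits_counted_per_hit(self):
        df = hits_df([("p1", "LIG"), ("p1", "LIG")])
        assert copy_numbers(df).loc[0, "LIG_hits"] == 2


def genes_df(rows):
    out = []
    for rank, strand, role in rows:
        out.append({"genome_id": "g1", "replicon_id": "chr", "rank": rank,
                    "start": rank * 1000 + 1, "end": rank * 1000 + 900,
                    "strand": strand, "role": role})
    return pd.DataFrame(out)


class TestNeighborhood:
    @pytest.mark.parametrize("ku,ligd,expected", [
        ((5, "+"), (8, "+"), "operonic"),
        ((5, "+"), (12, "-"), "proximal_opposite_strand"),
        ((5, "+"), (40, "+"), "distant"),
        ((5, "+"), (15, "+"), "operonic"),   # delta exactly 10, inclusive
        ((5, "+"), (15, "-"), "proximal_opposite_strand"),
    ])
    def test_window_rules(self, ku, ligd, expected):
        genes = genes_df([(ku[0], ku[1], "ku"), (ligd[0], ligd[1], "ligD")])
        assert neighborhood(genes, window=10) == expected

    def test_missing_gene_raises(self):
        with pytest.raises(ValueError):
            neighborhood(genes_df([(5, "+", "ku")]))

    def test_circular_distance(self):
        # ranks 2 and 98 on a 100-gene circular replicon are 4 apart
        genes = genes_df([(2, "+", "ku"), (98, "+", "ligD")])
        assert neighborhood(genes, window=10, replicon_sizes={"chr": 100}) == "operonic"
        assert neighborhood(genes, window=10) == "distant"

    def test_min_delta_pair_decides_with_same_strand_tiebreak(self):
        genes = genes_df([(5, "+", "ku"), (40, "+", "ligD"), (9, "-", "ligD")])
        assert neighborhood(genes, window=10) == "proximal_opposite_strand"
        genes2 = genes_df([(5, "+", "ku"), (9, "-", "ligD"), (9, "+", "ligD")])
        assert neighborhood(genes2, window=10) == "operonic"


class TestPhylumEnrichment:
    @staticmethod
    def build(a, b, c, d):
        states = {}
        tax = {}
        i = 0
        for count, phylum, focal in [(a, "P", True), (b, "P", False),
                                     (c, "Q", True), (d, "Q", False)]:
            for _ in range(count):
                g = f"g{i}"
                states[g] = "conventional_plus" if focal else "NHEJ_minus"
                tax[g] = phylum
                i += 1
        return pd.Series(states), pd.Series(tax)

    def test_odds_ratio_and_exact_p(self):
        states, tax = self.build(10, 5, 20, 40)
        out = phylum_enrichment(states, tax, "conventional_plus")
        row = out[out.phylum == "P"].iloc[0]
        assert row.odds_ratio == pytest.approx(4.0)
        assert row.p_value == pytest.approx(fisher_p_by_enumeration(10, 5, 20, 40),
                                            abs=1e-12)

    def test_symmetric_table_is_null(self):
        states, tax = self.build(7, 7, 7, 7)
        row = phylum_enrichment(states, tax, "conventional_plus").iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)

    def test_zero_cell_reports_raw_zero_and_corrected(self):
        states, tax = self.build(0, 5, 20, 40)
        row = phylum_enrichment(states, tax, "conventional_plus")
        row = row[row.phylum == "P"].iloc[0]
        assert row.odds_ratio == 0.0
        assert row.odds_ratio_corrected > 0.0
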