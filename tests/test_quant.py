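import numpy as np
import pandas as pd
import pytest

from oracles import oracle_classify
from proteotyper.quant import (
    OrthogroupMatrix,
    Tsca,
    build_tscas,
    classify_matrix,
    classify_og,
    expression_conservation_summary,
    filter_protein_groups,
    hamming,
    og_presence_matrix,
    read_orthogroups_tsv,
    relative_ibaq,
    zscore_ibaq,
)
from proteotyper.taxonomy import TaxonNode, Taxonomy


class TestRelativeIbaq:
    def test_single_protein_maps_to_ten(self):
        df = relative_ibaq(pd.DataFrame({"ibaq": [123.0]}))
        assert df["rel_ibaq_log10"].iloc[0] == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        df = relative_ibaq(pd.DataFrame({"ibaq": [1.0, 3.0]}))
        want = [10 + np.log10(0.25), 10 + np.log10(0.75)]
        assert np.allclose(df["rel_ibaq_log10"], want)

    def test_relative_values_sum_to_one_pre_log(self, rng):
        df = pd.DataFrame(
            {"ibaq": rng.lognormal(5, 2, 40), "sample": ["a"] * 20 + ["b"] * 20}
        )
        out = relative_ibaq(df)
        for _, grp in out.groupby("sample"):
            rel = 10 ** (grp["rel_ibaq_log10"] - 10)
            assert rel.sum() == pytest.approx(1.0, abs=1e-9)

    def test_global_scaling_invariance(self, rng):
        ibaq = rng.lognormal(5, 2, 30)
        a = relative_ibaq(pd.DataFrame({"ibaq": ibaq}))
        b = relative_ibaq(pd.DataFrame({"ibaq": ibaq * 7}))
        assert np.allclose(a["rel_ibaq_log10"], b["rel_ibaq_log10"])

    def test_zero_ibaq_is_missing_not_minus_inf(self):
        out = relative_ibaq(pd.DataFrame({"ibaq": [0.0, 5.0]}))
        assert np.isnan(out["rel_ibaq_log10"].iloc[0])

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            relative_ibaq(pd.DataFrame({"ibaq": [0.0, 0.0]}))


class TestZscoreIbaq:
    def test_two_proteins_map_to_four_and_six(self):
        out = zscore_ibaq(pd.DataFrame({"ibaq": [10.0, 1000.0]}))
        assert sorted(out["z_ibaq"]) == pytest.approx([4.0, 6.0])

    def test_mean_five_sd_one(self, rng):
        df = pd.DataFrame(
            {"ibaq": rng.lognormal(5, 2, 60), "sample": ["a"] * 30 + ["b"] * 30}
        )
        out = zscore_ibaq(df)
        for _, grp in out.groupby("sample"):
            assert grp["z_ibaq"].mean() == pytest.approx(5.0, abs=1e-9)
            assert grp["z_ibaq"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_global_scaling_invariance(self, rng):
        ibaq = rng.lognormal(5, 2, 30)
        a = zscore_ibaq(pd.DataFrame({"ibaq": ibaq}))
        b = zscore_ibaq(pd.DataFrame({"ibaq": ibaq * 13}))
        assert np.allclose(a["z_ibaq"], b["z_ibaq"])

    def test_zero_variance_error_names_sample(self):
        with pytest.raises(ValueError, match="flat"):
            zscore_ibaq(
                pd.DataFrame({"ibaq": [5.0, 5.0], "sample": ["flat", "flat"]})
            )

    def test_zeros_are_missing(self):
        out = zscore_ibaq(pd.DataFrame({"ibaq": [0.0, 10.0, 1000.0]}))
        assert np.isnan(out["z_ibaq"].iloc[0])


def six_rank_taxonomy():
    """Four species across 2 phyla / 3 genera with all six class ranks."""
    nodes = [TaxonNode(1, 1, "domain", "D")]
    # (taxid, parent, rank)
    layout = [
        (2, 1, "phylum"), (3, 1, "phylum"),
        (4, 2, "class"), (5, 3, "class"),
        (6, 4, "order"), (7, 5, "order"),
        (8, 6, "family"), (9, 7, "family"),
        (10, 8, "genus"), (11, 9, "genus"), (12, 9, "genus"),
        (100, 10, "species"), (101, 11, "species"),
        (102, 12, "species"), (103, 12, "species"),
    ]
    nodes += [TaxonNode(t, p, r, f"{r}{t}") for t, p, r in layout]
    return Taxonomy(nodes)


TAXID_ORDER = [100, 101, 102, 103]


class TestTscas:
    def test_domain_tsca_all_ones_and_phylum_pattern(self):
        tscas = build_tscas(six_rank_taxonomy(), TAXID_ORDER)
        domain = [t for t in tscas if t.rank == "domain"]
        assert len(domain) == 1 and domain[0].array.tolist() == [1, 1, 1, 1]
        phylum2 = next(t for t in tscas if t.rank == "phylum" and t.taxid == 2)
        assert phylum2.array.tolist() == [1, 0, 0, 0]

    def test_each_rank_partitions_the_taxa(self):
        tscas = build_tscas(six_rank_taxonomy(), TAXID_ORDER)
        for rank in ("domain", "phylum", "class", "order", "family", "genus"):
            total = sum(t.array for t in tscas if t.rank == rank)
            assert total.tolist() == [1, 1, 1, 1]

    def test_domain_emitted_even_without_domain_rank_nodes(self):
        tax = Taxonomy(
            [
                TaxonNode(1, 1, "no rank", "root"),
                TaxonNode(2, 1, "genus", "G"),
                TaxonNode(3, 2, "species", "s"),
            ]
        )
        tscas = build_tscas(tax, [3])
        assert any(t.rank == "domain" and t.array.tolist() == [1] for t in tscas)


class TestClassifyOg:
    def tscas(self):
        return build_tscas(six_rank_taxonomy(), TAXID_ORDER)

    def test_all_ones_row_is_domain_conserved_at_distance_zero(self):
        letter, dist, winner = classify_og([1, 1, 1, 1], self.tscas())
        assert (letter, dist) == ("D", 0) and winner.rank == "domain"

    def test_pure_phylum_row_classifies_as_p(self):
        letter, dist, winner = classify_og([1, 0, 0, 0], self.tscas())
        # phylum 2 contains exactly species 100 here, but so do its class,
        # order, family and genus: the most general rank wins the tie
        assert dist == 0 and letter == "P"

    def test_ties_prefer_most_general_rank(self):
        # the full phylum-3 clade coincides with class 5, order 7 and
        # family 9; the most general rank wins the tie
        letter, dist, _ = classify_og([0, 1, 1, 1], self.tscas())
        assert (letter, dist) == ("P", 0)

    def test_random_rows_match_exhaustive_oracle(self, rng):
        tscas = self.tscas()
        for _ in range(200):
            row = rng.integers(0, 2, size=4)
            got = classify_og(row, tscas)
            want = oracle_classify(row, tscas)
            assert (got[0], got[1], got[2].taxid) == (
                want[0], want[1], want[2].taxid
            )

    def test_hamming_definition(self):
        assert hamming(np.array([1, 0, 1]), np.array([0, 0, 1])) == 1


class TestPresenceMatrix:
    PROTEOMES = {
        1: ["p1", "p2"], 2: ["q1"], 3: ["r1", "r2"], 4: ["s1"],
    }

    def test_presence_row(self):
        ogs = {"OG1": {"p1", "r1"}}
        mat = og_presence_matrix(ogs, self.PROTEOMES)
        assert mat.presence.loc["OG1"].tolist() == [1, 0, 1, 0]

    def test_singleton_og_rejected(self):
        mat = og_presence_matrix({"OG1": {"p1"}}, self.PROTEOMES)
        assert "OG1" not in mat.presence.index

    def test_orphan_protein_ignored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            mat = og_presence_matrix(
                {"OG1": {"p1", "nowhere"}}, self.PROTEOMES
            )
        assert mat.presence.loc["OG1"].tolist() == [1, 0, 0, 0]
        assert any("no proteome" in m for m in caplog.messages)

    def test_column_sums_equal_brute_force_og_counts(self, rng):
        all_proteins = [p for ps in self.PROTEOMES.values() for p in ps]
        ogs = {
            f"OG{i}": set(
                rng.choice(all_proteins, size=rng.integers(2, 5), replace=False)
            )
            for i in range(20)
        }
        mat = og_presence_matrix(ogs, self.PROTEOMES)
        for taxid, prots in self.PROTEOMES.items():
            want = sum(
                1
                for og, members in ogs.items()
                if len(members) >= 2 and members & set(prots)
            )
            assert mat.presence[taxid].sum() == want

    def test_orthogroups_tsv_reader(self, tmp_path):
        path = tmp_path / "Orthogroups.tsv"
        path.write_text(
            "Orthogroup\tproteomeA\tproteomeB\n"
            "OG0000000\tp1, p2\tq1\n"
            "OG0000001\t\tq1\n"
        )
        ogs = read_orthogroups_tsv(path)
        assert ogs == {"OG0000000": {"p1", "p2", "q1"}, "OG0000001": {"q1"}}


class TestExpressionSummary:
    def classified(self):
        presence = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 0, 0]],
            index=["OG1", "OG2"], columns=TAXID_ORDER,
        )
        mat = OrthogroupMatrix(presence=presence)
        return classify_matrix(mat, build_tscas(six_rank_taxonomy(), TAXID_ORDER))

    def test_paralog_median_then_species_max(self):
        mat = self.classified()
        abundance = pd.DataFrame(
            {
                "og_id": ["OG1"] * 3 + ["OG2"] * 2,
                "taxid": [100, 100, 101, 100, 100],
                "z_ibaq": [4.0, 6.0, 5.1, 4.4, 4.6],
            }
        )
        out = expression_conservation_summary(mat, abundance)
        og1 = out[out.og_id == "OG1"].iloc[0]
        # species 100 median of paralogs {4, 6} = 5; max over {5, 5.1} = 5.1
        assert og1.og_expression == pytest.approx(5.1)
        og2 = out[out.og_id == "OG2"].iloc[0]
        assert og2.og_expression == pytest.approx(4.5)

    def test_unquantified_og_dropped(self):
        mat = self.classified()
        abundance = pd.DataFrame(
            {"og_id": ["OG1"], "taxid": [100], "z_ibaq": [5.0]}
        )
        out = expression_conservation_summary(mat, abundance)
        assert set(out.og_id) == {"OG1"}

    def test_quantile_filter_retains_at_least_three_quarters(self, rng):
        # continuous hamming surrogate: the 75% quantile keeps >=75% per class
        n = 400
        classes = pd.DataFrame(
            {
                "conservation_class": rng.choice(list("DPCOFG"), size=n),
                "hamming": rng.exponential(5.0, size=n),
                "winner_rank": "domain",
                "winner_taxid": 1,
            },
            index=[f"OG{i}" for i in range(n)],
        )
        classes.index.name = "og_id"
        presence = pd.DataFrame(
            np.ones((n, 4), dtype=np.int8),
            index=classes.index, columns=TAXID_ORDER,
        )
        mat = OrthogroupMatrix(presence=presence, classes=classes)
        abundance = pd.DataFrame(
            {
                "og_id": classes.index,
                "taxid": [100] * n,
                "z_ibaq": rng.normal(5, 1, size=n),
            }
        )
        out = expression_conservation_summary(mat, abundance, z_quantile=0.75)
        for letter, grp in classes.groupby("conservation_class"):
            kept = out[out.conservation_class == letter]
            assert len(kept) >= 0.75 * len(grp)

    def test_unclassified_matrix_is_error(self):
        presence = pd.DataFrame([[1, 1]], index=["OG1"], columns=[1, 2])
        with pytest.raises(ValueError):
            expression_conservation_summary(
                OrthogroupMatrix(presence=presence), pd.DataFrame()
            )


class TestProteinGroupFilter:
    def frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["Reverse", "Only identified by site",
                     "Potential contaminant", "Peptides", "iBAQ"],
        )

    def test_each_criterion_removes_its_row(self):
        df = self.frame(
            [
                ["+", "", "", 5, 10.0],   # decoy
                ["", "+", "", 5, 10.0],   # site only
                ["", "", "+", 5, 10.0],   # contaminant
                ["", "", "", 1, 10.0],    # too few peptides
                ["", "", "", 5, 10.0],    # clean
            ]
        )
        out = filter_protein_groups(df)
        assert len(out) == 1
        assert out.attrs["removal_counts"] == {
            "reverse": 1,
            "only_identified_by_site": 1,
            "potential_contaminant": 1,
            "fewer_than_two_peptides": 1,
            "zero_ibaq": 0,
        }

    def test_two_peptides_but_zero_ibaq_removed(self):
        out = filter_protein_groups(self.frame([["", "", "", 2, 0.0]]))
        assert len(out) == 0
        assert out.attrs["removal_counts"]["zero_ibaq"] == 1

    def test_empty_input_passes_through(self):
        out = filter_protein_groups(self.frame([]))
        assert len(out) == 0

    def test_missing_column_is_hard_error(self):
        with pytest.raises(ValueError, match="iBAQ"):
            filter_protein_groups(pd.DataFrame({"Reverse": []}))
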