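import random

import pytest

from oracles import oracle_count_psms
from proteotyper.digestion import DigestParams, PeptideSet, ProteinRecord, build_peptide_set
from proteotyper.identification import (
    TaxonCount,
    count_mapped_psms,
    identify,
    identify_strain,
    identify_with_fallback,
    map_psms_to_taxa,
    rank_taxa,
    write_report,
)
from proteotyper.psm_io import Psm, PsmTable
from proteotyper.reference import index_from_peptide_sets


def make_index(sets, level="species"):
    return index_from_peptide_sets(
        [PeptideSet(taxid=t, peptides=frozenset(p)) for t, p in sets.items()],
        DigestParams(),
        level=level,
    )


def make_table(peptides, score=20.0):
    return PsmTable(
        psms=tuple(
            Psm(f"r:{i}", pep, 2, score) for i, pep in enumerate(peptides)
        ),
        run_id="r",
    )


class TestMapping:
    def test_shared_peptides_counted_once_per_taxon(self):
        idx = make_index({1: {"AAAR", "CCCK"}, 2: {"AAAR"}})
        table = make_table(["AAAR", "AAAR", "CCCK"])
        counts = {c.taxid: c.psm_count for c in map_psms_to_taxa(table, idx)}
        assert counts == {1: 3, 2: 2}

    def test_unknown_peptides_contribute_nothing(self):
        idx = make_index({1: {"AAAR"}})
        table = make_table(["ZZZZ", "AAAR"])
        (count,) = map_psms_to_taxa(table, idx)
        assert count.psm_count == 1 and count.distinct_peptides == 1
        assert count_mapped_psms(table, idx) == 1

    def test_paralogs_do_not_double_count(self):
        # two paralogous proteins carrying the same peptide: the taxon's
        # peptide set contains it once, so one PSM adds exactly one count
        proteome = [
            ProteinRecord("p1", "p1", "MAAAAAAK", 9),
            ProteinRecord("p2", "p2", "MAAAAAAKCCC", 9),
        ]
        ps = build_peptide_set(proteome, DigestParams(min_len=1, max_len=50))
        idx = index_from_peptide_sets([ps], DigestParams())
        table = make_table(["MAAAAAAK"])
        (count,) = map_psms_to_taxa(table, idx)
        assert count.psm_count == 1

    def test_empty_index_is_error(self):
        idx = make_index({1: set()})
        with pytest.raises(ValueError):
            map_psms_to_taxa(make_table(["AAAR"]), idx)

    def test_empty_psm_table_yields_zero_counts(self, caplog):
        idx = make_index({1: {"AAAR"}})
        with caplog.at_level("WARNING"):
            counts = map_psms_to_taxa(make_table([]), idx)
        assert [c.psm_count for c in counts] == [0]

    def test_flat_scan_oracle_on_random_fixtures(self, rng):
        peptide_pool = [f"PEP{i}K" for i in range(200)]
        for _ in range(20):
            sets = {
                t: set(
                    rng.choice(peptide_pool,
                               size=rng.integers(1, 60), replace=False)
                )
                for t in range(1, int(rng.integers(2, 10)))
            }
            idx = make_index(sets)
            psms = [peptide_pool[i] for i in rng.integers(0, 200, size=100)]
            got = {c.taxid: c.psm_count
                   for c in map_psms_to_taxa(make_table(psms), idx)}
            assert got == oracle_count_psms(psms, sets)


def tc(taxid, psm_count, distinct=None):
    return TaxonCount(taxid, str(taxid), psm_count, distinct or min(psm_count, 1))


class TestRanking:
    def test_sorted_by_count(self):
        res = rank_taxa([tc(1, 3, 2), tc(2, 2, 2)], total_psms_mapped=600)
        assert res.top.taxid == 1 and not res.tie_at_rank1

    def test_count_tie_broken_by_distinct_peptides(self):
        res = rank_taxa([tc(1, 2, 1), tc(2, 2, 2)], total_psms_mapped=600)
        assert res.top.taxid == 2
        assert not res.tie_at_rank1  # broken by peptides, not ambiguous

    def test_unbroken_rank1_count_tie_is_flagged(self):
        res = rank_taxa([tc(1, 2, 2), tc(2, 2, 2)], total_psms_mapped=600)
        assert res.tie_at_rank1
        assert res.top.taxid == 1  # taxid ascending as last resort

    def test_qc_threshold(self):
        res = rank_taxa([tc(1, 499)], total_psms_mapped=499)
        assert not res.qc_pass and res.qc_reason == "PSMs<500"
        res = rank_taxa([tc(1, 500)], total_psms_mapped=500)
        assert res.qc_pass and res.qc_reason == ""


class TestIdentify:
    IDX = {1: {"AAAR", "CCCK"}, 2: {"AAAR"}, 3: {"EEEK"}}

    def test_composition_and_determinism(self):
        idx = make_index(self.IDX)
        table = make_table(["AAAR", "CCCK", "AAAR"])
        res1 = identify(table, idx, qc_threshold=2)
        res2 = identify(table, idx, qc_threshold=2)
        assert res1 == res2
        assert res1.iteration == "species"
        assert res1.top.taxid == 1
        assert res1.total_psms_mapped == 3 and res1.total_psms_input == 3
        assert res1.qc_pass

    def test_psm_order_never_changes_result(self):
        idx = make_index(self.IDX)
        peptides = ["AAAR", "CCCK", "EEEK", "AAAR", "ZZZZ"] * 3
        baseline = identify(make_table(peptides), idx, qc_threshold=1).ranked
        for seed in range(5):
            shuffled = peptides[:]
            random.Random(seed).shuffle(shuffled)
            assert identify(make_table(shuffled), idx, qc_threshold=1).ranked == baseline

    def test_disjoint_taxon_never_perturbs_ranking(self):
        table = make_table(["AAAR", "CCCK", "AAAR"])
        before = identify(table, make_index(self.IDX), qc_threshold=1)
        extended = {**self.IDX, 99: {"WWWR", "YYYK"}}
        after = identify(table, make_index(extended), qc_threshold=1)
        after_original = [t.taxid for t in after.ranked if t.taxid != 99]
        assert after_original == [t.taxid for t in before.ranked]
        assert after.top.taxid == before.top.taxid


class TestStrainIteration:
    def test_single_strain_index_takes_all_mapped_psms(self):
        idx = make_index({7: {"AAAR", "CCCK"}}, level="strain")
        res = identify_strain(make_table(["AAAR", "CCCK", "ZZZZ"]), idx,
                              qc_threshold=1)
        assert res.iteration == "strain"
        assert res.top.taxid == 7 and res.top.psm_count == 2
        assert res.total_psms_mapped == 2

    def test_private_peptides_separate_near_identical_strains(self):
        shared = {f"SHAREDPEP{i}K" for i in range(97)}
        true_private = {f"TRUEONLY{i}K" for i in range(3)}
        sib_private = {f"SIBONLY{i}K" for i in range(3)}
        idx = make_index(
            {1: shared | true_private, 2: shared | sib_private}, level="strain"
        )
        peptides = sorted(shared) + sorted(true_private) * 10  # 30 private PSMs
        res = identify_strain(make_table(peptides), idx, qc_threshold=1)
        assert res.top.taxid == 1 and not res.tie_at_rank1

    def test_empty_strain_index_is_error(self):
        idx = make_index({1: set()}, level="strain")
        with pytest.raises(ValueError):
            identify_strain(make_table(["AAAR"]), idx)


class TestFallback:
    BACTERIA = {1: {"AAAR"}}
    FUNGI = {50: {f"FUNGAL{i}K" for i in range(30)}}

    def test_fallback_consulted_on_qc_failure(self):
        table = make_table(["AAAR"] + [f"FUNGAL{i}K" for i in range(30)] * 2)
        res = identify_with_fallback(
            table, make_index(self.BACTERIA), make_index(self.FUNGI),
            qc_threshold=10,
        )
        assert res.source_db == "fallback" and res.top.taxid == 50

    def test_primary_pass_short_circuits(self):
        table = make_table(["AAAR"] * 20)
        res = identify_with_fallback(
            table, make_index(self.BACTERIA), make_index(self.FUNGI),
            qc_threshold=10,
        )
        assert res.source_db == "primary" and res.top.taxid == 1

    def test_no_fallback_returns_primary_unchanged(self):
        table = make_table(["AAAR"])
        res = identify_with_fallback(table, make_index(self.BACTERIA), None,
                                     qc_threshold=10)
        assert res.source_db == "primary" and not res.qc_pass

    def test_both_fail_returns_primary_with_qc_false(self):
        table = make_table(["AAAR", "FUNGAL0K"])
        res = identify_with_fallback(
            table, make_index(self.BACTERIA), make_index(self.FUNGI),
            qc_threshold=100,
        )
        assert res.source_db == "primary" and not res.qc_pass


class TestReport:
    def test_tsv_rows_and_order(self, tmp_path):
        idx = make_index({1: {"AAAR"}, 2: {"CCCK"}})
        res = identify(make_table(["AAAR", "AAAR", "CCCK"]), idx, qc_threshold=1)
        paths = write_report(res, tmp_path)
        lines = paths["tsv"].read_text().splitlines()
        assert len(lines) == 1 + len(res.ranked)
        assert lines[1].startswith("1\t")  # rank-1 row first
        assert paths["pdf"].exists() and paths["pdf"].stat().st_size > 0

    def test_tsv_bit_stable(self, tmp_path):
        idx = make_index({1: {"AAAR"}, 2: {"CCCK"}})
        res = identify(make_table(["AAAR"]), idx, qc_threshold=1)
        a = write_report(res, tmp_path / "a")["tsv"].read_bytes()
        b = write_report(res, tmp_path / "b")["tsv"].read_bytes()
        assert a == b

    def test_empty_result_writes_header_only(self, tmp_path):
        res = rank_taxa([], total_psms_mapped=0, total_psms_input=0)
        paths = write_report(res, tmp_path)
        assert paths["tsv"].read_text().splitlines() == [
            "taxid\tname\tpsm_count\tdistinct_peptides\trank"
        ]

    def test_expected_taxon_rank_reporting(self):
        idx = make_index({1: {"AAAR"}, 2: {"CCCK"}})
        res = identify(make_table(["AAAR", "AAAR", "CCCK"]), idx, qc_threshold=1)
        assert res.rank_of(2) == 2
        assert res.rank_of(999) is None
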