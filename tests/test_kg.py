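"""Knowledge-graph data model: I/O round-trips, splits, year tagging,
degree filtering, and clinical-phase outcome labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kglink import (
    Entity,
    KnowledgeGraph,
    Phase,
    PhaseRecord,
    RelationType,
    Triple,
    assign_edge_year,
    filter_benchmark_diseases,
    map_phase_to_outcome,
    read_edge_list,
    split_random,
    split_time,
    write_edge_list,
    write_entity_dict,
)
from kglink.kg import EdgeListParseError, SchemaError

BENCH = "therapeutic_relationship"


# -- construction and validation ------------------------------------------


class TestGraphValidation:
    def test_duplicate_triples_collapse(self):
        ents = [Entity("D1", "Disease"), Entity("G1", "GeneProtein")]
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        kg = KnowledgeGraph(ents, rel, [Triple("D1", BENCH, "G1"), Triple("D1", BENCH, "G1")])
        assert len(kg) == 1

    def test_duplicates_with_conflicting_years_keep_earliest(self):
        ents = [Entity("D1", "Disease"), Entity("G1", "GeneProtein")]
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        kg = KnowledgeGraph(
            ents, rel, [Triple("D1", BENCH, "G1", 2010), Triple("D1", BENCH, "G1", 2003)]
        )
        assert kg.triples[0].year == 2003

    def test_type_signature_violation_rejected(self):
        ents = [Entity("D1", "Disease"), Entity("G1", "GeneProtein")]
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        with pytest.raises(SchemaError, match="type signature"):
            KnowledgeGraph(ents, rel, [Triple("G1", BENCH, "D1")])

    def test_undeclared_entity_rejected(self):
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        with pytest.raises(SchemaError, match="undeclared entity"):
            KnowledgeGraph([Entity("D1", "Disease")], rel, [Triple("D1", BENCH, "GX")])


# -- edge-list I/O --------------------------------------------------------


class TestEdgeListIO:
    def test_round_trip_preserves_triples_and_years(self, tiny_kg, tmp_path):
        edges = tmp_path / "edges.tsv"
        ents = tmp_path / "entities.tsv"
        write_edge_list(tiny_kg, edges)
        write_entity_dict(tiny_kg, ents)
        back = read_edge_list(edges, ents)
        assert sorted(back.triples) == sorted(tiny_kg.triples)
        assert back.entity_types == tiny_kg.entity_types

    def test_empty_edge_file_gives_entities_no_triples(self, tmp_path):
        (tmp_path / "edges.tsv").write_text("# header\n")
        (tmp_path / "entities.tsv").write_text("D1\tDisease\nG1\tGeneProtein\n")
        kg = read_edge_list(tmp_path / "edges.tsv", tmp_path / "entities.tsv")
        assert kg.n_entities == 2 and len(kg) == 0

    def test_duplicate_rows_deduplicated(self, tmp_path):
        (tmp_path / "edges.tsv").write_text("D1\tr\tG1\t\nD1\tr\tG1\t\n")
        (tmp_path / "entities.tsv").write_text("D1\tDisease\nG1\tGeneProtein\n")
        kg = read_edge_list(tmp_path / "edges.tsv", tmp_path / "entities.tsv")
        assert len(kg) == 1

    def test_malformed_row_names_line_number(self, tmp_path):
        (tmp_path / "edges.tsv").write_text("D1\tr\tG1\t\nbroken line\n")
        (tmp_path / "entities.tsv").write_text("D1\tDisease\nG1\tGeneProtein\n")
        with pytest.raises(EdgeListParseError, match=":2"):
            read_edge_list(tmp_path / "edges.tsv", tmp_path / "entities.tsv")

    def test_signature_violation_on_read(self, tmp_path):
        (tmp_path / "edges.tsv").write_text("D1\tr\tG1\t\nG1\tr\tD1\t\n")
        (tmp_path / "entities.tsv").write_text("D1\tDisease\nG1\tGeneProtein\n")
        with pytest.raises(SchemaError):
            read_edge_list(tmp_path / "edges.tsv", tmp_path / "entities.tsv")

    def test_per_relation_counts_match_independent_scan(self, small_planted, tmp_path):
        kg, _ = small_planted
        edges = tmp_path / "edges.tsv"
        ents = tmp_path / "entities.tsv"
        write_edge_list(kg, edges)
        write_entity_dict(kg, ents)
        # independent scan: count relation column occurrences in the raw text
        from collections import Counter

        scan = Counter(
            line.split("\t")[1]
            for line in edges.read_text().splitlines()
            if line and not line.startswith("#")
        )
        back = read_edge_list(edges, ents)
        for rel in back.relation_types:
            assert len(back.triples_of_relation(rel)) == scan[rel]


# -- random split ---------------------------------------------------------


class TestSplitRandom:
    def test_60_20_20_counts(self, tiny_kg):
        # 6 benchmark triples -> floor(0.2*6)=1 each for valid/test, 4 to train
        ds = split_random(tiny_kg, BENCH, (0.6, 0.2, 0.2), seed=0)
        bench_train = [t for t in ds.train if t.relation == BENCH]
        assert (len(bench_train), len(ds.valid), len(ds.test)) == (4, 1, 1)
        # non-benchmark triples all in train
        assert sum(t.relation != BENCH for t in ds.train) == 4

    def test_ten_triples_split_6_2_2(self):
        ents = [Entity("D1", "Disease")] + [Entity(f"G{i}", "GeneProtein") for i in range(10)]
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        kg = KnowledgeGraph(ents, rel, [Triple("D1", BENCH, f"G{i}") for i in range(10)])
        ds = split_random(kg, BENCH, (0.6, 0.2, 0.2), seed=3)
        assert (len(ds.train), len(ds.valid), len(ds.test)) == (6, 2, 2)

    def test_60_40_gives_empty_test(self, tiny_kg):
        ds = split_random(tiny_kg, BENCH, (0.6, 0.4, 0.0), seed=0)
        assert len(ds.test) == 0
        assert len(ds.valid) == 2  # floor(0.4 * 6)

    def test_determinism_and_seed_sensitivity(self, tiny_kg):
        a = split_random(tiny_kg, BENCH, seed=5)
        b = split_random(tiny_kg, BENCH, seed=5)
        c = split_random(tiny_kg, BENCH, seed=6)
        assert sorted(a.valid) == sorted(b.valid) and sorted(a.test) == sorted(b.test)
        assert len(c.valid) == len(a.valid)
        assert sorted(c.valid) != sorted(a.valid) or sorted(c.test) != sorted(a.test)

    def test_disjoint_and_complete(self, small_planted):
        kg, _ = small_planted
        ds = split_random(kg, BENCH, seed=11)
        ds.check_disjoint()
        together = sorted(t.key() for t in ds.train + ds.valid + ds.test)
        assert together == sorted(t.key() for t in kg.triples)

    def test_unknown_relation_rejected(self, tiny_kg):
        with pytest.raises(SchemaError):
            split_random(tiny_kg, "nope")


# -- temporal split -------------------------------------------------------


def _year_kg(years):
    ents = [Entity("D1", "Disease")] + [Entity(f"G{i}", "GeneProtein") for i in range(len(years))]
    rel = [RelationType(BENCH, "Disease", "GeneProtein")]
    return KnowledgeGraph(
        ents, rel, [Triple("D1", BENCH, f"G{i}", y) for i, y in enumerate(years)]
    )


class TestSplitTime:
    def test_threshold_2010_window_5_bounds(self):
        kg = _year_kg([2010, 2011, 2015, 2016])
        ds = split_time(kg, BENCH, 2010, window_years=5)
        assert {t.year for t in ds.train} == {2010}
        assert {t.year for t in ds.test} == {2011, 2015}  # 2016 excluded

    def test_unbounded_window_takes_everything_after(self):
        kg = _year_kg([2000, 2006, 2010, 2019])
        ds = split_time(kg, BENCH, 2005, window_years=None)
        assert {t.year for t in ds.test} == {2006, 2010, 2019}

    def test_boundary_thresholds(self):
        kg = _year_kg([2000, 2005, 2010])
        assert len(split_time(kg, BENCH, 1990).train) == 0
        assert len(split_time(kg, BENCH, 2020).test) == 0

    def _mixed_kg(self):
        ents = [Entity("D1", "Disease"), Entity("G1", "GeneProtein"), Entity("G2", "GeneProtein")]
        rels = [
            RelationType(BENCH, "Disease", "GeneProtein"),
            RelationType("association", "Disease", "GeneProtein"),
        ]
        triples = [
            Triple("D1", BENCH, "G1", 2000),
            Triple("D1", BENCH, "G2", 2008),
            Triple("D1", "association", "G1"),  # no year tag
            Triple("D1", "association", "G2"),
        ]
        return KnowledgeGraph(ents, rels, triples)

    def test_untagged_relations_default_to_train(self):
        # 'association' triples carry no years but stay usable for training
        kg = self._mixed_kg()
        ds = split_time(kg, BENCH, 2004, relations_with_years=[BENCH])
        assert sum(t.relation == "association" for t in ds.train) == 2
        ds2 = split_time(kg, BENCH, 2004, relations_with_years=[BENCH], untagged="drop")
        assert all(t.relation == BENCH for t in ds2.train)

    def test_untagged_benchmark_triple_is_an_error(self, tiny_kg):
        # tiny_kg has one benchmark triple with no year
        with pytest.raises(SchemaError, match="lack year tags"):
            split_time(tiny_kg, BENCH, 2005, relations_with_years=[BENCH, "association"])

    def test_temporal_soundness_no_leakage(self):
        rng = np.random.default_rng(0)
        kg = _year_kg(list(rng.integers(1990, 2020, size=60)))
        ds = split_time(kg, BENCH, 2005, window_years=5)
        assert all(t.year <= 2005 for t in ds.train)
        assert all(2005 < t.year <= 2010 for t in ds.test)
        assert ds.valid == []


# -- year tagging ---------------------------------------------------------


class TestAssignEdgeYear:
    def test_earliest_mention_wins(self):
        assert assign_edge_year([2007, 1999, 2015]) == 1999
        assert assign_edge_year([2005]) == 2005

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            assign_edge_year([])

    @given(st.lists(st.integers(min_value=1900, max_value=2030), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_order_invariance(self, years):
        shuffled = list(reversed(years))
        assert assign_edge_year(years) == assign_edge_year(shuffled) == min(years)


# -- disease degree filter ------------------------------------------------


class TestFilterBenchmarkDiseases:
    def _kg_with_degrees(self, degrees):
        n_genes = max(degrees)
        ents = [Entity(f"G{i}", "GeneProtein") for i in range(n_genes)]
        ents += [Entity(f"D{j}", "Disease") for j in range(len(degrees))]
        rel = [RelationType(BENCH, "Disease", "GeneProtein")]
        triples = [
            Triple(f"D{j}", BENCH, f"G{i}") for j, deg in enumerate(degrees) for i in range(deg)
        ]
        return KnowledgeGraph(ents, rel, triples)

    def test_threshold_30_is_inclusive(self):
        kg = self._kg_with_degrees([30, 29, 31])
        kept = filter_benchmark_diseases(kg, BENCH, 30)
        assert kept == {"D0", "D2"}

    def test_min_degree_zero_keeps_all(self, tiny_kg):
        kept = filter_benchmark_diseases(tiny_kg, BENCH, 0)
        assert kept == {"D1", "D2", "D3"}

    def test_counts_match_brute_force(self, small_planted):
        kg, _ = small_planted
        from collections import defaultdict

        degree = defaultdict(set)
        for t in kg.triples:
            if t.relation == BENCH:
                degree[t.subject].add(t.object)
        for md in (0, 1, 3, 5):
            expected = {d for d in kg.entities_of_type("Disease") if len(degree[d]) >= md}
            assert filter_benchmark_diseases(kg, BENCH, md) == expected

    @given(st.integers(min_value=0, max_value=8))
    @settings(deadline=None)
    def test_monotone_in_min_degree(self, md):
        kg = self._kg_with_degrees([1, 3, 5, 7])
        assert filter_benchmark_diseases(kg, BENCH, md + 1) <= filter_benchmark_diseases(kg, BENCH, md)


# -- clinical phase outcomes ----------------------------------------------


def _rec(phase, disc=False, compound="c"):
    return PhaseRecord("GENE", "DIS", compound, phase, disc)


class TestPhaseOutcome:
    def test_multi_compound_aggregates_to_highest_phase(self):
        # three compounds reaching Discovery, an early discontinuation, and
        # an ongoing Phase II trial -> the pair aggregates to Phase II, which
        # is neither a success nor a Phase II/III discontinuation
        records = [
            _rec(Phase.DISCOVERY, compound="g-02113"),
            _rec(Phase.DISCOVERY, disc=True, compound="l-363377"),
            _rec(Phase.PHASE_II, compound="ptr-3172"),
        ]
        assert map_phase_to_outcome(records) == "unassigned"

    def test_preregistration_is_success(self):
        assert map_phase_to_outcome([_rec(Phase.PREREGISTRATION_OR_HIGHER)]) == "success"
        assert (
            map_phase_to_outcome([_rec(Phase.PHASE_II, disc=True), _rec(Phase.PREREGISTRATION_OR_HIGHER)])
            == "success"
        )

    def test_phase_one_is_unassigned(self):
        assert map_phase_to_outcome([_rec(Phase.PHASE_I)]) == "unassigned"
        assert map_phase_to_outcome([_rec(Phase.DISCOVERY, disc=True)]) == "unassigned"

    @pytest.mark.parametrize("phase", [Phase.PHASE_II, Phase.PHASE_III])
    def test_late_discontinuation_is_failure(self, phase):
        assert map_phase_to_outcome([_rec(phase, disc=True)]) == "failure"

    def test_ongoing_at_top_phase_is_not_failure(self):
        records = [_rec(Phase.PHASE_II, disc=True, compound="a"), _rec(Phase.PHASE_II, compound="b")]
        assert map_phase_to_outcome(records) == "unassigned"

    def test_order_invariance(self, rng):
        records = [
            _rec(Phase.DISCOVERY, compound="a"),
            _rec(Phase.PHASE_III, disc=True, compound="b"),
            _rec(Phase.PHASE_I, compound="c"),
        ]
        outcomes = set()
        for _ in range(10):
            perm = [records[i] for i in rng.permutation(len(records))]
            outcomes.add(map_phase_to_outcome(perm))
        assert outcomes == {"failure"}

    def test_empty_and_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            map_phase_to_outcome([])
        with pytest.raises(ValueError, match="multiple"):
            map_phase_to_outcome([_rec(Phase.PHASE_I), PhaseRecord("OTHER", "DIS", "c", Phase.PHASE_I)])
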