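import itertools

import pytest
from hypothesis import given, settings, strategies as st

from litppi import (
    AliasTable,
    LiteraturePPI,
    PPINetwork,
    filter_by_threshold,
    integrate,
    normalize_names,
    rescale_weights,
    sweep_counts,
)


def rec(a, b, s):
    return LiteraturePPI(a, b, s)


class TestAliasTable:
    def test_lookup_is_case_insensitive_and_trimmed(self):
        table = AliasTable({"cdc28": "YBR160W"})
        assert table.get(" CDC28 ") == "YBR160W"

    def test_conflicting_alias_rejected(self):
        table = AliasTable({"cdc28": "YBR160W"})
        with pytest.raises(ValueError):
            table.add("CDC28", "YOTHER")

    def test_roundtrip(self, tmp_path):
        table = AliasTable({"cdc28": "YBR160W", "cln2": "YPL256C"})
        p = tmp_path / "aliases.tsv"
        table.write(p)
        back = AliasTable.read(p)
        assert back.get("CLN2") == "YPL256C" and len(back) == 2


class TestNormalizeNames:
    def test_both_names_mapped(self):
        aliases = AliasTable({"cdc28": "YBR160W", "cln2": "YPL256C"})
        out = normalize_names([rec("cdc28", "CLN2", 0.4)], aliases)
        assert out == [rec("YBR160W", "YPL256C", 0.4)]

    def test_empty_alias_table_is_identity(self):
        records = [rec("a", "b", 0.1), rec("c", "d", -0.2)]
        assert normalize_names(records, AliasTable()) == records

    def test_unknown_name_left_unchanged(self):
        aliases = AliasTable({"cdc28": "YBR160W"})
        out = normalize_names([rec("cdc28", "mystery", 0.4)], aliases)
        assert out == [rec("YBR160W", "mystery", 0.4)]


class TestThresholdFilter:
    def test_boundary_is_inclusive(self):
        records = [rec("a", "b", -0.7), rec("c", "d", -0.6), rec("e", "f", 0.1)]
        kept = filter_by_threshold(records, -0.6)
        assert [r.score for r in kept] == [-0.6, 0.1]

    def test_minus_infinity_keeps_everything(self):
        records = [rec("a", "b", -5.0), rec("c", "d", 3.0)]
        assert filter_by_threshold(records, float("-inf")) == records

    def test_threshold_above_all_scores_empties(self):
        assert filter_by_threshold([rec("a", "b", 0.9)], 1.0) == []


class TestRescaleWeights:
    @pytest.fixture
    def net(self):
        return PPINetwork.from_edges([("A", "B", 0.2), ("B", "C", 1.0), ("C", "D", 0.3)], weighted=True)

    def test_affine_map_onto_weight_range(self, net):
        records = [rec("a", "b", -1.0), rec("c", "d", 0.0), rec("e", "f", 1.0)]
        out = rescale_weights(records, net)
        assert [r.score for r in out] == pytest.approx([0.2, 0.6, 1.0])

    def test_single_record_gets_mean_edge_weight(self, net):
        out = rescale_weights([rec("a", "b", 0.77)], net)
        assert out[0].score == pytest.approx(0.5)

    def test_identity_when_ranges_coincide(self, net):
        records = [rec("a", "b", 0.2), rec("c", "d", 0.7), rec("e", "f", 1.0)]
        out = rescale_weights(records, net)
        assert [r.score for r in out] == pytest.approx([0.2, 0.7, 1.0])

    def test_order_preserved(self, net):
        records = [rec("a", "b", s) for s in (-0.9, 0.3, -0.1, 0.8)]
        out = rescale_weights(records, net)
        ranks_in = sorted(range(4), key=lambda i: records[i].score)
        ranks_out = sorted(range(4), key=lambda i: out[i].score)
        assert ranks_in == ranks_out

    def test_unweighted_network_rejected(self):
        with pytest.raises(ValueError):
            rescale_weights([rec("a", "b", 0.5)], PPINetwork.from_edges([("A", "B")]))


class TestIntegrate:
    def test_endpoint_duplicate_and_added_counts(self):
        net = PPINetwork.from_edges([("A", "B")], proteins=["C"])
        records = [rec("A", "C", 0.9), rec("C", "D", 0.9), rec("A", "B", 0.9)]
        merged, report = integrate(net, records, threshold=0.0)
        assert sorted(p[:2] for p in merged.edges()) == [("A", "B"), ("A", "C")]
        assert report.n_added == 1
        assert report.n_skipped_unknown_protein == 1
        assert report.n_skipped_duplicate == 1

    def test_threshold_above_all_scores_changes_nothing(self):
        net = PPINetwork.from_edges([("A", "B")])
        merged, report = integrate(net, [rec("A", "B", 0.5)], threshold=0.9)
        assert merged == net and report.n_added == 0

    def test_existing_edge_weight_is_never_overwritten(self):
        net = PPINetwork.from_edges([("A", "B", 0.3), ("B", "C", 0.7)], weighted=True)
        merged, _ = integrate(net, [rec("A", "B", 0.99)], threshold=0.0)
        assert merged.edge_weight("A", "B") == 0.3

    def test_planted_truth_fixture_recovers_exactly_the_true_edges(self):
        proteins = [f"P{i}" for i in range(10)]
        base_edges = [(proteins[i], proteins[i + 1]) for i in range(9)]
        net = PPINetwork.from_edges(base_edges)
        true_missing = [(proteins[i], proteins[i + 2]) for i in range(8)] + [
            (proteins[0], proteins[5]),
            (proteins[1], proteins[7]),
        ]
        records = [rec(a, b, 0.9) for a, b in true_missing]
        records += [rec(f"X{i}", f"Z{i}", -0.95) for i in range(10)]
        merged, report = integrate(net, records, threshold=-0.6)
        added = {e[:2] for e in merged.edges()} - {e[:2] for e in net.edges()}
        assert added == {tuple(sorted(p)) for p in true_missing}
        # the spurious records fall below the threshold before the endpoint check
        assert report.n_added == 10 and report.n_normalized == 10

    def test_unweighted_network_discards_scores(self):
        net = PPINetwork.from_edges([("A", "B")], proteins=["C"])
        merged, _ = integrate(net, [rec("A", "C", 0.9)], threshold=0.0)
        assert not merged.weighted
        assert merged.edge_weight("A", "C") == 1.0  # unit weight convention

    def test_protein_set_invariant_and_idempotent(self):
        net = PPINetwork.from_edges([("A", "B")], proteins=["C", "D"])
        records = [rec("A", "C", 0.5), rec("B", "D", 0.2)]
        merged, r1 = integrate(net, records, threshold=0.0)
        assert merged.proteins == net.proteins
        again, r2 = integrate(merged, records, threshold=0.0)
        assert again == merged and r2.n_added == 0 and r2.n_skipped_duplicate == 2


class TestSweepCounts:
    def test_counts_by_hand(self):
        net = PPINetwork.from_edges([("A", "B")], proteins=["C", "D", "E", "F"])
        records = [rec("A", "C", 0.0), rec("B", "D", -0.5), rec("C", "E", -0.9)]
        reports = sweep_counts(net, records, thresholds=[0.0, -0.6, -0.9])
        assert [r.n_added for r in reports] == [1, 2, 3]

    def test_single_threshold_matches_integrate(self):
        net = PPINetwork.from_edges([("A", "B")], proteins=["C"])
        records = [rec("A", "C", 0.4)]
        (report,) = sweep_counts(net, records, thresholds=[0.0])
        assert report == integrate(net, records, 0.0)[1]

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            sweep_counts(PPINetwork.from_edges([("A", "B")]), [], thresholds=[])


@settings(deadline=None, max_examples=60)
@given(
    scores=st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=12),
    t1=st.floats(min_value=-1, max_value=1),
    t2=st.floats(min_value=-1, max_value=1),
)
def test_integration_nestedness(scores, t1, t2):
    """A stricter threshold never adds an edge the looser one would not."""
    t1, t2 = max(t1, t2), min(t1, t2)
    proteins = [f"P{i}" for i in range(2 * len(scores))]
    net = PPINetwork.from_edges([("P0", "P1")], proteins=proteins)
    records = [
        LiteraturePPI(proteins[2 * i], proteins[2 * i + 1], s) for i, s in enumerate(scores)
    ]
    strict, _ = integrate(net, records, t1)
    loose, _ = integrate(net, records, t2)
    strict_edges = {e[:2] for e in strict.edges()}
    loose_edges = {e[:2] for e in loose.edges()}
    assert strict_edges <= loose_edges
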