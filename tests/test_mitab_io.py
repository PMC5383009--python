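import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netkit import mitab_io
from netkit import synthetic_data as sd
from netkit.errors import ConflictingCategoryError, EmptyNetworkError
from netkit.mitab_io import FilterReport, InteractionRecord


def _row(id_a, id_b, tax_a, tax_b):
    cols = [id_a, id_b] + ["-"] * 7 + [tax_a, tax_b] + ["-"] * 4
    return "\t".join(cols)


def _rec(a, b, ta=9606, tb=9606, line=1):
    return InteractionRecord(a, b, ta, tb, None, None, line)


class TestParse:
    def test_two_row_fixture(self, tmp_path):
        path = tmp_path / "f.mitab"
        path.write_text(
            "#header\n"
            + _row("uniprotkb:P05067", "uniprotkb:P02647", "taxid:9606(human)", "taxid:9606(human)")
            + "\n"
            + _row("uniprotkb:P02766", "uniprotkb:P02647", "taxid:9606", "taxid:9606")
            + "\n"
        )
        records = mitab_io.parse_mitab(path)
        assert len(records) == 2
        assert records[0].accession_a == "P05067"
        assert records[0].taxon_b == 9606
        assert records[1].accession_b == "P02647"

    def test_chemical_namespace_retained_at_parse_stage(self, tmp_path):
        path = tmp_path / "c.mitab"
        path.write_text(
            _row("uniprotkb:P05067", "chebi:CHEBI:15377", "taxid:9606", "taxid:9606") + "\n"
        )
        records = mitab_io.parse_mitab(path)
        assert len(records) == 1
        assert records[0].namespace_b == "chebi"

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "e.mitab"
        path.write_text("#header only\n")
        with pytest.warns(UserWarning, match="empty-input"):
            assert mitab_io.parse_mitab(path) == []

    def test_malformed_row_skipped_and_counted(self, tmp_path):
        path = tmp_path / "m.mitab"
        path.write_text(
            "too\tfew\tcolumns\n"
            + _row("uniprotkb:A", "uniprotkb:B", "taxid:9606", "taxid:9606")
            + "\n"
        )
        records = mitab_io.parse_mitab(path)
        assert len(records) == 1
        assert mitab_io.last_malformed_counts[str(path)] == 1

    def test_first_alternative_and_isoform_collapse(self, tmp_path):
        path = tmp_path / "i.mitab"
        path.write_text(
            _row(
                "uniprotkb:P05067-2|intact:EBI-1",
                "uniprotkb:Q9Y287",
                "taxid:9606",
                "taxid:9606",
            )
            + "\n"
        )
        rec = mitab_io.parse_mitab(path)[0]
        assert rec.accession_a == "P05067"
        rec_keep = mitab_io.parse_mitab(path, collapse_isoforms=False)[0]
        assert rec_keep.accession_a == "P05067-2"


class TestFilterRecords:
    def test_mixed_contaminants_counted_by_class(self):
        clean = [_rec(f"uniprotkb:A{i}", f"uniprotkb:B{i}") for i in range(10)]
        mouse = [_rec("uniprotkb:X", "uniprotkb:Y", 10090, 10090) for _ in range(3)]
        chem = [_rec("uniprotkb:A0", "chebi:CHEBI:1") for _ in range(2)]
        kept, report = mitab_io.filter_records(clean + mouse + chem)
        assert len(kept) == 10
        assert report.rows_nonhuman_removed == 3
        assert report.rows_nonprotein_removed == 2

    def test_all_human_protein_rows_identity(self):
        rows = [_rec("uniprotkb:A", "uniprotkb:B"), _rec("uniprotkb:B", "uniprotkb:C")]
        kept, report = mitab_io.filter_records(rows)
        assert kept == rows and report.rows_nonhuman_removed == 0

    def test_mixed_taxon_row_removed_as_nonhuman(self):
        kept, report = mitab_io.filter_records([_rec("uniprotkb:A", "uniprotkb:B", 9606, 10090)])
        assert kept == [] and report.rows_nonhuman_removed == 1

    def test_order_stability_of_class_totals(self):
        rows = (
            [_rec(f"uniprotkb:A{i}", f"uniprotkb:B{i}") for i in range(5)]
            + [_rec("uniprotkb:M", "uniprotkb:N", 10090, 10090)]
            + [_rec("uniprotkb:A0", "chebi:C")]
        )
        shuffled = rows[:]
        random.Random(1).shuffle(shuffled)
        _, r1 = mitab_io.filter_records(rows)
        _, r2 = mitab_io.filter_records(shuffled)
        assert (r1.rows_nonhuman_removed, r1.rows_nonprotein_removed) == (
            r2.rows_nonhuman_removed,
            r2.rows_nonprotein_removed,
        )


class TestDedupeAndDeloop:
    def test_counts_on_hand_fixture(self):
        rows = [
            _rec("uniprotkb:A", "uniprotkb:B"),
            _rec("uniprotkb:B", "uniprotkb:A"),
            _rec("uniprotkb:A", "uniprotkb:A"),
            _rec("uniprotkb:A", "uniprotkb:B"),
        ]
        edges, report = mitab_io.dedupe_and_deloop(rows)
        assert edges == [("A", "B")]
        assert report.selfloops_removed == 1
        assert report.duplicates_removed == 2

    def test_simple_input_identity(self):
        rows = [_rec("uniprotkb:A", "uniprotkb:B"), _rec("uniprotkb:C", "uniprotkb:B")]
        edges, report = mitab_io.dedupe_and_deloop(rows)
        assert edges == [("A", "B"), ("B", "C")]
        assert report.duplicates_removed == 0 and report.selfloops_removed == 0

    def test_selfonly_node_detected(self):
        rows = [_rec("uniprotkb:A", "uniprotkb:B"), _rec("uniprotkb:Z", "uniprotkb:Z")]
        _, report = mitab_io.dedupe_and_deloop(rows)
        assert report.selfonly_nodes_removed == 1


class TestAssemble:
    def test_partner_of_partner_excluded_without_seed_link(self):
        edges = [("S1", "X"), ("X", "Y"), ("Y", "Z")]
        g, report = mitab_io.assemble_network(edges, ["S1"])
        assert set(g.nodes) == {"S1", "X"}
        assert list(g.edges) == [("S1", "X")]
        assert report.nodes_after_seed_step == 2

    def test_second_step_adds_edges_within_v1(self):
        edges = [("S1", "X"), ("S2", "Y"), ("X", "Y")]
        g, report = mitab_io.assemble_network(edges, ["S1", "S2"])
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3
        assert report.edges_after_seed_step == 2
        assert report.edges_final == 3

    def test_no_seed_match_raises(self):
        with pytest.raises(EmptyNetworkError):
            mitab_io.assemble_network([("A", "B")], ["ZZZ"])

    def test_synthetic_counts_match_ground_truth(self, tmp_path):
        net = sd.generate_scale_free(30, 2, seed=8)
        expected = sd.write_mitab(net, sd.ContaminationSpec(2, 1, 3, 2), 4, tmp_path / "s.mitab")
        g, report = mitab_io.run_curation(tmp_path / "s.mitab", sorted(net.nodes))
        assert report.nodes_final == expected.nodes_final == 30
        assert report.edges_final == expected.edges_final == net.number_of_edges()
        assert report.selfonly_nodes_removed == 3


class TestLabelNodes:
    def test_packaged_category_fixtures(self):
        cats = mitab_io.default_categories()
        assert cats["P05067"] == "in_vivo_amyloid"  # amyloid beta precursor
        assert cats["P37840"] == "in_vitro_amyloid"  # alpha-synuclein
        assert len(mitab_io.load_seed_proteins()) == 28
        assert len(mitab_io.load_related_proteins()) == 13

    def test_unlisted_node_labeled_other(self):
        g, _ = mitab_io.assemble_network([("P05067", "QXXXXX")], ["P05067"])
        mitab_io.label_nodes(g, mitab_io.default_categories())
        assert g.nodes["QXXXXX"]["category"] == "other"
        assert g.nodes["P05067"]["category"] == "in_vivo_amyloid"

    def test_conflicting_category_rejected(self):
        with pytest.raises(ConflictingCategoryError):
            mitab_io.merge_category_tables(
                {"P1": "in_vivo_amyloid"}, {"P1": "amyloid_related"}
            )


@settings(max_examples=20, deadline=None)
@given(
    nonhuman=st.integers(0, 5),
    chemical=st.integers(0, 5),
    selfloop=st.integers(0, 4),
    duplicate=st.integers(0, 6),
    seed=st.integers(0, 500),
)
def test_roundtrip_identity_over_random_contamination(
    tmp_path_factory, nonhuman, chemical, selfloop, duplicate, seed
):
    """write -> parse -> filter recovers exactly the clean edge set and counts."""
    tmp = tmp_path_factory.mktemp("rt")
    net = sd.generate_scale_free(12, 2, seed=seed)
    spec = sd.ContaminationSpec(nonhuman, chemical, selfloop, duplicate)
    path = tmp / f"rt_{seed}_{nonhuman}{chemical}{selfloop}{duplicate}.mitab"
    expected = sd.write_mitab(net, spec, seed, path)
    records = mitab_io.parse_mitab(path)
    kept, report = mitab_io.filter_records(records)
    edges, report = mitab_io.dedupe_and_deloop(kept, report)
    assert set(edges) == {tuple(sorted(e)) for e in net.edges}
    assert report.rows_nonhuman_removed == expected.rows_nonhuman_removed
    assert report.rows_nonprotein_removed == expected.rows_nonprotein_removed
    assert report.selfloops_removed == expected.selfloops_removed
    assert report.duplicates_removed == expected.duplicates_removed
    g, report = mitab_io.assemble_network(edges, sorted(net.nodes), report)
    assert set(g.edges) == set(net.edges) or {
        tuple(sorted(e)) for e in g.edges
    } == {tuple(sorted(e)) for e in net.edges}
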