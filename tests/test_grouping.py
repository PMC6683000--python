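"""Partitioning into minimal parameter groups and the grouped JSON format."""

import random

import pytest

from mzmeta import (
    ABSENT,
    DriftEvent,
    FileMetadata,
    GeneratorSpec,
    MetadataError,
    SourceFloat,
    ValidationError,
    diff_groups,
    generate_metadata,
    group_files,
    read_grouped_json,
    write_grouped_json,
)
from mzmeta.grouping import prepare_tree
from mzmeta.model import InstrumentMetadata, ModuleType, iter_leaves, join_path
from mzmeta.synthetic import default_templates

from conftest import brute_force_partition


def _file(name, **params):
    return FileMetadata(file_name=name, instruments=[
        InstrumentMetadata(model="MS", module_type=ModuleType.MS,
                           parameters=params)])


class TestGroupFiles:
    def test_one_template_many_files_one_group(self):
        spec = GeneratorSpec(n_files=10, templates=default_templates(1), seed=1)
        records, _ = generate_metadata(spec)
        collection = group_files(records)
        assert len(collection.groups) == 1
        assert len(collection.groups[0].file_names) == 10
        assert collection.groups[0].group_id == 1

    def test_single_leaf_difference_splits(self):
        a = _file("a.raw", V=SourceFloat("2.1"))
        b = _file("b.raw", V=SourceFloat("2.2"))
        collection = group_files([a, b])
        assert [g.file_names for g in collection.groups] == [["a.raw"], ["b.raw"]]

    def test_duplicate_names_and_empty_input_rejected(self):
        with pytest.raises(MetadataError):
            group_files([])
        with pytest.raises(MetadataError):
            group_files([_file("a.raw"), _file("a.raw")])

    def test_matches_all_pairs_deep_equality_oracle(self):
        spec = GeneratorSpec(
            n_files=200, templates=default_templates(4), seed=42,
            drift_events=[DriftEvent(
                60, "Q Exactive - Orbitrap_MS/Method/MS2/Top N", 25)])
        records, _ = generate_metadata(spec)
        collection = group_files(records)
        oracle = brute_force_partition(
            [(m.file_name, prepare_tree(m)) for m in records])
        assert [g.file_names for g in collection.groups] == oracle

    def test_permutation_invariance(self):
        spec = GeneratorSpec(n_files=30, templates=default_templates(3), seed=7)
        records, _ = generate_metadata(spec)
        reference = group_files(records)
        rng = random.Random(3)
        for _ in range(3):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert group_files(shuffled) == reference

    def test_idempotence_under_self_concatenation(self):
        spec = GeneratorSpec(n_files=12, templates=default_templates(3), seed=8)
        records, _ = generate_metadata(spec)
        doubled = records + [
            FileMetadata(file_name="z" + m.file_name,
                         acquired_date=m.acquired_date,
                         sample_info=m.sample_info,
                         instruments=m.instruments)
            for m in records
        ]
        base = group_files(records)
        both = group_files(doubled)
        assert len(both.groups) == len(base.groups)
        for g_base, g_both in zip(base.groups, both.groups):
            assert g_both.file_names == sorted(
                g_base.file_names + ["z" + n for n in g_base.file_names])

    def test_minimality_every_group_pair_differs(self):
        spec = GeneratorSpec(n_files=40, templates=default_templates(5), seed=6)
        records, _ = generate_metadata(spec)
        groups = group_files(records).groups
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                assert diff_groups(a, b)


class TestGroupedJsonRoundTrip:
    def test_single_group_round_trips(self, tmp_path):
        collection = group_files([_file("a.raw", V=1)])
        path = tmp_path / "grouped.json"
        write_grouped_json(collection, path)
        assert read_grouped_json(path) == collection

    def test_seeded_multi_group_round_trips_with_identical_hashes(self, tmp_path):
        from mzmeta.model import content_hash

        spec = GeneratorSpec(n_files=25, templates=default_templates(4), seed=5)
        records, _ = generate_metadata(spec)
        collection = group_files(records, failed=[("bad.json", "not json")])
        path = tmp_path / "grouped.json"
        write_grouped_json(collection, path)
        loaded = read_grouped_json(path)
        assert loaded == collection
        for got, expected in zip(loaded.groups, collection.groups):
            assert content_hash(got.shared) == content_hash(expected.shared)

    def test_overlapping_file_names_rejected_on_read(self, tmp_path):
        collection = group_files([_file("a.raw", V=1), _file("b.raw", V=2)])
        path = tmp_path / "grouped.json"
        write_grouped_json(collection, path)
        text = path.read_text(encoding="utf-8").replace('"b.raw"', '"a.raw"')
        path.write_text(text, encoding="utf-8")
        with pytest.raises(ValidationError) as err:
            read_grouped_json(path)
        assert "more than one group" in str(err.value)


class TestDiffGroups:
    def test_group_against_itself_is_empty(self):
        collection = group_files([_file("a.raw", V=1)])
        group = collection.groups[0]
        assert diff_groups(group, group) == []

    def test_injected_drift_reports_exactly_that_path(self):
        drift_path = "Q Exactive - Orbitrap_MS/Method/MS2/Normalized collision energy"
        spec = GeneratorSpec(
            n_files=10, templates=default_templates(1), seed=3,
            drift_events=[DriftEvent(5, drift_path, SourceFloat("35.0"))])
        records, truth = generate_metadata(spec)
        collection = group_files(records)
        assert len(collection.groups) == 2
        diffs = diff_groups(*collection.groups)
        assert [d[0] for d in diffs] == [drift_path]
        assert diffs[0][1].text == "27.0"
        assert diffs[0][2].text == "35.0"

    def test_one_sided_presence_marked_absent(self):
        a = group_files([_file("a.raw", V=1, Extra={"X": 2})]).groups[0]
        b = group_files([_file("b.raw", V=1)]).groups[0]
        diffs = diff_groups(a, b)
        assert diffs == [("MS/Extra/X", 2, ABSENT)]

    def test_matches_independent_tree_walk_oracle(self, rng):
        from conftest import leaf_token, random_tree, perturb_one_leaf

        for _ in range(50):
            tree_a = random_tree(rng)
            tree_b = perturb_one_leaf(tree_a, rng)
            group_a = group_files([_file("a.raw", **tree_a)]).groups[0]
            group_b = group_files([_file("b.raw", **tree_b)]).groups[0]

            flat_a = {join_path(p): v for p, v in iter_leaves(group_a.shared)}
            flat_b = {join_path(p): v for p, v in iter_leaves(group_b.shared)}
            expected = set()
            for path in set(flat_a) | set(flat_b):
                if path not in flat_a or path not in flat_b or \
                        leaf_token(flat_a[path]) != leaf_token(flat_b[path]):
                    expected.add(path)
            assert {d[0] for d in diff_groups(group_a, group_b)} == expected
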