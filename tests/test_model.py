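"""Tree canonicalization, hashing and file-specific stripping."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzmeta.model import (
    DuplicateKeyError,
    FileMetadata,
    InstrumentMetadata,
    ModuleType,
    SourceFloat,
    TreeStructureError,
    UnsupportedLeafError,
    apply_exclusions,
    canonical_serialize,
    content_hash,
    join_path,
    split_path,
    strip_file_specific,
    tree_equal,
)

from conftest import deep_equal, perturb_one_leaf, random_tree, shuffled_copy


def _instrument(model="MS", **params):
    return InstrumentMetadata(model=model, module_type=ModuleType.MS,
                              parameters=params)


class TestCanonicalSerialize:
    def test_empty_tree_is_fixed_constant(self):
        assert canonical_serialize({}) == b"{}"

    def test_sibling_order_does_not_matter(self):
        assert canonical_serialize({"b": 1, "a": 2}) == \
            canonical_serialize({"a": 2, "b": 1})

    def test_type_distinctions_survive(self):
        # the string "1", the integer 1 and the decimal 1.0 are different
        trees = [{"k": "1"}, {"k": 1}, {"k": SourceFloat("1.0")},
                 {"k": True}, {"k": None}]
        blobs = {canonical_serialize(t) for t in trees}
        assert len(blobs) == len(trees)

    def test_decimal_source_text_is_significant(self):
        # trailing zeros denote vendor formatting; "35.0" != "35.00"
        assert canonical_serialize({"t": SourceFloat("35.0")}) != \
            canonical_serialize({"t": SourceFloat("35.00")})

    def test_delimiters_in_strings_cannot_alias_structure(self):
        a = {"a": 'x", "b": 1'}
        b = {"a": "x", "b": 1}
        assert canonical_serialize(a) != canonical_serialize(b)

    def test_unsupported_leaf_names_path(self):
        with pytest.raises(UnsupportedLeafError) as err:
            canonical_serialize({"MS": {"Tune": object()}})
        assert "MS/Tune" in str(err.value)

    def test_nfc_collision_between_siblings_rejected(self):
        # composed \u00e9 and e + combining acute normalize to the same key
        tree = {"caf\u00e9": 1, "cafe\u0301": 2}
        with pytest.raises(DuplicateKeyError):
            canonical_serialize(tree)

    def test_bytes_equal_iff_deep_equal_on_random_corpus(self):
        # 500 random trees (plus shuffles) compared pairwise against the
        # recursive deep-equality oracle
        rng = random.Random(17)
        trees = [random_tree(rng) for _ in range(400)]
        trees += [shuffled_copy(t, rng) for t in trees[:100]]
        blobs = [canonical_serialize(t) for t in trees]
        for i in range(0, len(trees), 7):
            for j in range(i, len(trees), 13):
                assert (blobs[i] == blobs[j]) == deep_equal(trees[i], trees[j])


class TestContentHash:
    def test_stable_across_calls(self):
        tree = {"MS": {"Tune": {"Spray voltage": SourceFloat("2.1")}}}
        assert content_hash(tree) == content_hash(tree)
        assert len(content_hash(tree)) == 64  # sha-256 hex

    def test_shuffled_deep_copy_hashes_equal(self, rng):
        tree = random_tree(rng, depth=4)
        assert content_hash(tree) == content_hash(shuffled_copy(tree, rng))

    def test_single_leaf_perturbation_changes_hash(self, rng):
        for _ in range(200):
            tree = random_tree(rng)
            mutated = perturb_one_leaf(tree, rng)
            assert content_hash(tree) != content_hash(mutated)


class TestPaths:
    @given(st.lists(st.text(min_size=1).filter(bool), min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=200)
    def test_join_split_round_trip(self, keys):
        assert split_path(join_path(keys)) == tuple(keys)

    def test_literal_separator_is_escaped(self):
        assert join_path(["Scan range [m/z]"]) == "Scan range [m\\/z]"
        assert split_path("a\\/b/c") == ("a/b", "c")


class TestStripFileSpecific:
    def test_empty_instruments_gives_empty_tree(self):
        meta = FileMetadata(file_name="a.raw", acquired_date="2024-01-01T00:00:00")
        assert strip_file_specific(meta) == {}

    def test_header_fields_never_enter_the_tree(self):
        shared = {"Tune": {"V": SourceFloat("2.1")}}
        a = FileMetadata("a.raw", "2024-01-01T00:00:00", {"Sample ID": "S1"},
                         [_instrument(**shared)])
        b = FileMetadata("b.raw", "2024-02-02T12:00:00", {"Sample ID": "S2"},
                         [_instrument(**shared)])
        assert strip_file_specific(a) == strip_file_specific(b)
        assert content_hash(strip_file_specific(a)) == \
            content_hash(strip_file_specific(b))

    def test_duplicate_models_are_auto_suffixed(self):
        meta = FileMetadata("a.raw", instruments=[
            _instrument(x=1), _instrument(x=2)])
        tree = strip_file_specific(meta)
        assert set(tree) == {"MS", "MS#2"}

    def test_input_is_not_modified(self):
        params = {"Tune": {"File name": "x", "V": 1}}
        meta = FileMetadata("a.raw", instruments=[_instrument(**params)])
        strip_file_specific(meta, exclude_paths=["MS/Tune/File name"])
        assert params == {"Tune": {"File name": "x", "V": 1}}

    def test_reserved_key_collision_is_an_error(self):
        meta = FileMetadata("a.raw", instruments=[_instrument(Model="spoof")])
        with pytest.raises(TreeStructureError):
            strip_file_specific(meta)

    def test_excluded_nested_path_removed_siblings_kept(self, rng):
        # verified against an oracle that rebuilds the tree path-wise,
        # copying everything except the excluded path
        meta = FileMetadata("a.raw", instruments=[_instrument(
            Tune={"File name": "C:\\tune\\x.mstune", "V": SourceFloat("2.1")},
            Method={"R": 70000})])
        excluded = "MS/Tune/File name"
        tree = strip_file_specific(meta, exclude_paths=[excluded])

        def copy_without(node, prefix):
            out = {}
            for key, value in node.items():
                path = prefix + "/" + key if prefix else key
                if path == excluded:
                    continue
                out[key] = (copy_without(value, path)
                            if isinstance(value, dict) else value)
            return out

        oracle = copy_without(strip_file_specific(meta), "")
        assert deep_equal(tree, oracle)
        assert tree["MS"]["Tune"] == {"V": SourceFloat("2.1")}

    def test_exclusion_is_idempotent(self, rng):
        tree = random_tree(rng, depth=4)
        paths = [join_path((next(iter(tree)),))]
        once = apply_exclusions(tree, paths)
        twice = apply_exclusions(once, paths)
        assert tree_equal(once, twice)
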