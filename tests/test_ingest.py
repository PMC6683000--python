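"""Native JSON dialect, mzML header reading and collection scanning."""

import json

import pytest

from mzmeta import (
    DuplicateKeyError,
    FormatError,
    GeneratorSpec,
    NoInputFilesError,
    ValidationError,
    content_hash,
    generate_collection,
    read_mzml_metadata,
    read_native_json,
    scan_collection,
    write_native_json,
)
from mzmeta.grouping import prepare_tree
from mzmeta.ingest import read_collection
from mzmeta.synthetic import default_templates

MINIMAL = '{"FileName": "a.raw", "Instruments": []}\n'

MZML = """<?xml version="1.0" encoding="UTF-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1"><cv id="MS" fullName="PSI-MS" URI="x"/></cvList>
  <fileDescription><fileContent/></fileDescription>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000073" name="electrospray ionization"/>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="0.1"/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <run id="r" defaultInstrumentConfigurationRef="IC1"
       startTimeStamp="2024-03-01T08:00:00Z">
    <spectrumList count="0"/>
  </run>
</mzML>
"""


class TestNativeJson:
    def test_minimal_document(self, tmp_path):
        path = tmp_path / "a.json"
        path.write_text(MINIMAL, encoding="utf-8")
        meta = read_native_json(path)
        assert meta.file_name == "a.raw"
        assert meta.instruments == []
        assert meta.acquired_date is None
        assert meta.sample_info == {}

    def test_missing_file_name_names_pointer(self, tmp_path):
        path = tmp_path / "a.json"
        path.write_text('{"Instruments": []}', encoding="utf-8")
        with pytest.raises(ValidationError) as err:
            read_native_json(path)
        assert any(ptr == "/FileName" for ptr, _ in err.value.errors)

    def test_duplicate_keys_rejected(self, tmp_path):
        path = tmp_path / "a.json"
        path.write_text('{"FileName": "a", "FileName": "b", "Instruments": []}',
                        encoding="utf-8")
        with pytest.raises(DuplicateKeyError):
            read_native_json(path)

    def test_bad_timestamp_and_bad_module_type_reported(self, tmp_path):
        doc = {"FileName": "a", "AcquiredDate": "yesterday",
               "Instruments": [{"Model": "X", "ModuleType": "UV"}]}
        path = tmp_path / "a.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(ValidationError) as err:
            read_native_json(path)
        pointers = {ptr for ptr, _ in err.value.errors}
        assert pointers == {"/AcquiredDate", "/Instruments/0/ModuleType"}

    def test_generated_documents_round_trip_bit_identically(self, tmp_path):
        spec = GeneratorSpec(n_files=3, templates=default_templates(2), seed=9)
        manifest, _ = generate_collection(spec, tmp_path / "c")
        for entry in manifest.entries:
            meta = read_native_json(entry.path)
            out = tmp_path / ("rt_" + entry.file_name)
            write_native_json(meta, out)
            assert out.read_bytes() == entry.path.read_bytes()
            assert read_native_json(out) == meta


class TestMzml:
    def test_cv_params_become_leaves_with_accession_siblings(self, tmp_path):
        path = tmp_path / "a.mzML"
        path.write_text(MZML, encoding="utf-8")
        meta = read_mzml_metadata(path)
        assert meta.acquired_date == "2024-03-01T08:00:00Z"
        assert meta.sample_info == {}  # no sample element
        (inst,) = meta.instruments
        assert inst.module_type.value == "MS"
        assert inst.parameters == {
            "electrospray ionization": None,
            "electrospray ionization@accession": "MS:1000073",
            "scan start time": "0.1",
            "scan start time@accession": "MS:1000016",
        }

    def test_missing_configuration_list_is_a_format_error(self, tmp_path):
        path = tmp_path / "a.mzML"
        path.write_text(MZML.replace("instrumentConfigurationList",
                                     "somethingElse"), encoding="utf-8")
        with pytest.raises(FormatError):
            read_mzml_metadata(path)

    def test_non_xml_is_a_format_error(self, tmp_path):
        path = tmp_path / "a.mzML"
        path.write_text("not xml at all", encoding="utf-8")
        with pytest.raises(FormatError):
            read_mzml_metadata(path)

    def test_indexed_wrapper_is_transparent(self, tmp_path):
        body = MZML.split("\n", 1)[1]
        wrapped = ('<?xml version="1.0" encoding="UTF-8"?>\n'
                   '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
                   + body.replace("</mzML>", "</mzML>\n</indexedmzML>"))
        path = tmp_path / "a.mzML"
        path.write_text(wrapped, encoding="utf-8")
        meta = read_mzml_metadata(path)
        assert len(meta.instruments) == 1

    def test_cross_format_trees_hash_equal(self, tmp_path):
        # the same template emitted as native JSON and as mzML must strip
        # to hash-equal parameter trees
        spec = GeneratorSpec(n_files=3,
                             templates=default_templates(2, mzml=True),
                             seed=4, emit_formats=("json", "mzML"))
        manifest, _ = generate_collection(spec, tmp_path / "c")
        metas, failed = read_collection(manifest)
        assert failed == []
        hashes = {m.file_name: content_hash(prepare_tree(m)) for m in metas}
        for stem in {n.rsplit(".", 1)[0] for n in hashes}:
            assert hashes[stem + ".json"] == hashes[stem + ".mzML"]


class TestScanCollection:
    def test_directory_sorted_entries(self, tmp_path):
        for name in ("c.json", "a.json", "b.json"):
            (tmp_path / name).write_text(MINIMAL, encoding="utf-8")
        manifest = scan_collection(tmp_path)
        assert [e.file_name for e in manifest.entries] == \
            ["a.json", "b.json", "c.json"]

    def test_single_file(self, tmp_path):
        path = tmp_path / "one.json"
        path.write_text(MINIMAL, encoding="utf-8")
        manifest = scan_collection(path)
        assert [e.file_name for e in manifest.entries] == ["one.json"]

    def test_mixed_formats_tagged_against_listing_oracle(self, tmp_path):
        (tmp_path / "a.json").write_text(MINIMAL, encoding="utf-8")
        (tmp_path / "b.mzML").write_text(MZML, encoding="utf-8")
        (tmp_path / "ignore.txt").write_text("x", encoding="utf-8")
        manifest = scan_collection(tmp_path)
        oracle = sorted(
            (p.name, "json" if p.suffix.lower() == ".json" else "mzML")
            for p in tmp_path.iterdir()
            if p.suffix.lower() in (".json", ".mzml"))
        assert [(e.file_name, e.source_format) for e in manifest.entries] == oracle

    def test_empty_match_is_an_error(self, tmp_path):
        with pytest.raises(NoInputFilesError):
            scan_collection(tmp_path)

    def test_parallel_read_equals_sequential_and_collects_failures(self, tmp_path):
        spec = GeneratorSpec(n_files=6, templates=default_templates(2), seed=2)
        manifest, _ = generate_collection(spec, tmp_path)
        (tmp_path / "broken.json").write_text("{not json", encoding="utf-8")
        manifest = scan_collection(tmp_path)
        seq_meta, seq_failed = read_collection(manifest, jobs=1)
        par_meta, par_failed = read_collection(manifest, jobs=4)
        assert seq_meta == par_meta
        assert seq_failed == par_failed
        assert [name for name, _ in seq_failed] == ["broken.json"]
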