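"""GAF parsing and the three-rule organism screen."""

import io

import pandas as pd
import pytest

from gocensus.annotations import (AnnotationSet, GafParseError, coverage,
                                  filter_organisms, join_htp_records,
                                  load_hgt_list, parse_gaf)
from gocensus.ontology import terminal_mf_terms
from gocensus.simulate import write_gaf

GAF_HEADER = "!gaf-version: 2.1\n"


def _gaf_line(protein, term, aspect="F", qualifier=""):
    cols = ["SYNT", protein, protein, qualifier, term, "SYNT_REF:1", "IEA",
            "", aspect, "", "", "protein", "taxon:1", "20090101", "SYNT",
            "", ""]
    return "\t".join(cols) + "\n"


class TestParseGaf:
    def test_aspect_filter_keeps_only_f_records(self):
        text = GAF_HEADER + (_gaf_line("p1", "GO:1") + _gaf_line("p1", "GO:2")
                             + _gaf_line("p2", "GO:1")
                             + _gaf_line("p1", "GO:9", aspect="P")
                             + _gaf_line("p2", "GO:9", aspect="P"))
        aset = parse_gaf(io.StringIO(text), organism_id="x")
        assert len(aset.records) == 3
        assert all(a == "F" for _, _, a in aset.records)

    def test_not_qualified_records_dropped(self):
        text = GAF_HEADER + (_gaf_line("p1", "GO:1", qualifier="NOT")
                             + _gaf_line("p2", "GO:1"))
        aset = parse_gaf(io.StringIO(text), organism_id="x")
        assert aset.records == [("p2", "GO:1", "F")]

    def test_duplicate_records_kept_as_multiset(self):
        text = GAF_HEADER + _gaf_line("p1", "GO:1") * 3
        aset = parse_gaf(io.StringIO(text), organism_id="x")
        assert len(aset.records) == 3

    def test_wrong_column_count_names_line(self):
        text = GAF_HEADER + _gaf_line("p1", "GO:1") + "a\tb\tc\n"
        with pytest.raises(GafParseError, match="line 3"):
            parse_gaf(io.StringIO(text), organism_id="x")

    def test_roundtrip_through_write_gaf(self, sim_corpus, tmp_path):
        _graph, sets, metadata, _hgt, _truth = sim_corpus
        paths = write_gaf(sets, metadata, tmp_path / "gaf")
        for org, aset in sets.items():
            back = parse_gaf(paths[org], organism_id=org)
            assert sorted(back.records) == sorted(aset.records)

    def test_empty_genome_gives_header_only_file(self, tmp_path):
        sets = {"empty": AnnotationSet("empty", [], proteome_size=0)}
        meta = pd.DataFrame([{"organism_id": "empty", "superkingdom": "B",
                              "lifestyle": "free_living", "proteome_size": 0,
                              "is_type_strain": True}])
        paths = write_gaf(sets, meta, tmp_path)
        lines = open(paths["empty"]).read().splitlines()
        assert all(ln.startswith("!") for ln in lines)
        assert parse_gaf(paths["empty"], organism_id="empty").records == []

    def test_write_gaf_refuses_overwrite(self, tmp_path):
        sets = {"g": AnnotationSet("g", [("p", "GO:1", "F")])}
        meta = pd.DataFrame([{"organism_id": "g", "superkingdom": "A",
                              "lifestyle": "free_living", "proteome_size": 2,
                              "is_type_strain": True}])
        write_gaf(sets, meta, tmp_path)
        with pytest.raises(FileExistsError):
            write_gaf(sets, meta, tmp_path)
        write_gaf(sets, meta, tmp_path, force=True)


def _meta_row(org, lifestyle="free_living", proteome=100, type_strain=True,
              kingdom="B"):
    return {"organism_id": org, "superkingdom": kingdom,
            "lifestyle": lifestyle, "proteome_size": proteome,
            "is_type_strain": type_strain}


def _annots(org, n_proteins, term="GO:1"):
    return AnnotationSet(org, [(f"{org}_p{i}", term, "F")
                               for i in range(n_proteins)])


class TestFilterOrganisms:
    TERMS = {"GO:1"}

    def test_coverage_just_below_threshold_excluded(self):
        meta = pd.DataFrame([_meta_row("a", proteome=100)])
        retained, covs, log = filter_organisms(meta, {"a": _annots("a", 49)},
                                               self.TERMS)
        assert retained == []
        assert covs["a"] == pytest.approx(0.49)
        assert log.iloc[0]["rule"] == "coverage"

    def test_threshold_is_inclusive(self):
        meta = pd.DataFrame([_meta_row("a", proteome=100)])
        retained, _, log = filter_organisms(meta, {"a": _annots("a", 50)},
                                            self.TERMS)
        assert retained == ["a"]
        assert log.empty

    def test_rule_order_strain_lifestyle_coverage(self):
        meta = pd.DataFrame([
            _meta_row("s", type_strain=False, lifestyle="parasite"),
            _meta_row("p", lifestyle="parasite"),
            _meta_row("f", lifestyle="facultative_parasite"),
            _meta_row("c", proteome=1000),
        ])
        sets = {o: _annots(o, 60) for o in ("s", "p", "f", "c")}
        retained, _, log = filter_organisms(meta, sets, self.TERMS)
        assert retained == []
        rules = dict(zip(log["organism_id"], log["rule"]))
        assert rules == {"s": "strain", "p": "lifestyle", "f": "lifestyle",
                         "c": "coverage"}

    def test_order_independent(self):
        rows = [_meta_row("a"), _meta_row("b", lifestyle="parasite"),
                _meta_row("c", proteome=500)]
        sets = {o: _annots(o, 60) for o in ("a", "b", "c")}
        meta = pd.DataFrame(rows)
        r1, _, _ = filter_organisms(meta, sets, self.TERMS)
        r2, _, _ = filter_organisms(meta.iloc[::-1].reset_index(drop=True),
                                    sets, self.TERMS)
        assert set(r1) == set(r2)

    def test_missing_metadata_errors(self):
        meta = pd.DataFrame([_meta_row("a")])
        with pytest.raises(KeyError, match="missing from metadata"):
            filter_organisms(meta, {"a": _annots("a", 60),
                                    "ghost": _annots("ghost", 60)}, self.TERMS)

    def test_coverage_counts_only_terminal_terms(self):
        meta = pd.DataFrame([_meta_row("a", proteome=10)])
        records = ([(f"p{i}", "GO:1", "F") for i in range(3)]
                   + [(f"q{i}", "GO:other", "F") for i in range(7)])
        aset = AnnotationSet("a", records)
        assert coverage(aset, self.TERMS, proteome_size=10) == pytest.approx(0.3)

    def test_coverage_bounded_by_one(self):
        aset = _annots("a", 10)
        assert 0.0 <= coverage(aset, self.TERMS, proteome_size=5) <= 1.0

    def test_synthetic_quota_matches_ground_truth(self, sim_corpus):
        graph, sets, metadata, _hgt, truth = sim_corpus
        terminal = terminal_mf_terms(graph)
        retained, _, log = filter_organisms(metadata, sets, terminal)
        assert retained == truth.retained_expected
        reasons = dict(zip(log["organism_id"], log["rule"]))
        assert all(reasons[g] == "lifestyle" for g in truth.parasites)
        assert all(reasons[g] == "coverage" for g in truth.low_coverage)


def test_hgt_list_join(tmp_path, sim_corpus):
    _graph, sets, _meta, hgt_lists, truth = sim_corpus
    assert truth.hgt_terms, "default config plants lateral transfers"
    records = join_htp_records(sets, hgt_lists)
    assert records, "HTP proteins must join back to their annotations"
    assert {t for _, _, t in records} <= truth.hgt_terms
    # file round-trip of the per-genome protein lists
    org, proteins = next(iter(hgt_lists.items()))
    path = tmp_path / "x.txt"
    path.write_text("\n".join(proteins) + "\n")
    assert load_hgt_list(str(path)) == proteins
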