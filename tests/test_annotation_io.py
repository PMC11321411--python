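"""Parsers and writers for annotation tables, module files and hierarchies."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnotofunc.annotation_io import (
    Alternative,
    FunctionalHierarchy,
    GenomeAnnotation,
    UNANNOTATED,
    parse_gmm_text,
    parse_kegg_definition,
    read_gmm_definitions,
    read_hierarchy,
    read_ko_annotation,
    write_gmm_definitions,
    write_hierarchy,
    write_ko_annotation,
)
from gnotofunc.errors import ParseError


# ---------------------------------------------------------------------------
# gene -> KO tables
# ---------------------------------------------------------------------------

class TestReadKoAnnotation:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        ann = read_ko_annotation(path, "g1")
        assert ann.ko_counts == {} and ann.n_unassigned == 0

    def test_duplicate_kos_aggregate_to_copy_counts(self, tmp_path):
        rows = [
            "gene1\tK00001", "gene2\tK00001", "gene3\tK00002",
            "gene4\t", "gene5\tK00003",
        ]
        path = tmp_path / "ann.tsv"
        path.write_text("\n".join(rows) + "\n")
        ann = read_ko_annotation(path, "g1")
        assert ann.ko_counts == {"K00001": 2, "K00002": 1, "K00003": 1}
        assert ann.n_unassigned == 1

    def test_row_order_is_irrelevant(self, tmp_path):
        rows = ["a\tK00001", "b\tK00001", "c\tK00002", "d\t", "e\tK00003"]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("\n".join(rows) + "\n")
        p2.write_text("\n".join(reversed(rows)) + "\n")
        a1 = read_ko_annotation(p1, "g")
        a2 = read_ko_annotation(p2, "g")
        assert a1.ko_counts == a2.ko_counts
        assert a1.n_unassigned == a2.n_unassigned

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tK00001\nb\tK00002\textra\n")
        with pytest.raises(ParseError, match="line 2"):
            read_ko_annotation(path, "g")

    def test_duplicate_gene_warns_and_counts_once(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("a\tK00001\na\tK00001\n")
        with pytest.warns(UserWarning, match="duplicate gene"):
            ann = read_ko_annotation(path, "g")
        assert ann.ko_counts == {"K00001": 1}

    def test_noncanonical_token_warns_but_participates(self, tmp_path):
        path = tmp_path / "ec.tsv"
        path.write_text("a\tEC:1.1.1.1\n")
        with pytest.warns(UserWarning, match="not a canonical KO"):
            ann = read_ko_annotation(path, "g")
        assert ann.ko_counts == {"EC:1.1.1.1": 1}

    def test_crlf_and_trailing_whitespace_tolerated(self, tmp_path):
        path = tmp_path / "crlf.tsv"
        path.write_bytes(b"a\tK00001  \r\n\r\nb\tK00002\r\n")
        ann = read_ko_annotation(path, "g")
        assert ann.ko_counts == {"K00001": 1, "K00002": 1}

    def test_row_budget_invariant(self, tmp_path):
        # distinct copies + unassigned == number of (unique-gene) rows
        path = tmp_path / "n.tsv"
        path.write_text("a\tK00001\nb\tK00001\nc\t\nd\tK00009\n")
        ann = read_ko_annotation(path, "g")
        assert sum(ann.ko_counts.values()) + ann.n_unassigned == 4

    def test_round_trip(self, tmp_path):
        ann = GenomeAnnotation(
            "g7", {"phylum": "Bacillota"},
            {"K00010": 3, "K00002": 1}, n_unassigned=2,
        )
        path = tmp_path / "rt.tsv"
        write_ko_annotation(ann, path)
        back = read_ko_annotation(path, "g7", {"phylum": "Bacillota"})
        assert back == ann


# ---------------------------------------------------------------------------
# GMM flat files
# ---------------------------------------------------------------------------

class TestGmmParser:
    def test_two_step_block(self):
        mods = parse_gmm_text("MF9001\ttoy module\nK00001\nK00002,K00003\n///\n")
        assert len(mods) == 1
        (mod,) = mods
        assert mod.module_id == "MF9001" and mod.n_steps == 2
        assert len(mod.steps[0].alternatives) == 1
        assert len(mod.steps[1].alternatives) == 2

    def test_complex_token(self):
        mods = parse_gmm_text("MF1\tm\nK00004+K00005\n///\n")
        (alt,) = mods[0].steps[0].alternatives
        assert alt.required_kos == {"K00004", "K00005"}

    def test_empty_file(self):
        assert parse_gmm_text("") == []

    def test_comments_and_blank_lines_ignored(self):
        text = "# a comment\n\nMF1\tm\n\nK00001\n# inner\n///\n"
        assert len(parse_gmm_text(text)) == 1

    def test_missing_terminator_raises(self):
        with pytest.raises(ParseError, match="not terminated"):
            parse_gmm_text("MF1\tm\nK00001\n")

    def test_step_with_no_valid_token_names_module(self):
        with pytest.raises(ParseError, match="MF1"):
            parse_gmm_text("MF1\tm\n,,\n///\n")

    def test_duplicate_module_id_keeps_first(self):
        text = "MF1\tfirst\nK00001\n///\nMF1\tsecond\nK00002\n///\n"
        with pytest.warns(UserWarning, match="duplicate module id"):
            mods = parse_gmm_text(text)
        assert len(mods) == 1 and mods[0].name == "first"

    def test_round_trip(self, tmp_path):
        text = (
            "MF1\talpha\tcat A\nK00001\nK00002,K00003+K00004\n///\n"
            "MF2\tbeta\nK00005+-K00006\n-K00007\n///\n"
        )
        mods = parse_gmm_text(text)
        path = tmp_path / "db.gmm"
        write_gmm_definitions(mods, path)
        assert read_gmm_definitions(path) == mods


# ---------------------------------------------------------------------------
# KEGG-style boolean definitions
# ---------------------------------------------------------------------------

class TestKeggDefinitionParser:
    def test_serial_steps(self):
        mod = parse_kegg_definition("K00001 K00002", "M1", "m")
        assert mod.n_steps == 2
        assert all(len(s.alternatives) == 1 for s in mod.steps)

    def test_or_group(self):
        mod = parse_kegg_definition("(K00001,K00002) K00003", "M1", "m")
        assert len(mod.steps[0].alternatives) == 2
        assert len(mod.steps[1].alternatives) == 1

    def test_complex_and_optional(self):
        mod = parse_kegg_definition("K00001+K00002 -K00003", "M1", "m")
        assert mod.n_required_steps == 1
        (alt,) = mod.steps[0].alternatives
        assert alt.required_kos == {"K00001", "K00002"}
        assert mod.steps[1].optional and mod.steps[1].optional_kos == {"K00003"}

    def test_nested_parentheses_depth_three(self):
        mod = parse_kegg_definition(
            "((K00001,(K00002,K00003)),K00004) K00005", "M1", "m"
        )
        assert mod.n_steps == 2
        assert {frozenset(a.required_kos) for a in mod.steps[0].alternatives} == {
            frozenset({"K00001"}), frozenset({"K00002"}),
            frozenset({"K00003"}), frozenset({"K00004"}),
        }

    def test_or_of_complexes(self):
        mod = parse_kegg_definition("(K00001+K00002,K00003)", "M1", "m")
        assert {a.required_kos for a in mod.steps[0].alternatives} == {
            frozenset({"K00001", "K00002"}), frozenset({"K00003"}),
        }

    def test_unbalanced_parentheses_report_position(self):
        with pytest.raises(ParseError, match="position"):
            parse_kegg_definition("(K00001 K00002", "M1", "m")
        with pytest.raises(ParseError, match="position"):
            parse_kegg_definition("K00001) K00002", "M1", "m")


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

class TestHierarchy:
    HEADER = "ko\tpathway\tcategory\tsubcategory\n"

    def test_toy_file(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            self.HEADER
            + "K00001\tp1\tmetab\tsub1\nK00002\tp1\tmetab\tsub1\nK00003\tp2\tmetab\tsub2\n"
        )
        h = read_hierarchy(path)
        assert len(h) == 3

    def test_multi_pathway_ko(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            self.HEADER + "K00001\tp1\tmetab\tsub1\nK00001\tp2\tmetab\tsub2\n"
        )
        h = read_hierarchy(path)
        assert h.pathways_of("K00001") == ["p1", "p2"]

    def test_unknown_ko_gets_unannotated_bucket(self):
        h = FunctionalHierarchy({})
        assert h.lookup("K99999") == [UNANNOTATED]

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("ko\tpathway\nK00001\tp1\n")
        with pytest.raises(ParseError, match="4 columns"):
            read_hierarchy(path)

    def test_idempotent_round_trip(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            self.HEADER + "K00001\tp1\tmetab\tsub1\nK00001\tp2\tmetab\tsub2\n"
        )
        h = read_hierarchy(path)
        out = tmp_path / "h2.tsv"
        write_hierarchy(h, out)
        assert read_hierarchy(out).entries == h.entries


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

ko_ids = st.integers(0, 99999).map(lambda i: f"K{i:05d}")


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    counts=st.dictionaries(ko_ids, st.integers(1, 4), max_size=12),
    n_unassigned=st.integers(0, 3),
)
def test_annotation_round_trip_property(tmp_path_factory, counts, n_unassigned):
    """Write-then-read reproduces any annotation exactly."""
    tmp = tmp_path_factory.mktemp("rt")
    ann = GenomeAnnotation("gX", {}, counts, n_unassigned)
    path = tmp / "a.tsv"
    write_ko_annotation(ann, path)
    assert read_ko_annotation(path, "gX") == ann


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.lists(ko_ids, min_size=1, max_size=3, unique=True),
                min_size=1, max_size=5))
def test_gmm_parse_insensitive_to_line_ending_style(step_kos):
    """LF, CRLF and trailing-blank variants parse identically."""
    steps = ["{}".format(",".join(alt)) for alt in step_kos]
    base = "MX\tmod\n" + "\n".join(steps) + "\n///\n"
    crlf = base.replace("\n", "\r\n")
    padded = base.replace("\n///", "\n\n///") + "\n\n"
    assert parse_gmm_text(base) == parse_gmm_text(crlf) == parse_gmm_text(padded)
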