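import pytest

from mirkit import seqio
from mirkit.hairpin_classify import evaluate
from mirkit.folding import fold_mfe
from mirkit.precursor import CandidateWindow
from mirkit.seqio import (
    AlphabetError,
    EmptyInputError,
    Transcript,
    family_from_id,
    normalize,
    read_catalog,
    read_fasta,
    revcomp,
    write_catalog,
    write_fasta,
    write_gff3,
)


class TestNormalize:
    def test_dna_to_rna(self):
        assert normalize("acgt") == "ACGU"

    def test_rejects_bad_char(self):
        with pytest.raises(AlphabetError):
            normalize("ACGX")

    def test_n_flagged_only_when_allowed(self):
        assert normalize("ACGN", allow_n=True) == "ACGN"
        with pytest.raises(AlphabetError):
            normalize("ACGN")


def test_revcomp_example():
    assert revcomp("AUGC") == "GCAU"


from hypothesis import given
from hypothesis import strategies as st


@given(st.text(alphabet="ACGU", max_size=60))
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq


class TestReadFasta:
    def test_record_count(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGU\n>b\nGGGCCC\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]

    def test_dna_normalized(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nacgt\n")
        assert read_fasta(p, alphabet="dna")[0].sequence == "ACGU"

    def test_alphabet_error(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGX\n")
        with pytest.raises(AlphabetError):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_fasta(p)

    def test_duplicate_ids(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGU\n>a\nACGU\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_n_flagging(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGNU\n")
        recs = read_fasta(p, allow_n=True)
        assert recs[0].has_n

    def test_roundtrip(self, tmp_path):
        seqs = [("x1", "ACGUACGUACGU"), ("x2", "GGG" * 40)]
        p = tmp_path / "out.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(t.id, t.sequence) for t in back] == seqs


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("pde-miR159a", "MIR159"),
            ("pde-miR783", "MIR783"),
            ("pde-miR1312a", "MIR1312"),
            ("osa-MIR156k", "MIR156"),
            ("miR482", "MIR482"),
        ],
    )
    def test_examples(self, name, family):
        assert family_from_id(name) == family

    def test_unparseable(self):
        with pytest.raises(ValueError):
            family_from_id("not-a-mirna")


class TestCatalogIO:
    def test_empty_catalog(self, tmp_path):
        p = tmp_path / "catalog.tsv"
        write_catalog([], p)
        assert p.read_text().count("\n") == 1
        assert read_catalog(p) == []

    def test_single_record_roundtrip(self, tmp_path, catalog_records):
        p = tmp_path / "catalog.tsv"
        write_catalog(catalog_records[:1], p)
        assert len(p.read_text().splitlines()) == 2
        assert read_catalog(p) == catalog_records[:1]

    def test_fixture_row_count_and_roundtrip(self, tmp_path, catalog_records):
        p = tmp_path / "catalog.tsv"
        write_catalog(catalog_records, p)
        assert len(p.read_text().splitlines()) == 35
        back = read_catalog(p)
        assert back == list(catalog_records)

    def test_duplicate_names_rejected(self, tmp_path, catalog_records):
        with pytest.raises(ValueError, match="duplicate"):
            write_catalog([catalog_records[0]] * 2, tmp_path / "c.tsv")


def _candidate_for_gff(strand: str):
    from mirkit.synthetic_data import make_hairpin

    pre = make_hairpin("UUUGGUUUGAAGGGAGCUCUA", 0)
    win = CandidateWindow(
        transcript_id="t1",
        strand=strand,
        win_start=10,
        win_end=10 + len(pre),
        sequence=pre,
        mature_offset=0,
        mature_length=21,
    )
    return evaluate(win, fold_mfe(pre))


class TestGFF3:
    def test_coordinates_one_based(self, tmp_path):
        cand = _candidate_for_gff("+")
        p = tmp_path / "out.gff3"
        write_gff3([cand], {"t1": 500}, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        cols = lines[0].split("\t")
        assert cols[2] == "miRNA_primary_transcript"
        assert (int(cols[3]), int(cols[4])) == (11, 10 + cand.window.length)

    def test_minus_strand_emitted(self, tmp_path):
        cand = _candidate_for_gff("-")
        p = tmp_path / "out.gff3"
        write_gff3([cand], {"t1": 500}, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert all(l.split("\t")[6] == "-" for l in lines)

    def test_child_contained_and_grammar(self, tmp_path):
        for strand in "+-":
            cand = _candidate_for_gff(strand)
            p = tmp_path / f"out{strand}.gff3"
            write_gff3([cand], {"t1": 500}, p)
            lines = p.read_text().splitlines()
            assert lines[0] == "##gff-version 3"
            parent = lines[1].split("\t")
            child = lines[2].split("\t")
            assert len(parent) == len(child) == 9
            assert int(parent[3]) <= int(child[3]) <= int(child[4]) <= int(parent[4])
            assert "Parent=" in child[8]

    def test_out_of_bounds_rejected(self, tmp_path):
        cand = _candidate_for_gff("+")
        with pytest.raises(ValueError):
            write_gff3([cand], {"t1": 20}, tmp_path / "bad.gff3")
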