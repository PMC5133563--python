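"""Window extraction, benchmark assembly, and redundancy filtering."""

import pytest

import malsite as ms
from malsite.windows import AnnotationError, ParseError, hamming_identity


def test_read_fasta_single_and_empty(tmp_path):
    f = tmp_path / "one.fasta"
    f.write_text(">P1\nMKAA\n")
    recs = ms.read_fasta(f)
    assert [(r.id, r.sequence) for r in recs] == [("P1", "MKAA")]

    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert ms.read_fasta(empty) == []


def test_read_fasta_wrapped_and_lowercase(tmp_path):
    f = tmp_path / "w.fasta"
    f.write_text(">P1\nmka\nakk\n>P2\nKKKK\n")
    recs = ms.read_fasta(f)
    assert recs[0].sequence == "MKAAKK"
    assert recs[1].id == "P2"


def test_read_fasta_duplicate_id_errors(tmp_path):
    f = tmp_path / "dup.fasta"
    f.write_text(">P1\nMKAA\n>P1\nKKAA\n")
    with pytest.raises(ParseError, match="P1"):
        ms.read_fasta(f)


def test_nonstandard_residues_mapped_to_x(tmp_path):
    f = tmp_path / "u.fasta"
    f.write_text(">P1\nMKUBZ\n")
    recs = ms.read_fasta(f)
    assert recs[0].sequence == "MKXXX"


def test_extract_window_terminal_padding():
    p = ms.ProteinRecord("P1", "MKAA")
    w = ms.extract_window(p, 2)
    assert w.residues == "XXXXXMKAAXXXXXXX"
    assert len(w) == 16


def test_extract_window_interior_has_no_padding():
    p = ms.ProteinRecord("P1", "A" * 6 + "K" + "A" * 9)
    w = ms.extract_window(p, 7)
    assert "X" not in w.residues


@pytest.mark.parametrize("position", range(1, 21))
def test_extract_window_length_constant(position):
    p = ms.ProteinRecord("P1", "MKAVLKWKKYRKDSTQ" + "GHKP")
    assert len(ms.extract_window(p, position)) == 16


def test_extract_window_out_of_range():
    p = ms.ProteinRecord("P1", "MKAA")
    with pytest.raises(AnnotationError):
        ms.extract_window(p, 5)
    with pytest.raises(AnnotationError):
        ms.extract_window(p, 0)


def test_build_benchmark_auto_negatives():
    proteins = [ms.ProteinRecord("P1", "AKAKAKA")]
    annotations = [ms.SiteAnnotation("P1", 2, 1)]
    bench = ms.build_benchmark(proteins, annotations)
    pos = [w for w in bench if w.label == 1]
    neg = [w for w in bench if w.label == 0]
    assert len(pos) == 1 and pos[0].position == 2
    assert sorted(w.position for w in neg) == [4, 6]


def test_build_benchmark_counts_equal_lysine_count():
    proteins = [ms.ProteinRecord("P1", "KAKWKKYKDK"), ms.ProteinRecord("P2", "AAKAA")]
    annotations = [ms.SiteAnnotation("P1", 1, 1), ms.SiteAnnotation("P2", 3, 1)]
    bench = ms.build_benchmark(proteins, annotations)
    n_k = sum(p.sequence.count("K") for p in proteins)
    assert len(bench) == n_k


def test_build_benchmark_no_lysines_no_windows():
    proteins = [ms.ProteinRecord("P1", "AAAA")]
    assert ms.build_benchmark(proteins, []) == []


def test_build_benchmark_non_lysine_annotation_errors():
    proteins = [ms.ProteinRecord("P1", "AKAA")]
    with pytest.raises(AnnotationError, match="P1:3"):
        ms.build_benchmark(proteins, [ms.SiteAnnotation("P1", 3, 1)])


def test_build_benchmark_explicit_negatives_disable_auto():
    proteins = [ms.ProteinRecord("P1", "AKAKAKA")]
    annotations = [ms.SiteAnnotation("P1", 2, 1), ms.SiteAnnotation("P1", 4, 0)]
    bench = ms.build_benchmark(proteins, annotations)
    assert len(bench) == 2  # K6 not auto-added


def test_hamming_identity_thresholds():
    a = "AAAAAAKAAAAAAAAA"
    seven = "AAAAAAKCCCCCCCCC"  # agrees at 7/16 = 0.4375
    six = "AAAAACKCCCCCCCCC"  # agrees at 6/16 = 0.375
    assert hamming_identity(a, seven) == pytest.approx(7 / 16)
    assert hamming_identity(a, six) == pytest.approx(6 / 16)

    wa, w7, w6 = (ms.PeptideWindow(s) for s in (a, seven, six))
    kept, removed = ms.redundancy_filter([wa, w7], threshold=0.4)
    assert [w.residues for w in kept] == [a]
    assert removed[0].removed.residues == seven

    kept, removed = ms.redundancy_filter([wa, w6], threshold=0.4)
    assert len(kept) == 2 and not removed


def test_redundancy_filter_identical_and_log():
    w = ms.PeptideWindow("AAAAAAKAAAAAAAAA")
    kept, removed = ms.redundancy_filter([w, w])
    assert len(kept) == 1
    assert removed[0].identity == 1.0
    assert removed[0].closest_retained.residues == w.residues


def test_redundancy_filter_idempotent(small_dataset):
    ds, _, _ = small_dataset
    kept, _ = ms.redundancy_filter(list(ds.windows), threshold=0.6)
    again, removed = ms.redundancy_filter(kept, threshold=0.6)
    assert len(again) == len(kept) and not removed


def test_redundancy_filter_greedy_semantics():
    # b is removed against a; c matches b but not a, so c survives:
    # comparison is only against previously *retained* windows.
    a = ms.PeptideWindow("AAAAAAKAAAAAAAAA")
    b = ms.PeptideWindow("AAAAAAKAACCCCCCC")  # 9/16 vs a -> removed
    c = ms.PeptideWindow("CCCCCCKAACCCCCCC")  # 10/16 vs b, 4/16 vs a -> kept
    kept, removed = ms.redundancy_filter([a, b, c], threshold=0.4)
    assert [w.residues for w in kept] == [a.residues, c.residues]
    assert len(removed) == 1


def test_redundancy_filter_mixed_lengths_error():
    with pytest.raises(ValueError, match="mixed"):
        ms.redundancy_filter([ms.PeptideWindow("AK"), ms.PeptideWindow("AKA")])


def test_peptide_tsv_round_trip(tmp_path, small_dataset):
    ds, _, _ = small_dataset
    path = tmp_path / "peps.tsv"
    ms.write_peptides(ds.windows, path)
    back = ms.read_peptides(path)
    assert [w.residues for w in back] == [w.residues for w in ds.windows]
    assert [w.label for w in back] == [w.label for w in ds.windows]


def test_site_table_round_trip(tmp_path):
    anns = [ms.SiteAnnotation("P1", 2, 1), ms.SiteAnnotation("P2", 7, 0)]
    path = tmp_path / "sites.tsv"
    ms.write_site_table(anns, path)
    assert ms.read_site_table(path) == anns


def test_site_table_word_labels(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text("protein_id\tposition\tlabel\nP1\t2\tpositive\nP1\t4\tnegative\n")
    anns = ms.read_site_table(path)
    assert [a.label for a in anns] == [1, 0]
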