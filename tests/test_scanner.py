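"""Sequence scanning: coordinates, classes, disorder, summaries, FASTA I/O."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lirscan
from lirscan.errors import (
    DuplicateIdError,
    EmptySequenceError,
    FileFormatError,
    IntervalError,
    LirScanError,
)
from lirscan.patterns import AMINO_ACIDS
from .conftest import naive_scan


def _record(seq, pid="P1"):
    return lirscan.ProteinRecord(id=pid, sequence=seq)


def test_nef_worked_example():
    """EGWQTI embedded at position 11 of an inert context: one xLIR hit
    spanning 11-16."""
    hits = lirscan.scan_sequence(_record("P" * 10 + "EGWQTI" + "P" * 10))
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.window) == (11, 16, "EGWQTI")
    assert h.pattern_class == "xLIR"
    assert h.subtype == "W"
    assert not h.truncated


def test_icp34_5_worked_example():
    """RQWLHV at position 64: a single WxxL (not xLIR) hit, span 64-69."""
    hits = lirscan.scan_sequence(_record("P" * 63 + "RQWLHV" + "P" * 5))
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.window) == (64, 69, "RQWLHV")
    assert h.pattern_class == "WxxL"
    assert h.subtype == "W"


def test_inert_sequence_has_no_hits():
    assert lirscan.scan_sequence(_record("PPPPPP")) == []


def test_coordinates_are_one_based_inclusive():
    for h in lirscan.scan_sequence(_record("AAEGWQTIAAADSYEVLAA")):
        seq = "AAEGWQTIAAADSYEVLAA"
        assert seq[h.start - 1 : h.end] == h.window
        assert h.end - h.start + 1 == len(h.window)


def test_left_edge_truncated_windows():
    # core at position 1: 4-residue window, flagged, always WxxL
    hits = lirscan.scan_sequence(_record("WAALPPPPPP"))
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end, hits[0].window) == (1, 4, "WAAL")
    assert hits[0].truncated and hits[0].pattern_class == "WxxL"
    # core at position 2: 5-residue window
    hits = lirscan.scan_sequence(_record("AWAALPPPPP"))
    assert hits[0].window == "AWAAL" and hits[0].truncated


def test_truncated_hits_have_nan_score(default_pssm):
    hits = lirscan.scan_sequence(_record("WAALPPPPPP"), pssm=default_pssm)
    assert np.isnan(hits[0].pssm_score)


def test_nonstandard_residue_window_skipped(caplog):
    with caplog.at_level(logging.WARNING, logger="lirscan.scanner"):
        hits = lirscan.scan_sequence(_record("PPXGWQTIPP"))
    assert hits == []
    assert any("non-standard" in r.message for r in caplog.records)


def test_empty_sequence_rejected():
    with pytest.raises(EmptySequenceError):
        lirscan.ProteinRecord(id="X", sequence="")


def test_overlapping_hits_all_reported():
    # adjacent cores W..I and F..V share residues; both must be reported
    seq = "AAWFAIVLAA"
    got = {(h.start, h.end) for h in lirscan.scan_sequence(_record(seq))}
    expected = {(s, e) for s, e, *_ in naive_scan(seq)}
    assert got == expected and len(got) >= 2


@given(st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=200))
def test_scanner_equals_naive_regex_oracle(seq):
    got = [
        (h.start, h.end, h.window, h.pattern_class, h.truncated)
        for h in lirscan.scan_sequence(_record(seq))
    ]
    assert got == naive_scan(seq)


def test_scanner_equals_oracle_on_random_batch():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n = int(rng.integers(6, 201))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        got = [
            (h.start, h.end, h.window, h.pattern_class, h.truncated)
            for h in lirscan.scan_sequence(_record(seq))
        ]
        assert got == naive_scan(seq)


def test_prepending_inert_residues_shifts_coordinates():
    base = "AAEGWQTIAAADSYEVLAA"
    for k in (1, 5, 17):
        shifted = "P" * k + base
        a = lirscan.scan_sequence(_record(base))
        b = lirscan.scan_sequence(_record(shifted))
        assert [(h.start + k, h.end + k, h.window) for h in a if not h.truncated] == [
            (h.start, h.end, h.window) for h in b if not h.truncated
        ]


# --- disorder ---------------------------------------------------------------

def _hit(start, end):
    return lirscan.MotifHit(
        protein_id="P1", start=start, end=end, window="X" * (end - start + 1),
        pattern_class="WxxL", subtype="W", pssm_score=0.0,
    )


def test_disorder_full_containment():
    assert lirscan.annotate_disorder(_hit(64, 69), [(50, 100)]).in_disorder is True


def test_disorder_partial_overlap_is_false():
    assert lirscan.annotate_disorder(_hit(11, 16), [(14, 40)]).in_disorder is False


def test_disorder_absent_is_unknown():
    assert lirscan.annotate_disorder(_hit(11, 16), None).in_disorder == "unknown"


@pytest.mark.parametrize("bad", [[(10, 5)], [(1, 10), (5, 20)], [(20, 30), (1, 5)]])
def test_disorder_invalid_intervals(bad):
    with pytest.raises(IntervalError):
        lirscan.annotate_disorder(_hit(1, 6), bad)


# --- summaries --------------------------------------------------------------

def test_summaries_four_way_categories():
    xl = lirscan.scan_sequence(_record("P" * 10 + "EGWQTI" + "P" * 10))
    wx = lirscan.scan_sequence(_record("P" * 10 + "RQWLHV" + "P" * 10, pid="P2"))
    s1 = lirscan.summarize_protein("P1", xl)
    s2 = lirscan.summarize_protein("P2", wx)
    s3 = lirscan.summarize_protein("P3", [])
    s4 = lirscan.summarize_protein("P1", xl + [h for h in xl] )
    assert s1.category == "xlir_only" and s1.motifs_total == 1
    assert s2.category == "wxxl_only"
    assert s3.category == "none" and s3.motifs_total == 0
    both = lirscan.summarize_protein(
        "P1", xl + [lirscan.MotifHit("P1", 30, 35, "RQWLHV", "WxxL", "W", 0.0)]
    )
    assert both.category == "both" and both.motifs_total == 2
    assert s4.motifs_total == s4.n_xlir + s4.n_wxxl


def test_summary_rejects_mixed_proteins():
    hits = lirscan.scan_sequence(_record("P" * 10 + "EGWQTI" + "P" * 10))
    with pytest.raises(LirScanError):
        lirscan.summarize_protein("OTHER", hits)


# --- FASTA / TSV I/O --------------------------------------------------------

TWO_RECORD_FASTA = (
    ">NEF_HV1 Protein Nef OS=Human immunodeficiency virus 1\n"
    + "P" * 10 + "EGWQTI" + "P" * 10 + "\n"
    ">ICP34.5 Neurovirulence factor OS=Human herpesvirus 1\n"
    + "P" * 63 + "RQWLHV" + "P" * 5 + "\n"
)


def test_scan_fasta_two_records(tmp_path, default_pssm):
    fp = tmp_path / "two.fasta"
    fp.write_text(TWO_RECORD_FASTA)
    hits, summaries = lirscan.scan_fasta(fp, pssm=default_pssm)
    assert len(hits) == 2
    assert list(hits.columns) == lirscan.scanner.HIT_COLUMNS
    assert hits.loc[0, "accession"] == "NEF_HV1"
    assert hits.loc[0, "species"] == "Human immunodeficiency virus 1"
    assert set(summaries["category"]) == {"xlir_only", "wxxl_only"}


def test_scan_fasta_empty(tmp_path):
    fp = tmp_path / "empty.fasta"
    fp.write_text("")
    hits, summaries = lirscan.scan_fasta(fp)
    assert hits.empty and summaries.empty


def test_scan_fasta_duplicate_ids(tmp_path):
    fp = tmp_path / "dup.fasta"
    fp.write_text(">A\nPPPPPPP\n>A\nPPPPPPP\n")
    with pytest.raises(DuplicateIdError):
        lirscan.scan_fasta(fp)


def test_disorder_tsv_parsing_and_errors(tmp_path):
    ok = tmp_path / "d.tsv"
    ok.write_text("protein_id\tstart\tend\nICP\t50\t100\n")
    assert lirscan.read_disorder_tsv(ok) == {"ICP": [(50, 100)]}
    bad = tmp_path / "bad.tsv"
    bad.write_text("ICP\t50\n")
    with pytest.raises(FileFormatError) as exc:
        lirscan.read_disorder_tsv(bad)
    assert "line 1" in str(exc.value)
    nonint = tmp_path / "nonint.tsv"
    nonint.write_text("ICP\t50\tXX\n")
    with pytest.raises(FileFormatError):
        lirscan.read_disorder_tsv(nonint)


def test_scan_fasta_with_disorder(tmp_path):
    fp = tmp_path / "p.fasta"
    fp.write_text(">ICP\n" + "P" * 63 + "RQWLHV" + "P" * 51 + "\n")
    dp = tmp_path / "d.tsv"
    dp.write_text("ICP\t50\t100\n")
    hits, _ = lirscan.scan_fasta(fp, disorder_path=dp)
    assert hits.loc[0, "anchor_flag"] is True or hits.loc[0, "anchor_flag"] == True  # noqa: E712


def test_planted_fixture_recovered_exactly():
    spec = lirscan.FixtureSpec(
        n_proteins=20,
        min_length=120,
        max_length=160,
        planted=tuple(
            lirscan.PlantedMotif(i, 31 + 10 * (i % 5), "EGWQTI" if i % 2 else "RQWLHV")
            for i in range(20)
        ),
        background="inert",
        seed=11,
    )
    fasta, truth = lirscan.generate_proteome(spec)
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        fh.write(fasta)
        path = fh.name
    try:
        hits, _ = lirscan.scan_fasta(path)
    finally:
        os.unlink(path)
    got = set(zip(hits["accession"], hits["start"], hits["end"], hits["motif"]))
    expected = set(
        zip(truth["protein_id"], truth["start"], truth["end"], truth["window"])
    )
    assert got == expected and len(got) == 20
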