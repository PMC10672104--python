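"""Read ingestion, length/stop filters and reading-frame selection."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vnarpan import _codec, sequence_io as sio
from vnarpan.pools import PoolId
from vnarpan.simulate import FLANK5

POOL = PoolId("N", 3)

# nt offset of the CDR3 in a simulator amplicon: 5' flank + 87 framework
# and diversity residues (FR1..FR3b) in codons
CDR3_NT_OFFSET = len(FLANK5) + 87 * 3


def _read(seq: str, rid: str = "r0") -> sio.NucleotideRead:
    return sio.NucleotideRead(rid, seq, POOL)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_read_pool_roundtrips_fastq_and_fasta(tmp_path):
    fq = tmp_path / "two.fastq"
    fq.write_text("@a x\nACGT\n+\nIIII\n@b\nGGCC\n+\nIIII\n")
    reads = list(sio.read_pool(fq, POOL))
    assert [r.read_id for r in reads] == ["a", "b"]
    assert [r.sequence for r in reads] == ["ACGT", "GGCC"]

    fa = tmp_path / "two.fasta"
    fa.write_text(">a\nACGT\n>b\nGGCC\n")
    assert [r.sequence for r in sio.read_pool(fa, POOL)] == ["ACGT", "GGCC"]


def test_empty_fasta_yields_empty_stream(tmp_path):
    fa = tmp_path / "empty.fasta"
    fa.write_text("")
    assert list(sio.read_pool(fa, POOL)) == []


def test_malformed_fastq_errors_with_record_index(tmp_path):
    fq = tmp_path / "bad.fastq"
    fq.write_text("@a\nACGT\n+\nIIII\n@b\nACGT\nIIII\n")  # missing '+' line
    with pytest.raises(ValueError, match="index 1"):
        list(sio.read_pool(fq, POOL))


def test_unknown_format_rejected(tmp_path):
    p = tmp_path / "reads.bin"
    p.write_text("")
    with pytest.raises(ValueError):
        list(sio.read_pool(p, POOL))
    with pytest.raises(ValueError):
        list(sio.read_pool(p, POOL, format="sam"))


def test_simulator_fastq_read_count_matches_ledger(tmp_path, small_ledger):
    reads = small_ledger.reads["N3"]
    fq = tmp_path / "N3.fastq"
    reads.write_fastq(fq)
    parsed = list(sio.read_pool(fq, POOL))
    assert len(parsed) == len(reads) == 3000


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,expected", [(401, True), (400, False), (1, False)])
def test_length_filter_is_strict(length, expected):
    assert sio.filter_length(_read("A" * length)) is expected


def test_frame_selection_on_clean_and_shifted_reads(clean_read):
    rid, seq = clean_read
    cand = sio.select_frame_and_translate(_read(seq))
    assert cand.passed_filters and cand.frame == 0

    shifted = sio.select_frame_and_translate(_read("G" + seq))
    assert shifted.passed_filters and shifted.frame == 1
    assert shifted.protein == cand.protein  # same coding content


def test_stop_codon_in_cdr3_rejected(clean_read):
    _rid, seq = clean_read
    mutated = seq[:CDR3_NT_OFFSET] + "TAA" + seq[CDR3_NT_OFFSET + 3 :]
    # oracle: the chosen frame's codons over the VNAR span contain a stop
    assert "TAA" in {mutated[i : i + 3] for i in range(0, len(mutated) - 2, 3)}
    cand = sio.select_frame_and_translate(_read(mutated))
    assert not cand.passed_filters
    assert cand.reject_reason == "internal_stop"


def test_ambiguous_base_inside_span_rejected_outside_kept(clean_read):
    _rid, seq = clean_read
    in_span = seq[:CDR3_NT_OFFSET] + "N" + seq[CDR3_NT_OFFSET + 1 :]
    cand = sio.select_frame_and_translate(_read(in_span))
    assert cand.reject_reason == "ambiguous_base"

    outside = "N" + seq[1:]  # within the 5' vector flank
    cand2 = sio.select_frame_and_translate(_read(outside))
    assert cand2.passed_filters


def test_vectorless_read_has_no_frame():
    cand = sio.select_frame_and_translate(_read("ACGT" * 120))
    assert cand.reject_reason == "no_frame"
    assert not cand.passed_filters


def test_revcomp_search_recovers_reverse_strand_reads(clean_read):
    _rid, seq = clean_read
    rc = _codec.revcomp(seq)
    assert sio.select_frame_and_translate(_read(rc)).reject_reason == "no_frame"
    cand = sio.select_frame_and_translate(_read(rc), revcomp=True)
    assert cand.passed_filters and cand.strand == "-"


def test_filter_composition_is_order_independent(small_ledger):
    """(length then stop) and (stop then length) pass the same read set."""
    reads = list(small_ledger.reads["N3"])[:300]
    batch = sio.filter_and_translate_pool(reads, POOL)
    for (rid, seq), cand in zip(reads, batch):
        seq = seq.decode()
        # independent evaluation of each predicate on every read
        long_enough = len(seq) > 400
        frame_ok = sio.select_frame_and_translate(_read(seq, rid))
        span_clean = frame_ok.passed_filters
        assert cand.passed_filters == (long_enough and span_clean)


def test_batch_and_single_read_paths_agree(small_ledger):
    reads = list(small_ledger.reads["L3"])[:300]
    batch = sio.filter_and_translate_pool(reads, POOL)
    for (rid, seq), cand in zip(reads, batch):
        seq = seq.decode()
        if len(seq) <= 400:
            assert cand.reject_reason == "too_short"
            continue
        single = sio.select_frame_and_translate(_read(seq, rid))
        assert (single.passed_filters, single.frame, single.protein, single.reject_reason) == (
            cand.passed_filters,
            cand.frame,
            cand.protein,
            cand.reject_reason,
        )


def test_planted_pass_fail_partition(clean_read, tmp_path):
    """Exactly the planted survivors pass; the ledger explains the rest."""
    _rid, seq = clean_read
    reads = []
    for i in range(10):
        reads.append((f"pass:{i}", seq))
    for i in range(6):
        reads.append((f"short:{i}", seq[:380]))
    for i in range(4):
        stopped = seq[:CDR3_NT_OFFSET] + "TGA" + seq[CDR3_NT_OFFSET + 3 :]
        reads.append((f"stop:{i}", stopped))
    cands = sio.filter_and_translate_pool(reads, POOL)
    passed = {c.read_id for c in cands if c.passed_filters}
    assert passed == {f"pass:{i}" for i in range(10)}

    ledger_path = tmp_path / "rejects.tsv"
    sio.write_rejection_ledger(cands, ledger_path)
    import pandas as pd

    df = pd.read_csv(ledger_path, sep="\t")
    by_reason = df.groupby("reject_reason")["read_id"].count().to_dict()
    assert by_reason == {"too_short": 6, "internal_stop": 4}


def test_nucleotide_read_validation():
    with pytest.raises(ValueError):
        sio.NucleotideRead("x", "", POOL)
    with pytest.raises(ValueError):
        sio.NucleotideRead("x", "ACGU", POOL)


def test_manifest_roundtrip(tmp_path):
    (tmp_path / "a.fastq").write_text("")
    (tmp_path / "b.fastq").write_text("")
    mf = tmp_path / "manifest.tsv"
    mf.write_text("file\tcondition\tround\na.fastq\tInput\t0\nb.fastq\tN\t3\n")
    entries = sio.read_manifest(mf)
    assert [p.label for _, p in entries] == ["Input", "N3"]
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.tsv"
        bad.write_text("file\tcondition\na.fastq\tN\n")
        sio.read_manifest(bad)
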