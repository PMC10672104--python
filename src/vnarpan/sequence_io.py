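"""Raw-read ingestion and the VNAR coding-sequence filters.

Amplicon reads from a sequenced phage pool pass through three gates before
annotation:

1. a strict length filter (> 400 bp — amplicons shorter than the VNAR
   cassette are truncation artefacts);
2. forward-frame selection: the unique reading frame whose translation
   carries both CDR3 framework anchors (reverse-strand search is optional,
   phagemid amplicons being directional);
3. rejection of reads with a stop codon or an ambiguous base *within the
   anchored VNAR span* — vector context outside the span may contain
   stops or Ns without prejudice.

Quality strings are parsed and discarded; no trimming is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import _codec
from .annotation import AnchorConfig, DEFAULT_ANCHORS
from .pools import PoolId

NT_ALPHABET = set("ACGTN")

REJECT_REASONS = ("too_short", "internal_stop", "no_frame", "ambiguous_base")


@dataclass(frozen=True)
class NucleotideRead:
    read_id: str
    sequence: str
    pool: PoolId

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence.upper()) - NT_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranslatedCandidate:
    """Outcome of the filter + frame-selection stage for one read."""

    read_id: str
    pool: PoolId
    frame: int | None = None
    strand: str = "+"
    protein: str | None = None
    passed_filters: bool = False
    reject_reason: str | None = None
    cdr3: str | None = None  # cached from frame selection (same anchors)


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".fastq", ".fq"):
        return "fastq"
    if suffix in (".fasta", ".fa", ".fna", ".faa"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}; pass format explicitly")


def read_pool(path, pool: PoolId, format: str | None = None) -> Iterator[NucleotideRead]:
    """Stream reads of one pool from a FASTQ or FASTA file, order preserved."""
    fmt = format or _infer_format(path)
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unknown format {fmt!r}")
    with open(path) as handle:
        parser = (
            ((t, s) for t, s, _q in FastqGeneralIterator(handle))
            if fmt == "fastq"
            else SimpleFastaParser(handle)
        )
        index = 0
        while True:
            try:
                title, seq = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record at index {index}: {exc}") from exc
            yield NucleotideRead(title.split()[0], seq.upper(), pool)
            index += 1


def read_manifest(path) -> list[tuple[str, PoolId]]:
    """Parse a TSV manifest with columns file, condition, round."""
    df = pd.read_csv(path, sep="\t", dtype={"condition": str})
    missing = {"file", "condition", "round"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    base = Path(path).parent
    entries = []
    for row in df.itertuples(index=False):
        pool = PoolId(row.condition, int(row.round))
        file = Path(row.file)
        entries.append((str(file if file.is_absolute() else base / file), pool))
    return entries


def filter_length(read: NucleotideRead, min_exclusive: int = 400) -> bool:
    """True iff the read is strictly longer than ``min_exclusive`` bases."""
    return len(read.sequence) > min_exclusive


def _resolve_frame(frames: Sequence[bytes], anchors: AnchorConfig):
    """First frame (lowest index) whose translation holds both CDR3 anchors."""
    compiled = anchors.compiled()
    n_re, c_re = compiled["FR3b"], compiled["FR4"]
    for f, prot in enumerate(frames):
        m = n_re.search(prot)
        if m is None:
            continue
        m2 = c_re.search(prot, m.end())
        if m2 is not None:
            return f, prot, m, m2
    return None


def _span_verdict(prot: bytes, m, m2, anchors: AnchorConfig) -> str | None:
    """Reject reason from stop/N checks over the anchored VNAR span."""
    fr1 = anchors.compiled()["FR1"].search(prot, 0, m.start())
    span_start = fr1.start() if fr1 is not None else m.start()
    span = prot[span_start : m2.end()]
    if b"*" in span:
        return "internal_stop"
    if b"X" in span:
        return "ambiguous_base"
    return None


def select_frame_and_translate(
    read: NucleotideRead,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
    revcomp: bool = False,
) -> TranslatedCandidate:
    """Translate the forward frames and pick the anchored VNAR frame.

    With ``revcomp=True`` the three reverse-complement frames are searched
    as well (forward frames take precedence).
    """
    cand = TranslatedCandidate(read_id=read.read_id, pool=read.pool)
    for strand in ("+", "-") if revcomp else ("+",):
        seq = read.sequence if strand == "+" else _codec.revcomp(read.sequence)
        mat, lengths = _codec.encode_reads([seq])
        frames = [_codec.translate_matrix(mat, lengths, f)[0] for f in range(3)]
        hit = _resolve_frame(frames, anchors)
        if hit is not None:
            f, prot, m, m2 = hit
            cand.frame, cand.strand = f, strand
            reason = _span_verdict(prot, m, m2, anchors)
            if reason is None:
                cand.protein = prot.decode("ascii")
                cand.passed_filters = True
                cand.cdr3 = prot[m.end() : m2.start()].decode("ascii")
            else:
                cand.reject_reason = reason
            return cand
    cand.reject_reason = "no_frame"
    return cand


def filter_and_translate_pool(
    reads: Iterable[NucleotideRead] | Iterable[tuple[str, str]],
    pool: PoolId,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
    min_len: int = 400,
    revcomp: bool = False,
) -> list[TranslatedCandidate]:
    """Apply length filter + frame selection to a whole pool, vectorised.

    Accepts :class:`NucleotideRead` objects, plain ``(id, seq)`` pairs, or
    any object exposing ``code_matrix()``/``ids`` (the simulator's in-memory
    output, which then skips the text round trip).  Returns one candidate
    per input read, order preserved; the length and stop filters commute,
    so the fixed evaluation order here is a pure implementation choice.
    """
    seq_of = None  # lazy accessor, needed only for the revcomp fallback
    if hasattr(reads, "code_matrix"):
        full_mat, full_lens = reads.code_matrix()
        ids = list(reads.ids)
        seq_of = lambda i: reads.sequences[i].decode("ascii")  # noqa: E731
    else:
        ids = []
        seqs: list[str] = []
        for item in reads:
            if isinstance(item, NucleotideRead):
                ids.append(item.read_id)
                seqs.append(item.sequence)
            else:
                rid, seq = item
                ids.append(rid)
                seqs.append(seq if isinstance(seq, str) else seq.decode("ascii"))
        full_mat, full_lens = _codec.encode_reads(seqs)
        seq_of = lambda i: seqs[i]  # noqa: E731

    candidates = [TranslatedCandidate(read_id=rid, pool=pool) for rid in ids]
    keep_mask = full_lens > min_len
    keep_idx = np.flatnonzero(keep_mask).tolist()
    for i in np.flatnonzero(~keep_mask).tolist():
        candidates[i].reject_reason = "too_short"
    if not keep_idx:
        return candidates

    # translate the whole matrix (cheaper than gathering the kept rows) but
    # resolve frames only for length-passing reads
    mat = full_mat
    lengths = full_lens
    compiled = anchors.compiled()
    n_re, c_re, fr1_re = compiled["FR3b"], compiled["FR4"], compiled["FR1"]

    def finish(cand: TranslatedCandidate, f: int, prot: bytes, m, m2) -> None:
        cand.frame = f
        fr1 = fr1_re.search(prot, 0, m.start())
        span_start = fr1.start() if fr1 is not None else m.start()
        span = prot[span_start : m2.end()]
        if b"*" in span:
            cand.reject_reason = "internal_stop"
        elif b"X" in span:
            cand.reject_reason = "ambiguous_base"
        else:
            cand.protein = prot.decode("ascii")
            cand.passed_filters = True
            cand.cdr3 = prot[m.end() : m2.start()].decode("ascii")

    # frame 0 first for every read; the other frames are translated only
    # for the few reads frame 0 cannot resolve
    frame0 = _codec.translate_matrix(mat, lengths, 0)
    unresolved: list[int] = []
    for i in keep_idx:
        prot = frame0[i]
        m = n_re.search(prot)
        m2 = c_re.search(prot, m.end()) if m is not None else None
        if m2 is not None:
            finish(candidates[i], 0, prot, m, m2)
        else:
            unresolved.append(i)

    if unresolved:
        sub = mat[unresolved]
        sub_lens = lengths[unresolved]
        frames12 = [_codec.translate_matrix(sub, sub_lens, f) for f in (1, 2)]
        for k, i in enumerate(unresolved):
            hit = None
            for f in (1, 2):
                prot = frames12[f - 1][k]
                m = n_re.search(prot)
                if m is None:
                    continue
                m2 = c_re.search(prot, m.end())
                if m2 is not None:
                    hit = (f, prot, m, m2)
                    break
            if hit is not None:
                finish(candidates[i], *hit)
            elif revcomp:
                candidates[i] = select_frame_and_translate(
                    NucleotideRead(ids[i], seq_of(i), pool), anchors, revcomp=True
                )
            else:
                candidates[i].reject_reason = "no_frame"
    return candidates


def write_protein_fasta(candidates: Iterable[TranslatedCandidate], path) -> int:
    """Write passing candidates as protein FASTA; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for cand in candidates:
            if cand.passed_filters:
                fh.write(f">{cand.read_id}\n{cand.protein}\n")
                n += 1
    return n


def write_rejection_ledger(candidates: Iterable[TranslatedCandidate], path) -> int:
    """Write a TSV of rejected reads (read_id, reject_reason)."""
    rows = [(c.read_id, c.reject_reason) for c in candidates if not c.passed_filters]
    pd.DataFrame(rows, columns=["read_id", "reject_reason"]).to_csv(path, sep="\t", index=False)
    return len(rows)
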