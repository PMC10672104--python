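"""Nucleotide/protein codecs shared by the read pipeline and the simulator.

Translation uses the standard genetic code (NCBI table 1, via Biopython's
codon tables) applied in bulk with a 5-letter alphabet (A, C, G, T plus a
sentinel for N/padding).  Codons containing the sentinel translate to ``X``,
stop codons to ``*`` — both are plain characters so that downstream motif
scans and span checks can reason about them positionally.

Back-translation picks one fixed codon per residue (the highest-frequency
E. coli codon); it is deterministic, so ``translate(back_translate(p)) == p``
holds exactly and the simulator's emitted reads are reproducible.
"""
from __future__ import annotations

from itertools import product
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

NT_LETTERS = b"ACGT"
_SENTINEL = 4  # N or padding

# byte value -> 0..3 code, anything else -> sentinel
_NT_CODE = np.full(256, _SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(NT_LETTERS):
    _NT_CODE[_b] = _i
    _NT_CODE[_b + 32] = _i  # lowercase

_NT_BYTE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _build_codon_lut() -> np.ndarray:
    """64-entry standard-code lookup embedded in a 125-entry base-5 table."""
    table = CodonTable.unambiguous_dna_by_id[1]
    lut = np.full(5 * 5 * 5, ord("X"), dtype=np.uint8)
    for a, b, c in product(range(4), repeat=3):
        codon = "".join(chr(NT_LETTERS[x]) for x in (a, b, c))
        aa = "*" if codon in table.stop_codons else table.forward_table[codon]
        lut[a * 25 + b * 5 + c] = ord(aa)
    return lut


_CODON_LUT = _build_codon_lut()

#: One fixed codon per amino acid: the majority codon in highly expressed
#: E. coli genes.  Shipped as data so the simulator's encoder is transparent.
PREFERRED_CODONS = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAG", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(protein: str) -> str:
    """Encode a protein with the fixed preferred-codon table."""
    try:
        return "".join(PREFERRED_CODONS[aa] for aa in protein)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from None


def encode_reads(seqs: Sequence[bytes | str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack reads into a padded uint8 code matrix.

    Returns ``(matrix, lengths)`` where the matrix holds 0-3 nucleotide codes
    with the sentinel value for N and for padding beyond each read's length.
    """
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    width = int(lengths.max()) if len(seqs) else 0
    buf = np.full((len(seqs), width), _SENTINEL, dtype=np.uint8)
    for i, s in enumerate(seqs):
        raw = s.encode("ascii") if isinstance(s, str) else s
        buf[i, : len(raw)] = _NT_CODE[np.frombuffer(raw, dtype=np.uint8)]
    return buf, lengths


_CODE2NT = bytes.maketrans(bytes(range(5)), b"ACGTN")


def decode_codes(codes: np.ndarray) -> bytes:
    """Turn a 1-D code vector back into nucleotide letters."""
    return codes.tobytes().translate(_CODE2NT)


def translate_matrix(mat: np.ndarray, lengths: np.ndarray, frame: int) -> list[bytes]:
    """Translate every row of a code matrix in the given forward frame.

    Each returned protein is trimmed to the complete codons of that read;
    codons touching an N become ``X`` and stops become ``*``.
    """
    n, width = mat.shape
    n_codons = (width - frame) // 3
    if n_codons <= 0:
        return [b""] * n
    trimmed = mat[:, frame : frame + 3 * n_codons]
    cods = trimmed.reshape(n, n_codons, 3)
    # base-5 codon index; max value 124 so uint8 arithmetic cannot overflow
    idx = cods[:, :, 0] * np.uint8(25) + cods[:, :, 1] * np.uint8(5) + cods[:, :, 2]
    aa = _CODON_LUT[idx]  # (n, n_codons) of ascii bytes
    flat = aa.tobytes()
    aa_lens = np.maximum((lengths - frame) // 3, 0).tolist()
    return [flat[i * n_codons : i * n_codons + aa_lens[i]] for i in range(n)]


def translate(seq: str | bytes, frame: int = 0) -> str:
    """Translate a single sequence in one forward frame (standard code)."""
    mat, lengths = encode_reads([seq])
    return translate_matrix(mat, lengths, frame)[0].decode("ascii")


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def iter_chunks(items: Sequence, size: int) -> Iterable[Sequence]:
    for start in range(0, len(items), size):
        yield items[start : start + size]
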