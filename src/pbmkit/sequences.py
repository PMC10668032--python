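"""DNA sequence utilities shared across the package.

Sequences are strings over {A,C,G,T}; internally most routines work on
integer-encoded arrays (A=0, C=1, G=2, T=3) so that k-mers can be packed
into machine integers and whole probe sets processed with numpy.
All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# IUPAC degenerate nucleotide codes -> set of concrete bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# base-set -> smallest IUPAC code covering it
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    joined = encode("".join(seqs))
    return joined.reshape(len(seqs), lengths.pop())


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of encoded sequences into integers.

    ``enc`` is (n, L) uint8; returns (n, L-k+1) integer codes where code =
    sum base_j * 4**(k-1-j), i.e. big-endian in sequence order.
    """
    enc = np.atleast_2d(enc)
    n, L = enc.shape
    w = L - k + 1
    if w <= 0:
        raise ValueError(f"sequences of length {L} have no {k}-mers")
    out = np.zeros((n, w), dtype=np.int64)
    for j in range(k):
        out = out * 4 + enc[:, j:j + w]
    return out


def revcomp_code_table(k: int) -> np.ndarray:
    """Lookup table mapping each packed k-mer code to its reverse complement's code."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    for j in range(k):
        base = (codes >> (2 * j)) & 3          # base at position k-1-j
        rc = rc | ((3 - base) << (2 * (k - 1 - j)))
    # position k-1-j complements to position j of the reverse complement:
    # shifting by 2*(k-1-j) places it at rc position j read big-endian.
    return rc


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append(BASES[(code >> (2 * j)) & 3])
    return "".join(out)


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * 4 + _BASE_TO_CODE[ch]
    return code


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regular expression over ACGT."""
    parts = []
    for ch in pattern:
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(ch if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return "".join(parts)
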