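"""DNA sequence primitives: validation, one-hot encoding, reverse
complementation, palindrome detection and FASTA I/O.

A DNA *palindrome* here is the molecular-biology notion — a sequence equal
to its own reverse complement (an inverted repeat reading identically on
both strands), characteristic of transposon ends and REP elements.  Two
detection modes are supported:

``strict``
    the sequence equals its reverse complement exactly; such sequences
    necessarily have even length.
``center-gapped``
    additionally accepts odd lengths whose single center base is left
    unpaired, i.e. the prefix before the center equals the reverse
    complement of the suffix after it.  This is the default for feature
    searches, so that odd-length inverted repeats such as ``CGTTGGCAACG``
    count as palindromic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGTN"
#: fixed channel order of the one-hot encoding
CHANNELS = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(CHANNELS)}

PalindromeMode = Literal["strict", "center-gapped"]


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,N}."""


@dataclasses.dataclass(frozen=True)
class DnaSequence:
    """An uppercase DNA string over {A,C,G,T,N} with an identifier."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        folded = self.bases.upper()
        if folded != self.bases:
            object.__setattr__(self, "bases", folded)
        invalid = set(self.bases) - set(DNA_ALPHABET)
        if invalid:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters: {sorted(invalid)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, item) -> str:
        return self.bases[item]


@dataclasses.dataclass(frozen=True)
class PalindromeHit:
    """A maximal palindromic substring, 0-based half-open coordinates."""

    start: int
    end: int
    mode: PalindromeMode

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_bases(seq: "DnaSequence | str") -> str:
    if isinstance(seq, DnaSequence):
        return seq.bases
    return DnaSequence("anonymous", seq).bases


def reverse_complement(seq: "DnaSequence | str") -> "DnaSequence | str":
    """Watson–Crick complement, reversed. N maps to N; an involution."""
    if isinstance(seq, DnaSequence):
        return DnaSequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1])
    return _as_bases(seq).translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: "DnaSequence | str", dtype=np.float32) -> np.ndarray:
    """Encode a sequence as an L×4 matrix, channel order (A,C,G,T).

    N encodes as an all-zero row: it sets no channel bit and contributes
    nothing to downstream convolutions.
    """
    bases = _as_bases(seq)
    mat = np.zeros((len(bases), 4), dtype=dtype)
    for i, b in enumerate(bases):
        j = _BASE_INDEX.get(b)
        if j is not None:
            mat[i, j] = 1
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an L×4 matrix, got shape {matrix.shape}")
    out = []
    for row in matrix:
        hot = np.flatnonzero(row)
        out.append(CHANNELS[hot[0]] if hot.size else "N")
    return "".join(out)


def _pairs(a: str, b: str) -> bool:
    """True if base `a` Watson–Crick pairs with base `b` (N pairs nothing)."""
    return a != "N" and b == a.translate(_COMPLEMENT)


def is_palindromic(seq: "DnaSequence | str", mode: PalindromeMode = "strict") -> bool:
    """Is the sequence equal to its reverse complement?

    ``center-gapped`` mode additionally accepts odd lengths with one
    unpaired center base; on even lengths the two modes coincide.
    """
    bases = _as_bases(seq)
    n = len(bases)
    if n == 0:
        return False
    if n % 2 == 1:
        if mode != "center-gapped":
            return False
        half = n // 2
        return all(_pairs(bases[i], bases[n - 1 - i]) for i in range(half))
    return all(_pairs(bases[i], bases[n - 1 - i]) for i in range(n // 2))


def find_palindromes(
    seq: "DnaSequence | str",
    min_len: int = 10,
    mode: PalindromeMode = "center-gapped",
) -> list[PalindromeHit]:
    """All maximal palindromic substrings of length ≥ ``min_len``.

    Uses expansion around every pairing center.  A hit is *maximal* when it
    cannot be extended by one base on both ends while remaining palindromic
    (extension is necessarily symmetric: it preserves the center).
    Overlapping maximal hits at different centers are all reported, sorted
    by start.

    Parameters
    ----------
    min_len:
        minimum reported length, ≥ 2.
    mode:
        ``strict`` searches even-length centers only; ``center-gapped``
        also expands around odd centers with one unpaired middle base.
    """
    if min_len < 2:
        raise ValueError("min_len must be ≥ 2")
    bases = _as_bases(seq)
    n = len(bases)
    hits: list[PalindromeHit] = []

    def expand(lo: int, hi: int) -> tuple[int, int]:
        # grow [lo, hi) while the outer bases pair
        while lo > 0 and hi < n and _pairs(bases[lo - 1], bases[hi]):
            lo -= 1
            hi += 1
        return lo, hi

    # even centers: between positions c-1 and c
    for c in range(1, n):
        lo, hi = expand(c, c)
        if hi - lo >= max(min_len, 2):
            hits.append(PalindromeHit(lo, hi, mode))
    if mode == "center-gapped":
        # odd centers: unpaired base at c
        for c in range(n):
            lo, hi = expand(c, c + 1)
            if hi - lo >= max(min_len, 3):
                hits.append(PalindromeHit(lo, hi, mode))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def read_fasta(path: "str | Path") -> list[DnaSequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Bases are case-folded to uppercase; characters outside {A,C,G,T,N}
    raise :class:`SequenceError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(DnaSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(seqs: Iterable[DnaSequence], path: "str | Path", width: int = 80) -> None:
    """Write sequences as FASTA with ``width``-column wrapping."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")
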