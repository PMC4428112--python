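"""2-bit k-mer codec: encoding, reverse complement, canonical form, extraction.

A k-mer (k <= 32) is packed into a Python integer at 2 bits per base,
A=0, C=1, G=2, T=3, with the first base in the most significant bits, so
that lexicographic order of equal-length k-mer strings coincides with
integer order of their codes. Matching is strand-independent: every k-mer
is reduced to its *canonical* form, the smaller of the forward and
reverse-complement codes, before being stored or looked up.

Input handling is deliberately tolerant: lower case is accepted and U is
read as T. Any other character (N, IUPAC ambiguity codes, gaps) makes the
window invalid; :func:`extract_kmers` silently skips invalid windows,
which is the k-spectrum convention.
"""

from __future__ import annotations

from .errors import AmbiguousBaseError, ConfigurationError

MAX_K = 32

_BASES = "ACGT"

# ord(char) -> 2-bit code, -1 for anything that invalidates a window
_CODE = [-1] * 256
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

_RC_TABLE = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ConfigurationError(f"k must be in [1, {MAX_K}], got {k}")


def encode_kmer(seq: str) -> int:
    """Pack a k-mer string into its 2-bit integer code.

    Raises :class:`AmbiguousBaseError` on any non-ACGT character and
    :class:`ConfigurationError` if ``len(seq)`` is outside [1, 32].
    """
    _check_k(len(seq))
    code = 0
    for ch in seq:
        b = _CODE[ord(ch)] if ord(ch) < 256 else -1
        if b < 0:
            raise AmbiguousBaseError(f"non-ACGT base {ch!r} in k-mer {seq!r}")
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`; returns the upper-case k-mer string."""
    _check_k(k)
    if not 0 <= code < 1 << (2 * k):
        raise ValueError(f"code {code} out of range for k={k}")
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer (an involution)."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> int:
    """Strand-independent representative: min(code, revcomp(code))."""
    rc = revcomp_code(code, k)
    return code if code <= rc else rc


def revcomp_seq(seq: str) -> str:
    """Reverse complement of a nucleotide string; non-ACGTU characters pass through."""
    return seq.translate(_RC_TABLE)[::-1]


def extract_kmers(seq: str, k: int) -> list[tuple[int, int]]:
    """All valid k-mer windows of ``seq`` as (0-based start, canonical code).

    Windows containing any non-ACGTU character are skipped; a sequence
    shorter than k yields an empty list. Uses a rolling update so both the
    forward and reverse-complement codes cost O(1) per window.
    """
    _check_k(k)
    mask = (1 << (2 * k)) - 1
    rc_shift = 2 * (k - 1)
    out: list[tuple[int, int]] = []
    fwd = 0
    rc = 0
    run = 0  # length of the current run of valid bases
    code_of = _CODE
    for i, ch in enumerate(seq):
        o = ord(ch)
        b = code_of[o] if o < 256 else -1
        if b < 0:
            run = 0
            fwd = 0
            rc = 0
            continue
        fwd = ((fwd << 2) | b) & mask
        rc = (rc >> 2) | ((3 - b) << rc_shift)
        run += 1
        if run >= k:
            out.append((i - k + 1, fwd if fwd <= rc else rc))
    return out
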