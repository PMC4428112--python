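"""Independent string-based brute-force oracles used by the test suite.

Everything here works on k-mer *strings* with plain dict/set tabulation,
deliberately sharing no code with the package's integer-coded pipeline.
Lexicographic order over {A<C<G<T} coincides with the 2-bit integer
order, so string canonicalization (min of forward and reverse complement)
matches the package's canonical codes.
"""

from collections import Counter

_RC = str.maketrans("ACGT", "TGCA")
_VALID = set("ACGT")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def valid_windows(seq: str, k: int) -> list[tuple[int, str]]:
    """All (position, canonical k-mer string) windows containing only ACGT."""
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= _VALID:
            out.append((i, canon(w)))
    return out


def brute_discriminative(
    genomes: list[tuple[str, str]],
    k: int,
    min_occurrence: int = 1,
    arm_pairs: list[tuple[str, str, str]] = (),
) -> dict[str, Counter]:
    """Per-target Counter of discriminative canonical k-mers.

    Tabulates every window of every (label, sequence) input, drops k-mers
    seen in more than one label — re-routing those seen in exactly the two
    arms of a declared pair to the centromere pseudo-label — then applies
    the minimum-occurrence filter.
    """
    per_label: dict[str, Counter] = {}
    for label, seq in genomes:
        counter = per_label.setdefault(label, Counter())
        for _pos, w in valid_windows(seq, k):
            counter[w] += 1
    owners: dict[str, set] = {}
    totals: Counter = Counter()
    for label, counter in per_label.items():
        for w, n in counter.items():
            owners.setdefault(w, set()).add(label)
            totals[w] += n
    cent_of = {frozenset((a, b)): c for a, b, c in arm_pairs}
    out: dict[str, Counter] = {label: Counter() for label in per_label}
    for _a, _b, c in arm_pairs:
        out.setdefault(c, Counter())
    for w, who in owners.items():
        if len(who) == 1:
            (dest,) = who
        elif len(who) == 2 and frozenset(who) in cent_of:
            dest = cent_of[frozenset(who)]
        else:
            continue
        if totals[w] >= min_occurrence:
            out[dest][w] = totals[w]
    return out


def brute_hits(read: str, k: int, disc: dict[str, Counter]) -> dict[str, int]:
    """Per-target window hit counts for one read, by direct set membership."""
    hits = dict.fromkeys(disc, 0)
    for _pos, w in valid_windows(read, k):
        for label, counter in disc.items():
            if w in counter:
                hits[label] += 1
    return hits
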