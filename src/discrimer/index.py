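"""Discriminative k-mer index: counting, cross-target filtering, sampling, storage.

The index is built in two passes. First every k-mer of every target
sequence is tabulated with (a) the id of one target containing it, (b) the
exact number of *distinct* targets containing it and (c) its total
occurrence count. Second, any k-mer present in more than one target is
removed — with one exception: a k-mer present in exactly the two arms of a
declared chromosome-arm pair (and nowhere else) is re-assigned to that
pair's centromere pseudo-target, since arm-shared sequence marks the
centromeric region of overlap. A minimum-occurrence filter then discards
rare k-mers, which tend to be spurious when targets are built from reads.

Two memory-reduction samplings of a built index are supported:

``half``
    keep every other k-mer of each target's code-sorted discriminative
    set (the half-sized index used by the early-stopping default mode);
``light_stride``
    k = 27 only: keep one 27-mer window then skip the next four
    non-overlapping ones, i.e. only k-mers starting at positions that are
    multiples of 135 in the original target sequences (the low-memory
    variant).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError, IndexCorruptedError, IndexFormatError
from .kmer_core import extract_kmers

SAMPLING_NONE = "none"
SAMPLING_HALF = "half"
SAMPLING_LIGHT = "light_stride"
_SAMPLINGS = (SAMPLING_NONE, SAMPLING_HALF, SAMPLING_LIGHT)

LIGHT_K = 27
#: keep one 27-mer window, skip the next four non-overlapping ones
LIGHT_STRIDE = 5 * LIGHT_K

_MAGIC = b"DKMIX"
_VERSION = 1


@dataclass
class TargetTable:
    """Ordered target labels plus the sequence->target mapping.

    ``arm_pairs`` optionally declares (long-arm, short-arm, centromere)
    label triples; centromere pseudo-labels are appended to ``labels``
    automatically if absent and must not carry input sequences.
    """

    labels: list[str]
    seq_to_target: dict[str, str] = field(default_factory=dict)
    arm_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.arm_pairs = [tuple(p) for p in self.arm_pairs]  # type: ignore[misc]
        for long_arm, short_arm, cent in self.arm_pairs:
            for arm in (long_arm, short_arm):
                if arm not in self.labels:
                    raise ConfigurationError(f"arm pair references unknown target {arm!r}")
            if cent in (long_arm, short_arm):
                raise ConfigurationError(f"centromere label {cent!r} clashes with an arm label")
            if cent not in self.labels:
                self.labels.append(cent)
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("target labels must be unique")
        self._ids = {label: i for i, label in enumerate(self.labels)}
        cents = self.centromere_labels()
        for seq_id, label in self.seq_to_target.items():
            if label not in self._ids:
                raise ConfigurationError(f"sequence {seq_id!r} mapped to unknown target {label!r}")
            if label in cents:
                raise ConfigurationError(f"centromere pseudo-target {label!r} cannot own sequences")

    def id_of(self, label: str) -> int:
        try:
            return self._ids[label]
        except KeyError:
            raise ConfigurationError(f"unknown target label {label!r}") from None

    def label_of(self, target_id: int) -> str:
        return self.labels[target_id]

    def centromere_labels(self) -> set[str]:
        return {cent for _, _, cent in self.arm_pairs}

    @property
    def n_targets(self) -> int:
        return len(self.labels)


class RawIndexEntry:
    """Per-k-mer tally from the counting pass.

    Tracks the first two distinct target ids inline and any further ones
    in a lazily created set, so ``n_targets`` is an exact distinct count
    while single-target k-mers (the vast majority) stay cheap.
    """

    __slots__ = ("target_id", "occurrences", "_second", "_extra")

    def __init__(self, target_id: int):
        self.target_id = target_id
        self.occurrences = 1
        self._second = -1
        self._extra: set[int] | None = None

    def add(self, target_id: int) -> None:
        self.occurrences += 1
        if target_id == self.target_id or target_id == self._second:
            return
        if self._second < 0:
            self._second = target_id
        elif self._extra is None:
            self._extra = {target_id}
        else:
            self._extra.add(target_id)

    @property
    def n_targets(self) -> int:
        n = 1 + (self._second >= 0)
        if self._extra is not None:
            n += len(self._extra)
        return n

    def target_ids(self) -> list[int]:
        ids = [self.target_id]
        if self._second >= 0:
            ids.append(self._second)
        if self._extra is not None:
            ids.extend(sorted(self._extra))
        return ids


@dataclass
class DiscriminativeIndex:
    """Map canonical k-mer code -> (target_id, occurrences) after filtering."""

    k: int
    entries: dict[int, tuple[int, int]]
    table: TargetTable
    min_occurrence: int = 1
    sampling: str = SAMPLING_NONE

    def __post_init__(self) -> None:
        if self.sampling not in _SAMPLINGS:
            raise ConfigurationError(f"unknown sampling mode {self.sampling!r}")

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def per_target_kmers(self) -> dict[str, list[int]]:
        """Code-sorted discriminative k-mer list per target label."""
        by_target: dict[str, list[int]] = {label: [] for label in self.table.labels}
        for code, (tid, _occ) in self.entries.items():
            by_target[self.table.label_of(tid)].append(code)
        for codes in by_target.values():
            codes.sort()
        return by_target

    def per_target_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(self.table.labels, 0)
        for _code, (tid, _occ) in self.entries.items():
            counts[self.table.label_of(tid)] += 1
        return counts

    def params_digest(self) -> str:
        """Hash of the build parameters, used to detect stale index files."""
        return build_params_digest(
            self.k, self.min_occurrence, self.sampling, self.table
        )


def build_params_digest(
    k: int, min_occurrence: int, sampling: str, table: TargetTable
) -> str:
    h = hashlib.sha256()
    payload = (
        k,
        min_occurrence,
        sampling,
        tuple(table.labels),
        tuple(sorted(table.seq_to_target.items())),
        tuple(table.arm_pairs),
    )
    h.update(repr(payload).encode())
    return h.hexdigest()


def count_target_kmers(
    targets: Iterable[tuple[str, str]], table: TargetTable, k: int
) -> dict[int, RawIndexEntry]:
    """Tabulate all canonical k-mers of ``targets`` ((sequence, label) pairs).

    Multiple sequences with the same label are one target: ``n_targets``
    counts distinct labels, and occurrences sum over all sequences.
    """
    raw: dict[int, RawIndexEntry] = {}
    n_inputs = 0
    for seq, label in targets:
        n_inputs += 1
        tid = table.id_of(label)
        for _pos, code in extract_kmers(seq, k):
            entry = raw.get(code)
            if entry is None:
                raw[code] = RawIndexEntry(tid)
            else:
                entry.add(tid)
    if n_inputs == 0:
        raise ConfigurationError("empty target set: no input sequences")
    return raw


def merge_kmer_distribution(
    raw: dict[int, RawIndexEntry],
    distribution: Mapping[int, int],
    table: TargetTable,
    label: str,
) -> None:
    """Fold a pre-counted k-mer distribution (canonical code -> count) into ``raw``.

    Used when a target is supplied as a k-mer distribution file instead of
    sequences.
    """
    tid = table.id_of(label)
    for code, count in distribution.items():
        if count <= 0:
            continue
        entry = raw.get(code)
        if entry is None:
            entry = RawIndexEntry(tid)
            entry.occurrences = count
            raw[code] = entry
        else:
            entry.add(tid)
            entry.occurrences += count - 1


def make_discriminative(
    raw: Mapping[int, RawIndexEntry],
    table: TargetTable,
    min_occurrence: int = 1,
    k: int = 0,
) -> DiscriminativeIndex:
    """Remove cross-target k-mers (with the centromere exception) and rare k-mers.

    A k-mer in >= 2 targets is dropped unless those targets are exactly the
    two arms of a declared arm pair, in which case it is re-assigned to the
    pair's centromere pseudo-target. Surviving entries with fewer than
    ``min_occurrence`` total occurrences are dropped. The raw map does not
    record k, so pass the k it was counted at (or use :func:`build_index`).
    """
    if min_occurrence < 1:
        raise ConfigurationError("min_occurrence must be >= 1")
    cent_of: dict[frozenset[int], int] = {}
    for long_arm, short_arm, cent in table.arm_pairs:
        pair = frozenset((table.id_of(long_arm), table.id_of(short_arm)))
        cent_of[pair] = table.id_of(cent)

    entries: dict[int, tuple[int, int]] = {}
    for code, entry in raw.items():
        n = entry.n_targets
        if n == 1:
            tid = entry.target_id
        elif n == 2 and cent_of:
            cent = cent_of.get(frozenset(entry.target_ids()))
            if cent is None:
                continue
            tid = cent
        else:
            continue
        if entry.occurrences >= min_occurrence:
            entries[code] = (tid, entry.occurrences)
    return DiscriminativeIndex(k=k, entries=entries, table=table, min_occurrence=min_occurrence)


def build_index(
    targets: Iterable[tuple[str, str]],
    table: TargetTable,
    k: int,
    min_occurrence: int = 1,
) -> DiscriminativeIndex:
    """Counting pass + discriminative filtering in one call (sampling: none)."""
    raw = count_target_kmers(targets, table, k)
    return make_discriminative(raw, table, min_occurrence, k=k)


def sample_index(
    index: DiscriminativeIndex,
    mode: str,
    targets: Iterable[tuple[str, str]] | None = None,
) -> DiscriminativeIndex:
    """Reduce an unsampled index for the default (half) or light (stride) mode.

    ``default_half`` keeps the even ranks of each target's code-sorted
    discriminative set, so roughly half the k-mers per target survive and
    the selection is deterministic. ``light_stride`` (k = 27 only) keeps
    k-mers starting at positions = 0 (mod 135) in the original target
    sequences, which must be passed as ``targets``; a kept k-mer must
    still be discriminative, so the position sample is intersected with
    the existing entries.
    """
    if index.sampling != SAMPLING_NONE:
        raise ConfigurationError(f"index already sampled ({index.sampling})")
    if mode == "default_half":
        kept: dict[int, tuple[int, int]] = {}
        for codes in index.per_target_kmers().values():
            for code in codes[::2]:
                kept[code] = index.entries[code]
        new_sampling = SAMPLING_HALF
    elif mode == SAMPLING_LIGHT:
        if index.k != LIGHT_K:
            raise ConfigurationError(f"light-stride sampling requires k={LIGHT_K}, got k={index.k}")
        if targets is None:
            raise ConfigurationError("light-stride sampling needs the original target sequences")
        sampled: set[int] = set()
        for seq, _label in targets:
            for pos, code in extract_kmers(seq, LIGHT_K):
                if pos % LIGHT_STRIDE == 0:
                    sampled.add(code)
        kept = {code: v for code, v in index.entries.items() if code in sampled}
        new_sampling = SAMPLING_LIGHT
    else:
        raise ConfigurationError(f"unknown sampling mode {mode!r}")
    return DiscriminativeIndex(
        k=index.k,
        entries=kept,
        table=index.table,
        min_occurrence=index.min_occurrence,
        sampling=new_sampling,
    )


# ---------------------------------------------------------------------------
# serialization
#
# magic | version u8 | k u8 | sampling u8 | min_occurrence u32 | digest
# (u8 len + ascii) | labels (u32 n, each u16 len + utf8) | seq_to_target
# (u32 n, each u16+utf8 key, u32 label id) | arm pairs (u32 n, each 3*u32
# label ids) | entries (u64 n, then code-sorted (u64 code, u32 target_id,
# u32 occurrences) records)

_HDR = struct.Struct("<BBBI")
_REC = struct.Struct("<QII")


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IndexCorruptedError(f"index file truncated while reading {what}")
    return buf


def _write_str(fh, s: str) -> None:
    b = s.encode()
    fh.write(struct.pack("<H", len(b)))
    fh.write(b)


def _read_str(fh, what: str) -> str:
    (n,) = struct.unpack("<H", _read_exact(fh, 2, what))
    return _read_exact(fh, n, what).decode()


def save_index(index: DiscriminativeIndex, path) -> None:
    """Write the index to ``path`` (binary; bit-exact round trip)."""
    table = index.table
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(
            _HDR.pack(
                _VERSION,
                index.k,
                _SAMPLINGS.index(index.sampling),
                index.min_occurrence,
            )
        )
        digest = index.params_digest().encode("ascii")
        fh.write(struct.pack("<B", len(digest)))
        fh.write(digest)
        fh.write(struct.pack("<I", len(table.labels)))
        for label in table.labels:
            _write_str(fh, label)
        fh.write(struct.pack("<I", len(table.seq_to_target)))
        for seq_id, label in sorted(table.seq_to_target.items()):
            _write_str(fh, seq_id)
            fh.write(struct.pack("<I", table.id_of(label)))
        fh.write(struct.pack("<I", len(table.arm_pairs)))
        for triple in table.arm_pairs:
            fh.write(struct.pack("<III", *(table.id_of(x) for x in triple)))
        fh.write(struct.pack("<Q", len(index.entries)))
        for code in sorted(index.entries):
            tid, occ = index.entries[code]
            fh.write(_REC.pack(code, tid, occ))


def read_index_header(path) -> dict:
    """Parameters stored in an index file header, without loading entries."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError(f"{path}: not a discrimer index file (bad magic)")
        version, k, sampling_code, min_occurrence = _HDR.unpack(
            _read_exact(fh, _HDR.size, "header")
        )
        if version != _VERSION:
            raise IndexFormatError(f"{path}: unsupported index format version {version}")
        if sampling_code >= len(_SAMPLINGS):
            raise IndexCorruptedError(f"{path}: invalid sampling code {sampling_code}")
        (dlen,) = struct.unpack("<B", _read_exact(fh, 1, "digest"))
        digest = _read_exact(fh, dlen, "digest").decode("ascii")
        return {
            "k": k,
            "sampling": _SAMPLINGS[sampling_code],
            "min_occurrence": min_occurrence,
            "digest": digest,
        }


def load_index(path) -> DiscriminativeIndex:
    """Read an index written by :func:`save_index`.

    Raises :class:`IndexFormatError` on a wrong magic string or version and
    :class:`IndexCorruptedError` on truncation.
    """
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError(f"{path}: not a discrimer index file (bad magic)")
        version, k, sampling_code, min_occurrence = _HDR.unpack(
            _read_exact(fh, _HDR.size, "header")
        )
        if version != _VERSION:
            raise IndexFormatError(f"{path}: unsupported index format version {version}")
        if sampling_code >= len(_SAMPLINGS):
            raise IndexCorruptedError(f"{path}: invalid sampling code {sampling_code}")
        (dlen,) = struct.unpack("<B", _read_exact(fh, 1, "digest"))
        _read_exact(fh, dlen, "digest")
        (n_labels,) = struct.unpack("<I", _read_exact(fh, 4, "label table"))
        labels = [_read_str(fh, "label table") for _ in range(n_labels)]
        (n_seqs,) = struct.unpack("<I", _read_exact(fh, 4, "sequence table"))
        seq_to_target = {}
        for _ in range(n_seqs):
            seq_id = _read_str(fh, "sequence table")
            (tid,) = struct.unpack("<I", _read_exact(fh, 4, "sequence table"))
            seq_to_target[seq_id] = labels[tid]
        (n_pairs,) = struct.unpack("<I", _read_exact(fh, 4, "arm pairs"))
        arm_pairs = []
        for _ in range(n_pairs):
            a, b, c = struct.unpack("<III", _read_exact(fh, 12, "arm pairs"))
            arm_pairs.append((labels[a], labels[b], labels[c]))
        table = TargetTable(labels=labels, seq_to_target=seq_to_target, arm_pairs=arm_pairs)
        (n_entries,) = struct.unpack("<Q", _read_exact(fh, 8, "entry count"))
        entries: dict[int, tuple[int, int]] = {}
        for _ in range(n_entries):
            code, tid, occ = _REC.unpack(_read_exact(fh, _REC.size, "entries"))
            entries[code] = (tid, occ)
        return DiscriminativeIndex(
            k=k,
            entries=entries,
            table=table,
            min_occurrence=min_occurrence,
            sampling=_SAMPLINGS[sampling_code],
        )
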