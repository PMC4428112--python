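"""Readers and writers for the package's text formats.

FASTA/FASTQ parsing is streamed and line-tracked so malformed records are
reported with their 1-based line number; gzip-compressed inputs are
detected by their magic bytes and decoded transparently. Record ids are
the first whitespace-delimited token of the header. Also covered here:
the k-mer distribution text format (one k-mer and its count per line),
the targets-definition TSV (sequence/file -> target label, with optional
``#armpair`` header lines), the truth TSV emitted by the simulator, and
the per-object results CSV.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import AmbiguousBaseError, SequenceFormatError
from .index import TargetTable
from .kmer_core import canonical_code, encode_kmer


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: str | None = None  # FASTQ only; same length as sequence


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path) -> str:
    """'fasta', 'fastq' or 'kmer_distribution', from the first non-blank line."""
    with _open_text(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                return "fasta"
            if s.startswith("@"):
                return "fastq"
            return "kmer_distribution"
    return "fasta"  # empty file: treat as empty FASTA


def read_sequences(path, format: str = "auto") -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTA or FASTQ file.

    ``format='auto'`` sniffs '>' vs '@' on the first non-blank line.
    Malformed records raise :class:`SequenceFormatError` naming the line.
    """
    if format == "auto":
        format = sniff_format(path)
        if format == "kmer_distribution":
            raise SequenceFormatError(f"{path}: not FASTA or FASTQ", lineno=1)
    if format == "fasta":
        yield from _read_fasta(path)
    elif format == "fastq":
        yield from _read_fastq(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _record_id(header: str, lineno: int) -> str:
    rid = header[1:].split(None, 1)[0] if len(header) > 1 else ""
    if not rid:
        raise SequenceFormatError("empty record id", lineno)
    return rid


def _read_fasta(path) -> Iterator[SequenceRecord]:
    rid = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                if rid is not None:
                    yield SequenceRecord(id=rid, sequence="".join(chunks))
                rid = _record_id(line, lineno)
                chunks = []
            else:
                if rid is None:
                    raise SequenceFormatError("sequence data before the first '>' header", lineno)
                chunks.append(line.strip())
    if rid is not None:
        yield SequenceRecord(id=rid, sequence="".join(chunks))


def _read_fastq(path) -> Iterator[SequenceRecord]:
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            if not header.strip():
                continue
            header = header.rstrip()
            if not header.startswith("@"):
                raise SequenceFormatError("expected '@' record header", lineno)
            rid = _record_id(header, lineno)
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise SequenceFormatError(f"truncated record {rid!r}", lineno)
            seq = seq.rstrip()
            qual = qual.rstrip()
            if not plus.startswith("+"):
                raise SequenceFormatError(f"missing '+' separator in record {rid!r}", lineno + 2)
            if len(qual) != len(seq):
                raise SequenceFormatError(
                    f"quality length {len(qual)} != sequence length {len(seq)} in record {rid!r}",
                    lineno + 3,
                )
            yield SequenceRecord(id=rid, sequence=seq, quality=qual)
            lineno += 3


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def read_kmer_distribution(path, k: int) -> dict[int, int]:
    """Parse a k-mer distribution file into canonical code -> summed count.

    Each data line holds a k-mer and a non-negative integer count,
    whitespace-separated; '#' lines are comments. Counts of a k-mer and
    its reverse complement land on one canonical entry.
    """
    dist: dict[int, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise SequenceFormatError(
                    f"expected 'kmer count', got {len(parts)} fields", lineno
                )
            kmer, count_s = parts
            if len(kmer) != k:
                raise SequenceFormatError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {k}", lineno
                )
            try:
                count = int(count_s)
            except ValueError:
                raise SequenceFormatError(f"non-integer count {count_s!r}", lineno) from None
            if count < 0:
                raise SequenceFormatError(f"negative count {count}", lineno)
            try:
                code = canonical_code(encode_kmer(kmer), k)
            except AmbiguousBaseError as exc:
                raise SequenceFormatError(str(exc), lineno) from None
            dist[code] = dist.get(code, 0) + count
    return dist


def read_targets_table(path) -> TargetTable:
    """Parse the targets-definition TSV.

    Data lines are ``path_or_sequence_id<whitespace>target_label``; target
    order follows first appearance. Optional header lines
    ``#armpair LONG SHORT CENTROMERE`` declare chromosome-arm pairs.
    """
    labels: list[str] = []
    seen: set[str] = set()
    seq_to_target: dict[str, str] = {}
    arm_pairs: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                parts = s[1:].split()
                if parts and parts[0].lower() == "armpair":
                    if len(parts) != 4:
                        raise SequenceFormatError(
                            "armpair header needs: long-arm short-arm centromere", lineno
                        )
                    arm_pairs.append((parts[1], parts[2], parts[3]))
                continue
            parts = s.split()
            if len(parts) != 2:
                raise SequenceFormatError(
                    f"expected 'sequence_or_path<TAB>label', got {len(parts)} fields", lineno
                )
            key, label = parts
            if key in seq_to_target:
                raise SequenceFormatError(f"duplicate sequence entry {key!r}", lineno)
            seq_to_target[key] = label
            if label not in seen:
                seen.add(label)
                labels.append(label)
    return TargetTable(labels=labels, seq_to_target=seq_to_target, arm_pairs=arm_pairs)


def write_truth_tsv(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\tposition\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.label}\t{t.position}\n")


def read_truth_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if not s or s.startswith("read_id\t"):
                continue
            parts = s.split("\t")
            if len(parts) < 2:
                raise SequenceFormatError("expected at least read_id and label columns", lineno)
            out[parts[0]] = parts[1]
    return out


_BASE_COLUMNS = ["object_id", "n_kmers", "assignment", "h1", "h2", "confidence", "tie"]


def write_results_csv(results, path, target_labels: Sequence[str] | None = None) -> None:
    """Write per-object results; pass ``target_labels`` to add the full-mode
    per-target hit-count columns."""
    columns = list(_BASE_COLUMNS)
    if target_labels is not None:
        columns += list(target_labels)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for r in results:
            conf = "" if r.confidence is None else f"{r.confidence:.4f}"
            row = [r.object_id, r.n_kmers, r.assignment, r.h1, r.h2, conf, int(r.tie)]
            if target_labels is not None:
                hits = r.hits or {}
                row += [hits.get(label, 0) for label in target_labels]
            w.writerow(row)


def read_results_csv(path) -> list:
    """Read back a results CSV (base columns only) as ObjectResult objects."""
    from .classify import ObjectResult

    out = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            conf = row["confidence"]
            out.append(
                ObjectResult(
                    object_id=row["object_id"],
                    n_kmers=int(row["n_kmers"]),
                    h1=int(row["h1"]),
                    h2=int(row["h2"]),
                    assignment=row["assignment"],
                    confidence=float(conf) if conf else None,
                    tie=bool(int(row["tie"])),
                )
            )
    return out
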