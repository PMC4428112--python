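"""Assignment of query sequences ("objects") to targets, with confidence scores.

Four execution modes over a discriminative index:

``full``
    count hits against every target; report the whole hit vector and the
    confidence score h1/(h1+h2), where h1 and h2 are the top and
    runner-up per-target hit counts;
``default``
    same scoring against the half-sampled index, but stop querying an
    object's k-mers as soon as one target has collected at least half of
    the object's total possible hits;
``express``
    query only non-overlapping k-mers (start positions 0, k, 2k, ...) and
    assign to the first target hit. Because discriminative sets are
    pairwise disjoint, an object drawn from a target can only ever hit
    that one target, so the first hit already decides the assignment; no
    confidence is measured;
``light``
    full-style scoring against the strided 27-mer index.

A hit is a window of the object whose canonical k-mer belongs to a
target's discriminative set; repeated k-mers count once per window. An
object with no hits is ``UNASSIGNED``. A top-count tie is assigned to the
smallest target id with ``tie=True`` and confidence 0.5.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .index import (
    LIGHT_K,
    SAMPLING_HALF,
    SAMPLING_LIGHT,
    SAMPLING_NONE,
    DiscriminativeIndex,
)
from .kmer_core import extract_kmers

UNASSIGNED = "UNASSIGNED"

MODES = ("full", "default", "express", "light")


@dataclass
class ObjectResult:
    """Per-object classification outcome."""

    object_id: str
    n_kmers: int  #: valid k-mer windows in the object
    h1: int  #: hit count of the top target
    h2: int  #: hit count of the runner-up target
    assignment: str  #: target label or UNASSIGNED
    confidence: float | None  #: h1/(h1+h2); None when unassigned or in express mode
    tie: bool
    hits: dict[str, int] | None = None  #: per-target hit counts (full/light modes)

    @property
    def assigned(self) -> bool:
        return self.assignment != UNASSIGNED


@dataclass
class EvalReport:
    """Precision/sensitivity summary of a labelled classification run.

    precision = correct / assigned, sensitivity = correct / total objects,
    assignment_rate = assigned / total. High-confidence fields use the
    strict cutoff confidence > threshold.
    """

    precision: float
    sensitivity: float
    assignment_rate: float
    mean_confidence: float
    high_conf_precision: float
    high_conf_rate: float
    n_objects: int = 0
    n_assigned: int = 0
    n_correct: int = 0


def _unassigned(object_id: str, n_kmers: int, hits: dict[str, int] | None) -> ObjectResult:
    return ObjectResult(object_id, n_kmers, 0, 0, UNASSIGNED, None, False, hits)


def _score(
    counts: Counter[int],
    index: DiscriminativeIndex,
    object_id: str,
    n_kmers: int,
    with_hits: bool,
) -> ObjectResult:
    hits = None
    if with_hits:
        hits = {label: counts.get(tid, 0) for tid, label in enumerate(index.table.labels)}
    ranked = sorted(counts.items(), key=lambda it: (-it[1], it[0]))
    if not ranked or ranked[0][1] == 0:
        return _unassigned(object_id, n_kmers, hits)
    top_tid, h1 = ranked[0]
    h2 = ranked[1][1] if len(ranked) > 1 else 0
    return ObjectResult(
        object_id=object_id,
        n_kmers=n_kmers,
        h1=h1,
        h2=h2,
        assignment=index.table.label_of(top_tid),
        confidence=h1 / (h1 + h2),
        tie=h2 == h1,
        hits=hits,
    )


def classify_full(seq: str, index: DiscriminativeIndex, object_id: str = "") -> ObjectResult:
    """Count hits against all targets and score; requires an unsampled index."""
    if index.sampling != SAMPLING_NONE:
        raise ConfigurationError("full mode requires an unsampled index")
    return _classify_all_windows(seq, index, object_id)


def classify_light(seq: str, index: DiscriminativeIndex, object_id: str = "") -> ObjectResult:
    """Full-style scoring against the strided 27-mer light index."""
    if index.sampling != SAMPLING_LIGHT or index.k != LIGHT_K:
        raise ConfigurationError(f"light mode requires a light-stride index with k={LIGHT_K}")
    return _classify_all_windows(seq, index, object_id)


def _classify_all_windows(seq: str, index: DiscriminativeIndex, object_id: str) -> ObjectResult:
    entries = index.entries
    counts: Counter[int] = Counter()
    n_kmers = 0
    for _pos, code in extract_kmers(seq, index.k):
        n_kmers += 1
        hit = entries.get(code)
        if hit is not None:
            counts[hit[0]] += 1
    return _score(counts, index, object_id, n_kmers, with_hits=True)


def classify_default(seq: str, index: DiscriminativeIndex, object_id: str = "") -> ObjectResult:
    """Early-stopping scoring against the half-sampled index.

    Windows are queried left to right; querying stops once some target has
    collected at least ceil(n_kmers/2) hits, where n_kmers counts *all*
    valid windows of the object, and the assignment is made from the
    counts accumulated so far.
    """
    if index.sampling != SAMPLING_HALF:
        raise ConfigurationError("default mode requires a half-sampled index")
    kmers = extract_kmers(seq, index.k)
    n_kmers = len(kmers)
    if n_kmers == 0:
        return _unassigned(object_id, 0, None)
    threshold = math.ceil(n_kmers / 2)
    entries = index.entries
    counts: Counter[int] = Counter()
    for _pos, code in kmers:
        hit = entries.get(code)
        if hit is not None:
            tid = hit[0]
            counts[tid] += 1
            if counts[tid] >= threshold:
                break
    return _score(counts, index, object_id, n_kmers, with_hits=False)


def classify_express(seq: str, index: DiscriminativeIndex, object_id: str = "") -> ObjectResult:
    """First-hit assignment over non-overlapping k-mers; no confidence score."""
    k = index.k
    kmers = extract_kmers(seq, k)
    entries = index.entries
    for pos, code in kmers:
        if pos % k:
            continue
        hit = entries.get(code)
        if hit is not None:
            return ObjectResult(
                object_id=object_id,
                n_kmers=len(kmers),
                h1=1,
                h2=0,
                assignment=index.table.label_of(hit[0]),
                confidence=None,
                tie=False,
                hits=None,
            )
    return _unassigned(object_id, len(kmers), None)


_MODE_FN = {
    "full": classify_full,
    "default": classify_default,
    "express": classify_express,
    "light": classify_light,
}

# worker-process state for the multiprocessing path
_POOL_STATE: dict = {}


def _pool_init(index: DiscriminativeIndex, mode: str) -> None:
    _POOL_STATE["index"] = index
    _POOL_STATE["fn"] = _MODE_FN[mode]


def _pool_classify(item: tuple[str, str]) -> ObjectResult:
    object_id, seq = item
    return _POOL_STATE["fn"](seq, _POOL_STATE["index"], object_id)


def classify_objects(
    objects: Iterable,
    index: DiscriminativeIndex,
    mode: str = "full",
    workers: int = 1,
) -> list[ObjectResult]:
    """Classify a collection of sequence records in one mode.

    ``objects`` yields records with ``id`` and ``sequence`` attributes (or
    (id, sequence) pairs). Results are returned in input order and are
    independent of ``workers``: parallelism only partitions the objects.
    """
    if mode not in _MODE_FN:
        raise ConfigurationError(f"unknown classification mode {mode!r}")
    items = [
        (obj.id, obj.sequence) if hasattr(obj, "sequence") else (obj[0], obj[1])
        for obj in objects
    ]
    if workers > 1:
        try:
            import multiprocessing as mp

            ctx = mp.get_context("fork")
        except ValueError:
            ctx = None
        if ctx is not None:
            chunk = max(1, len(items) // (workers * 4) or 1)
            with ctx.Pool(workers, initializer=_pool_init, initargs=(index, mode)) as pool:
                return pool.map(_pool_classify, items, chunksize=chunk)
    fn = _MODE_FN[mode]
    return [fn(seq, index, object_id) for object_id, seq in items]


def evaluate(
    results: Sequence[ObjectResult],
    truth: Mapping[str, str],
    high_conf_threshold: float = 0.75,
) -> EvalReport:
    """Score classification results against known source labels.

    Every result's object_id must appear in ``truth`` (KeyError otherwise).
    With zero assigned objects precision is undefined and reported as NaN
    with a warning.
    """
    n = len(results)
    n_assigned = n_correct = 0
    conf_sum = 0.0
    n_conf = 0
    hc_total = hc_correct = 0
    for r in results:
        if r.object_id not in truth:
            raise KeyError(f"object {r.object_id!r} missing from the truth table")
        if not r.assigned:
            continue
        n_assigned += 1
        correct = r.assignment == truth[r.object_id]
        n_correct += correct
        if r.confidence is not None:
            conf_sum += r.confidence
            n_conf += 1
            if r.confidence > high_conf_threshold:
                hc_total += 1
                hc_correct += correct
    if n_assigned == 0:
        warnings.warn("no objects were assigned; precision is undefined", stacklevel=2)
    return EvalReport(
        precision=n_correct / n_assigned if n_assigned else math.nan,
        sensitivity=n_correct / n if n else math.nan,
        assignment_rate=n_assigned / n if n else math.nan,
        mean_confidence=conf_sum / n_conf if n_conf else math.nan,
        high_conf_precision=hc_correct / hc_total if hc_total else math.nan,
        high_conf_rate=hc_total / n if n else math.nan,
        n_objects=n,
        n_assigned=n_assigned,
        n_correct=n_correct,
    )


def summarize_results(
    results: Sequence[ObjectResult], high_conf_threshold: float = 0.75
) -> dict:
    """Run summary in the style of a sample report: assignment-rate and
    high/low-confidence breakdown plus the most frequent high-confidence targets.
    """
    n = len(results)
    assigned = [r for r in results if r.assigned]
    with_conf = [r for r in assigned if r.confidence is not None]
    high = [r for r in with_conf if r.confidence > high_conf_threshold]
    low = [r for r in with_conf if r.confidence <= high_conf_threshold]
    top = Counter(r.assignment for r in high).most_common(5)
    return {
        "n_objects": n,
        "assignment_rate": len(assigned) / n if n else 0.0,
        "high_conf_frac": len(high) / n if n else 0.0,
        "low_conf_frac": len(low) / n if n else 0.0,
        "unassigned_frac": (n - len(assigned)) / n if n else 0.0,
        "mean_confidence": (
            sum(r.confidence for r in with_conf) / len(with_conf) if with_conf else math.nan
        ),
        "top_high_conf_targets": top,
    }
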