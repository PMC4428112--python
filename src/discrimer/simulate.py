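"""Synthetic communities and labelled read sets for controlled experiments.

The generator produces i.i.d. uniform-ACGT genomes and optionally plants
*shared blocks*: segments copied into two or more genomes, emulating
sequence held in common between targets (conserved genes, recent
transfer, homologous arms). Shared blocks may be copied verbatim or with
independent per-copy substitutions (``block_divergence``), which models
homologous-but-diverged regions such as paralogs or genomes of related
species — the regime in which classification errors concentrate.

Reads are sampled uniformly over genomes and positions on the forward
strand (strand symmetry is already guaranteed by canonical k-mer
matching) with an independent per-base substitution error model; indels
are not simulated, so the recorded source position of every read is
exact. Both the community and the reads are deterministic functions of
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError
from .index import TargetTable
from .io import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


@dataclass
class SharedBlock:
    """A segment planted into several genomes.

    ``sequence`` is the block consensus; ``placements`` maps each
    recipient genome label to the 0-based start of its copy. Copies equal
    the consensus exactly when the community was built with
    ``block_divergence == 0``.
    """

    sequence: str
    placements: dict[str, int]

    @property
    def labels(self) -> list[str]:
        return list(self.placements)


@dataclass
class SyntheticCommunity:
    genomes: list[tuple[str, str]]  #: (label, sequence) in label order
    shared_blocks: list[SharedBlock] = field(default_factory=list)
    seed: int = 0

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.genomes]

    def genome(self, label: str) -> str:
        for lab, seq in self.genomes:
            if lab == label:
                return seq
        raise KeyError(label)

    def target_table(self, arm_pairs: list[tuple[str, str, str]] | None = None) -> TargetTable:
        return TargetTable(
            labels=self.labels,
            seq_to_target={label: label for label in self.labels},
            arm_pairs=arm_pairs or [],
        )


class ReadTruth(NamedTuple):
    read_id: str
    label: str
    position: int


def make_community(
    n_targets: int,
    genome_len: int,
    shared_block_len: int = 0,
    n_shared_blocks: int = 0,
    seed: int = 0,
    *,
    copies_per_block: int = 2,
    block_divergence: float = 0.0,
) -> SyntheticCommunity:
    """Generate a community of random genomes with planted shared blocks.

    Each of the ``n_shared_blocks`` blocks of length ``shared_block_len``
    is copied into ``copies_per_block`` distinct genomes at
    non-overlapping positions (block j lives inside bin j of each genome,
    so copies of different blocks never collide). With
    ``block_divergence > 0`` every copy is independently mutated at that
    per-base substitution rate.
    """
    if n_targets < 1:
        raise ConfigurationError("n_targets must be >= 1")
    if n_shared_blocks < 0 or shared_block_len < 0:
        raise ConfigurationError("block counts/lengths must be non-negative")
    if n_shared_blocks > 0:
        if shared_block_len == 0:
            raise ConfigurationError("shared blocks require shared_block_len > 0")
        if not 2 <= copies_per_block <= n_targets:
            raise ConfigurationError(
                f"copies_per_block must be in [2, n_targets], got {copies_per_block}"
            )
        if genome_len <= shared_block_len * n_shared_blocks:
            raise ConfigurationError(
                "genomes too short to hold the requested shared blocks"
            )
    if not 0.0 <= block_divergence < 1.0:
        raise ConfigurationError("block_divergence must be in [0, 1)")

    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(n_targets)]
    arrays = [rng.integers(0, 4, genome_len, dtype=np.uint8) for _ in range(n_targets)]

    blocks: list[SharedBlock] = []
    if n_shared_blocks:
        bin_len = genome_len // n_shared_blocks
        for j in range(n_shared_blocks):
            block = rng.integers(0, 4, shared_block_len, dtype=np.uint8)
            recipients = rng.choice(n_targets, size=copies_per_block, replace=False)
            placements: dict[str, int] = {}
            for g in sorted(int(x) for x in recipients):
                offset = int(rng.integers(0, bin_len - shared_block_len + 1))
                pos = j * bin_len + offset
                copy = block.copy()
                if block_divergence > 0:
                    mut = rng.random(shared_block_len) < block_divergence
                    shift = rng.integers(1, 4, shared_block_len, dtype=np.uint8)
                    copy[mut] = (copy[mut] + shift[mut]) % 4
                arrays[g][pos : pos + shared_block_len] = copy
                placements[labels[g]] = pos
            blocks.append(SharedBlock(sequence=_to_str(block), placements=placements))

    genomes = [(label, _to_str(arr)) for label, arr in zip(labels, arrays)]
    return SyntheticCommunity(genomes=genomes, shared_blocks=blocks, seed=seed)


def sample_reads(
    community: SyntheticCommunity,
    n_reads: int,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Sample labelled reads with independent per-base substitution errors.

    Source genome and start position are uniform; each base is substituted
    with probability ``error_rate`` to a uniformly chosen *different*
    base. Read ids carry the truth as ``readN|label|pos``; the returned
    truth table repeats it separately. Quality strings are the constant
    'I' (Phred 40), since the classifier ignores them.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ConfigurationError("error_rate must be in [0, 1)")
    genome_len = len(community.genomes[0][1])
    if read_len > genome_len or read_len < 1:
        raise ConfigurationError(f"read_len must be in [1, {genome_len}]")

    rng = np.random.default_rng(seed)
    arrays = [
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in community.genomes
    ]
    # map ASCII back to 2-bit codes once
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arrays = [lut[a] for a in arrays]

    gidx = rng.integers(0, len(arrays), n_reads)
    starts = rng.integers(0, genome_len - read_len + 1, n_reads)
    quality = "I" * read_len
    records: list[SequenceRecord] = []
    truth: list[ReadTruth] = []
    for i in range(n_reads):
        g = int(gidx[i])
        pos = int(starts[i])
        bases = arrays[g][pos : pos + read_len].copy()
        if error_rate > 0:
            mut = rng.random(read_len) < error_rate
            if mut.any():
                shift = rng.integers(1, 4, int(mut.sum()), dtype=np.uint8)
                bases[mut] = (bases[mut] + shift) % 4
        label = community.labels[g]
        read_id = f"read{i}|{label}|{pos}"
        records.append(SequenceRecord(id=read_id, sequence=_to_str(bases), quality=quality))
        truth.append(ReadTruth(read_id, label, pos))
    return records, truth


def truth_map(truth: list[ReadTruth]) -> dict[str, str]:
    """read_id -> source label, the form :func:`~discrimer.classify.evaluate` wants."""
    return {t.read_id: t.label for t in truth}
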