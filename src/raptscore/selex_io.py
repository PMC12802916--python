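"""Reading HT-SELEX rounds and building weighted pretraining corpora.

One sequencing round is reduced to a unique-sequence count table over the
variable region.  Three duplicate-handling policies turn a count table into a
training corpus: keep duplicates ``as_is`` (weight = raw count), compress them
with ``log_weight`` (weight = ceil(log(count)) + 1), or ``dedup`` to weight 1.
Fixed 5'/3' adapter (primer) regions can be attached to or stripped from the
variable region; whether the model ever sees adapters is one of the
calibration axes.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
DUPLICATE_POLICIES = ("as_is", "log_weight", "dedup")


def _normalize(seq: str) -> str:
    """Uppercase and map RNA U to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class LibraryDesign:
    """Library layout: fixed adapters flanking a random region of known length."""

    adapter5: str
    adapter3: str
    variable_length: int

    def __post_init__(self):
        object.__setattr__(self, "adapter5", _normalize(self.adapter5))
        object.__setattr__(self, "adapter3", _normalize(self.adapter3))
        for name in ("adapter5", "adapter3"):
            bad = set(getattr(self, name)) - _DNA
            if bad:
                raise ValueError(f"{name} contains non-DNA symbols {sorted(bad)}")
        if self.variable_length < 7:
            raise ValueError(
                f"variable_length must be >= 7 (minimum scorable length), got {self.variable_length}"
            )


@dataclass
class SelexRound:
    """Unique-sequence count table for one selection round."""

    round_index: int
    counts: Dict[str, int]
    total_reads: int
    dropped: int = 0

    def __post_init__(self):
        if self.round_index < 0:
            raise ValueError("round_index must be non-negative")
        if sum(self.counts.values()) != self.total_reads:
            raise ValueError("counts must sum to total_reads")
        lengths = {len(s) for s in self.counts}
        if len(lengths) > 1:
            raise ValueError(f"non-uniform sequence lengths in round: {sorted(lengths)}")

    @property
    def n_unique(self) -> int:
        return len(self.counts)


@dataclass
class WeightedCorpus:
    """Pretraining corpus: (sequence, integer replication weight) pairs."""

    entries: List[Tuple[str, int]]
    policy_used: str
    adapters_included: bool = False

    @property
    def total_weight(self) -> int:
        return sum(w for _, w in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_reads(path, format: str = "auto") -> List[str]:
    """Read sequences from FASTA/FASTQ (optionally gzipped).

    Returns uppercased sequences with U mapped to T, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    if format == "auto":
        ext = Path(name).suffix.lower()
        if ext in (".fq", ".fastq"):
            format = "fastq"
        elif ext in (".fa", ".fasta", ".fna"):
            format = "fasta"
        else:
            raise ValueError(f"cannot detect format from extension {ext!r}; pass format=")
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")

    opener = gzip.open if path.name.endswith(".gz") else open
    seqs: List[str] = []
    with opener(path, "rt") as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, format)):
                seqs.append(_normalize(str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"malformed {format} record at index {len(seqs)}: {exc}") from exc
    return seqs


def count_unique(records: Sequence[str], design: LibraryDesign, round_index: int = 0) -> SelexRound:
    """Collapse reads to a variable-region count table.

    Reads whose length differs from ``design.variable_length`` or that contain
    symbols outside the DNA/RNA alphabet are dropped and counted.
    """
    if not records:
        raise ValueError("no input records")
    counts: Counter = Counter()
    dropped = 0
    for rec in records:
        seq = _normalize(rec)
        if len(seq) != design.variable_length or set(seq) - _DNA:
            dropped += 1
            continue
        counts[seq] += 1
    if not counts:
        raise ValueError("no conforming reads (all records dropped)")
    if dropped:
        logger.info("count_unique: dropped %d of %d reads", dropped, len(records))
    total = sum(counts.values())
    return SelexRound(round_index=round_index, counts=dict(counts), total_reads=total, dropped=dropped)


def apply_duplicate_policy(round: SelexRound, policy: str, log_base: float = 10.0) -> WeightedCorpus:
    """Turn a count table into a weighted corpus under a duplicate policy.

    ``log_weight`` uses ceil(log(count)) + 1, so the weight grows by one per
    decade of duplication count under the default base 10 (count 1 -> 1,
    count 10 -> 2, count 1000 -> 4).
    """
    if policy not in DUPLICATE_POLICIES:
        raise ValueError(f"unknown duplicate policy {policy!r}; expected one of {DUPLICATE_POLICIES}")
    if not round.counts:
        raise ValueError("empty round")
    entries: List[Tuple[str, int]] = []
    for seq in sorted(round.counts):
        c = round.counts[seq]
        if policy == "as_is":
            w = c
        elif policy == "dedup":
            w = 1
        else:
            w = math.ceil(round_safe_log(c, log_base)) + 1
        entries.append((seq, w))
    return WeightedCorpus(entries=entries, policy_used=policy, adapters_included=False)


def round_safe_log(count: int, base: float) -> float:
    """log(count) in the given base, robust to float noise at exact powers."""
    if count < 1:
        raise ValueError("duplication count must be positive")
    val = math.log(count) / math.log(base)
    nearest = round(val)
    if abs(val - nearest) < 1e-9:
        return float(nearest)
    return val


def attach_adapters(sequence: str, design: LibraryDesign, include: bool = True) -> str:
    """Flank the variable region with the library adapters (or return as-is)."""
    if len(sequence) != design.variable_length:
        raise ValueError(
            f"sequence length {len(sequence)} != variable_length {design.variable_length}"
        )
    if not include:
        return sequence
    return design.adapter5 + sequence + design.adapter3


def strip_adapters(sequence: str, design: LibraryDesign) -> str:
    """Inverse of :func:`attach_adapters` for adapter-flanked sequences."""
    a5, a3 = design.adapter5, design.adapter3
    if not (sequence.startswith(a5) and sequence.endswith(a3)):
        raise ValueError("sequence does not carry the design's adapters")
    core = sequence[len(a5):len(sequence) - len(a3)]
    if len(core) != design.variable_length:
        raise ValueError("stripped core length does not match variable_length")
    return core


def corpus_with_adapters(corpus: WeightedCorpus, design: LibraryDesign) -> WeightedCorpus:
    """Return a copy of the corpus with adapters attached to every entry."""
    if corpus.adapters_included:
        return corpus
    entries = [(attach_adapters(s, design, True), w) for s, w in corpus.entries]
    return WeightedCorpus(entries=entries, policy_used=corpus.policy_used, adapters_included=True)


# ---------------------------------------------------------------------------
# export helpers

def write_count_table(round: SelexRound, path) -> None:
    """TSV with columns (sequence, count, frequency)."""
    total = round.total_reads
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tfrequency\n")
        for seq in sorted(round.counts, key=lambda s: (-round.counts[s], s)):
            c = round.counts[seq]
            fh.write(f"{seq}\t{c}\t{c / total:.6f}\n")


def write_corpus(corpus: WeightedCorpus, path, as_rna: bool = False) -> None:
    """One sequence per line, repeated according to its replication weight."""
    with open(path, "w") as fh:
        for seq, w in corpus.entries:
            out = seq.replace("T", "U") if as_rna else seq
            for _ in range(w):
                fh.write(out + "\n")
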