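"""Synthetic HT-SELEX: round-over-round enrichment of a planted binding motif.

The simulator emulates the one property of real selection data that the
scoring pipeline exploits: subsequences conferring binding get amplified
round over round, so late rounds are enriched in motif-bearing reads.  Ground
truth binding ("fitness") of a sequence is the best sliding-window identity
fraction against a fixed planted motif — 1.0 iff the motif appears verbatim.
Each selection round resamples reads with Boltzmann weights exp(beta *
fitness) and applies independent per-base substitution noise (no indels, so
the variable-region length stays uniform, as real HT-SELEX count tables
assume).  A noisy relative-activity table (control = 100 scale) stands in
for an SPR panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from raptscore.selex_io import LibraryDesign, SelexRound

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default planted motif: a fixed 13-nt literal
DEFAULT_MOTIF = "CCAAGGTTGCCGG"


@dataclass(frozen=True)
class SimulationConfig:
    variable_length: int = 30
    motif: str = DEFAULT_MOTIF
    library_size: int = 10000
    rounds: int = 5
    selection_strength: float = 5.0  # beta in exp(beta * fitness)
    mutation_rate: float = 0.01     # per-base substitution per amplification
    depth: int = 5000               # reads emitted per round
    activity_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if len(self.motif) >= self.variable_length:
            raise ValueError("motif must be shorter than variable_length")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class SimulatedSelex:
    rounds: List[SelexRound]                # indices 0 .. cfg.rounds
    true_fitness: Dict[str, float]          # every emitted sequence
    config: SimulationConfig

    @property
    def design(self) -> LibraryDesign:
        """Adapter-less design matching the simulated variable region."""
        return LibraryDesign(adapter5="", adapter3="", variable_length=self.config.variable_length)


def _to_int(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    return arr


def true_fitness(sequence: str, motif: str) -> float:
    """Best-window identity fraction of the motif within the sequence.

    Maximum over all alignments of (matching positions / motif length);
    equals 1.0 iff the motif is an exact substring.  Sequences shorter than
    the motif are scored on the best partial overlap of the sequence inside
    the motif (flagged via a log message).
    """
    seq, m = sequence.upper().replace("U", "T"), motif.upper().replace("U", "T")
    if len(seq) < len(m):
        logger.warning("true_fitness: sequence shorter than motif; using best partial overlap")
        best = max(
            sum(a == b for a, b in zip(seq, m[i:i + len(seq)]))
            for i in range(len(m) - len(seq) + 1)
        )
        return best / len(m)
    return _fitness_batch([seq], m)[0]


def _fitness_batch(seqs: Sequence[str], motif: str) -> np.ndarray:
    """Vectorized best-window identity for equal-length sequences."""
    arr = _to_int(seqs)
    mot = np.frombuffer(motif.encode(), dtype=np.uint8)
    L, m = arr.shape[1], len(mot)
    best = np.zeros(arr.shape[0], dtype=np.int64)
    for off in range(L - m + 1):
        matches = (arr[:, off:off + m] == mot).sum(axis=1)
        np.maximum(best, matches, out=best)
    return best / m


def simulate_selex(cfg: SimulationConfig) -> SimulatedSelex:
    """Run the simulator; fully reproducible from ``cfg.seed``.

    Round 0 is drawn uniformly at random from a random initial library;
    round r+1 resamples round r's reads with probability proportional to
    exp(beta * fitness), applies per-base substitution, and emits
    ``cfg.depth`` reads.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.variable_length

    library = _BASES[rng.integers(0, 4, size=(cfg.library_size, L))]
    reads = library[rng.integers(0, cfg.library_size, size=cfg.depth)]

    fitness: Dict[str, float] = {}
    rounds: List[SelexRound] = []

    def record_round(idx: int, read_arr: np.ndarray) -> np.ndarray:
        seqs = [row.tobytes().decode() for row in read_arr]
        fits = _fitness_batch(seqs, cfg.motif)
        counts: Dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        for s, f in zip(seqs, fits):
            fitness[s] = float(f)
        rounds.append(SelexRound(round_index=idx, counts=counts, total_reads=len(seqs)))
        return fits

    fits = record_round(0, reads)
    for r in range(1, cfg.rounds + 1):
        w = np.exp(cfg.selection_strength * fits)
        idx = rng.choice(len(reads), size=cfg.depth, p=w / w.sum())
        reads = reads[idx].copy()
        if cfg.mutation_rate > 0:
            hit = rng.random(reads.shape) < cfg.mutation_rate
            reads[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
        fits = record_round(r, reads)
    return SimulatedSelex(rounds=rounds, true_fitness=fitness, config=cfg)


def make_activity_table(sequences: Sequence[str], fitness: Dict[str, float],
                        noise_sd: float, seed: int = 0,
                        ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Noisy relative-activity panel: 100 * fitness + N(0, sd), max rescaled to 100."""
    if len(sequences) == 0:
        raise ValueError("empty sequence list")
    missing = [s for s in sequences if s not in fitness]
    if missing:
        raise KeyError(f"fitness undefined for {len(missing)} sequences, e.g. {missing[0]}")
    rng = np.random.default_rng(seed)
    raw = np.array([100.0 * fitness[s] for s in sequences])
    raw = raw + rng.normal(0.0, noise_sd, size=len(raw))
    top = raw.max()
    if top <= 0:
        raise ValueError("all activities non-positive; cannot rescale to control=100")
    act = 100.0 * raw / top
    if ids is None:
        ids = [f"seq_{i:04d}" for i in range(len(sequences))]
    return pd.DataFrame({"id": list(ids), "sequence": list(sequences),
                         "relative_activity": act})


def sample_motif_bearing(n: int, cfg: SimulationConfig, rng: np.random.Generator,
                         offset: Optional[int] = None) -> List[str]:
    """Random variable-length sequences with the planted motif as a substring.

    With ``offset=None`` each sequence gets the motif at an independent random
    position; a fixed ``offset`` plants it at the same position in every
    sequence, emulating an aligned clonal family (descendants of one enriched
    ancestor share their motif register).
    """
    L, m = cfg.variable_length, len(cfg.motif)
    if offset is not None and not 0 <= offset <= L - m:
        raise ValueError(f"offset must be in [0, {L - m}]")
    out = []
    for _ in range(n):
        arr = _BASES[rng.integers(0, 4, size=L)].copy()
        off = int(rng.integers(0, L - m + 1)) if offset is None else offset
        arr[off:off + m] = np.frombuffer(cfg.motif.encode(), dtype=np.uint8)
        out.append(arr.tobytes().decode())
    return out


def sample_random(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> List[str]:
    return [row.tobytes().decode()
            for row in _BASES[rng.integers(0, 4, size=(n, cfg.variable_length))]]


# ---------------------------------------------------------------------------
# file emission

def write_round_fastq(round: SelexRound, path, quality: str = "I") -> None:
    """Constant-quality FASTQ, one record per read (duplicates expanded)."""
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(round.counts):
            for _ in range(round.counts[seq]):
                fh.write(f"@r{round.round_index}_{i:07d}\n{seq}\n+\n{quality * len(seq)}\n")
                i += 1


def write_round_fasta(round: SelexRound, path) -> None:
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(round.counts):
            for _ in range(round.counts[seq]):
                fh.write(f">r{round.round_index}_{i:07d}\n{seq}\n")
                i += 1


def write_simulation(sim: SimulatedSelex, outdir, fmt: str = "fastq") -> Path:
    """Emit per-round reads, a fitness table, and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rnd in sim.rounds:
        if fmt == "fastq":
            write_round_fastq(rnd, outdir / f"round_{rnd.round_index}.fastq")
        else:
            write_round_fasta(rnd, outdir / f"round_{rnd.round_index}.fasta")
    pd.DataFrame(
        [(s, f) for s, f in sorted(sim.true_fitness.items())],
        columns=["sequence", "fitness"],
    ).to_csv(outdir / "fitness.tsv", sep="\t", index=False)
    manifest = asdict(sim.config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
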