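"""Masked-language-model definition, pretraining, and checkpointing.

A model is a BERT-style encoder over the overlapping k-mer vocabulary (see
:mod:`raptscore.nn` for the numerics).  Pretraining follows the contiguous
masking scheme used for k-mer language models: a target *nucleotide* position
is chosen, and the k tokens covering that nucleotide are masked together, so
the nucleotide is fully hidden from the model; the standard 80% MASK /
10% random / 10% keep replacement is applied per target.  Replication weights
from the duplicate policy are realized by sampling sequences into batches
proportionally to their weight.

Two presets are provided: ``REFERENCE_PRESET`` mirrors the published
full-scale configuration (12 layers, hidden 768, ~86M parameters) and
``TINY_PRESET`` is a 2-layer model small enough to train on one CPU in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from raptscore import nn
from raptscore.selex_io import LibraryDesign, WeightedCorpus, corpus_with_adapters
from raptscore.tokenizer import KmerVocabulary, build_vocabulary, encode

INIT_MODES = ("from_scratch", "from_checkpoint")


@dataclass(frozen=True)
class EncoderConfig:
    num_layers: int = 2
    hidden_size: int = 64
    num_heads: int = 4
    intermediate_size: int = 256
    max_positions: int = 128
    vocab_size: int = 69
    dropout: float = 0.1

    def __post_init__(self):
        if self.num_layers < 1 or self.hidden_size < 1 or self.num_heads < 1 \
                or self.intermediate_size < 1 or self.max_positions < 1 or self.vocab_size < 1:
            raise ValueError("all EncoderConfig dimensions must be positive")
        if self.hidden_size % self.num_heads != 0:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by num_heads {self.num_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


#: full-scale reference configuration (~86M parameters with the MLM head)
REFERENCE_PRESET = EncoderConfig(num_layers=12, hidden_size=768, num_heads=12,
                                 intermediate_size=3072, max_positions=512,
                                 vocab_size=69, dropout=0.1)

#: desk-scale configuration used throughout the tests
TINY_PRESET = EncoderConfig(num_layers=2, hidden_size=64, num_heads=4,
                            intermediate_size=256, max_positions=128,
                            vocab_size=69, dropout=0.1)


@dataclass
class TrainingConfig:
    steps: int = 2000
    batch_size: int = 64
    learning_rate: float = 3e-3
    mask_rate: float = 0.15
    warmup_fraction: float = 0.1
    weight_decay: float = 0.01
    log_every: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must be in (0, 1)")


class MaskedLanguageModel:
    """Encoder + MLM head with its vocabulary and configuration."""

    def __init__(self, config: EncoderConfig, vocab: KmerVocabulary,
                 params: Optional[Dict[str, np.ndarray]] = None, seed: int = 0):
        if config.vocab_size != vocab.size:
            raise ValueError(
                f"config.vocab_size {config.vocab_size} != vocabulary size {vocab.size}"
            )
        self.config = config
        self.vocab = vocab
        self.seed = seed
        self.params = params if params is not None else nn.init_params(config, seed)

    def forward(self, ids: np.ndarray, attn_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-position log-probability vectors over the full vocabulary (eval mode)."""
        log_probs, _ = nn.forward(self.params, self.config, ids, attn_mask, train=False)
        return log_probs

    def assemble(self, sequences: Sequence[str]) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, ...]]]:
        """CLS + k-mer ids + SEP, PAD-padded; returns (ids, attn_mask, kmer_id_tuples)."""
        v = self.vocab
        toks = [encode(s, v).token_ids for s in sequences]
        max_len = max(len(t) for t in toks) + 2
        if max_len > self.config.max_positions:
            worst = max(len(t) for t in toks) + v.k - 1
            raise ValueError(
                f"assembled input length {max_len} exceeds max_positions "
                f"{self.config.max_positions} (sequence length {worst} nt)"
            )
        ids = np.full((len(toks), max_len), v.pad_id, dtype=np.int64)
        attn = np.zeros((len(toks), max_len), dtype=nn.DTYPE)
        for i, t in enumerate(toks):
            ids[i, 0] = v.cls_id
            ids[i, 1:1 + len(t)] = t
            ids[i, 1 + len(t)] = v.sep_id
            attn[i, :len(t) + 2] = 1.0
        return ids, attn, toks


def init_model(config: EncoderConfig, init_mode: str = "from_scratch",
               checkpoint_path=None, vocab: Optional[KmerVocabulary] = None,
               seed: int = 0) -> MaskedLanguageModel:
    """Create a model, either freshly initialized or restored from disk."""
    if init_mode not in INIT_MODES:
        raise ValueError(f"unknown init_mode {init_mode!r}; expected one of {INIT_MODES}")
    if init_mode == "from_checkpoint":
        if checkpoint_path is None:
            raise ValueError("from_checkpoint requires checkpoint_path")
        model = load_checkpoint(checkpoint_path)
        diffs = [f for f in asdict(config)
                 if getattr(model.config, f) != getattr(config, f)]
        if diffs:
            raise ValueError(f"checkpoint config mismatch in fields: {diffs}")
        return model
    if vocab is None:
        k = next((kk for kk in range(1, 7) if 4 ** kk + 5 == config.vocab_size), None)
        if k is None:
            raise ValueError(
                f"vocab_size {config.vocab_size} is not 4**k + 5; pass an explicit vocabulary"
            )
        vocab = build_vocabulary(k)
    return MaskedLanguageModel(config, vocab, seed=seed)


# ---------------------------------------------------------------------------
# parameter counting

def count_parameters(config: EncoderConfig, include_mlm_head: bool = True) -> int:
    """Closed-form number of trainable scalars."""
    H, I, V, P = config.hidden_size, config.intermediate_size, config.vocab_size, config.max_positions
    emb = V * H + P * H + 2 * H
    per_layer = 4 * (H * H + H) + 2 * H + (H * I + I) + (I * H + H) + 2 * H
    total = emb + config.num_layers * per_layer
    if include_mlm_head:
        total += (H * H + H) + 2 * H + (H * V + V)
    return total


def enumerate_parameters(config: EncoderConfig, include_mlm_head: bool = True) -> int:
    """Direct enumeration over the parameter shape registry."""
    return sum(int(np.prod(s)) for s in nn.param_spec(config, include_mlm_head).values())


# ---------------------------------------------------------------------------
# pretraining

def _mask_batch(ids: np.ndarray, toks: List[Tuple[int, ...]], vocab: KmerVocabulary,
                mask_rate: float, rng: np.random.Generator):
    """Contiguous nucleotide-level masking; returns (masked ids, labels)."""
    masked = ids.copy()
    labels = np.full_like(ids, -100)
    k = vocab.k
    lo, hi = vocab.n_specials, vocab.size
    for row, t in enumerate(toks):
        n = len(t)
        L = n + k - 1
        pick = rng.random(L) < mask_rate
        if not pick.any():
            pick[rng.integers(L)] = True
        for i in np.flatnonzero(pick):
            j0, j1 = max(0, i - k + 1), min(n - 1, int(i))
            span = np.arange(j0, j1 + 1)
            labels[row, 1 + span] = ids[row, 1 + span]
            u = rng.random()
            if u < 0.8:
                masked[row, 1 + span] = vocab.mask_id
            elif u < 0.9:
                masked[row, 1 + span] = rng.integers(lo, hi, size=span.size)
            # else: keep original tokens
    return masked, labels


def pretrain(model: MaskedLanguageModel, corpus: WeightedCorpus, tcfg: TrainingConfig,
             design: Optional[LibraryDesign] = None, include_adapters: bool = False
             ) -> Tuple[MaskedLanguageModel, List[Tuple[int, float]]]:
    """Train the model in place on a weighted corpus; returns (model, loss history).

    History holds one (step, mean loss over the logging interval) entry per
    ``log_every`` steps.  Fully reproducible from ``tcfg.seed``.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if include_adapters and not corpus.adapters_included:
        if design is None:
            raise ValueError("include_adapters requires a LibraryDesign")
        corpus = corpus_with_adapters(corpus, design)

    seqs = [s for s, _ in corpus.entries]
    weights = np.array([w for _, w in corpus.entries], dtype=np.float64)
    probs = weights / weights.sum()

    longest = max(len(s) for s in seqs)
    if longest - model.vocab.k + 1 + 2 > model.config.max_positions:
        raise ValueError(
            f"sequence of length {longest} nt exceeds model max_positions "
            f"{model.config.max_positions}"
        )

    rng = np.random.default_rng(tcfg.seed)
    opt = nn.AdamW(model.params, lr=tcfg.learning_rate, total_steps=tcfg.steps,
                   warmup_fraction=tcfg.warmup_fraction, weight_decay=tcfg.weight_decay)
    history: List[Tuple[int, float]] = []
    window: List[float] = []
    for step in range(1, tcfg.steps + 1):
        idx = rng.choice(len(seqs), size=min(tcfg.batch_size, len(seqs)), p=probs)
        batch = [seqs[i] for i in idx]
        ids, attn, toks = model.assemble(batch)
        masked, labels = _mask_batch(ids, toks, model.vocab, tcfg.mask_rate, rng)
        loss, grads = nn.loss_and_grads(model.params, model.config, masked, attn,
                                        labels, drop_rng=rng)
        opt.step(model.params, grads)
        window.append(loss)
        if step % tcfg.log_every == 0 or step == tcfg.steps:
            history.append((step, float(np.mean(window))))
            window = []
    return model, history


def predict_log_probs(model: MaskedLanguageModel, ids: np.ndarray,
                      attn_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Eval-mode per-position log-probabilities for a batch of token ids.

    The output for a sequence depends only on its content, not on batch
    composition or the amount of PAD padding.
    """
    ids = np.asarray(ids)
    if ids.ndim != 2:
        raise ValueError("ids must be a (batch, positions) array")
    if ids.min() < 0 or ids.max() >= model.config.vocab_size:
        raise ValueError("token id out of range")
    return model.forward(ids, attn_mask)


# ---------------------------------------------------------------------------
# checkpoints: directory with config (key=value text), vocabulary, weights

def save_checkpoint(model: MaskedLanguageModel, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg_lines = [f"{k}={v}" for k, v in asdict(model.config).items()]
    cfg_lines.append(f"seed={model.seed}")
    (path / "config.txt").write_text("\n".join(cfg_lines) + "\n")
    (path / "vocab.txt").write_text(model.vocab.to_text())
    np.savez(path / "weights.npz", **model.params)
    return path


def load_checkpoint(path) -> MaskedLanguageModel:
    path = Path(path)
    if not (path / "config.txt").exists():
        raise IOError(f"not a checkpoint directory: {path}")
    kv = dict(line.split("=", 1) for line in
              (path / "config.txt").read_text().strip().splitlines())
    seed = int(kv.pop("seed", "0"))
    fields = {f: (float(kv[f]) if f == "dropout" else int(kv[f])) for f in kv}
    config = EncoderConfig(**fields)
    vocab = KmerVocabulary.from_text((path / "vocab.txt").read_text())
    with np.load(path / "weights.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return MaskedLanguageModel(config, vocab, params=params, seed=seed)
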