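"""Overlapping k-mer tokenization of DNA sequences.

A sequence of length ``L`` becomes ``n = L - k + 1`` overlapping k-mer tokens;
token ``t`` (0-based) covers nucleotides ``t .. t+k-1``.  The vocabulary holds
five special tokens (PAD, UNK, CLS, SEP, MASK) followed by the ``4**k`` k-mers
in lexicographic order, so for k=3 there are 64 k-mer tokens and 69 tokens in
total.  Token indices in a :class:`TokenSequence` refer to k-mer positions
only; CLS/SEP framing is added by the model-input assembly, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import List

DNA = "ACGT"
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")


@dataclass(frozen=True)
class KmerVocabulary:
    """Token alphabet: 5 special tokens followed by all ``4**k`` k-mers."""

    k: int
    tokens: tuple  # full ordered token list, specials first

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    @property
    def n_specials(self) -> int:
        return len(SPECIAL_TOKENS)

    @property
    def kmer_tokens(self) -> tuple:
        return self.tokens[self.n_specials:]

    @property
    def kmer_ids(self) -> range:
        """Dense id range of the non-special (k-mer) tokens."""
        return range(self.n_specials, self.size)

    def id_of(self, token: str) -> int:
        try:
            return self._token_to_id[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary (k={self.k})")

    def token_of(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def pad_id(self) -> int:
        return self.id_of("[PAD]")

    @property
    def cls_id(self) -> int:
        return self.id_of("[CLS]")

    @property
    def sep_id(self) -> int:
        return self.id_of("[SEP]")

    @property
    def mask_id(self) -> int:
        return self.id_of("[MASK]")

    def __post_init__(self):
        object.__setattr__(self, "_token_to_id", {t: i for i, t in enumerate(self.tokens)})

    # -- serialization: one token per line, id == line number ---------------
    def to_text(self) -> str:
        return "\n".join(self.tokens) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "KmerVocabulary":
        tokens = tuple(line.strip() for line in text.strip().splitlines())
        n_kmers = len(tokens) - len(SPECIAL_TOKENS)
        k = next(kk for kk in range(1, 8) if 4 ** kk == n_kmers)
        return cls(k=k, tokens=tokens)


@dataclass(frozen=True)
class TokenSequence:
    """Encoded sequence: k-mer token ids only (no CLS/SEP/PAD)."""

    token_ids: tuple
    k: int
    source_length: int

    @property
    def n(self) -> int:
        return len(self.token_ids)

    def __post_init__(self):
        if self.n != self.source_length - self.k + 1:
            raise ValueError(
                f"token count {self.n} inconsistent with L={self.source_length}, k={self.k}"
            )


def build_vocabulary(k: int = 3) -> KmerVocabulary:
    """Deterministic vocabulary: specials first, k-mers lexicographic."""
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in [1, 6], got {k}")
    kmers = ("".join(p) for p in product(DNA, repeat=k))
    return KmerVocabulary(k=k, tokens=SPECIAL_TOKENS + tuple(kmers))


def encode(sequence: str, vocab: KmerVocabulary) -> TokenSequence:
    """Encode a DNA string as overlapping k-mer token ids.

    ``"ATGCAT"`` with k=3 encodes to the tokens ATG, TGC, GCA, CAT.
    """
    k = vocab.k
    seq = sequence.upper().replace("U", "T")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    bad = set(seq) - set(DNA)
    if bad:
        raise ValueError(f"non-DNA symbols {sorted(bad)} in sequence")
    ids = tuple(vocab.id_of(seq[i:i + k]) for i in range(len(seq) - k + 1))
    return TokenSequence(token_ids=ids, k=k, source_length=len(seq))


def decode(tokens: TokenSequence, vocab: KmerVocabulary) -> str:
    """Invert :func:`encode`; consecutive tokens must overlap on k-1 chars."""
    kmers: List[str] = [vocab.token_of(i) for i in tokens.token_ids]
    seq = kmers[0]
    for prev, cur in zip(kmers, kmers[1:]):
        if prev[1:] != cur[:-1]:
            raise ValueError(f"non-contiguous token sequence: {prev} -> {cur}")
        seq += cur[-1]
    return seq
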