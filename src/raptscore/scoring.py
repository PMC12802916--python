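"""The modified pseudo-log-likelihood score with consecutive-triplet masking.

For a sequence of length L tokenized into n = L - k + 1 overlapping k-mers
W = (w_1, ..., w_n), the score masks the triplet M_t = (w_t, w_{t+1}, w_{t+2})
for every t in [2, n-3] and sums log P(w_{t+1} | W \\ M_t) over t (central
mode), or the log-probabilities of all three masked tokens (all-three mode).
Masking a triplet at an interior t hides exactly one nucleotide — the one
covered by all three tokens — whereas masking at the termini would hide a
whole 3-nt segment, which is why the first and last token positions are
never used as triplet starts.  The number of scored positions is
n - 4 = L - k - 3 (L - 6 for k = 3).

When special tokens are excluded, the probability mass assigned to the five
specials is removed and the distribution renormalized over the remaining
4**k k-mer tokens (64 for k = 3) before taking logs.  Scores are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from raptscore.mlm import MaskedLanguageModel
from raptscore.selex_io import LibraryDesign
from raptscore.tokenizer import encode

TOKEN_SUM_MODES = ("central", "all_three")
SPECIAL_HANDLINGS = ("include", "exclude_renormalize")


@dataclass(frozen=True)
class ScoreSettings:
    """The six calibration axes.

    The first four fields (round_index, init_mode, duplicate_policy,
    adapters_included) identify the training run that produced a checkpoint;
    the last two (token_sum_mode, special_handling) are free per scoring call
    and never require retraining.
    """

    round_index: int = 0
    init_mode: str = "from_scratch"
    duplicate_policy: str = "log_weight"
    adapters_included: bool = False
    token_sum_mode: str = "central"
    special_handling: str = "exclude_renormalize"
    length_normalize: bool = True
    normalize_denominator: str = "scored_positions"  # or "nucleotides"

    def __post_init__(self):
        if self.token_sum_mode not in TOKEN_SUM_MODES:
            raise ValueError(f"token_sum_mode must be one of {TOKEN_SUM_MODES}")
        if self.special_handling not in SPECIAL_HANDLINGS:
            raise ValueError(f"special_handling must be one of {SPECIAL_HANDLINGS}")
        if self.normalize_denominator not in ("scored_positions", "nucleotides"):
            raise ValueError("normalize_denominator must be 'scored_positions' or 'nucleotides'")

    @property
    def training_key(self) -> tuple:
        return (self.round_index, self.init_mode, self.duplicate_policy, self.adapters_included)


@dataclass
class RaptScoreResult:
    total: float
    per_position: List[Tuple[int, float]]  # (0-based central nucleotide index, contribution)
    n_scored: int
    normalized: float
    token_sum_mode: str
    sequence: str
    terminal_exclusion: int = 3  # nucleotides per terminus with no central contribution


def _check_provenance(model: MaskedLanguageModel, settings: ScoreSettings) -> None:
    prov = getattr(model, "provenance", None)
    if prov is None:
        return
    mismatches = {
        f: (prov[f], getattr(settings, f))
        for f in ("round_index", "init_mode", "duplicate_policy", "adapters_included")
        if f in prov and prov[f] != getattr(settings, f)
    }
    if mismatches:
        raise ValueError(f"settings/checkpoint mismatch: {mismatches}")


def raptscore(sequence: str, model: MaskedLanguageModel, settings: ScoreSettings,
              design: Optional[LibraryDesign] = None) -> RaptScoreResult:
    """Score one sequence; all triplet maskings are evaluated in a single batch.

    If ``settings.adapters_included``, the library adapters are attached
    before tokenization so that scoring sees the same representation the
    model was trained on (candidates of any length get the same flanks).
    """
    _check_provenance(model, settings)
    vocab = model.vocab
    k = vocab.k
    seq = sequence.upper().replace("U", "T")
    if settings.adapters_included:
        if design is None:
            raise ValueError("adapters_included=True requires a LibraryDesign")
        seq = design.adapter5 + seq + design.adapter3

    toks = encode(seq, vocab).token_ids
    n = len(toks)
    n_scored = n - 4
    if n_scored < 1:
        raise ValueError(
            f"no scorable positions: length {len(seq)} nt gives n={n} tokens, "
            f"need at least {k + 4} nt"
        )

    # one batch row per triplet start t0 (0-based, t0 in [1, n-4])
    ids, attn, _ = model.assemble([seq] * n_scored)
    rows = np.arange(n_scored)
    t0 = rows + 1
    for off in range(3):
        ids[rows, 1 + t0 + off] = vocab.mask_id
    log_probs = model.forward(ids, attn).astype(np.float64)

    lo, hi = vocab.n_specials, vocab.size

    def token_logprob(row: int, tok_idx: int) -> float:
        pos = 1 + tok_idx  # CLS offset
        vec = log_probs[row, pos]
        orig = toks[tok_idx]
        if settings.special_handling == "include":
            return float(vec[orig])
        kvec = vec[lo:hi]
        return float(kvec[orig - lo] - logsumexp(kvec))

    center_offset = 1 + (k - 1) // 2  # central token start + center of that token
    per_position: List[Tuple[int, float]] = []
    for r in range(n_scored):
        start = r + 1
        if settings.token_sum_mode == "central":
            contrib = token_logprob(r, start + 1)
        else:
            contrib = sum(token_logprob(r, start + off) for off in range(3))
        per_position.append((start + center_offset, contrib))

    total = float(sum(c for _, c in per_position))
    denom = n_scored if settings.normalize_denominator == "scored_positions" else len(seq)
    return RaptScoreResult(
        total=total,
        per_position=per_position,
        n_scored=n_scored,
        normalized=total / denom,
        token_sum_mode=settings.token_sum_mode,
        sequence=seq,
    )


def position_profile(result: RaptScoreResult, terminal_exclusion: int = 3
                     ) -> List[Tuple[int, float]]:
    """Per-nucleotide contribution profile of a central-mode score.

    The contribution of triplet t is assigned to the nucleotide at the center
    of the central token, so for k=3 the scored centers are nucleotides
    4..L-3 (1-based): three nucleotides per terminus carry no contribution.
    ``terminal_exclusion=4`` widens the displayed exclusion by dropping the
    outermost scored position on each side (a display convention only; the
    score itself is unchanged).
    """
    if result.token_sum_mode != "central":
        raise ValueError("position profile is defined for central mode only")
    if terminal_exclusion not in (3, 4):
        raise ValueError("terminal_exclusion must be 3 or 4")
    profile = list(result.per_position)
    if terminal_exclusion == 4 and len(profile) > 2:
        profile = profile[1:-1]
    return profile


def score_candidates(candidates: Union[Sequence[str], Sequence[Tuple[str, str]], Dict[str, str]],
                     model: MaskedLanguageModel, settings: ScoreSettings,
                     design: Optional[LibraryDesign] = None) -> pd.DataFrame:
    """Score a candidate list; unscorable entries are flagged, not fatal.

    Accepts a dict {id: sequence}, a list of (id, sequence) pairs, or a bare
    sequence list (ids are generated).  Returns one row per candidate with
    columns (id, sequence, length, n_scored, total, normalized, ok, note);
    mixed lengths are supported and cross-length comparisons should use the
    ``normalized`` column.
    """
    if isinstance(candidates, dict):
        items = list(candidates.items())
    else:
        items = [c if isinstance(c, tuple) else (f"seq_{i:04d}", c)
                 for i, c in enumerate(candidates)]
    rows = []
    for cid, seq in items:
        try:
            res = raptscore(seq, model, settings, design=design)
            rows.append(dict(id=cid, sequence=seq, length=len(seq), n_scored=res.n_scored,
                             total=res.total, normalized=res.normalized, ok=True, note=""))
        except ValueError as exc:
            rows.append(dict(id=cid, sequence=seq, length=len(seq), n_scored=0,
                             total=np.nan, normalized=np.nan, ok=False, note=str(exc)))
    return pd.DataFrame(rows, columns=["id", "sequence", "length", "n_scored",
                                       "total", "normalized", "ok", "note"])


def write_score_table(table: pd.DataFrame, path) -> None:
    """Diffable TSV export with 6-decimal scores."""
    out = table.copy()
    for col in ("total", "normalized"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def write_profile(result: RaptScoreResult, path, terminal_exclusion: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcontribution\n")
        for pos, c in position_profile(result, terminal_exclusion):
            fh.write(f"{pos}\t{c:.6f}\n")
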