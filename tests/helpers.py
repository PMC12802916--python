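"""Independent oracles used by the tests.

`raptscore_naive` re-implements the score as the literal one-triplet-at-a-time
loop over separate single-row forward passes; it shares nothing with the
batched implementation beyond the model's forward pass itself.
"""

import math

import numpy as np

from raptscore.tokenizer import encode


def raptscore_naive(sequence, model, token_sum_mode="central",
                    special_handling="exclude_renormalize"):
    """Literal per-t masking loop: one forward pass per triplet."""
    vocab = model.vocab
    toks = encode(sequence, vocab).token_ids
    n = len(toks)
    total = 0.0
    for t0 in range(1, n - 3):  # 0-based triplet starts; 1-based t in [2, n-3]
        ids = np.array([[vocab.cls_id, *toks, vocab.sep_id]], dtype=np.int64)
        for off in range(3):
            ids[0, 1 + t0 + off] = vocab.mask_id
        log_probs = model.forward(ids).astype(np.float64)

        def lp(tok_idx):
            vec = log_probs[0, 1 + tok_idx]
            orig = toks[tok_idx]
            if special_handling == "include":
                return float(vec[orig])
            kvec = vec[vocab.n_specials:]
            shifted = kvec - kvec.max()
            return float(shifted[orig - vocab.n_specials]
                         - math.log(np.exp(shifted).sum()))

        if token_sum_mode == "central":
            total += lp(t0 + 1)
        else:
            total += lp(t0) + lp(t0 + 1) + lp(t0 + 2)
    return total


def best_window_identity(sequence, motif):
    """Brute-force sliding-window maximum identity fraction."""
    best = 0
    for i in range(len(sequence) - len(motif) + 1):
        window = sequence[i:i + len(motif)]
        best = max(best, sum(a == b for a, b in zip(window, motif)))
    return best / len(motif)
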