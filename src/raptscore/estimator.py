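"""Scikit-learn-compatible wrapper around the train-then-score core.

`AptamerScorer` bundles "pretrain a masked language model on a round's
sequences" (fit) with "assign each candidate a pseudo-log-likelihood"
(score_samples) behind the standard estimator interface, so the scorer can
sit inside sklearn model-selection or pipeline code.  The full pipeline
(simulation, calibration, GA) lives in the dedicated modules.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from raptscore.mlm import EncoderConfig, TrainingConfig, init_model, pretrain
from raptscore.scoring import ScoreSettings, score_candidates
from raptscore.selex_io import WeightedCorpus


class AptamerScorer(BaseEstimator):
    """Train a k-mer MLM on sequences and score candidates by pseudo-log-likelihood.

    Parameters mirror the encoder/training configuration; the two
    scoring-side settings (``token_sum_mode``, ``special_handling``) select
    the score variant.  After ``fit``, ``model_`` holds the trained
    masked-language model.

    Examples
    --------
    >>> scorer = AptamerScorer(steps=200, seed=0)
    >>> scorer.fit(["ACGTACGTACGTACGT"] * 50)       # doctest: +SKIP
    >>> scorer.score_samples(["ACGTACGTACGTACGT"])   # doctest: +SKIP
    """

    def __init__(self, k: int = 3, num_layers: int = 2, hidden_size: int = 64,
                 num_heads: int = 4, intermediate_size: int = 256,
                 max_positions: int = 128, dropout: float = 0.1,
                 steps: int = 800, batch_size: int = 32, learning_rate: float = 1e-3,
                 mask_rate: float = 0.15, token_sum_mode: str = "central",
                 special_handling: str = "exclude_renormalize", seed: int = 0):
        self.k = k
        self.num_layers = num_layers
        self.hidden_size = hidden_size
        self.num_heads = num_heads
        self.intermediate_size = intermediate_size
        self.max_positions = max_positions
        self.dropout = dropout
        self.steps = steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.mask_rate = mask_rate
        self.token_sum_mode = token_sum_mode
        self.special_handling = special_handling
        self.seed = seed

    def fit(self, X: Sequence[str], y=None, sample_weight: Optional[Sequence[int]] = None):
        """Pretrain the MLM on sequences ``X`` (optionally replication-weighted)."""
        X = list(X)
        if not X:
            raise ValueError("X must contain at least one sequence")
        if sample_weight is None:
            sample_weight = [1] * len(X)
        entries = [(s.upper().replace("U", "T"), int(w)) for s, w in zip(X, sample_weight)]
        corpus = WeightedCorpus(entries=entries, policy_used="as_is")
        config = EncoderConfig(num_layers=self.num_layers, hidden_size=self.hidden_size,
                               num_heads=self.num_heads,
                               intermediate_size=self.intermediate_size,
                               max_positions=self.max_positions,
                               vocab_size=4 ** self.k + 5, dropout=self.dropout)
        tcfg = TrainingConfig(steps=self.steps, batch_size=self.batch_size,
                              learning_rate=self.learning_rate, mask_rate=self.mask_rate,
                              seed=self.seed)
        model = init_model(config, "from_scratch", seed=self.seed)
        model, history = pretrain(model, corpus, tcfg)
        self.model_ = model
        self.loss_history_ = history
        self.n_features_in_ = 1
        return self

    def _settings(self) -> ScoreSettings:
        return ScoreSettings(token_sum_mode=self.token_sum_mode,
                             special_handling=self.special_handling)

    def score_samples(self, X: Sequence[str]) -> np.ndarray:
        """Length-normalized score per candidate (NaN for unscorable entries)."""
        check_is_fitted(self, "model_")
        table = score_candidates(list(X), self.model_, self._settings())
        return table["normalized"].to_numpy(dtype=float)

    def score_table(self, X: Sequence[str]):
        """Full per-candidate score table (id, length, total, normalized, flags)."""
        check_is_fitted(self, "model_")
        return score_candidates(list(X), self.model_, self._settings())
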