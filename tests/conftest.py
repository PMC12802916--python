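"""Shared fixtures.

The expensive artifacts — the seed-42 synthetic SELEX run and the tiny model
trained on its final round — are session-scoped so the end-to-end tests
(scoring oracle, motif recovery, calibration, GA) share one training run.
"""

import numpy as np
import pytest

from raptscore import (
    EncoderConfig,
    ScoreSettings,
    SimulationConfig,
    TrainingConfig,
    TINY_PRESET,
    build_vocabulary,
    init_model,
    pretrain,
    simulate_selex,
)
from raptscore.selex_io import apply_duplicate_policy


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary(3)


@pytest.fixture(scope="session")
def uniform_model():
    """Model whose output logits are identically zero: uniform distribution."""
    model = init_model(TINY_PRESET, seed=0)
    model.params["out_w"][:] = 0.0
    model.params["out_b"][:] = 0.0
    return model


@pytest.fixture(scope="session")
def random_model():
    """Untrained (randomly initialized) tiny model; deterministic outputs."""
    return init_model(TINY_PRESET, seed=123)


@pytest.fixture(scope="session")
def sim42():
    """The reference synthetic SELEX run: planted 13-nt motif, beta=5, depth 5000."""
    return simulate_selex(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def trained_tiny(sim42):
    """Tiny model pretrained on the final simulated round (shared across tests)."""
    corpus = apply_duplicate_policy(sim42.rounds[-1], "log_weight")
    model = init_model(TINY_PRESET, seed=0)
    model, history = pretrain(model, corpus, TrainingConfig(seed=0))
    model.loss_history = history
    return model


@pytest.fixture(scope="session")
def motif_corpus_model(sim42):
    """Tiny model pretrained on motif-planted 30-mers (the truncation fixture).

    The GA fixture trains on sequences that carry the planted motif verbatim
    (at random offsets), so the model's preference is anchored to the exact
    motif rather than to the near-motif variants a finite selection run
    enriches; see the methods note.
    """
    import numpy as np
    from raptscore.selex_io import WeightedCorpus
    from raptscore.synthetic import sample_motif_bearing

    rng = np.random.default_rng(42)
    seqs = sample_motif_bearing(2000, sim42.config, rng)
    corpus = WeightedCorpus(entries=[(s, 1) for s in seqs], policy_used="dedup")
    model = init_model(TINY_PRESET, seed=0)
    model, _ = pretrain(model, corpus, TrainingConfig(seed=0))
    return model


@pytest.fixture
def default_settings():
    return ScoreSettings(round_index=5, duplicate_policy="log_weight")
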