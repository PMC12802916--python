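"""Model initialization, parameter counting, prediction contracts, training."""

import numpy as np
import pytest

from raptscore import nn
from raptscore.mlm import (
    EncoderConfig,
    REFERENCE_PRESET,
    TINY_PRESET,
    TrainingConfig,
    count_parameters,
    enumerate_parameters,
    init_model,
    load_checkpoint,
    predict_log_probs,
    pretrain,
    save_checkpoint,
)
from raptscore.selex_io import WeightedCorpus

PROBE = ["ACGTACGTACGTACG", "TTTTGGGGCCCCAAA"]


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden_size=0)
    with pytest.raises(ValueError):
        EncoderConfig(hidden_size=65, num_heads=4)


def test_seeded_init_is_reproducible():
    a = init_model(TINY_PRESET, seed=7)
    b = init_model(TINY_PRESET, seed=7)
    ids, attn, _ = a.assemble(PROBE)
    np.testing.assert_array_equal(a.forward(ids, attn), b.forward(ids, attn))
    c = init_model(TINY_PRESET, seed=8)
    assert not np.allclose(a.forward(ids, attn), c.forward(ids, attn))


def test_checkpoint_round_trip(tmp_path):
    model = init_model(TINY_PRESET, seed=3)
    save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(tmp_path / "ckpt")
    assert restored.config == model.config
    for k in model.params:
        np.testing.assert_array_equal(restored.params[k], model.params[k])
    ids, attn, _ = model.assemble(PROBE)
    np.testing.assert_array_equal(model.forward(ids, attn), restored.forward(ids, attn))


def test_from_checkpoint_config_mismatch_lists_fields(tmp_path):
    model = init_model(TINY_PRESET, seed=3)
    save_checkpoint(model, tmp_path / "ckpt")
    wrong = EncoderConfig(num_layers=2, hidden_size=64, num_heads=4,
                          intermediate_size=256, max_positions=128,
                          vocab_size=21, dropout=0.1)
    with pytest.raises(ValueError, match="vocab_size"):
        init_model(wrong, "from_checkpoint", checkpoint_path=tmp_path / "ckpt")


def test_reference_preset_parameter_count_rounds_to_86_million():
    total = count_parameters(REFERENCE_PRESET, include_mlm_head=True)
    assert round(total / 1e6) == 86
    assert total == enumerate_parameters(REFERENCE_PRESET, include_mlm_head=True)


def test_tiny_parameter_count_matches_actual_arrays():
    model = init_model(TINY_PRESET, seed=0)
    actual = sum(p.size for p in model.params.values())
    assert actual == count_parameters(TINY_PRESET, include_mlm_head=True)
    assert actual == enumerate_parameters(TINY_PRESET, include_mlm_head=True)


def test_count_parameters_rejects_bad_config():
    with pytest.raises(ValueError):
        count_parameters(EncoderConfig(hidden_size=0))


def test_log_probs_normalize(random_model):
    ids, attn, _ = random_model.assemble(PROBE)
    lp = predict_log_probs(random_model, ids, attn)
    np.testing.assert_allclose(np.exp(lp).sum(-1), 1.0, atol=1e-5)


def test_uniform_logit_model_gives_uniform_distribution(uniform_model):
    ids, attn, _ = uniform_model.assemble(PROBE[:1])
    lp = predict_log_probs(uniform_model, ids, attn)
    np.testing.assert_allclose(lp, np.log(1.0 / 69), atol=1e-6)


def test_padding_invariance(random_model):
    """Same masked sequence alone vs inside a longer padded batch."""
    short, long = "ACGTACGTACG", "ACGTACGTACGTACGTACGTACGTACGTAC"
    ids_a, attn_a, _ = random_model.assemble([short])
    lp_alone = predict_log_probs(random_model, ids_a, attn_a)
    ids_b, attn_b, _ = random_model.assemble([short, long])
    lp_batch = predict_log_probs(random_model, ids_b, attn_b)
    T = ids_a.shape[1]
    np.testing.assert_allclose(lp_alone[0], lp_batch[0, :T], atol=1e-4)


def test_predict_rejects_bad_ids(random_model):
    with pytest.raises(ValueError):
        predict_log_probs(random_model, np.array([[0, 99]]))


def test_pretrain_reduces_loss_and_is_reproducible():
    rng = np.random.default_rng(11)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(50)]
    corpus = WeightedCorpus(entries=[(s, 1) for s in seqs], policy_used="dedup")
    tcfg = TrainingConfig(steps=120, batch_size=16, seed=5, log_every=40)
    m1, h1 = pretrain(init_model(TINY_PRESET, seed=1), corpus, tcfg)
    assert h1[-1][1] < h1[0][1]
    m2, h2 = pretrain(init_model(TINY_PRESET, seed=1), corpus, tcfg)
    assert h1 == h2  # identical seed + corpus + config -> identical loss history


def test_pretrain_degenerate_corpus_memorizes():
    """Single repeated sequence: its score far exceeds a random sequence's."""
    from raptscore.scoring import ScoreSettings, raptscore
    seq = "ACGTTGCACCTTGACGGTTACGGTAA"
    corpus = WeightedCorpus(entries=[(seq, 1)], policy_used="dedup")
    model, hist = pretrain(init_model(TINY_PRESET, seed=2), corpus,
                           TrainingConfig(steps=250, batch_size=16, seed=2))
    assert hist[-1][1] < 0.8  # near the entropy floor of a one-sequence corpus
    s = ScoreSettings()
    trained = raptscore(seq, model, s).total
    random_seq = "TGCATGCATGCATGCATGCATGCATG"
    assert trained > raptscore(random_seq, model, s).total + 20


def test_pretrain_rejects_empty_and_overlong():
    with pytest.raises(ValueError, match="empty"):
        pretrain(init_model(TINY_PRESET, seed=0),
                 WeightedCorpus(entries=[], policy_used="dedup"), TrainingConfig(steps=1))
    long_seq = "A" * 200  # 198 tokens + CLS/SEP > 128 positions
    with pytest.raises(ValueError, match="max_positions"):
        pretrain(init_model(TINY_PRESET, seed=0),
                 WeightedCorpus(entries=[(long_seq, 1)], policy_used="dedup"),
                 TrainingConfig(steps=1))


def test_weighted_replication_ratio():
    """Appearance ratio in sampled batches tracks the weight ratio (3:1)."""
    corpus = WeightedCorpus(entries=[("A" * 10, 3), ("C" * 10, 1)], policy_used="as_is")
    weights = np.array([w for _, w in corpus.entries], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(0)
    draws = rng.choice(2, size=12000, p=probs)  # same sampling rule as pretrain
    ratio = (draws == 0).sum() / (draws == 1).sum()
    assert abs(ratio - 3.0) / 3.0 < 0.05
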