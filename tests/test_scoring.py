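"""Score semantics: closed forms, oracle equivalence, profiles, batching."""

import math

import numpy as np
import pytest

from raptscore.scoring import (
    ScoreSettings,
    position_profile,
    raptscore,
    score_candidates,
)
from raptscore.selex_io import LibraryDesign
from helpers import raptscore_naive

L30 = "ACGTTGCACCAAGGTTGCCGGTTACGGTAA"


def test_uniform_model_closed_form_renormalized(uniform_model):
    """Uniform logits + special exclusion: total = (L-6) * log(1/64)."""
    s = ScoreSettings(special_handling="exclude_renormalize")
    res = raptscore(L30, uniform_model, s)
    assert res.n_scored == 24
    assert res.total == pytest.approx(24 * math.log(1 / 64), abs=1e-4)


def test_uniform_model_closed_form_including_specials(uniform_model):
    s = ScoreSettings(special_handling="include")
    res = raptscore(L30, uniform_model, s)
    assert res.total == pytest.approx(24 * math.log(1 / 69), abs=1e-4)


def test_uniform_model_all_three_mode(uniform_model):
    s = ScoreSettings(token_sum_mode="all_three")
    res = raptscore(L30, uniform_model, s)
    assert res.total == pytest.approx(3 * 24 * math.log(1 / 64), abs=3e-4)


def test_n_scored_arithmetic(uniform_model):
    for L in (7, 10, 30):
        res = raptscore("A" * L, uniform_model, ScoreSettings())
        assert res.n_scored == L - 6


def test_too_short_sequence_is_error(uniform_model):
    with pytest.raises(ValueError, match="no scorable positions"):
        raptscore("ACGTAC", uniform_model, ScoreSettings())


@pytest.mark.parametrize("mode", ["central", "all_three"])
@pytest.mark.parametrize("handling", ["include", "exclude_renormalize"])
def test_batched_equals_naive_loop(trained_tiny, mode, handling):
    """Optimized implementation vs literal per-triplet masking loop."""
    rng = np.random.default_rng(99)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(10, 31)))
            for _ in range(5)]
    s = ScoreSettings(round_index=5, duplicate_policy="log_weight",
                      token_sum_mode=mode, special_handling=handling)
    for seq in seqs:
        fast = raptscore(seq, trained_tiny, s).total
        slow = raptscore_naive(seq, trained_tiny, mode, handling)
        assert fast == pytest.approx(slow, abs=1e-4)


def test_naive_oracle_on_random_model_many_sequences(random_model):
    rng = np.random.default_rng(7)
    s = ScoreSettings()
    for _ in range(20):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        assert raptscore(seq, random_model, s).total == pytest.approx(
            raptscore_naive(seq, random_model), abs=1e-4)


def test_determinism_across_batch_composition(random_model):
    s = ScoreSettings()
    alone = raptscore(L30, random_model, s).total
    again = raptscore(L30, random_model, s).total
    assert alone == again
    table = score_candidates([L30, "ACGTACGTACGT", L30[::-1]], random_model, s)
    assert table.loc[0, "total"] == pytest.approx(alone, abs=1e-9)


def test_renormalization_preserves_scores_when_specials_have_no_mass(uniform_model):
    """With zero mass on specials, include vs exclude give identical scores."""
    model = uniform_model
    # force specials to -inf-ish logits: big negative bias on the 5 special ids
    saved = model.params["out_b"].copy()
    model.params["out_b"][:5] = -60.0
    try:
        inc = raptscore(L30, model, ScoreSettings(special_handling="include")).total
        exc = raptscore(L30, model, ScoreSettings(special_handling="exclude_renormalize")).total
        assert inc == pytest.approx(exc, abs=1e-6)
    finally:
        model.params["out_b"][:] = saved


def test_profile_covers_interior_and_sums_to_total(uniform_model):
    res = raptscore(L30, uniform_model, ScoreSettings())
    prof = position_profile(res)
    assert len(prof) == 24
    positions = [p for p, _ in prof]
    # scored centers are consecutive interior nucleotides (0-based 3..26)
    assert positions == list(range(3, 27))
    assert sum(c for _, c in prof) == pytest.approx(res.total, abs=1e-6)


def test_profile_widened_terminal_exclusion(uniform_model):
    res = raptscore(L30, uniform_model, ScoreSettings())
    prof4 = position_profile(res, terminal_exclusion=4)
    assert len(prof4) == 22
    assert [p for p, _ in prof4] == list(range(4, 26))


def test_profile_rejects_all_three_mode(uniform_model):
    res = raptscore(L30, uniform_model, ScoreSettings(token_sum_mode="all_three"))
    with pytest.raises(ValueError, match="central"):
        position_profile(res)


def test_profile_highlights_planted_motif(trained_tiny, sim42, default_settings):
    """Mean contribution inside the planted motif exceeds outside."""
    motif = sim42.config.motif
    rng = np.random.default_rng(5)
    inside_vals, outside_vals = [], []
    for _ in range(10):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 30 - len(motif)))
        off = int(rng.integers(4, 30 - len(motif) - 3))
        seq = flank[:off] + motif + flank[off:]
        res = raptscore(seq, trained_tiny, default_settings)
        for pos, c in position_profile(res):
            (inside_vals if off <= pos < off + len(motif) else outside_vals).append(c)
    assert np.mean(inside_vals) > np.mean(outside_vals)


def test_score_candidates_flags_unscorable_and_continues(random_model):
    table = score_candidates({"ok": L30, "short": "ACGTAC"}, random_model, ScoreSettings())
    assert table.loc[table["id"] == "ok", "ok"].item()
    bad = table[table["id"] == "short"]
    assert not bad["ok"].item() and np.isnan(bad["total"].item())


def test_identical_candidates_get_identical_rows(random_model):
    t = score_candidates([L30, L30], random_model, ScoreSettings())
    assert t.loc[0, "total"] == t.loc[1, "total"]


def test_normalized_scores_equal_across_lengths_under_uniform_model(uniform_model):
    t = score_candidates(["A" * 7, L30], uniform_model, ScoreSettings())
    assert t.loc[0, "normalized"] == pytest.approx(math.log(1 / 64), abs=1e-5)
    assert t.loc[0, "normalized"] == pytest.approx(t.loc[1, "normalized"], abs=1e-5)


def test_adapters_attached_before_scoring(uniform_model):
    design = LibraryDesign("GGGAG", "CTCGA", 30)
    s = ScoreSettings(adapters_included=True)
    res = raptscore(L30, uniform_model, s, design=design)
    assert res.sequence == "GGGAG" + L30 + "CTCGA"
    assert res.n_scored == len(res.sequence) - 6
    with pytest.raises(ValueError, match="LibraryDesign"):
        raptscore(L30, uniform_model, s)


def test_provenance_mismatch_raises(random_model):
    random_model.provenance = dict(round_index=5, init_mode="from_scratch",
                                   duplicate_policy="as_is", adapters_included=False)
    try:
        with pytest.raises(ValueError, match="mismatch"):
            raptscore(L30, random_model, ScoreSettings(round_index=2,
                                                       duplicate_policy="as_is"))
        ok = raptscore(L30, random_model,
                       ScoreSettings(round_index=5, duplicate_policy="as_is"))
        assert ok.n_scored == 24
    finally:
        del random_model.provenance


def test_triplet_masking_hides_exactly_one_interior_nucleotide(vocab):
    """Reconstructing from unmasked tokens recovers all but one nucleotide."""
    from raptscore.tokenizer import encode
    seq = L30
    toks = encode(seq, vocab).token_ids
    n = len(toks)
    for t0 in (1, 5, n - 4):
        visible = {i: vocab.token_of(tid) for i, tid in enumerate(toks)
                   if i not in (t0, t0 + 1, t0 + 2)}
        known = set()
        for i, kmer in visible.items():
            for off, base in enumerate(kmer):
                known.add(i + off)
        hidden = set(range(len(seq))) - known
        assert hidden == {t0 + 2}  # the single nucleotide covered by all three
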