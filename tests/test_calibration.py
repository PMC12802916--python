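"""Frequency/enrichment baselines, representative selection, correlation search."""

import numpy as np
import pandas as pd
import pytest

from raptscore.calibration import (
    ActivityTable,
    CalibrationGrid,
    grid_calibrate,
    occurrence_metrics,
    pearson,
    select_representatives,
    top_k_coverage,
)
from raptscore.mlm import TINY_PRESET, TrainingConfig
from raptscore.selex_io import SelexRound


def _round(idx, counts):
    return SelexRound(idx, counts, sum(counts.values()))


def _metrics_value(df, seq, rnd, col):
    return df[(df["sequence"] == seq) & (df["round"] == rnd)][col].item()


def test_frequency_and_enrichment_closed_forms():
    r1 = _round(1, {"AAAA": 3, "CCCC": 997})
    r2 = _round(2, {"AAAA": 50, "CCCC": 950})
    df = occurrence_metrics([r1, r2])
    assert _metrics_value(df, "AAAA", 1, "frequency") == pytest.approx(0.003)
    assert _metrics_value(df, "AAAA", 2, "enrichment") == pytest.approx(
        (50 / 1000) / (3 / 1000))


def test_frequency_sums_to_one_per_round():
    r1 = _round(0, {"AAAA": 7, "CCCC": 13, "GGGG": 80})
    r2 = _round(1, {"AAAA": 10, "TTTT": 90})
    df = occurrence_metrics([r1, r2])
    for rnd, grp in df.groupby("round"):
        assert grp["frequency"].sum() == pytest.approx(1.0, abs=1e-9)


def test_enrichment_undefined_exactly_where_absent_before():
    r1 = _round(1, {"AAAA": 5, "CCCC": 5})
    r2 = _round(2, {"AAAA": 5, "GGGG": 5})
    df = occurrence_metrics([r1, r2])
    # earliest round: always undefined
    assert df[df["round"] == 1]["enrichment"].isna().all()
    # present in both rounds: defined
    assert np.isfinite(_metrics_value(df, "AAAA", 2, "enrichment"))
    # newly appearing: undefined
    assert np.isnan(_metrics_value(df, "GGGG", 2, "enrichment"))


def test_duplicate_round_index_rejected():
    with pytest.raises(ValueError, match="duplicate round_index"):
        occurrence_metrics([_round(1, {"AAAA": 1}), _round(1, {"CCCC": 1})])


def test_representatives_backfill_when_no_enrichment():
    counts = {f"{b1}{b2}AA": 10 - i for i, (b1, b2) in
              enumerate([(a, b) for a in "ACGT" for b in "ACGT"][:8])}
    df = occurrence_metrics([_round(1, counts)])
    reps = select_representatives(df, 1)
    assert len(reps) == 6  # all six backfilled from frequency
    by_freq = sorted(counts, key=lambda s: (-counts[s], s))
    assert reps == by_freq[:6]


def test_representatives_disjoint_and_overlapping():
    r1 = _round(1, {"AAAA": 40, "CCCC": 30, "GGGG": 20, "TTTT": 5, "ACGT": 3, "TGCA": 2})
    # enrichment ranking differs from frequency ranking
    r2 = _round(2, {"AAAA": 10, "CCCC": 20, "GGGG": 30, "TTTT": 25, "ACGT": 10, "TGCA": 5})
    df = occurrence_metrics([r1, r2])
    reps = select_representatives(df, 2)
    assert len(reps) == 6
    assert len(set(reps)) == 6
    # top-3 by frequency in round 2 present
    for s in ("GGGG", "TTTT", "CCCC"):
        assert s in reps


def test_representatives_shortfall_on_tiny_round():
    df = occurrence_metrics([_round(1, {"AAAA": 2, "CCCC": 1})])
    reps = select_representatives(df, 1)
    assert reps == ["AAAA", "CCCC"]  # only two distinct sequences exist


def test_pearson_closed_forms_and_hand_computed():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)
    # hand-computed via the textbook formula for y=(1,3,2,4)
    assert pearson(x, [1.0, 3.0, 2.0, 4.0]) == pytest.approx(0.8)


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError, match="degenerate"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])


def test_top_k_coverage_values():
    ids = [f"s{i}" for i in range(10)]
    act = ActivityTable(pd.DataFrame({
        "id": ids, "sequence": ["ACGTACG"] * 10,
        "relative_activity": np.linspace(100, 10, 10)}))
    perfect = pd.DataFrame({"id": ids, "normalized": np.linspace(1.0, 0.1, 10)})
    assert top_k_coverage(perfect, act, 5) == 1.0
    reversed_ = pd.DataFrame({"id": ids, "normalized": np.linspace(0.1, 1.0, 10)})
    assert top_k_coverage(reversed_, act, 5) == 0.0
    # four of the top five shared -> 0.8
    partial = perfect.copy()
    partial.loc[partial["id"] == "s4", "normalized"] = 0.0  # drop one top-5 to bottom
    assert top_k_coverage(partial, act, 5) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        top_k_coverage(perfect, act, 11)


def test_activity_table_validation():
    with pytest.raises(ValueError, match="missing columns"):
        ActivityTable(pd.DataFrame({"id": ["a"], "sequence": ["ACGT"]}))
    with pytest.raises(ValueError, match="unique"):
        ActivityTable(pd.DataFrame({"id": ["a", "a"], "sequence": ["ACGT", "ACGT"],
                                    "relative_activity": [1.0, 2.0]}))


def test_grid_with_single_cell_returns_that_cell(sim42):
    """One-cell grid: best == that cell, and best_r is reproducible from the table."""
    from raptscore.calibration import occurrence_metrics as om
    from raptscore.synthetic import make_activity_table
    rounds = sim42.rounds
    metrics = om(rounds)
    reps = []
    for rnd in rounds:
        for s in select_representatives(metrics, rnd.round_index):
            if s not in reps:
                reps.append(s)
    act = ActivityTable(make_activity_table(reps, sim42.true_fitness, noise_sd=5.0,
                                            seed=1, ids=[f"r{i}" for i in range(len(reps))]))
    grid = CalibrationGrid(rounds=(5,), duplicate_policies=("dedup",),
                           token_sum_modes=("central",),
                           special_handlings=("exclude_renormalize",))
    tcfg = TrainingConfig(steps=60, batch_size=16, seed=0)
    result = grid_calibrate(rounds, act, grid, TINY_PRESET, tcfg)
    assert len(result.table) == 1
    assert result.best_setting.round_index == 5
    assert result.best_r == pytest.approx(result.table["pearson_r"].max())


def test_grid_missing_activity_rows_listed(sim42):
    act = ActivityTable(pd.DataFrame({"id": ["x"], "sequence": ["ACGTACG"],
                                      "relative_activity": [50.0]}))
    grid = CalibrationGrid(rounds=(5,), duplicate_policies=("dedup",))
    with pytest.raises(KeyError, match="missing"):
        grid_calibrate(sim42.rounds, act, grid, TINY_PRESET,
                       TrainingConfig(steps=1, batch_size=4, seed=0))
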