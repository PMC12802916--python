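"""Occurrence baselines and Pearson-correlation calibration of score settings.

Frequency (count / total reads per round) and enrichment (frequency ratio
between consecutive rounds, undefined when the sequence is absent from the
earlier round) are the classical HT-SELEX ranking metrics; they also choose
the representative sequences whose measured activities calibrate the score.
Calibration trains one model per training-side setting combination (round,
initialization, duplicate policy, adapter inclusion), scores the shared
representative panel under both scoring-side variants (token-sum mode,
special-token handling), computes the Pearson correlation with activity per
setting, and keeps the setting with the highest r.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from raptscore.mlm import EncoderConfig, TrainingConfig, init_model, pretrain
from raptscore.scoring import ScoreSettings, score_candidates
from raptscore.selex_io import LibraryDesign, SelexRound, apply_duplicate_policy
from raptscore.synthetic import SimulatedSelex

logger = logging.getLogger(__name__)

#: TSV schema of an activity panel
ACTIVITY_COLUMNS = ("id", "sequence", "relative_activity")


class ActivityTable:
    """Measured relative binding activities (control = 100 scale)."""

    def __init__(self, table: pd.DataFrame):
        missing = set(ACTIVITY_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"activity table missing columns {sorted(missing)}")
        if table["id"].duplicated().any():
            raise ValueError("activity table ids must be unique")
        if not np.isfinite(table["relative_activity"].to_numpy(dtype=float)).all():
            raise ValueError("activities must be finite")
        t = table.copy()
        t["sequence"] = t["sequence"].str.upper().str.replace("U", "T")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "ActivityTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def activity_of(self, sequences: Sequence[str]) -> np.ndarray:
        by_seq = dict(zip(self.table["sequence"], self.table["relative_activity"]))
        missing = [s for s in sequences if s not in by_seq]
        if missing:
            raise KeyError(
                f"activity missing for {len(missing)} representative(s): {missing[:3]}"
            )
        return np.array([by_seq[s] for s in sequences], dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CalibrationResult:
    table: pd.DataFrame          # one row per setting with pearson_r, n_points
    best_setting: ScoreSettings
    best_r: float

    def to_json(self, path) -> None:
        payload = {
            "best_setting": asdict(self.best_setting),
            "best_r": self.best_r,
            "settings": [
                {**{k: row[k] for k in ("round_index", "init_mode", "duplicate_policy",
                                        "adapters_included", "token_sum_mode",
                                        "special_handling")},
                 "pearson_r": row["pearson_r"], "spearman_r": row["spearman_r"],
                 "n_points": int(row["n_points"])}
                for _, row in self.table.iterrows()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# occurrence metrics

def occurrence_metrics(rounds: Sequence[SelexRound]) -> pd.DataFrame:
    """Long-format table (sequence, round, count, frequency, enrichment).

    Enrichment at round r is frequency_r / frequency_{r-1} over *consecutive
    present rounds*; it is NaN (never imputed) for the earliest round and
    wherever the sequence is absent from the prior round.
    """
    indices = [r.round_index for r in rounds]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate round_index in rounds")
    ordered = sorted(rounds, key=lambda r: r.round_index)
    rows = []
    prev_freq: Optional[Dict[str, float]] = None
    prev_index: Optional[int] = None
    for rnd in ordered:
        freq = {s: c / rnd.total_reads for s, c in rnd.counts.items()}
        for s in sorted(freq):
            enr = np.nan
            if prev_freq is not None and rnd.round_index == prev_index + 1 and s in prev_freq:
                enr = freq[s] / prev_freq[s]
            rows.append((s, rnd.round_index, rnd.counts[s], freq[s], enr))
        prev_freq, prev_index = freq, rnd.round_index
    return pd.DataFrame(rows, columns=["sequence", "round", "count", "frequency", "enrichment"])


def select_representatives(metrics: pd.DataFrame, round_index: int,
                           k_freq: int = 3, k_enr: int = 3) -> List[str]:
    """Top k_freq by frequency plus top k_enr by enrichment, de-duplicated.

    If enrichment defines fewer than k_enr candidates (earliest round, or no
    sequence present in consecutive rounds), the shortfall is backfilled from
    the frequency ranking so the combined total is k_freq + k_enr where the
    round has enough distinct sequences.  Ties break lexicographically.
    """
    sub = metrics[metrics["round"] == round_index]
    if sub.empty:
        raise ValueError(f"no sequences recorded for round {round_index}")
    by_freq = sub.sort_values(["frequency", "sequence"],
                              ascending=[False, True])["sequence"].tolist()
    enr_sub = sub.dropna(subset=["enrichment"])
    by_enr = enr_sub.sort_values(["enrichment", "sequence"],
                                 ascending=[False, True])["sequence"].tolist()

    chosen: List[str] = []
    for s in by_freq[:k_freq]:
        if s not in chosen:
            chosen.append(s)
    for s in by_enr[:k_enr]:
        if s not in chosen:
            chosen.append(s)
    target = k_freq + k_enr
    for s in by_freq:
        if len(chosen) >= target:
            break
        if s not in chosen:
            chosen.append(s)
    if len(chosen) < target:
        logger.info("round %d: only %d distinct sequences for %d slots",
                    round_index, len(chosen), target)
    return chosen


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation with strict input validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# settings grid search

@dataclass(frozen=True)
class CalibrationGrid:
    """Axes of the settings search; training axes x scoring axes."""

    rounds: Tuple[int, ...]
    init_modes: Tuple[str, ...] = ("from_scratch",)
    duplicate_policies: Tuple[str, ...] = ("as_is", "log_weight", "dedup")
    adapters: Tuple[bool, ...] = (False,)
    token_sum_modes: Tuple[str, ...] = ("central", "all_three")
    special_handlings: Tuple[str, ...] = ("include", "exclude_renormalize")


def grid_calibrate(rounds: Sequence[SelexRound], activity: ActivityTable,
                   grid: CalibrationGrid, model_config: EncoderConfig,
                   training: TrainingConfig, design: Optional[LibraryDesign] = None,
                   checkpoint_path=None, k_freq: int = 3, k_enr: int = 3
                   ) -> CalibrationResult:
    """Exhaustive settings search maximizing Pearson r against activity.

    One model is trained per (round, init_mode, duplicate_policy, adapters)
    cell and reused across the four scoring-side variants.  The representative
    panel (top-by-frequency and top-by-enrichment per round, pooled over all
    rounds) is fixed before calibration and shared by every setting.  Ties in
    best r break deterministically to the first setting in enumeration order.
    """
    by_index = {r.round_index: r for r in rounds}
    if len(by_index) != len(rounds):
        raise ValueError("duplicate round_index in rounds")
    metrics = occurrence_metrics(rounds)

    reps: List[str] = []
    for rnd in sorted(by_index):
        for s in select_representatives(metrics, rnd, k_freq, k_enr):
            if s not in reps:
                reps.append(s)
    act = activity.activity_of(reps)  # raises listing missing ids

    rows = []
    settings_order: List[ScoreSettings] = []
    for rnd_idx, init_mode, policy, adapt in itertools.product(
            grid.rounds, grid.init_modes, grid.duplicate_policies, grid.adapters):
        if rnd_idx not in by_index:
            raise ValueError(f"grid round {rnd_idx} not among supplied rounds")
        corpus = apply_duplicate_policy(by_index[rnd_idx], policy)
        model = init_model(model_config, init_mode, checkpoint_path=checkpoint_path,
                           seed=training.seed)
        model, _ = pretrain(model, corpus, training, design=design, include_adapters=adapt)
        model.provenance = dict(round_index=rnd_idx, init_mode=init_mode,
                                duplicate_policy=policy, adapters_included=adapt)
        for tsm, sph in itertools.product(grid.token_sum_modes, grid.special_handlings):
            settings = ScoreSettings(round_index=rnd_idx, init_mode=init_mode,
                                     duplicate_policy=policy, adapters_included=adapt,
                                     token_sum_mode=tsm, special_handling=sph)
            table = score_candidates(reps, model, settings, design=design)
            scores = table["normalized"].to_numpy()
            r = pearson(scores, act)
            rho = float(stats.spearmanr(scores, act).statistic)
            rows.append(dict(round_index=rnd_idx, init_mode=init_mode,
                             duplicate_policy=policy, adapters_included=adapt,
                             token_sum_mode=tsm, special_handling=sph,
                             pearson_r=r, spearman_r=rho, n_points=len(reps)))
            settings_order.append(settings)

    table = pd.DataFrame(rows)
    best_pos = int(np.argmax(table["pearson_r"].to_numpy()))  # first max wins ties
    return CalibrationResult(table=table, best_setting=settings_order[best_pos],
                             best_r=float(table["pearson_r"].iloc[best_pos]))


def top_k_coverage(score_table: pd.DataFrame, activity: ActivityTable, k: int = 5,
                   score_col: str = "normalized") -> float:
    """|top-k by score  ∩  top-k by activity| / k over a shared id set."""
    score_ids = set(score_table["id"])
    act_ids = set(activity.table["id"])
    if score_ids != act_ids:
        raise ValueError("score table and activity table must cover the same ids")
    if k > len(score_ids):
        raise ValueError(f"k={k} larger than id set of size {len(score_ids)}")
    top_score = set(score_table.sort_values([score_col, "id"], ascending=[False, True])
                    .head(k)["id"])
    top_act = set(activity.table.sort_values(["relative_activity", "id"],
                                             ascending=[False, True]).head(k)["id"])
    return len(top_score & top_act) / k
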