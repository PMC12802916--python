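"""Exhaustive deletion enumeration and score-guided truncation of aptamers.

All 1..d_max nucleotide deletions of a parent variable region are enumerated
as position-sets (0-based indices into the parent; adapters are never
deletable).  Simultaneous multi-position deletion uses set semantics — all
listed original positions are removed in one pass — so deleting P then Q on
re-indexed intermediates equals deleting P ∪ Q directly.  Variants are ranked
by raw score within each resulting length (same-length comparison); the top-k
and bottom-k per length are reported, mirroring the select-and-assay loop
used to validate truncations experimentally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from raptscore.mlm import MaskedLanguageModel
from raptscore.scoring import ScoreSettings, score_candidates
from raptscore.selex_io import LibraryDesign

logger = logging.getLogger(__name__)

MIN_SCORABLE_NT = 7  # k + 4 for k = 3


@dataclass(frozen=True)
class DeletionVariant:
    parent_id: str
    deleted_positions: frozenset
    sequence: str

    @staticmethod
    def from_parent(parent: str, positions: Iterable[int], parent_id: str = "parent"
                    ) -> "DeletionVariant":
        pos = frozenset(int(p) for p in positions)
        if not pos:
            raise ValueError("empty deletion set")
        if min(pos) < 0 or max(pos) >= len(parent):
            raise ValueError(f"deletion positions out of bounds for length {len(parent)}")
        seq = "".join(c for i, c in enumerate(parent) if i not in pos)
        return DeletionVariant(parent_id=parent_id, deleted_positions=pos, sequence=seq)


@dataclass
class TruncationReport:
    """Scored variants grouped by resulting length, with top/bottom picks."""

    table: pd.DataFrame                   # variant-level score table
    top: Dict[int, pd.DataFrame]          # length -> top_k rows
    bottom: Dict[int, pd.DataFrame]       # length -> bottom_k rows
    top_k: int
    bottom_k: int


def enumerate_deletions(parent: str, d_max: int = 3, parent_id: str = "parent",
                        dedup: bool = False) -> List[DeletionVariant]:
    """All position-sets of 1..d_max deletions: sum_d C(L, d) variants.

    With ``dedup`` variants with identical resulting strings are collapsed to
    one (the lexicographically smallest position-set), keeping all
    position-sets available through :func:`deletion_provenance`.
    """
    L = len(parent)
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if L - d_max < MIN_SCORABLE_NT:
        raise ValueError(
            f"parent of length {L} with d_max={d_max} yields unscorable variants "
            f"(< {MIN_SCORABLE_NT} nt)"
        )
    variants: List[DeletionVariant] = []
    for d in range(1, d_max + 1):
        for pos in combinations(range(L), d):
            variants.append(DeletionVariant.from_parent(parent, pos, parent_id))
    if dedup:
        seen: Dict[str, DeletionVariant] = {}
        for v in variants:
            if v.sequence not in seen:
                seen[v.sequence] = v
        variants = list(seen.values())
    return variants


def deletion_provenance(variants: Sequence[DeletionVariant]) -> Dict[str, List[frozenset]]:
    """sequence -> all position-sets that produce it."""
    prov: Dict[str, List[frozenset]] = {}
    for v in variants:
        prov.setdefault(v.sequence, []).append(v.deleted_positions)
    return prov


def combine_sites(parent: str, validated_sites: Sequence[int],
                  sizes: Iterable[int] = (2, 3), parent_id: str = "parent"
                  ) -> List[DeletionVariant]:
    """Multi-site variants from single-deletion sites that kept activity.

    Emits every size-2 and/or size-3 subset of the validated sites as one
    simultaneous deletion.  Requesting a size larger than the site list
    yields nothing for that size (with a warning).
    """
    sites = sorted(set(int(s) for s in validated_sites))
    if len(sites) != len(validated_sites):
        raise ValueError("validated_sites must be distinct")
    if sites and (sites[0] < 0 or sites[-1] >= len(parent)):
        raise ValueError("validated_sites out of parent bounds")
    bad = set(sizes) - {2, 3}
    if bad:
        raise ValueError(f"sizes must be a subset of {{2, 3}}, got {sorted(bad)}")
    out: List[DeletionVariant] = []
    for size in sorted(set(sizes)):
        if len(sites) < size:
            logger.warning("combine_sites: only %d sites for size-%d combinations",
                           len(sites), size)
            continue
        for pos in combinations(sites, size):
            out.append(DeletionVariant.from_parent(parent, pos, parent_id))
    return out


def rank_variants(variants: Sequence[DeletionVariant], model: MaskedLanguageModel,
                  settings: ScoreSettings, top_k: int = 3, bottom_k: int = 3,
                  design: Optional[LibraryDesign] = None, dedup: bool = True
                  ) -> TruncationReport:
    """Score variants and report per-length top/bottom picks by raw score.

    Identical resulting strings get identical scores, so sequence-level dedup
    is on by default; ties break lexicographically by sequence.
    """
    if top_k < 1 or bottom_k < 0:
        raise ValueError("top_k must be >= 1 and bottom_k >= 0")
    prov = deletion_provenance(variants)
    if dedup:
        uniq: Dict[str, DeletionVariant] = {}
        for v in variants:
            uniq.setdefault(v.sequence, v)
        variants = list(uniq.values())

    items = [(f"{v.parent_id}|del:" + ",".join(map(str, sorted(v.deleted_positions))),
              v.sequence) for v in variants]
    scored = score_candidates(items, model, settings, design=design)
    scored = scored[scored["ok"]].copy()
    scored["n_position_sets"] = scored["sequence"].map(lambda s: len(prov.get(s, [])))

    table_rows = []
    top: Dict[int, pd.DataFrame] = {}
    bottom: Dict[int, pd.DataFrame] = {}
    for length, grp in scored.groupby("length"):
        grp = grp.sort_values(["total", "sequence"], ascending=[False, True]).reset_index(drop=True)
        grp["rank"] = grp.index + 1
        if top_k + bottom_k > len(grp):
            logger.warning("length %d: group of %d smaller than top_k+bottom_k=%d",
                           length, len(grp), top_k + bottom_k)
        top[int(length)] = grp.head(top_k).copy()
        bottom[int(length)] = grp.tail(min(bottom_k, len(grp))).copy()
        table_rows.append(grp)
    full = pd.concat(table_rows, ignore_index=True) if table_rows else scored
    return TruncationReport(table=full, top=top, bottom=bottom, top_k=top_k, bottom_k=bottom_k)


def write_variant_table(report: TruncationReport, path) -> None:
    out = report.table.copy()
    for col in ("total", "normalized"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
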