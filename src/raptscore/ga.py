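"""NSGA-III truncation search over an {A,C,G,T,X} genome.

Each individual is a fixed-length string over the DNA alphabet extended with
the truncation character X; its phenotype is the genome with every X removed.
Two objectives are optimized jointly: the pseudo-log-likelihood score of the
phenotype (maximized; raw or per-token, configurable) and the phenotype
length (minimized).  Selection is the elitist NSGA-III scheme: parents and
offspring are pooled, non-dominated sorting ranks the pool, and the partial
last front is filled by reference-point niching on Das-Dennis directions.
Phenotypes shorter than the minimum scorable length are infeasible and are
never preferred over feasible members (constrained domination — the
"worst-case objectives" treatment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from raptscore.mlm import MaskedLanguageModel
from raptscore.scoring import ScoreSettings, raptscore
from raptscore.selex_io import LibraryDesign

logger = logging.getLogger(__name__)

GENOME_ALPHABET = "ACGTX"


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1        # per-individual probability of entering mutation
    reference_point_divisions: Optional[int] = None  # default: population_size - 1
    min_length: int = 7               # shortest feasible (scorable) phenotype
    objective_mode: str = "raw"       # "raw" total or "per_token" normalized score
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.objective_mode not in ("raw", "per_token"):
            raise ValueError("objective_mode must be 'raw' or 'per_token'")


@dataclass
class Individual:
    genome: str
    phenotype: str
    score: Optional[float]       # objective 1 (maximize); None if infeasible
    per_token: Optional[float]
    feasible: bool

    @property
    def length(self) -> int:
        return len(self.phenotype)

    @property
    def objectives(self) -> Optional[Tuple[float, int]]:
        return None if not self.feasible else (self.score, self.length)


@dataclass
class GAResult:
    population: List[Individual]
    front: List[Individual]              # first non-dominated front, final generation
    history: pd.DataFrame                # per-generation summary
    front_history: List[List[Tuple[float, float]]]  # first-front objectives per generation
    evaluations: int                     # scoring-model calls
    cache_hits: int


def phenotype(genome: str) -> str:
    """Remove every truncation character X; order of bases preserved."""
    bad = set(genome) - set(GENOME_ALPHABET)
    if bad:
        raise ValueError(f"genome contains invalid symbols {sorted(bad)}")
    return genome.replace("X", "")


def dominates(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    """a dominates b under (maximize score, minimize length)."""
    return (a[0] >= b[0] and a[1] <= b[1]) and (a[0] > b[0] or a[1] < b[1])


def non_dominated_sort(points: Sequence[Tuple[float, float]]) -> List[List[int]]:
    """Fast non-dominated sort; front 0 holds the points dominated by none."""
    n = len(points)
    for p in points:
        if not np.isfinite(p).all():
            raise ValueError("objectives must be finite")
    dominated_by: List[List[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(points[i], points[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dominates(points[j], points[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts: List[List[int]] = []
    current = [i for i in range(n) if dom_count[i] == 0]
    while current:
        fronts.append(current)
        nxt: List[int] = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def reference_points(n_objectives: int = 2, divisions: int = 99) -> np.ndarray:
    """Das-Dennis simplex lattice: C(divisions + M - 1, M - 1) weight vectors.

    For two objectives, ``divisions`` p gives p + 1 evenly spaced points on
    the unit simplex.
    """
    if divisions < 1:
        raise ValueError("divisions must be >= 1")

    def recurse(left: int, dims: int):
        if dims == 1:
            yield (left,)
            return
        for i in range(left + 1):
            for rest in recurse(left - i, dims - 1):
                yield (i,) + rest

    pts = np.array(list(recurse(divisions, n_objectives)), dtype=float) / divisions
    return pts


# ---------------------------------------------------------------------------
# internal machinery

class _Evaluator:
    """Phenotype-keyed score cache; identical phenotypes are never re-scored."""

    def __init__(self, model, settings, design, min_length):
        self.model = model
        self.settings = settings
        self.design = design
        self.min_length = min_length
        self.cache: Dict[str, Tuple[float, float]] = {}
        self.evaluations = 0
        self.cache_hits = 0

    def make(self, genome: str) -> Individual:
        ph = phenotype(genome)
        if len(ph) < self.min_length:
            return Individual(genome=genome, phenotype=ph, score=None,
                              per_token=None, feasible=False)
        if ph in self.cache:
            self.cache_hits += 1
            total, per_tok = self.cache[ph]
        else:
            res = raptscore(ph, self.model, self.settings, design=self.design)
            total, per_tok = res.total, res.total / res.n_scored
            self.cache[ph] = (total, per_tok)
            self.evaluations += 1
        return Individual(genome=genome, phenotype=ph, score=total,
                          per_token=per_tok, feasible=True)


def _objective(ind: Individual, mode: str) -> Tuple[float, float]:
    val = ind.score if mode == "raw" else ind.per_token
    return (val, float(ind.length))


def _rank(pop: List[Individual], mode: str) -> List[List[int]]:
    """Constrained non-dominated sort: all infeasible members form a trailing front."""
    feas = [i for i, ind in enumerate(pop) if ind.feasible]
    infeas = [i for i, ind in enumerate(pop) if not ind.feasible]
    fronts: List[List[int]] = []
    if feas:
        pts = [_objective(pop[i], mode) for i in feas]
        fronts = [[feas[i] for i in fr] for fr in non_dominated_sort(pts)]
    if infeas:
        fronts.append(infeas)
    return fronts


def _niche_select(pop: List[Individual], fronts: List[List[int]], n_select: int,
                  refs: np.ndarray, mode: str, rng: np.random.Generator) -> List[int]:
    """NSGA-III environmental selection of ``n_select`` indices from the pool."""
    selected: List[int] = []
    fl = 0
    while fl < len(fronts) and len(selected) + len(fronts[fl]) <= n_select:
        selected.extend(fronts[fl])
        fl += 1
    if len(selected) == n_select or fl >= len(fronts):
        return selected[:n_select]
    last = list(fronts[fl])

    considered = selected + last
    feas_idx = [i for i in considered if pop[i].feasible]
    if not feas_idx:  # degenerate: fill arbitrarily but deterministically
        order = rng.permutation(len(last))
        return selected + [last[i] for i in order[:n_select - len(selected)]]

    # minimization objectives, min-max normalized over the considered pool
    obj = np.array([[-_objective(pop[i], mode)[0], _objective(pop[i], mode)[1]]
                    for i in feas_idx])
    lo = obj.min(axis=0)
    span = obj.max(axis=0) - lo
    span[span <= 0] = 1.0
    norm = (obj - lo) / span

    ref_norm = refs / np.linalg.norm(refs, axis=1, keepdims=True).clip(min=1e-12)
    proj = norm @ ref_norm.T                       # (n_feas, n_refs)
    perp = np.linalg.norm(norm[:, None, :] - proj[:, :, None] * ref_norm[None, :, :],
                          axis=2)
    assoc = perp.argmin(axis=1)
    dist = perp[np.arange(len(feas_idx)), assoc]
    assoc_of = dict(zip(feas_idx, assoc))
    dist_of = dict(zip(feas_idx, dist))

    niche = np.zeros(len(refs), dtype=int)
    for i in selected:
        if i in assoc_of:
            niche[assoc_of[i]] += 1

    remaining = [i for i in last if pop[i].feasible]
    infeasible_rest = [i for i in last if not pop[i].feasible]
    active = set(range(len(refs)))
    while len(selected) < n_select and remaining:
        counts = {r: niche[r] for r in active}
        if not counts:
            break
        min_count = min(counts.values())
        candidates_refs = sorted(r for r, c in counts.items() if c == min_count)
        r = candidates_refs[int(rng.integers(len(candidates_refs)))]
        members = [i for i in remaining if assoc_of[i] == r]
        if not members:
            active.discard(r)
            continue
        if niche[r] == 0:
            pick = min(members, key=lambda i: (dist_of[i], pop[i].phenotype))
        else:
            pick = members[int(rng.integers(len(members)))]
        selected.append(pick)
        remaining.remove(pick)
        niche[r] += 1
    for i in infeasible_rest:
        if len(selected) >= n_select:
            break
        selected.append(i)
    return selected[:n_select]


def _tournament(pop: List[Individual], rank_of: Dict[int, int],
                rng: np.random.Generator) -> int:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    if rank_of[int(i)] < rank_of[int(j)]:
        return int(i)
    if rank_of[int(j)] < rank_of[int(i)]:
        return int(j)
    return int(i if rng.random() < 0.5 else j)


def _crossover(g1: str, g2: str, rng: np.random.Generator) -> Tuple[str, str]:
    cut = int(rng.integers(1, len(g1)))
    return g1[:cut] + g2[cut:], g2[:cut] + g1[cut:]


def _mutate(genome: str, rate: float, rng: np.random.Generator) -> str:
    if rng.random() >= rate:
        return genome
    p_gene = 1.0 / len(genome)
    chars = list(genome)
    for i in range(len(chars)):
        if rng.random() < p_gene:
            chars[i] = GENOME_ALPHABET[int(rng.integers(5))]
    return "".join(chars)


def run_nsga3(initial: Sequence[str], model: MaskedLanguageModel,
              settings: ScoreSettings, cfg: GAConfig,
              design: Optional[LibraryDesign] = None) -> GAResult:
    """Run the truncation GA; seeded and fully reproducible.

    ``initial`` is a list of equal-length sequences (no X) used as the
    starting population; it is resampled or truncated to
    ``cfg.population_size``.  The per-generation history records the mean and
    standard deviation of the per-token score and of the phenotype length
    over feasible members, mirroring the usual convergence diagnostics.
    """
    if not initial:
        raise ValueError("empty initial population")
    lengths = {len(s) for s in initial}
    if len(lengths) != 1:
        raise ValueError(f"initial sequences must have uniform length, got {sorted(lengths)}")
    rng = np.random.default_rng(cfg.seed)
    genomes = [s.upper().replace("U", "T") for s in initial]
    if len(genomes) > cfg.population_size:
        genomes = genomes[:cfg.population_size]
    while len(genomes) < cfg.population_size:
        genomes.append(genomes[int(rng.integers(len(genomes)))])

    divisions = cfg.reference_point_divisions or (cfg.population_size - 1)
    refs = reference_points(2, divisions)

    ev = _Evaluator(model, settings, design, cfg.min_length)
    pop = [ev.make(g) for g in genomes]
    if not any(ind.feasible for ind in pop):
        raise ValueError("all initial individuals infeasible; check sequence lengths")

    hist_rows = []
    front_history: List[List[Tuple[float, float]]] = []

    def log_generation(gen: int):
        fr0 = _rank(pop, cfg.objective_mode)[0]
        front_history.append([_objective(pop[i], cfg.objective_mode)
                              for i in fr0 if pop[i].feasible])
        feas = [ind for ind in pop if ind.feasible]
        pt = np.array([ind.per_token for ind in feas])
        ln = np.array([ind.length for ind in feas], dtype=float)
        hist_rows.append(dict(generation=gen,
                              mean_per_token_score=pt.mean(), std_per_token_score=pt.std(),
                              mean_length=ln.mean(), std_length=ln.std(),
                              n_feasible=len(feas)))

    log_generation(0)
    for gen in range(1, cfg.generations + 1):
        fronts = _rank(pop, cfg.objective_mode)
        rank_of = {i: fi for fi, fr in enumerate(fronts) for i in fr}
        offspring: List[Individual] = []
        while len(offspring) < cfg.population_size:
            p1 = pop[_tournament(pop, rank_of, rng)].genome
            p2 = pop[_tournament(pop, rank_of, rng)].genome
            if rng.random() < cfg.crossover_rate:
                c1, c2 = _crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(offspring) >= cfg.population_size:
                    break
                offspring.append(ev.make(_mutate(child, cfg.mutation_rate, rng)))
        pool = pop + offspring
        pool_fronts = _rank(pool, cfg.objective_mode)
        keep = _niche_select(pool, pool_fronts, cfg.population_size, refs,
                             cfg.objective_mode, rng)
        pop = [pool[i] for i in keep]
        if not any(ind.feasible for ind in pop):
            raise RuntimeError(f"generation {gen}: population entirely infeasible")
        log_generation(gen)

    final_fronts = _rank(pop, cfg.objective_mode)
    front = [pop[i] for i in final_fronts[0] if pop[i].feasible]
    history = pd.DataFrame(hist_rows)
    return GAResult(population=pop, front=front, history=history,
                    front_history=front_history,
                    evaluations=ev.evaluations, cache_hits=ev.cache_hits)


def write_history(result: GAResult, path) -> None:
    out = result.history.copy()
    for col in out.columns:
        if col not in ("generation", "n_feasible"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def write_front(result: GAResult, fasta_path, tsv_path) -> None:
    rows = sorted(result.front, key=lambda ind: (ind.length, -ind.score))
    with open(fasta_path, "w") as fh:
        for i, ind in enumerate(rows):
            fh.write(f">front_{i:03d} length={ind.length} score={ind.score:.4f}\n")
            fh.write(ind.phenotype + "\n")
    pd.DataFrame([dict(id=f"front_{i:03d}", genome=ind.genome, phenotype=ind.phenotype,
                       length=ind.length, score=ind.score, per_token=ind.per_token)
                  for i, ind in enumerate(rows)]).to_csv(tsv_path, sep="\t", index=False)
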