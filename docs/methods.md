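# Methods

## The score

An aptamer sequence `S = (s_1 … s_L)` is tokenized into overlapping k-mers
(k = 3 throughout; larger k shrinks the scorable interior of short
sequences), giving tokens `W = (w_1 … w_n)` with `n = L − k + 1`.  A
BERT-style masked language model (MLM), continually pretrained on the reads
of one HT-SELEX round, assigns conditional probabilities to masked tokens.

The standard pseudo-log-likelihood masks one token at a time, but with
overlapping k-mers a single masked token is trivially recoverable from its
neighbours.  The score therefore masks **three consecutive tokens as one
unit**, `M_t = (w_t, w_{t+1}, w_{t+2})`, and sums the log-probability of the
central token over interior triplet starts:

    score(W) = Σ_{t=2}^{n−3}  log P_MLM( w_{t+1} | W \ M_t )

Masking an interior triplet hides exactly one nucleotide (the one covered by
all three tokens); masking at the ends would hide a whole terminal 3-mer,
which is why `t` starts and stops one token in from the ends.  The number of
scored positions is `n − 4 = L − k − 3` (`L − 6` for k = 3), so the shortest
scorable sequence is `k + 4 = 7` nt.  Logs are natural (scores in nats);
every downstream use (correlation, ranking) is base-invariant.

Two per-call variants:

* **token-sum mode** — `central` (above) or `all_three`, which adds the
  log-probabilities of `w_t` and `w_{t+2}` as well;
* **special-token handling** — `include` uses the raw distribution over all
  69 tokens; `exclude_renormalize` removes the probability mass on the five
  special tokens (PAD, UNK, CLS, SEP, MASK) and renormalizes over the 64
  k-mer tokens before taking logs.

Equation indices range over k-mer tokens only: CLS/SEP are model-input
framing, never masked and never indexed by `t`.  This resolves the
off-by-one ambiguity between the model's input positions and the score's
token positions.

The length-normalized score divides the total by the number of scored
positions (configurable to nucleotide length); cross-length comparisons use
the normalized value, same-length rankings the raw total.

### Per-position profile

In central mode each triplet contributes at the central nucleotide of its
central token, i.e. nucleotides 4…L−3 (1-based) for k = 3 — three excluded
nucleotides per terminus by pure k-mer arithmetic.  Published profile plots
describe four excluded terminal nucleotides; the profile therefore carries a
display option (`terminal_exclusion=4`) that additionally drops the
outermost scored position on each side.  The discrepancy is a presentation
convention, not a scoring difference, and is left visible rather than
silently resolved.

## The model

The encoder is the standard BERT architecture restricted to what MLM
pretraining and scoring need: token + learned position embeddings,
post-layer-norm transformer blocks with GELU feed-forward, and an MLM head
(dense → GELU → layer norm → untied output projection).  There is no pooler
and no token-type embedding.  Two presets:

| preset | layers | hidden | heads | FFN | max pos | parameters |
|---|---|---|---|---|---|---|
| reference | 12 | 768 | 12 | 3072 | 512 | 86.1 M |
| tiny | 2 | 64 | 4 | 256 | 128 | 0.12 M |

The reference preset mirrors the full-scale published configuration (its
parameter count rounds to 86 million, verified closed-form against direct
enumeration); the tiny preset is the desk-scale model used by the tests and
the acceptance script.  The implementation is pure NumPy with explicit
forward/backward passes (verified against central finite differences to
~1e-6 relative error on the well-conditioned parameters), a fast
tanh-approximation GELU, and AdamW with linear warmup (10%) then linear
decay.

### Pretraining

Masking is nucleotide-contiguous: each nucleotide position is selected
independently at rate 0.15, and the k tokens covering a selected nucleotide
are masked together so the nucleotide is fully hidden; per selected
position the standard 80% MASK / 10% random k-mer / 10% keep replacement
applies.  Duplicate-policy weights are realized by sampling sequences into
batches with probability proportional to weight.

Tiny-preset training defaults: 2000 steps, batch 64, peak learning rate
3e-3, weight decay 0.01, dropout 0.1.  The learning rate is deliberately
higher than full-scale BERT practice: at ~0.12 M parameters and a 69-token
vocabulary the loss surface tolerates it, and at 1e-3 the tiny model is
visibly undertrained within 2000 steps (the held-out motif separation below
degrades substantially).  All of these are exposed in `TrainingConfig`.

## Settings and calibration

Six axes define a scoring configuration.  Four are training-side and
identify a checkpoint — the SELEX round used for pretraining, the weight
initialization (from scratch or from an existing checkpoint), the duplicate
policy (`as_is`, `log_weight` = ceil(log10 n)+1, `dedup`), and adapter
inclusion.  Two are scoring-side and free per call (token-sum mode,
special handling).  Grid calibration trains one model per training-side
cell, scores a fixed representative panel under all four scoring-side
variants, computes the Pearson correlation with measured relative activity
per setting, and returns the setting with the highest r (ties break to the
first setting in enumeration order; Spearman is reported as a secondary
column).  The representative panel — per round, the top 3 by frequency plus
top 3 by enrichment, backfilled from frequency when enrichment defines
fewer than 3 — is fixed once and shared by every setting, matching how a
single measured activity panel is reused in practice.

The duplicate-weight logarithm is base 10 (weight grows by one per decade
of duplication count); the base is configurable because only the rounding
rule, not the base, is pinned by the published description.

## Occurrence baselines

frequency(s, r) = count_r(s) / total_r; enrichment(s, r) =
frequency_r(s) / frequency_{r−1}(s), defined only when the sequence is
present in both consecutive rounds — the earliest round never has
enrichment, and missing values are marked, never imputed.  Ranking ties
break lexicographically for run-to-run determinism.

## Truncation

All 1…d_max nucleotide deletions of a parent are enumerated as 0-based
position-sets into the variable region (adapters are never deletable);
multi-position deletion uses set semantics, so deleting P then Q on
re-indexed intermediates equals deleting P ∪ Q at once.  Identical
resulting strings are deduplicated for ranking (position-set provenance
retained), groups are formed per resulting length, and the top-k / bottom-k
per length (default 3, range 3–5) are reported by raw score.
`combine_sites` builds all size-2/3 simultaneous deletions from
single-deletion sites that experimentally retained activity.

## NSGA-III truncation GA

Genomes are fixed-length strings over {A, C, G, T, X}; the phenotype
deletes every X.  Objectives: maximize the score of the phenotype (raw by
default; per-token optional, since raw sums inherently favour shorter
sequences) and minimize phenotype length.  Operating parameters follow the
published run: population 100, 50 generations, crossover 0.8, mutation 0.1.
Design choices where the published description is silent:

* one-point crossover at a uniform cut (preserves contiguous motif blocks);
* mutation enters an individual with probability 0.1, then each gene
  mutates independently with probability 1/genome-length to a uniform draw
  from the five symbols — X→base back-mutations are what alignment-level
  "insertions" correspond to, since the fixed-length genome forbids true
  length growth;
* binary tournament on front rank for parent selection;
* environmental selection pools parents and offspring, ranks by
  non-dominated sorting, and fills the partial last front by Das–Dennis
  reference-point niching (population−1 divisions, i.e. 100 points for the
  default population) with per-generation min–max normalization of the
  pooled objectives — a simplified ideal/nadir estimate that is robust with
  two objectives;
* phenotypes shorter than 7 nt (unscorable) are infeasible; they are never
  preferred over feasible members (constrained domination realizes the
  worst-case-objectives treatment without distorting objective
  normalization);
* scores are cached by phenotype string, so identical phenotypes are never
  re-scored and the evaluation count is the number of distinct phenotypes
  seen.

## Synthetic SELEX

The simulator reproduces the one property the scoring pipeline exploits:
motif-bearing sequences amplify round over round.  Ground-truth binding
("fitness") of a sequence is its best sliding-window identity fraction
against a fixed planted 13-nt motif (1.0 iff the motif appears verbatim) —
a deliberately transparent choice with a brute-force oracle, not a PWM.
Round 0 draws reads uniformly from a random library (default 10,000
molecules, 30-nt variable region); each subsequent round resamples reads
with Boltzmann weights exp(β·fitness) (default β = 5), applies independent
per-base substitution at rate 0.01 (a modest aggregate amplification/
sequencing error rate; substitutions only, so the variable-region length
stays uniform as real HT-SELEX count tables assume), and emits 5,000 reads.
An activity panel is simulated as 100·fitness plus Gaussian noise (default
SD 5) rescaled so the maximum is 100, mirroring control-normalized
measurements.

Under these defaults the mean fitness rises by ≈0.23 over five rounds and
the late rounds are dominated by descendants of the best initial molecules —
near-motif carriers at 11–12/13 identity, since an exact 13-mer is never
present in a random initial library of this size.  That makes the recovery
task honest: the trained model must generalize from enriched *near*-motif
context to held-out exact-motif sequences.

What the simulator does not model: PCR bias, sequencing error profiles,
indels, secondary-structure-dependent amplification inefficiency.  Passing
tests therefore demonstrate that the pipeline recovers a planted sequence
signal under idealized selection, not that it reproduces the quantitative
behaviour of any real SELEX experiment.

### The truncation-GA fixture

The GA study fixture differs from the enrichment fixture in two deliberate
ways.  First, the scoring model is trained on motif-*planted* sequences
(the motif verbatim at random offsets) rather than on a selection round:
a finite selection run started from a random library enriches *near*-motif
clones (best window 11–12/13) and a model trained on it has no reason to
prefer the exact canonical motif, so a GA guided by it will happily trade a
motif base for length.  Anchoring the model to the exact motif makes
"motif preserved after truncation" a well-posed measurement.  Second, the
100 initial parents carry the motif at a common offset, emulating an
aligned clonal family — descendants of one enriched ancestor share their
motif register.  With per-parent random offsets, one-point crossover of
misaligned parents is almost always motif-destructive and the GA stalls;
with an aligned register the GA trims flanks aggressively (mean phenotype
length ≈ 17 nt after 50 generations) while >90% of the population retains
the exact 13-nt motif.

## Problem sizes and numerical choices

The test suite and the acceptance script use the tiny preset throughout;
the synthetic run is 5 selection rounds at depth 5,000, pretraining is
2,000 steps (about two to four minutes on one CPU core), calibration grids
are kept to a handful of training cells, and the GA runs its published
100×50 configuration.  Scores are accumulated in float64 on top of a
float32 forward pass; profile/total conservation holds to 1e-6 and batched
vs naive-loop scoring to 1e-4.  Checkpoints round-trip exactly (config and
vocabulary as text, weights as an `.npz` blob).  Degenerate inputs are
rejected rather than patched: zero-variance correlation inputs, sequences
shorter than 7 nt, empty corpora, all-infeasible GA populations.

## Known limitations

* Sequence-only scoring: no secondary-structure awareness; very short
  phenotypes can score well while being structurally implausible.
* The calibration statistic is Pearson's r on a small panel; it is noisy at
  panel sizes typical of measured-activity experiments.
* The tiny preset is a study vehicle: conclusions about full-scale models
  (capacity, pretraining transfer from genomic corpora) are out of reach at
  desk scale.
* `from_checkpoint` initialization is supported and tested for round-trip
  fidelity, but no published pretrained weights ship with the package.
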