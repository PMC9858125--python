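# Methods

## Model

A population of N virtual embryos evolves toward a monotonic axis of
positional information.  Each embryo is a length-L array of integer
*structural genes* (one per cell) plus one *competency gene* `c` giving the
number of adjacent cell swaps it may execute during development.  Default
geometry is L = 50 cells, N = 100 embryos (200 in mixed populations).
Founding genomes are independent uniform random permutations of `1..L`, so
every founding axis has distinct positional values and expected fitness 0.5.

### Fitness

Fitness measures how close the cell array is to ascending order.  The
default counts over all C(L, 2) position pairs:

    f(g) = 1 − inv(g) / C(L, 2),

with `inv` the strict inversion count (equivalently, a rescaled Kendall-tau
distance to the sorted order; the suite cross-checks this against scipy's
tau).  An `adjacent` variant, f = (ordered adjacent pairs) / (L − 1), is
kept as a configuration switch: both anchor ascending → 1.0, descending →
0.0, random → 0.5, but the all-pairs count gives selection a much smoother
gradient and is the variant under which the package's reference dynamics
(breakthrough times, dominance thresholds) were established — under
adjacent counting a hardwired population stalls below fitness 0.9 for
hundreds of generations.

Tied pairs count as ordered in both variants.  Duplicated gene values can
arise from mutation and cross-over; no adjacent swap can improve a tied
pair, so counting ties against the embryo would make fitness 1.0
permanently unreachable for such genomes.

### Development: restricted bubble sort

Competent embryos run classic left-to-right bubble passes over their cell
array, swapping any strictly descending adjacent pair, until either a full
pass makes no swap or `c` swaps have been executed.  Comparisons are free;
only executed swaps consume budget.  Because every executed swap removes
exactly one inversion,

    inv(phenotype) = max(0, inv(genes) − c),

which pins the exact relation `f_phen = min(1, f_geno + c / C(L, 2))` under
all-pairs counting.  The test suite checks this lemma exhaustively for all
permutations of length ≤ 6 and budgets ≤ 15 against brute-force pair
counting, and by property test on random inputs with duplicates.  Any
adjacent-swap schedule that only fixes out-of-order pairs yields the same
inversion arithmetic; the classic pass order is the simplest such schedule.
Development operates on a working copy — structural genes are never
modified (no Lamarckian inheritance), and children are always born
undeveloped.

### Genetic algorithm

Per generation, in order:

1. genotypic fitness of every embryo is recorded ("just born");
2. every embryo develops (hardwired embryos are identities);
3. phenotypic — and, under a competency cost, penalised — fitness is
   recorded; this is where the per-generation record is taken;
4. the top `floor(0.10 · N)` by selection fitness survive, ties broken by
   population index (lowest first);
5. the population refills by single-point cross-over of uniformly random
   distinct survivor pairs: genomes are cut at a uniform split in
   `[1, L−1]` and right-hand segments exchanged; each child inherits the
   competency gene of its left-segment donor; one child of the final pair
   is discarded if the deficit is odd;
6. each individual (survivors included — the whole repopulated population)
   receives, with probability 0.6, exactly one point mutation: a uniformly
   chosen gene is resampled uniformly from its value range.  The competency
   gene is mutable only in `evolvable` mode, where it occupies an (L+1)-th
   slot and resamples over `[1, 500]`.

All randomness flows from one numpy `Generator` per run in a fixed draw
order (initialisation; then per generation: pairing, splits, mutation mask,
slots, values), so a run is reproducible bit-for-bit from its seed.  Repeat
`r` of a run uses `seed + r`; experiment suites space condition seeds by a
fixed stride (100003).

### Competency modes

* `hardwired` — c = 0 everywhere; genotype and phenotype coincide.
* `fixed` — every embryo shares a constant budget (the standard comparison
  levels are 20, 100 and 400 swaps).
* `evolvable` — c is heritable and mutable; initialised uniformly in
  `[1, 15]` so competency must be discovered, mutable over `[1, 500]`.
* `mixed` — a hardwired majority seeded with a competent minority at a
  fixed level.  The competency gene is not mutable (types cannot
  interconvert), and parents pair **within type**: the partner of each
  first parent is drawn uniformly among same-type survivors (a lone
  survivor of its type reproduces clonally).  Free interbreeding with
  left-donor inheritance would produce competent/hardwired sibling pairs
  differing only in competency, which ratchets any competent minority to
  fixation regardless of level; within-type pairing preserves type
  identity, yields children in proportion to survivor shares, and produces
  the sharp dominance thresholds the model is meant to study.

### Competency cost (Baldwin-effect runs)

With penalty factor λ > 0, selection ranks by `max(0, f_phen − λ·c)` while
the recorded phenotypic fitness stays unpenalised.  The subtractive form is
used because it lets moderate λ values re-expose the genome to selection
without annihilating competent lineages outright.  At λ = 1e-4 the model
shows genetic assimilation: phenotypic fitness saturates early and stays
saturated, the best genotype keeps improving for hundreds of generations
afterwards, and the best competency gene decays — early plastic gains are
absorbed into the genome.

## Recorded quantities and conventions

Records are taken at stage 3, before selection.  "Best" metrics describe
the single individual that tops the selection ranking (first index on
ties); `best_genotypic_fitness` is that same individual's fitness at birth,
i.e. what it would have scored without its competency.  Population
min/max/mean of the competency gene, competent prevalence, mean swaps used,
and the within-generation Pearson correlation between individuals'
genotypic and phenotypic fitness are recorded alongside (a generation where
either variable has no variance contributes correlation 0, which is what
makes the windowed correlation collapse once phenotypes saturate).

Breakthrough (threshold-crossing) trajectories treat the founding
population as generation 1 *recorded at birth*: its best fitness is
genotypic, because its developmental phase has not yet run; every later
generation is recorded post-development.  Crossing times are read off the
repeat-averaged trajectory (mean over repeats, then first crossing), not
averaged per-repeat crossings.

Dominance in mixed populations follows the rule: the first generation at
which mean competent prevalence exceeds 0.5 and never decreases afterwards.
Prevalence is a composition, recorded for the population as it stands each
generation starting with the founding mixture.

The per-gene change frequencies compare the best individual's genome
(50 structural genes + competency gene) between consecutive generations and
accumulate a count per gene.  The stable competency value of an evolvable
run is the mean best-individual competency gene over the final 10% of
generations.

Confidence bands are normal-approximation mean ± 1.96·SD/√n over repeats.
Group comparisons use the pooled-variance two-sample Student's t-test; a
zero-pooled-variance input is reported explicitly as degenerate.  The
hyperparameter scan covers 12 mutation probabilities × 11 selection
fractions evenly spaced inclusive over [0.2, 0.8] (132 cells) and reports
Pearson correlations of the per-cell stable competency value against each
axis.

## Problem sizes

The packaged experiment scales are chosen to keep a full reproduction on
one core in minutes while leaving Monte-Carlo noise well below the effect
sizes: breakthrough suite 25 repeats × 350 generations; mixed suite
20 repeats × 30 generations; evolvable and Baldwin suites 10 repeats ×
1000 generations; scan 132 cells × 250 generations × 1 repeat.  The inner
swap loop is JIT-compiled with numba; inversion counting is vectorised over
the population.

## What the simulator does and does not emulate

The generator produces exactly the study conditions — permutation founders,
the stated population sizes, mutation and selection rates — and nothing
more.  There is no gene regulation, no 2-D/3-D morphology, no cell types,
no organism-level learning, and no noise in development (the bubble sort is
deterministic given the genome and budget).  Passing tests therefore
demonstrate properties of this idealised positional-information model, not
of any real developmental system.

## Known limitations

* The swap–inversion lemma rigidly couples the evolvable-competency
  equilibrium: once phenotypes saturate (inv ≤ c), the best genotypic
  fitness is pinned near `1 − c/C(L, 2)` (~0.62–0.64 for c ≈ 470–490).  A
  regime with simultaneously low genotypic fitness (~0.52), saturated
  phenotypes, and c ≈ 470 is arithmetically unreachable under this
  development operator.  Related consequences in the saturated regime:
  competency-gene resamples over [1, 500] are mostly rejected while
  structural mutations drift neutrally, so the best individual's
  competency gene changes *less* often than the structural average, and
  the stable competency value correlates *positively* with mutation
  probability (heavier mutation load → more inversions to repair).
* Uniform resampling of the competency gene makes high competency reachable
  in a handful of generations; an incremental mutation kernel would slow
  that discovery and change the early transient.
* With N = 100 and 10 survivors, drift is strong; threshold-crossing times
  at the 1.0 boundary are effectively the maximum over repeats and carry
  the largest sampling variance of all reported quantities.
* The within-type pairing rule in mixed mode is one defensible choice among
  several (free interbreeding, assortative redraw); it changes how easily
  marginal competent minorities fix, and is therefore documented rather
  than hidden behind a default.
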