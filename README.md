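# embryogeny

Evolutionary simulation of minimal 1-D virtual embryos with a *cellular
competency* layer between genotype and phenotype.

## The problem

How does developmental problem-solving by cells change evolutionary
dynamics?  In most evolutionary simulations the genome directly encodes the
phenotype that selection sees.  Real development is regulative: cells sense
neighbours and correct errors before selection ever happens.  This package
implements a minimal model of that distinction and the experiments it
enables — evolutionary acceleration, population takeover by competent
embryos, spontaneous evolution of competency, genotype shielding (the
collapse of the genotype–phenotype fitness correlation), and genetic
assimilation of plastic gains when competency carries a cost (the Baldwin
effect).

## The model

An embryo is a 1-D array of `L = 50` cells; cell *i* carries an integer
structural gene `g_i ∈ [1, 50]` encoding its positional value.  Fitness is
the monotonicity of the axis: with `inv(g)` the number of inverted pairs
(`i < j` with `g_i > g_j`),

    f(g) = 1 − inv(g) / C(L, 2),

so an ascending axis scores 1.0, a descending one 0.0, and a random
permutation 0.5 in expectation.  (A variant counting only adjacent pairs is
available via `fitness_variant="adjacent"`.)

Development is a *restricted bubble sort*: a competent embryo with
competency gene `c` may execute up to `c` adjacent cell swaps (left-to-right
passes, swapping strict descents) before fitness is evaluated.  Each
executed swap removes exactly one inversion, so the developed phenotype
satisfies `inv(phenotype) = max(0, inv(g) − c)` — the swap–inversion lemma
that the test suite verifies exhaustively.  A hardwired embryo (`c = 0`)
develops into itself.  Phenotypes are never inherited.

The genetic algorithm, per generation: record genotypic fitness (fitness of
the genes at birth), develop, record phenotypic fitness, keep the fittest
10% by phenotypic fitness (minus `λ·c` when a competency cost λ is set),
refill the population by single-point cross-over of random survivor pairs,
then give each individual one uniform point mutation with probability 0.6.

## Worked example

```python
from embryogeny import GAConfig, run_evolution

hardwired = run_evolution(GAConfig(generations=100, seed=1))
competent = run_evolution(
    GAConfig(competency_mode="fixed", competency_level=400,
             generations=100, seed=1)
)
for label, run in [("hardwired", hardwired), ("competent-400", competent)]:
    r = run.records[99]
    print(f"{label:14s} best phenotypic {r.best_phenotypic_fitness:.3f} "
          f"best genotypic {r.best_genotypic_fitness:.3f}")
```

prints

```
hardwired      best phenotypic 0.996 best genotypic 0.996
competent-400  best phenotypic 1.000 best genotypic 0.690
```

After 100 generations the hardwired population is still assembling a good
genome (its two fitness values are identical by construction), while the
competent population reached a perfect phenotype long ago — carried by a
mediocre genome whose defects development silently repairs.  That gap is
genotype shielding: selection cannot see the structural genes behind the
competency.

The same experiments are available from the shell:

```bash
embryogeny fixed-suite --repeats 25 --out results/fixed
embryogeny mixed-suite --seed 7 --out results/mixed
embryogeny evolvable --generations 1000 --repeats 10 --out results/evolvable
embryogeny baldwin --penalty 1e-4 --out results/baldwin
embryogeny scan --out results/scan
```

Each command writes long-format per-generation CSV records plus a JSON
summary; re-running with the same seed reproduces the CSV byte-for-byte.

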