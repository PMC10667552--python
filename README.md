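# clonalmate

Mate allocation for clonally propagated crops such as sugarcane: simulate
the progeny of every candidate cross, predict each progeny's breeding
value and clonal value from markers alone, and pick the best constrained
set of crosses by integer linear programming.

## The problem

In a clonal crop the variety that reaches farmers is a single genotype
propagated vegetatively, so it expresses its *total* genetic value —
additive effects plus dominance, epistasis, and the benefit of being
highly heterozygous — not just the additive part that is passed on to
offspring. Conventional crossing plans rank parents by genomic estimated
breeding value (GEBV) and mate the best, which optimises additive gain
but ignores everything non-additive. This package implements and
compares two mate-allocation strategies on simulated ("phantom")
progeny:

* **GEBV strategy** — score each candidate cross by the predicted
  breeding values of its progeny (GBLUP, additive only);
* **GPCP strategy** (genomic prediction of clonal performance) — score
  each cross by the predicted clonal values of its progeny, using an
  extended GBLUP model with dominance, additive×additive epistasis, and
  a genome-wide heterozygosity covariate.

## Models

For `m` clones with one adjusted phenotypic record each:

GBLUP: `y = Xβ + u + ε`, with `u ~ N(0, G_A σ²_A)`.

Extended GBLUP: `y = Xβ + u + d + t + b·Het + ε`, with
`d ~ N(0, G_D σ²_D)` and `t ~ N(0, G_AA σ²_AA)`, and `Het_k` the
observed/expected genome-wide heterozygosity ratio of clone `k`.

`G_A` is the allele-frequency-standardised additive relationship matrix
(GCTA-style elements, unbiased diagonal `1 + F`), `G_D` uses the
dominance coding `x_D ∈ {0, 2p, 4p−2}` that is orthogonal to the
additive coding at Hardy–Weinberg genotype frequencies, and
`G_AA = (G_A ⊙ G_A) / (tr(G_A ⊙ G_A)/m)` is the normalised Hadamard
square. Variance components are estimated by average-information REML;
effects solve the mixed-model equations; unphenotyped progeny get each
component by conditional expectation through their relationship blocks
with the training set. The genomic inbreeding of any individual is
`F = G_A[k,k] − 1`.

Progeny genotypes come from a count-location meiosis simulator: per
chromosome the crossover count is Poisson in the map length (Morgans)
and crossover positions are uniform — no interference, i.e. the Haldane
map function `r = (1 − e^(−2d))/2`.

The cross set is chosen by ILP (HiGHS via `scipy.optimize.milp`):
maximise summed cross merit (mean of each cross's top-decile progeny)
subject to a fixed number of crosses and a per-parent usage cap.

## Worked example

```python
import clonalmate as cm

config = cm.ExperimentConfig(trait="tch", seed=1)   # desk scale
report = cm.run_experiment(config)
for k in ("epv_gebv", "epv_gpcp", "gpcp_improvement",
          "pib_gebv", "pib_gpcp", "overlap"):
    mean, sd = report.aggregate[k]
    print(f"{k:18s} {mean:8.3f} ({sd:.3f})")
```

prints (400 training clones × ~2,000 markers, 12 parents per sex,
20 progeny per cross, 2 iterations):

```
epv_gebv             10.397 (0.123)
epv_gpcp             13.616 (0.141)
gpcp_improvement      0.310 (0.029)
pib_gebv              0.064 (0.009)
pib_gpcp             -0.026 (0.001)
overlap               5.000 (2.828)
```

Read: selecting the 20 crosses on predicted clonal value instead of
predicted breeding value raises the average expected progeny value by
~31 % for this cane-yield-like trait (large epistatic and
heterozygosity effects), and the selected progeny are *less* inbred
than the population average (negative mean F), while only 5 of the 20
selected crosses coincide between the strategies. The same report also
carries `delta_u`/`delta_g` (gain of the selected set over the mean of
all candidate crosses, on the breeding-value and clonal-value scales)
and the true genetic values of the selected families, which are known
in simulation.

A command-line front end mirrors the stages:

```bash
clonalmate run-all --config config.yaml --seed 1 --out runs/demo
```

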