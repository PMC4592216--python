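# hostswitch

Individual-based simulation of parasite host-switching by **ecological
fitting**: how an ecologically specialized lineage colonizes new hosts using
standing phenotypic variation, without first evolving host-specific novelty.

The package is for researchers in host–parasite evolution, symbiont ecology
and emerging-disease dynamics who want a reproducible, scriptable
implementation of the "sloppy fitness space" colonization model: a single
quantitative phenotype per parasite, Gaussian stabilizing selection imposed
by the occupied host, and one random colonization opportunity per
generation.

## Model in brief

Each parasite *i* has a phenotype *p<sub>i</sub>* ∈ ℝ; the occupied host
*r* has an optimum *p<sub>r</sub>* and imposes per-generation survival

$$S(p_i, p_r) = \exp\!\left(-\frac{(p_i - p_r)^2}{2\sigma_r^2}\right),$$

so survival at distance 3σ<sub>r</sub> is exp(−4.5) ≈ 1%. Generations
iterate reproduction (birth rate *b*, hard cap *K*, offspring = midparent +
Normal(0, σ<sub>v</sub>) mutation, selfing allowed), the offer of one random
resource *r′* with optimum uniform in *p<sub>r</sub>* ± δ<sub>r</sub>,
per-individual emigration with probability *d*, and host-imposed mortality.
A switch establishes when ≥ 1 emigrant is alive on *r′* at the end of the
generation; the simulation then follows the founders and drops the
ancestral population. A colonization is *successful* if the founded lineage
does not go extinct before the next establishment (or the 1000-generation
cap).

The key observable is the **Information Space**
IS = (p<sub>max</sub> − p<sub>min</sub>)/σ<sub>r</sub>, the standardized
phenotypic amplitude of the population. The analysis layer computes IS and
related standardized metrics per generation, bins colonization events into
success curves and phase diagrams, and estimates the partial Spearman
correlation between population size and IS controlling for the time since
the last switch. See `docs/methods.md` for the full model account,
conventions and limitations.

## Worked example

One replicate at the standard parameters (N₀ = 1, b = 0.5, K = 500,
d = 0.05, σ<sub>r</sub> = 0.5, σ<sub>v</sub> = 0.2, δ<sub>r</sub> = 5):

```sh
$ hostswitch simulate --seed 7 --out demo/run
run ended at generation 37 (extinct), 3 colonization event(s)
```

The events table (`demo/run/events.tsv`) shows a stepping-stone sequence —
two establishments that persisted until the next switch, then one that led
the lineage to extinction:

```text
generation  standardized_distance  n_founders  pre_switch_size  pre_switch_IS  outcome
19          0.624                  7           462              2.95           success
23          0.357                  1           20               1.78           success
35          0.781                  2           29               1.75           failure
```

Read: at generation 19 the population (462 individuals spanning an IS of
~3 kernel widths) established 7 founders on a resource 0.62 σ<sub>r</sub>
away; the bottlenecked colony (IS collapsed) hopped again at generations 23
and 35; the last colony of 2 founders died out at generation 37, ending the
run.

A batch with pooled statistics:

```sh
$ hostswitch batch --runs 300 --seed 1 --out demo/batch
300 runs, 7425 post-burn-in records, 602 events
```

`demo/batch/summary.json` then contains (excerpt):

```json
{
  "partial_rho_size_IS": 0.8473,
  "overall_success_fraction": 0.774,
  "max_switch_distance": 3.094,
  "survival_at_3_sigma": 0.0111
}
```

i.e. population size and Information Space are strongly rank-correlated
even after controlling for the time since the last switch (ρ ≈ 0.85),
about three quarters of establishments found persistent lineages, and
switches concentrate within ~3 kernel widths. The batch command also writes
binned success surfaces (`surface_IS_x_distance.tsv` etc.) — the phase
diagrams of colonization success over pre-switch IS, distance and
population size.

`hostswitch sweep` repeats a reduced batch over the 36-combination
robustness grid (b, K, d, σ<sub>v</sub>), and `hostswitch accept` runs a
large batch and reports the headline statistics with standard errors.

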