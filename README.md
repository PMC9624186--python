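# hierstruct

Hierarchical Bayesian admixture analysis of diploid codominant genotypes
(microsatellite-style multi-allelic markers), with Evanno delta-K model
selection, recursive per-cluster re-analysis, supporting population-genetic
statistics, and meta-experiments on when delta-K collapses to K = 2.

## What's inside

| module | contents |
| --- | --- |
| `hierstruct.genotype_data` | `GenotypeMatrix` data model; STRUCTURE (two dialects) and GenePop I/O; allele frequencies; subsetting |
| `hierstruct.synthetic_data` | F-model simulator: Dirichlet drift down a deme tree, diploid sampling, parametric Gst ground truth, a 38-deme "study mimic" preset |
| `hierstruct.admixture_mcmc` | Gibbs sampler for the admixture clustering model (independent allele-frequency prior, inferred alpha); evidence estimate mean − var/2; replicate-run label alignment |
| `hierstruct.model_selection` | Evanno table (L', \|L''\|, delta-K) and optimal-K selection |
| `hierstruct.hierarchical_pipeline` | recursive per-cluster re-analysis until no subset divides further; terminal "genetic components"; per-population uniqueness summary |
| `hierstruct.popgen_stats` | pairwise F_ST (Weir–Cockerham theta / Nei Gst), Nm, Nei distances (standard + unbiased), 3-level AMOVA with permutation tests, UPGMA → Newick, PCoA |
| `hierstruct.experiments` | subsample-size experiment (K* vs number of populations) and clade-composition experiment (K* of 4-population samples vs clades spanned) |

The sampler has two engines: a compiled numba whole-chain kernel (default)
and a pure-numpy reference implementation (`run_mcmc(..., engine="numpy")`).
Both sample identical full conditionals; the numpy per-update functions are
the unit-tested reference.

## CLI

```sh
# simulate a 38-population hierarchically structured dataset
hierstruct simulate --seed 1 --out demo.str

# one MCMC run at fixed K
hierstruct run demo.str --k 2 --seed 1 --out-prefix k2

# full recursive analysis
hierstruct hier demo.str --seed 1 --out-prefix hier

# statistics
hierstruct stats demo.str --what fst   --out fst.tsv
hierstruct stats demo.str --what upgma --out tree.nwk
hierstruct stats demo.str --what amova --groups groups.json --out amova.json

# meta-experiments
hierstruct experiment subsample demo.str --levels 4,8,16 --seed 1
hierstruct experiment clades demo.str --annotation clades.json --seed 1
```

MCMC and hierarchy parameters come from a YAML config
(`--config cfg.yaml`):

```yaml
mcmc:
  burn_in: 2000
  reps: 8000
  thin: 10
hierarchy:
  runs_per_k: 5
  k_max: 12
  min_individuals: 10
  q_threshold: 0.6
```

## File formats

* STRUCTURE text: two-rows-per-individual or one-row dialects, missing `-9`,
  integer population column with a `<file>.labels.tsv` sidecar label map.
* GenePop: 2- or 3-digit alleles, `000`/`000000` missing.
* Distance matrices as square TSV; trees as Newick; AMOVA as JSON;
  experiment output as tidy TSV + JSON.
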