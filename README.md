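# padsub

Pathway-activity-based consensus subtyping of lung adenocarcinoma (LUAD)
transcriptomes.

Bulk LUAD expression cohorts are molecularly heterogeneous, and single-gene
classifiers transfer poorly across platforms. `padsub` stratifies tumors by
the *joint activity of 50 landmark molecular pathways* instead: each sample
is scored with a single-sample enrichment statistic (a GSVA-style
kernel-CDF → rank → weighted random-walk score, computed within each
dataset so batches never mix), the cohort is repeatedly re-scored under
k-fold resampling, each perturbed score matrix is embedded (UMAP) and
segmented into subpopulations (walktrap community detection), and the
subpopulation centroids accumulated across iterations are consensus-
clustered into final subtypes. Samples get the subtype they were assigned
the majority of times. The package also covers everything downstream of the
labels: association tables, adjusted Cox survival models, TMB/CNA/signature
burden comparisons, immune-infiltration profiling, nested-GLM immunotherapy
response modeling, and a cross-study drug-vulnerability rule for subtyped
cell lines — plus a synthetic-cohort generator that plants all of this
structure so the entire pipeline is testable without any download.

It is aimed at computational oncologists who want a reproducible,
scriptable version of this analysis for their own cohorts, or a controlled
sandbox for studying the method itself.

## The score at the core

For gene $i$ in sample $j$, expression is converted to
$z_{ij} = \hat F_i(x_{ij})$ (Gaussian-kernel CDF, bandwidth $s_i/4$, per
dataset). Genes are ranked per sample by decreasing $z$, and for a gene set
$S$ ($|S| = m$, universe size $N$) the walk

$$v(\ell) = \frac{\sum_{t \le \ell,\, g_t \in S} |r_t - N/2|^\tau}{\sum_{g \in S} |r_g - N/2|^\tau} - \frac{\#\{t \le \ell : g_t \notin S\}}{N - m}$$

yields the enrichment score $\max(v, 0) + \min(v, 0)$ (max-diff, default)
in $[-1, 1]$. Subtype discovery, prediction, and the immune module are all
built on this statistic.

## Worked example

```python
from padsub import (PipelineConfig, discover_subtypes, predict_subtypes,
                    simulate_cohort)
from sklearn.metrics import adjusted_rand_score

# 5 datasets x 100 samples, 5000 genes, 7 planted subtypes
cohort = simulate_cohort(seed=1)
cfg = PipelineConfig(n_iterations=20, base_seed=1)
model = discover_subtypes(cohort.expression, cohort.gene_sets, cfg)
print(model.n_subtypes)
print(model.final_labels.value_counts().to_dict())
print(round(adjusted_rand_score(cohort.truth.subtype_of, model.final_labels), 3))
```

prints

```
7
{'AD1': 99, 'AD2': 88, 'AD3': 83, 'AD4': 76, 'AD5': 74, 'AD6': 48, 'AD7': 32}
1.0
```

— the framework rediscovers the seven planted subtypes exactly (adjusted
Rand index 1.0 against the generator's truth), with group sizes ordered by
convention (AD1 largest). Prediction then classifies new samples onto the
trained map:

```python
held = simulate_cohort(n_datasets=2, n_per_dataset=100, seed=601)
pred = predict_subtypes(model, held.expression, held.gene_sets,
                        n_iterations=10, seed=902)
print(pred.to_frame().head(3))
```

```
       label  vote_fraction  tie  mean_neighbor_distance
sample
S0000    AD2            1.0    0                0.888299
S0001    AD2            1.0    0                0.871181
S0002    AD6            1.0    0                1.117450
```

Each row is a new sample's majority label over resampled iterations, the
fraction of iterations agreeing (a confidence diagnostic), a tie flag, and
the mean distance to its 51 nearest reference neighbors.

A command-line interface mirrors the library:
`padsub simulate | score | discover | predict | characterize | immune |
response | drugs` (see `padsub <cmd> --help`).

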