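# priorank

Multi-source candidate gene prioritization by guilt-by-association
sub-models and order-statistics rank fusion.

## The problem

High-throughput experiments routinely yield long lists of candidate
genes of which only a few are truly relevant to the disease, phenotype
or biological process under study. Given a set of *seed genes* already
known to be involved, `priorank` ranks candidate genes by how closely
their evidence profile across heterogeneous genomic data sources
resembles that of the seeds, so that downstream validation effort can
be concentrated on the most promising candidates. It is aimed at
computational biologists and medical geneticists who want a
transparent, scriptable prioritizer and a harness to benchmark it.

## The method

The pipeline has three steps, each per evidence source:

1. **Train.** Each source gets a sub-model of the seed set:
   - *annotation* sources (term → gene sets, GMT): terms
     over-represented among the seeds are kept with their one-sided
     hypergeometric p-value, `P(X ≥ k)` for `k` of `n` seeds among `K`
     carriers in a genome of `N` genes (retention threshold
     `α_retain = 0.05`);
   - *profile* sources (genes × conditions matrix): the centroid of the
     seed rows;
   - *network* and *similarity* sources: the set of seeds present in
     the source.
2. **Score & rank.** Each candidate is scored against each sub-model —
   Fisher's omnibus statistic `X = −2 Σ ln pᵢ` over its retained
   annotations, Pearson correlation with the centroid, total edge
   weight to the seeds, or best similarity to any other seed. Scores
   become descending mid-ranks; a candidate with no usable data in a
   source is *missing* there, not penalized. The rank ratio is
   `r = rank / n_scored`.
3. **Fuse.** A candidate scored in `N` sources has sorted ratios
   `r₍₁₎ ≤ … ≤ r₍N₎`. The Q statistic is the probability that `N` iid
   Uniform(0,1) order statistics fall componentwise below them
   (`V₀ = 1`, `V_k = Σᵢ (−1)^{i−1} V_{k−i} r₍N−k+1₎^i / i!`,
   `Q = N!·V_N`). Q is referred to a Monte-Carlo null calibrated for
   that gene's own `N`, which is what lets sparsely covered genes be
   compared fairly with well-annotated ones. The output is the global
   ranking sorted by this p-value.

Benchmarking follows two standard protocols: leave-one-out
cross-validation (each gold-set gene is hidden and re-ranked among 99
random decoys; AUC = `(n − rank)/(n − 1)`, compared against randomly
built control sets ≈ 50%), and a time-stamped protocol (train on an
earlier association snapshot, evaluate whole-genome rankings only on
associations that appear later). A synthetic-data generator with a
planted process module exercises everything without external
databases.

## Worked example

```python
import numpy as np
import priorank as pr

cfg = pr.SimConfig.strong(seed=3)          # high-signal planted module
ds = pr.simulate(cfg)
module = sorted(ds.module_genes)
rng = np.random.default_rng(0)
others = [g for g in ds.genome if g not in ds.module_genes]
candidates = [module[10]] + list(rng.choice(others, size=99, replace=False))

model = pr.PrioritizationModel(ds.sources(), module[:10], candidates, ds.genome)
res = model.fit()
print(res.summary(top=5))
```

```
Candidate gene prioritization
================================================================
genome: 1000 genes (synthetic)
seeds: 10   candidates: 100   sources: 4
alpha_retain: 0.05   null draws: 100000
----------------------------------------------------------------
rank  gene             p_value           Q   N
   1  g512             0.00026   4.609e-06   4
   2  g913               0.051   1.560e-02   2
   3  g398              0.0674   2.160e-02   2
   4  g157               0.068   2.180e-02   2
   5  g663              0.0917   3.120e-02   2
================================================================
```

The held-out module gene `g512` is scored in all four sources (`N=4`)
with consistently small rank ratios, so its order-statistics value
`Q ≈ 4.6·10⁻⁶` is far into the tail of the 4-source null
(`p ≈ 2.6·10⁻⁴`) and it tops the ranking; the runners-up are background
genes that happened to do well in two sources each.

The same pipeline is available from a shell:

```bash
priorank simulate --preset strong --rng-seed 3 --out data/
priorank prioritize --genome data/genome.txt --seeds seeds.txt --whole-genome \
    --source annotation:data/annotation.gmt --source profile:data/profile.tsv \
    --source network:data/network.tsv --source similarity:data/similarity.tsv \
    --out run/
priorank benchmark --genome data/genome.txt --gold data/gold.gmt \
    --source annotation:data/annotation.gmt --source profile:data/profile.tsv \
    --source network:data/network.tsv --source similarity:data/similarity.tsv \
    --out bench/
```

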