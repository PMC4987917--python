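# Methods

## Model and assumptions

`priorank` implements guilt-by-association gene prioritization: a
process of interest is represented only through its seed genes, and a
candidate is promising to the extent that its evidence across data
sources resembles the seeds'. The method makes no mechanistic
assumptions; its statistical assumptions are (i) under the null that a
candidate is unrelated to the seeds, its per-source rank ratio is
approximately Uniform(0,1), and (ii) ratios are independent across
sources. Redundant sources violate (ii) and make fused p-values
anti-conservative — users are expected not to select strongly
overlapping sources.

### Sub-models ("train")

- **Annotation.** A term is retained when its one-sided hypergeometric
  upper-tail p-value (seeds vs genome background) is ≤ `α_retain`
  (default 0.05; Benjamini–Hochberg adjustment across a source's terms
  is available but off by default). The background is the full genome,
  not the candidate set, because the model is built before candidates
  are seen. The retained p-value is reused at scoring time.
- **Profile.** The unweighted condition-wise mean of seed rows. This is
  deliberately the simplest defensible statistic; no per-condition
  weighting or regression is attempted.
- **Network / similarity.** The set of seeds present in the source.

### Scoring

All scorers emit "higher is better". The annotation score is Fisher's
omnibus statistic `X = −2 Σ ln pᵢ` over the retained terms annotating
the candidate (using X rather than the combined χ²(2m) tail avoids a
direction flip with varying m; the tail is still computable for
reporting via `fisher_omnibus`). Profile scoring is Pearson correlation
with the centroid; network scoring is summed edge weight to the seeds;
similarity scoring is the best pair score against any *other* seed, so
a candidate that is itself a seed cannot use self-evidence.

Missingness is a first-class outcome: a gene absent from a source (or
with no retained annotation, or a zero-variance profile row)
contributes no ratio there, whereas a gene present with zero evidence
(e.g. in the network but with no seed edge) is scored 0 and ranked.
Mid-ranks are used throughout so ties do not depend on gene labels.

### Fusion

Per gene, the sorted ratios from the sources that scored it enter the
order-statistics recursion (`Q = N!·V_N`); ratios are clipped to
`[1e-12, 1]` and the final factorial is applied in log space, keeping
the computation stable to at least N = 64. Q is converted to a p-value
against a Monte-Carlo null for that gene's own N
(`p = (1 + #{null ≤ Q}) / (M + 1)`, default `M = 10⁵` draws, fixed
seed, cached per N) — an assumption-free, directly testable choice in
place of any parametric approximation. Conditioning on each gene's own
N is what makes sparsely covered genes comparable with well-covered
ones. The global order is (p, Q, gene id); genes with no data anywhere
are appended last with p = 1 and a `no_data` flag.

With `M = 10⁵`, the p-value granularity is `≈ 10⁻⁵` and the empirical
CDF itself carries Kolmogorov error `≈ 0.86/√M ≈ 0.003`; applications
needing finer resolution can raise `draws`.

## Benchmarks

**LOOCV.** Each gold-set gene in turn becomes the single positive among
itself plus 99 decoys drawn without replacement from the genome outside
the *whole* gold set (so no decoy is a known positive). Decoys are
resampled per left-out gene. The positive's rank is its mid-rank in the
fused order — by p-value, with no-data genes strictly last and ties
averaged. Ranking by p alone would tie a "scored but uninformative"
positive (sole scored gene, ratio 1, p ≈ 1) with all no-data decoys;
the fused-order mid-rank keeps such evidence-bearing genes ahead, while
remaining exactly unbiased under the random-set control, where the
left-out gene and the decoys are exchangeable (grand-mean control AUC
= 50% by construction). AUC for one positive among n candidates is
`(n − rank)/(n − 1)`. The grand mean is the unweighted mean of per-set
means. Sources whose category tag matches the gold standard's category
are withheld from the run (leakage exclusion).

**Time-stamped.** Seeds come from the earlier association snapshot A
(terms with ≥ 5 genes, configurable); the whole genome minus the seeds
is ranked; each novel pair in B \ A contributes
`auc_from_rank(rank, n_candidates)`; the overall AUC is the mean over
novel pairs.

## Synthetic data generator

One planted module of `m` genes (default 20) in a genome of `G`
(default 1000), visible in four sources:

| source | mechanism | defaults |
|---|---|---|
| annotation | 10 process terms hit module genes w.p. `q_in`, others w.p. `q_out`; 50 background terms hit all genes w.p. 0.05 | `q_in=0.6`, `q_out=0.02` |
| profile | shared latent vector of RMS magnitude μ on module rows + N(0, σ²) noise, 10 conditions | `μ=0.4`, `σ=1` |
| network | planted-partition Bernoulli edges | `p_in=0.03`, `p_out=0.01` |
| similarity | within-module pairs at density 0.05 with scores U(0.5, 1); background pairs at density 0.01 with scores U(0, 0.9) | |

The defaults were calibrated in pilot runs so that each individual
source is only weakly-to-moderately informative: with stronger per-source
settings the fused LOOCV AUC saturates near 1 for any annotation
signal, and the response of the benchmark to `q_in` — the
parameter-recovery property the test suite checks — becomes
unresolvable. At these settings the planted-module LOOCV AUC spans
roughly 0.83 (annotation at null) to 0.96 (`q_in=0.9`). The
`SimConfig.strong()` preset (`q_in=0.9`, `μ=2`, `p_in=0.3`,
within-density 0.8) makes every source individually strong, and
`SimConfig.null()` removes all signal. Replicate sweeps over `q_in`
reuse the same seeds per level: the generator's independent RNG streams
then keep the non-annotation sources bit-identical across levels, so
level contrasts are paired (common random numbers).

What the generator does *not* emulate: scale-free network topology,
ontology structure among terms (terms are independent), correlated
conditions in profiles, batch effects, and any cross-source dependence
beyond shared module membership. Passing benchmarks on this generator
therefore demonstrate the correctness and calibration of the machinery
— chance-level controls, null uniformity, monotone signal response —
not absolute performance on real databases.

Two-snapshot associations: per term, the full set B is a random subset
of the module (4–12 genes); snapshot A withholds a `growth` fraction
(≥ 1 gene). The held-out genes are the novel associations; a
`random_novel` variant draws them from outside the module instead,
giving a chance-level null for the time-stamped harness.

## Numerical and design choices

- Exact hypergeometric tails (`scipy.stats.hypergeom.sf`), no normal
  approximation; enrichment p-values floored at 1e-300 before logs.
- Mid-ranks (`scipy.stats.rankdata`, method="average") everywhere ties
  arise; the fused table's deterministic tie-break is (p, Q, gene id).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning, so datasets, decoys, nulls and
  whole benchmark runs are bit-reproducible; CLI outputs embed the tool
  version, a config hash and the seed.
- Problem sizes used by the shipped benchmarks (G = 1000, four sources,
  200 control sets, 99 decoys, `M = 10⁵`) keep a full control run
  around two minutes on one CPU while leaving the grand-mean standard
  error near 0.7 AUC percentage points.
- Gene identifiers are opaque case-sensitive strings; no cross-species
  or cross-namespace mapping is attempted.

## Known limitations

- Per-source scoring functions for profile/network/similarity sources
  are simple stand-ins (centroid correlation, direct-neighbor weight,
  best-pair score); diffusion-based network scoring or learned models
  are out of scope.
- Fusion treats sources symmetrically; there is no reliability
  weighting.
- The empirical-null p-value is exchangeable-uniform only up to the
  discreteness of rank ratios and of the Monte-Carlo ECDF; with few
  scored genes in a source the ratio grid is coarse and small p-values
  are unattainable from that source alone.
- Candidates overlapping the seed set are allowed (with a warning) but
  only similarity self-evidence is identifiable and excluded; a seed
  candidate still benefits from, e.g., its own network edges to other
  seeds.
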