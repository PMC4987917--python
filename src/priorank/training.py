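"""Sub-model training: build one per-source model from the seed genes.

The seed genes define the biological process of interest.  For each
evidence source a small "sub-model" summarises what the seeds look like
in that source:

* annotation sources — the set of terms significantly over-represented
  among the seeds (one-sided hypergeometric test against the genome
  background), each kept with its enrichment p-value;
* profile sources — the condition-wise centroid of the seed rows;
* network and similarity sources — the set of seeds present in the
  source (the seed neighborhood / seed sequence set).

Sub-models deliberately stay simple: candidate scoring (see
:mod:`priorank.scoring`) measures how well each candidate fits them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .sources import (
    AnnotationSource,
    Genome,
    NetworkSource,
    ProfileSource,
    SimilaritySource,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSubModel",
    "ProfileSubModel",
    "NetworkSubModel",
    "SimilaritySubModel",
    "hypergeom_overrep",
    "train_annotation",
    "train_profile",
    "train_network",
    "train_similarity",
    "train",
]


@dataclass(frozen=True)
class AnnotationSubModel:
    source_name: str
    retained_terms: dict[str, float]  # term id -> over-representation p-value
    seed_count: int
    background_count: int


@dataclass(frozen=True)
class ProfileSubModel:
    source_name: str
    centroid: np.ndarray | None  # None when no seed has a profile row
    n_seed_rows: int


@dataclass(frozen=True)
class NetworkSubModel:
    source_name: str
    seed_set: frozenset[str]


@dataclass(frozen=True)
class SimilaritySubModel:
    source_name: str
    seed_set: frozenset[str]


def hypergeom_overrep(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Probability that a uniform draw of ``n`` genes from a genome of size
    ``N``, of which ``K`` carry the term, contains at least the observed
    ``k`` term carriers.  This is the one-sided (enrichment) Fisher exact
    test p-value.
    """
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"hypergeom_overrep: need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if not (0 < n <= N and 0 <= K <= N):
        raise ValidationError(f"hypergeom_overrep: need n <= N and K <= N, got n={n}, K={K}, N={N}")
    # sf(k-1) = P(X >= k); exact tail from scipy's hypergeometric pmf
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def train_annotation(
    source: AnnotationSource,
    seeds: frozenset[str] | set[str],
    genome: Genome,
    alpha_retain: float = 0.05,
    bh_correct: bool = False,
) -> AnnotationSubModel:
    """Retain the terms over-represented among the seeds.

    A term is retained when its hypergeometric upper-tail p-value is
    ``<= alpha_retain`` (optionally after Benjamini-Hochberg adjustment
    across the source's terms).  Retained p-values are what candidate
    scoring later combines with Fisher's method.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValidationError("train_annotation: empty seed set")
    unknown = seeds - set(genome.genes)
    if unknown:
        raise ValidationError(f"train_annotation: seeds outside genome: {sorted(unknown)[:5]}")
    n, N = len(seeds), len(genome)
    terms = sorted(source.term_to_genes)
    ks = np.array([len(source.term_to_genes[t] & seeds) for t in terms], dtype=int)
    Ks = np.array([len(source.term_to_genes[t]) for t in terms], dtype=int)
    if terms and not ks.any():
        logger.warning(
            "source %r: no seed gene is annotated; sub-model has zero terms", source.name
        )
        return AnnotationSubModel(source.name, {}, n, N)
    pvals = stats.hypergeom.sf(ks - 1, N, Ks, n) if terms else np.empty(0)
    crit = pvals
    if bh_correct and len(pvals):
        crit = stats.false_discovery_control(pvals, method="bh")
    retained = {
        t: float(pvals[i]) for i, t in enumerate(terms) if crit[i] <= alpha_retain
    }
    if not retained:
        logger.warning("source %r: no term retained at alpha=%g", source.name, alpha_retain)
    return AnnotationSubModel(source.name, retained, n, N)


def train_profile(source: ProfileSource, seeds: frozenset[str] | set[str]) -> ProfileSubModel:
    """Condition-wise mean of the seed-gene rows (unweighted centroid)."""
    rows = [source.row(g) for g in sorted(seeds)]
    rows = [r for r in rows if r is not None]
    if not rows:
        logger.warning("source %r: no seed gene has a profile row; inert sub-model", source.name)
        return ProfileSubModel(source.name, None, 0)
    return ProfileSubModel(source.name, np.mean(rows, axis=0), len(rows))


def train_network(source: NetworkSource, seeds: frozenset[str] | set[str]) -> NetworkSubModel:
    present = frozenset(seeds) & source.nodes
    if not present:
        logger.warning("source %r: no seed gene in network; inert sub-model", source.name)
    return NetworkSubModel(source.name, present)


def train_similarity(source: SimilaritySource, seeds: frozenset[str] | set[str]) -> SimilaritySubModel:
    present = frozenset(seeds) & source.genes
    if not present:
        logger.warning("source %r: no seed gene in similarity pairs; inert sub-model", source.name)
    return SimilaritySubModel(source.name, present)


def train(source, seeds, genome: Genome, alpha_retain: float = 0.05):
    """Dispatch to the trainer matching the source type."""
    if isinstance(source, AnnotationSource):
        return train_annotation(source, seeds, genome, alpha_retain=alpha_retain)
    if isinstance(source, ProfileSource):
        return train_profile(source, seeds)
    if isinstance(source, NetworkSource):
        return train_network(source, seeds)
    if isinstance(source, SimilaritySource):
        return train_similarity(source, seeds)
    raise TypeError(f"unknown source type: {type(source).__name__}")
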