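"""Synthetic multi-source datasets with a planted process module.

The generator emulates, at desk scale, the situation the prioritizer is
built for: a genome in which one group of genes (the "process module")
shares biology, visible as correlated signal across four heterogeneous
evidence sources:

* annotation — process terms annotate module genes with probability
  ``q_in`` and background genes with ``q_out``; background terms
  annotate all genes at a common rate;
* profile — module genes share a latent condition profile of magnitude
  ``signal`` plus Gaussian noise, other genes are pure noise;
* network — Bernoulli edges with probability ``p_in`` inside the module
  and ``p_out`` elsewhere (a planted-partition graph);
* similarity — within-module pairs appear at higher density and with a
  higher-scoring distribution than background pairs.

Default parameter values are deliberately *moderate* per source, so
that no single source resolves the module on its own and multi-source
fusion is actually exercised; ``SimConfig.strong()`` gives a
high-signal preset and ``SimConfig.null()`` a no-signal one.
Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .benchmark import GoldStandardSet
from .errors import ValidationError
from .sources import (
    AnnotationSource,
    Genome,
    NetworkSource,
    ProfileSource,
    SimilaritySource,
    write_edge_list,
    write_gene_list,
    write_gmt,
    write_pair_scores,
    write_profile_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSettings",
    "ProfileSettings",
    "NetworkSettings",
    "SimilaritySettings",
    "SimConfig",
    "SimDataset",
    "simulate",
    "simulate_snapshots",
]


@dataclass(frozen=True)
class AnnotationSettings:
    n_process_terms: int = 10
    n_background_terms: int = 50
    q_in: float = 0.6      # P(process term annotates a module gene)
    q_out: float = 0.02    # P(process term annotates a background gene)
    background_rate: float = 0.05  # P(background term annotates any gene)


@dataclass(frozen=True)
class ProfileSettings:
    n_conditions: int = 10
    signal: float = 0.4    # RMS magnitude of the shared latent profile
    noise: float = 1.0     # per-condition Gaussian noise SD


@dataclass(frozen=True)
class NetworkSettings:
    p_in: float = 0.03     # edge probability within the module
    p_out: float = 0.01    # edge probability elsewhere
    weight: float = 1.0


@dataclass(frozen=True)
class SimilaritySettings:
    within_density: float = 0.05
    background_density: float = 0.01
    within_low: float = 0.5
    within_high: float = 1.0
    background_low: float = 0.0
    background_high: float = 0.9


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    genome_size: int = 1000
    module_size: int = 20
    annotation: AnnotationSettings = field(default_factory=AnnotationSettings)
    profile: ProfileSettings = field(default_factory=ProfileSettings)
    network: NetworkSettings = field(default_factory=NetworkSettings)
    similarity: SimilaritySettings = field(default_factory=SimilaritySettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.module_size < self.genome_size:
            raise ValidationError("need 2 <= module_size < genome_size")
        a, n = self.annotation, self.network
        if not 0 <= a.q_out <= a.q_in <= 1:
            raise ValidationError("need 0 <= q_out <= q_in <= 1")
        if not 0 <= n.p_out <= n.p_in <= 1:
            raise ValidationError("need 0 <= p_out <= p_in <= 1")
        if self.profile.noise <= 0 or self.profile.signal < 0:
            raise ValidationError("need noise > 0 and signal >= 0")

    @classmethod
    def null(cls, genome_size: int = 1000, module_size: int = 20, seed: int = 0) -> "SimConfig":
        """No-signal configuration: the module is statistically invisible."""
        return cls(
            genome_size=genome_size,
            module_size=module_size,
            annotation=AnnotationSettings(q_in=0.02, q_out=0.02),
            profile=ProfileSettings(signal=0.0),
            network=NetworkSettings(p_in=0.01, p_out=0.01),
            similarity=SimilaritySettings(
                within_density=0.01, background_density=0.01,
                within_low=0.0, within_high=1.0,
                background_low=0.0, background_high=1.0,
            ),
            seed=seed,
        )

    @classmethod
    def strong(cls, genome_size: int = 1000, module_size: int = 20, seed: int = 0) -> "SimConfig":
        """High-signal preset: every source clearly resolves the module."""
        return cls(
            genome_size=genome_size,
            module_size=module_size,
            annotation=AnnotationSettings(q_in=0.9, q_out=0.02),
            profile=ProfileSettings(signal=2.0),
            network=NetworkSettings(p_in=0.3, p_out=0.01),
            similarity=SimilaritySettings(within_density=0.8, background_density=0.01),
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimDataset:
    """One synthetic genome with its four evidence sources and truth."""

    genome: Genome
    module_genes: frozenset[str]
    annotation: AnnotationSource
    profile: ProfileSource
    network: NetworkSource
    similarity: SimilaritySource
    config: SimConfig
    associations_a: dict[str, frozenset[str]] | None = None
    associations_b: dict[str, frozenset[str]] | None = None

    def sources(self) -> list:
        return [self.annotation, self.profile, self.network, self.similarity]

    def gold_set(self, set_id: str = "planted_module") -> GoldStandardSet:
        return GoldStandardSet(set_id=set_id, genes=self.module_genes,
                               category_label="planted")

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the package's on-disk formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_list(outdir / "genome.txt", self.genome.genes)
        write_gmt(outdir / "annotation.gmt", self.annotation)
        write_profile_tsv(outdir / "profile.tsv", self.profile)
        write_edge_list(outdir / "network.tsv", self.network)
        write_pair_scores(outdir / "similarity.tsv", self.similarity)
        write_gmt(outdir / "gold.gmt", {self.gold_set().set_id: self.module_genes})
        if self.associations_a is not None:
            write_gmt(outdir / "snapshot_A.gmt", self.associations_a)
            write_gmt(outdir / "snapshot_B.gmt", self.associations_b)
        truth = {"module_genes": sorted(self.module_genes), "config": self.config.to_dict()}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def _streams(config: SimConfig) -> list[np.random.Generator]:
    """Six independent, reproducible RNG streams derived from the seed."""
    children = np.random.SeedSequence(config.seed).spawn(6)
    return [np.random.default_rng(c) for c in children]


def _gene_ids(genome_size: int) -> list[str]:
    width = len(str(genome_size - 1))
    return [f"g{i:0{width}d}" for i in range(genome_size)]


def _module_mask(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(config.genome_size, size=config.module_size, replace=False)
    mask = np.zeros(config.genome_size, dtype=bool)
    mask[idx] = True
    return mask


def simulate(config: SimConfig) -> SimDataset:
    """Generate one dataset under ``config`` (bit-reproducible from seed)."""
    r_mod, r_ann, r_prof, r_net, r_sim, _ = _streams(config)
    ids = _gene_ids(config.genome_size)
    genome = Genome(ids, species_label="synthetic")
    mask = _module_mask(config, r_mod)
    genes = np.array(ids)
    module = frozenset(genes[mask])

    annotation = _simulate_annotation(config, genes, mask, r_ann)
    profile = _simulate_profile(config, genes, mask, r_prof)
    network = _simulate_network(config, genes, mask, r_net)
    similarity = _simulate_similarity(config, genes, mask, r_sim)
    return SimDataset(genome, module, annotation, profile, network, similarity, config)


def _simulate_annotation(config, genes, mask, rng) -> AnnotationSource:
    a = config.annotation
    g = len(genes)
    term_to_genes: dict[str, frozenset[str]] = {}
    probs = np.where(mask, a.q_in, a.q_out)
    for t in range(a.n_process_terms):
        members = genes[rng.random(g) < probs]
        if len(members):
            term_to_genes[f"PROC{t:03d}"] = frozenset(members)
    for t in range(a.n_background_terms):
        members = genes[rng.random(g) < a.background_rate]
        if len(members):
            term_to_genes[f"BG{t:03d}"] = frozenset(members)
    if not term_to_genes:
        logger.warning("synthetic annotation source has no non-empty terms")
    return AnnotationSource(name="annotation", term_to_genes=term_to_genes,
                            category="annotation")


def _simulate_profile(config, genes, mask, rng) -> ProfileSource:
    p = config.profile
    g, d = len(genes), p.n_conditions
    latent = rng.standard_normal(d)
    latent *= p.signal / max(np.sqrt(np.mean(latent**2)), 1e-12)
    mat = rng.normal(0.0, p.noise, size=(g, d))
    mat[mask] += latent
    labels = tuple(f"c{j}" for j in range(d))
    return ProfileSource(name="profile", genes=tuple(genes), matrix=mat,
                         condition_labels=labels, category="profile")


def _pair_arrays(g: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(g, k=1)
    return iu[0], iu[1]


def _simulate_network(config, genes, mask, rng) -> NetworkSource:
    n = config.network
    i, j = _pair_arrays(len(genes))
    within = mask[i] & mask[j]
    p = np.where(within, n.p_in, n.p_out)
    keep = rng.random(len(i)) < p
    edges = [(genes[a], genes[b], n.weight) for a, b in zip(i[keep], j[keep])]
    return NetworkSource.from_edges("network", edges, category="network")


def _simulate_similarity(config, genes, mask, rng) -> SimilaritySource:
    s = config.similarity
    i, j = _pair_arrays(len(genes))
    within = mask[i] & mask[j]
    dens = np.where(within, s.within_density, s.background_density)
    keep = rng.random(len(i)) < dens
    iw, jw, w_within = i[keep], j[keep], within[keep]
    lo = np.where(w_within, s.within_low, s.background_low)
    hi = np.where(w_within, s.within_high, s.background_high)
    scores = lo + rng.random(len(iw)) * (hi - lo)
    pair_scores = {
        (genes[a], genes[b]): float(sc) for a, b, sc in zip(iw, jw, scores)
    }
    return SimilaritySource(name="similarity", pair_scores=pair_scores,
                            category="similarity")


def simulate_snapshots(
    config: SimConfig,
    n_terms: int = 20,
    growth: float = 0.2,
    random_novel: bool = False,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Two association snapshots A (earlier) and B (later), A strictly in B.

    Per term, the full gene set B is drawn from the planted module (so
    novel genes share the module's evidence); the earlier snapshot A
    withholds a ``growth`` fraction (at least one gene) per term — the
    held-out genes are the "novel associations" a time-stamped benchmark
    must rediscover.  With ``random_novel=True`` the novel genes are
    instead drawn uniformly from outside the module, producing a null
    benchmark where chance-level performance is expected.
    """
    if not 0 < growth < 1:
        raise ValidationError("need 0 < growth < 1")
    *_, rng = _streams(config)
    ids = np.array(_gene_ids(config.genome_size))
    r_mod = _streams(config)[0]
    mask = _module_mask(config, r_mod)
    module = ids[mask]
    non_module = ids[~mask]

    assoc_a: dict[str, frozenset[str]] = {}
    assoc_b: dict[str, frozenset[str]] = {}
    max_size = min(12, len(module))
    for t in range(n_terms):
        size = int(rng.integers(4, max_size + 1))
        full = rng.choice(module, size=size, replace=False)
        n_novel = max(1, round(growth * size))
        if size - n_novel < 2:
            logger.warning("snapshot term %d: fewer than 2 training genes; dropped", t)
            continue
        novel = set(rng.choice(full, size=n_novel, replace=False))
        if random_novel:
            novel = set(rng.choice(non_module, size=n_novel, replace=False))
            a_genes = frozenset(full) - set(rng.choice(full, size=n_novel, replace=False))
            b_genes = frozenset(a_genes) | novel
        else:
            a_genes = frozenset(full) - novel
            b_genes = frozenset(full)
        assoc_a[f"ASSOC{t:03d}"] = frozenset(a_genes)
        assoc_b[f"ASSOC{t:03d}"] = frozenset(b_genes)
    return assoc_a, assoc_b
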