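"""Benchmark protocols: leave-one-out cross-validation and time-stamped.

LOOCV with decoys
    Each gene of a gold-standard set is in turn left out; the model is
    trained on the remaining genes and the left-out gene is ranked among
    itself plus ``n_decoys`` (default 99) genes drawn at random from the
    genome outside the gold set.  The rank of the single positive among
    the ``n`` candidates converts to an AUC of ``(n - rank) / (n - 1)``.
    Per-set mean AUCs are averaged (unweighted) into a grand mean, which
    is compared against the same protocol run on randomly assembled
    "gold" sets — the control, expected at chance level (~50%).

Time-stamped protocol
    Associations frozen at an earlier snapshot (A) provide the seeds;
    the whole genome minus the seeds is ranked; performance is measured
    only on the associations that appear in a later snapshot (B \\ A),
    mimicking prospective validation.

The AUC rank of the left-out gene is its mid-rank in the fused order
(by p-value, genes without any data last, ties averaged), so that
deterministic tie-breaking by gene id cannot bias the control away
from 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import PrioritizationModel
from .sources import Genome

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandardSet",
    "LoocvRecord",
    "BenchmarkSummary",
    "TimeStampedResult",
    "auc_from_rank",
    "run_loocv",
    "exclude_leaky_sources",
    "control_benchmark",
    "random_gold_sets",
    "time_stamped_benchmark",
]


@dataclass(frozen=True)
class GoldStandardSet:
    """A curated gene set used for benchmarking (>= 2 genes)."""

    set_id: str
    genes: frozenset[str]
    category_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if len(self.genes) < 2:
            raise ValidationError(
                f"gold set {self.set_id!r}: needs >= 2 genes (a left-out gene must leave seeds)"
            )


@dataclass(frozen=True)
class LoocvRecord:
    """One leave-one-out iteration."""

    set_id: str
    left_out_gene: str
    decoys: tuple[str, ...]
    rank_of_left_out: float
    auc: float


@dataclass
class BenchmarkSummary:
    """Per-set and grand-mean AUC of a LOOCV benchmark."""

    per_set: pd.DataFrame  # set_id, n_genes, mean_auc
    records: list[LoocvRecord] = field(repr=False)
    n_sets: int = 0
    n_genes: int = 0
    grand_mean_auc: float = float("nan")
    record_mean_auc: float = float("nan")
    grand_se: float = float("nan")

    @classmethod
    def from_records(cls, records: Sequence[LoocvRecord]) -> "BenchmarkSummary":
        if not records:
            raise ValidationError("no benchmark records")
        df = pd.DataFrame(
            {"set_id": [r.set_id for r in records], "auc": [r.auc for r in records]}
        )
        per_set = (
            df.groupby("set_id")["auc"].agg(["count", "mean"]).reset_index()
            .rename(columns={"count": "n_genes", "mean": "mean_auc"})
        )
        means = per_set["mean_auc"].to_numpy()
        se = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else float("nan")
        return cls(
            per_set=per_set,
            records=list(records),
            n_sets=len(per_set),
            n_genes=int(per_set["n_genes"].sum()),
            grand_mean_auc=float(means.mean()),
            record_mean_auc=float(df["auc"].mean()),
            grand_se=se,
        )


def auc_from_rank(rank: float, n: int) -> float:
    """AUC for a single positive at ``rank`` among ``n`` ranked items.

    Equals the fraction of the ``n - 1`` negatives ranked below the
    positive; mid-ranks (fractional) are allowed.
    """
    if n < 2:
        raise ValidationError("auc_from_rank: need n >= 2")
    if not 1 <= rank <= n:
        raise ValidationError(f"auc_from_rank: need 1 <= rank <= n, got rank={rank}, n={n}")
    return (n - rank) / (n - 1)


def exclude_leaky_sources(sources: Sequence, gold_category: str) -> list:
    """Drop sources whose category tag matches the gold standard's.

    Implements the benchmark rule that a source explicitly containing
    the association to be predicted must not take part in the run.
    """
    kept, removed = [], []
    for s in sources:
        if gold_category and s.category == gold_category:
            removed.append(s.name)
        else:
            kept.append(s)
    if removed:
        logger.info("excluded leaky source(s) %s for category %r", removed, gold_category)
    if not kept:
        raise ValidationError(f"all sources excluded for category {gold_category!r}")
    return kept


def _fused_midranks(table) -> np.ndarray:
    """Mid-ranks of the fused ordering: by p-value, genes without any
    data strictly last, ties averaged (p <= 1 < 2 keeps groups apart)."""
    key = table["p_value"].to_numpy() + 2.0 * table["no_data"].to_numpy()
    return stats.rankdata(key, method="average")


def _midrank_of(results, gene: str) -> float:
    tbl = results.fused.table
    pos = tbl.index[tbl["gene"] == gene]
    if pos.empty:
        raise KeyError(gene)
    return float(_fused_midranks(tbl)[pos[0]])


def run_loocv(
    gold: GoldStandardSet,
    sources: Sequence,
    genome: Genome,
    n_decoys: int = 99,
    seed: int | np.random.SeedSequence = 0,
    alpha_retain: float = 0.05,
    null_draws: int = 100_000,
    null_seed: int = 0,
) -> list[LoocvRecord]:
    """Leave-one-out cross-validation of one gold-standard set.

    Decoys are resampled per left-out gene from the genome outside the
    gold set; the whole run is deterministic given ``seed``.
    """
    missing = gold.genes - set(genome.genes)
    if missing:
        raise ValidationError(f"gold set {gold.set_id!r}: genes outside genome: {sorted(missing)[:5]}")
    pool = np.array(sorted(set(genome.genes) - gold.genes))
    if len(pool) < n_decoys:
        raise ValidationError(
            f"gold set {gold.set_id!r}: decoy pool has {len(pool)} genes, need {n_decoys}"
        )
    rng = np.random.default_rng(seed)
    records: list[LoocvRecord] = []
    for left_out in sorted(gold.genes):
        seeds = gold.genes - {left_out}
        decoys = tuple(rng.choice(pool, size=n_decoys, replace=False))
        candidates = [left_out, *decoys]
        model = PrioritizationModel(sources, seeds, candidates, genome,
                                    alpha_retain=alpha_retain)
        res = model.fit(null_draws=null_draws, null_seed=null_seed)
        rank = _midrank_of(res, left_out)
        records.append(
            LoocvRecord(
                set_id=gold.set_id,
                left_out_gene=left_out,
                decoys=decoys,
                rank_of_left_out=rank,
                auc=auc_from_rank(rank, len(candidates)),
            )
        )
    return records


def random_gold_sets(
    genome: Genome,
    n_sets: int,
    set_size_range: tuple[int, int] = (5, 40),
    rng: np.random.Generator | None = None,
    category_label: str = "random_control",
) -> list[GoldStandardSet]:
    """Gold sets drawn uniformly at random from the genome (control)."""
    if n_sets < 1:
        raise ValidationError("need n_sets >= 1")
    lo, hi = set_size_range
    if not 2 <= lo <= hi:
        raise ValidationError("need 2 <= lo <= hi for set sizes")
    rng = rng or np.random.default_rng(0)
    pool = np.array(sorted(genome.genes))
    out = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(rng.choice(pool, size=size, replace=False))
        out.append(GoldStandardSet(f"random{i:04d}", genes, category_label))
    return out


def control_benchmark(
    genome: Genome,
    sources: Sequence,
    n_sets: int,
    set_size_range: tuple[int, int] = (5, 40),
    n_decoys: int = 99,
    seed: int = 0,
    alpha_retain: float = 0.05,
    null_draws: int = 100_000,
    null_seed: int = 0,
) -> BenchmarkSummary:
    """LOOCV on randomly built gold sets — the chance-level control.

    Random sets carry no shared biology, so the grand-mean AUC is
    expected at ~50% whatever the sources contain.
    """
    ss = np.random.SeedSequence(seed)
    set_rng = np.random.default_rng(ss.spawn(1)[0])
    golds = random_gold_sets(genome, n_sets, set_size_range, rng=set_rng)
    records: list[LoocvRecord] = []
    loocv_seeds = ss.spawn(n_sets + 1)[1:]
    for gold, sub_ss in zip(golds, loocv_seeds):
        records.extend(
            run_loocv(
                gold, sources, genome,
                n_decoys=n_decoys, seed=sub_ss,
                alpha_retain=alpha_retain,
                null_draws=null_draws, null_seed=null_seed,
            )
        )
    return BenchmarkSummary.from_records(records)


@dataclass
class TimeStampedResult:
    """Whole-genome prospective-style benchmark results."""

    per_pair: pd.DataFrame  # term, novel_gene, rank, n_candidates, auc
    overall_auc: float
    n_terms: int
    n_novel_pairs: int


def time_stamped_benchmark(
    model_sources: Sequence,
    associations_a: Mapping[str, Iterable[str]],
    associations_b: Mapping[str, Iterable[str]],
    genome: Genome,
    min_seed: int = 5,
    seed: int = 0,
    alpha_retain: float = 0.05,
    null_draws: int = 100_000,
    null_seed: int = 0,
) -> TimeStampedResult:
    """Train on snapshot-A associations, evaluate on B \\ A novel pairs.

    For every term with at least ``min_seed`` snapshot-A genes, the
    whole genome (minus the seeds) is ranked and each novel gene's rank
    is converted to an AUC; the overall AUC is the mean over all novel
    gene-term pairs.
    """
    rows = []
    n_terms_used = 0
    for term in sorted(associations_a):
        a_genes = frozenset(associations_a[term]) & set(genome.genes)
        b_genes = frozenset(associations_b.get(term, frozenset()))
        novel = sorted((b_genes - frozenset(associations_a[term])) & set(genome.genes))
        if len(a_genes) < min_seed:
            logger.info("term %r: only %d snapshot-A genes (< %d); skipped", term, len(a_genes), min_seed)
            continue
        if not novel:
            continue
        n_terms_used += 1
        model = PrioritizationModel(model_sources, a_genes, None, genome,
                                    alpha_retain=alpha_retain)
        res = model.fit(null_draws=null_draws, null_seed=null_seed)
        tbl = res.fused.table
        ranks = _fused_midranks(tbl)
        gene_pos = {g: i for i, g in enumerate(tbl["gene"])}
        n = len(tbl)
        for g in novel:
            if g not in gene_pos:  # novel gene was a seed already (B inconsistency)
                continue
            rank = float(ranks[gene_pos[g]])
            rows.append(
                {"term": term, "novel_gene": g, "rank": rank,
                 "n_candidates": n, "auc": auc_from_rank(rank, n)}
            )
    if not rows:
        raise ValidationError("time-stamped benchmark: no novel associations to evaluate")
    per_pair = pd.DataFrame(rows)
    return TimeStampedResult(
        per_pair=per_pair,
        overall_auc=float(per_pair["auc"].mean()),
        n_terms=n_terms_used,
        n_novel_pairs=len(per_pair),
    )
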