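"""Statsmodels-style facade: a prioritization model and its results.

:class:`PrioritizationModel` bundles the three algorithmic steps —
train per-source sub-models from the seeds, score and rank the
candidates per source, fuse the rankings with order statistics — behind
a single ``fit()`` that returns a :class:`PrioritizationResults` object
carrying the global ranking, per-source rankings, sub-models and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .fusion import FusedResult, fuse
from .scoring import SourceRanking, score_and_rank
from .sources import Genome
from .training import train

logger = logging.getLogger(__name__)

__all__ = ["PrioritizationModel", "PrioritizationResults"]

SEED_GUIDANCE = (5, 40)  # advisory seed-set size range; runs proceed with a warning


class PrioritizationModel:
    """Guilt-by-association candidate gene prioritization.

    Parameters
    ----------
    sources
        Evidence sources (any mix of annotation / profile / network /
        similarity sources) with unique names.
    seeds
        Genes already known to belong to the process of interest.
    candidates
        Genes to rank.  Pass ``None`` to prioritize the whole genome
        minus the seeds.
    genome
        The gene universe.
    alpha_retain
        Retention threshold for over-represented annotation terms.
    """

    def __init__(
        self,
        sources: Sequence,
        seeds: Iterable[str],
        candidates: Iterable[str] | None,
        genome: Genome,
        alpha_retain: float = 0.05,
    ):
        sources = list(sources)
        if not sources:
            raise ValidationError("need at least one evidence source")
        names = [s.name for s in sources]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate source names: {names}")
        seeds = set(seeds)
        unknown = {g for g in seeds if g not in genome}
        if unknown:
            logger.warning("%d seed(s) not in genome dropped", len(unknown))
            seeds -= unknown
        if not seeds:
            raise ValidationError("no seed gene is in the genome")
        lo, hi = SEED_GUIDANCE
        if not lo <= len(seeds) <= hi:
            logger.warning(
                "seed set size %d outside the advised range [%d, %d]; proceeding",
                len(seeds), lo, hi,
            )
        if candidates is None:
            candidates = [g for g in genome if g not in seeds]
        else:
            candidates = list(dict.fromkeys(candidates))
            unknown_c = [g for g in candidates if g not in genome]
            if unknown_c:
                logger.warning("%d candidate(s) not in genome dropped", len(unknown_c))
                candidates = [g for g in candidates if g in genome]
            overlap = seeds.intersection(candidates)
            if overlap:
                logger.warning(
                    "%d candidate(s) overlap the seed set (self-evidence is "
                    "excluded where identifiable)", len(overlap),
                )
        if not candidates:
            raise ValidationError("empty candidate set after validation")
        self.sources = sources
        self.seeds = frozenset(seeds)
        self.candidates = tuple(candidates)
        self.genome = genome
        self.alpha_retain = float(alpha_retain)

    def fit(self, null_draws: int = 100_000, null_seed: int = 0) -> "PrioritizationResults":
        """Train, score and fuse; returns the results object."""
        submodels = {s.name: train(s, self.seeds, self.genome, alpha_retain=self.alpha_retain)
                     for s in self.sources}
        rankings = [
            score_and_rank(s, submodels[s.name], self.candidates) for s in self.sources
        ]
        fused = fuse(rankings, self.candidates, draws=null_draws, seed=null_seed)
        return PrioritizationResults(self, submodels, rankings, fused)


class PrioritizationResults:
    """Fitted prioritization: global ranking plus per-source diagnostics."""

    def __init__(
        self,
        model: PrioritizationModel,
        submodels: dict,
        source_rankings: list[SourceRanking],
        fused: FusedResult,
    ):
        self.model = model
        self.submodels = submodels
        self.source_rankings = source_rankings
        self.fused = fused

    @property
    def ranking(self) -> pd.DataFrame:
        """The fused global ranking table."""
        return self.fused.table

    def rank_of(self, gene: str) -> int:
        return self.fused.rank_of(gene)

    def pvalue_of(self, gene: str) -> float:
        return self.fused.pvalue_of(gene)

    def summary(self, top: int = 10) -> str:
        """Readable run summary with the top-ranked candidates."""
        m = self.model
        lines = [
            "Candidate gene prioritization",
            "=" * 64,
            f"genome: {len(m.genome)} genes ({m.genome.species_label})",
            f"seeds: {len(m.seeds)}   candidates: {len(m.candidates)}   "
            f"sources: {len(m.sources)}",
            f"alpha_retain: {m.alpha_retain:g}   null draws: {self.fused.null_draws}",
            "-" * 64,
            f"{'rank':>4}  {'gene':<14}{'p_value':>10}{'Q':>12}{'N':>4}",
        ]
        for _, row in self.fused.table.head(top).iterrows():
            q = "" if pd.isna(row["Q"]) else f"{row['Q']:.3e}"
            lines.append(
                f"{int(row['global_rank']):>4}  {row['gene']:<14}"
                f"{row['p_value']:>10.3g}{q:>12}{int(row['N']):>4}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_tsv(self, outdir: str | Path, header_lines: Sequence[str] = ()) -> list[Path]:
        """Write the fused table and one TSV per source ranking."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        fused_path = outdir / "fused_ranking.tsv"
        _write_tsv(fused_path, self.fused.table, header_lines)
        written.append(fused_path)
        for rk in self.source_rankings:
            p = outdir / f"ranking_{rk.source_name}.tsv"
            _write_tsv(p, rk.to_frame(), header_lines)
            written.append(p)
        return written

    def plot_source_ranks(self, top: int = 20, ax=None):
        """Rank-ratio profile of the top fused genes across sources.

        A static stand-in for an interactive parallel-coordinates view;
        requires matplotlib.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        cols = [c for c in self.fused.table.columns if c.startswith("r:")]
        sub = self.fused.table.head(top)
        for _, row in sub.iterrows():
            ax.plot(range(len(cols)), [row[c] for c in cols], marker="o", alpha=0.6,
                    label=row["gene"])
        ax.set_xticks(range(len(cols)))
        ax.set_xticklabels([c[2:] for c in cols], rotation=30, ha="right")
        ax.set_ylabel("rank ratio")
        ax.set_ylim(0, 1.05)
        ax.invert_yaxis()
        if top <= 10:
            ax.legend(fontsize=7)
        return ax


def _write_tsv(path: Path, df: pd.DataFrame, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
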