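"""Candidate scoring and per-source ranking.

Every scorer follows the same contract: higher score = better fit to the
seed sub-model, and a candidate with *no usable data* in a source is
``missing`` for that source (returned as ``None``) rather than being
given a bad score.  Missingness matters downstream: the fusion step
judges each gene only against the sources where it could be scored, so
poorly annotated genes are compared fairly.

Scorers
-------
* annotation — Fisher's omnibus statistic X = -2 * sum(ln p_i) over the
  retained-term p-values of the terms annotating the candidate
  (annotations not in the sub-model are ignored; no retained annotation
  means missing);
* profile — Pearson correlation with the seed centroid;
* network — total edge weight to the seed set (0 when present with no
  seed edge, which counts as scored; absent from the network is missing);
* similarity — best pair score against any *other* seed (self-pairs are
  excluded by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .sources import AnnotationSource, NetworkSource, ProfileSource, SimilaritySource
from .training import (
    AnnotationSubModel,
    NetworkSubModel,
    ProfileSubModel,
    SimilaritySubModel,
)

__all__ = [
    "SourceRanking",
    "fisher_omnibus",
    "score_annotation",
    "score_profile",
    "score_network",
    "score_similarity",
    "rank_candidates",
    "score_and_rank",
]

_MIN_P = 1e-300  # guards log of underflowed enrichment p-values


def fisher_omnibus(pvalues: Iterable[float]) -> tuple[float, float]:
    """Fisher's omnibus combination of independent p-values.

    Returns ``(X, tail)`` where ``X = -2 * sum(ln p_i)`` and ``tail`` is
    the chi-square survival probability with ``2m`` degrees of freedom.
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValidationError("fisher_omnibus: no p-values")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValidationError("fisher_omnibus: p-values must lie in (0, 1]")
    x = -2.0 * np.log(np.maximum(ps, _MIN_P)).sum()
    return float(x), float(stats.chi2.sf(x, 2 * ps.size))


def score_annotation(
    gene: str, submodel: AnnotationSubModel, source: AnnotationSource
) -> float | None:
    """Fisher statistic over the candidate's retained-term p-values."""
    terms = source.gene_to_terms.get(gene, ())
    ps = [submodel.retained_terms[t] for t in terms if t in submodel.retained_terms]
    if not ps:
        return None
    x, _ = fisher_omnibus(ps)
    return x


def score_profile(gene: str, submodel: ProfileSubModel, source: ProfileSource) -> float | None:
    """Pearson correlation between the candidate row and the seed centroid."""
    if submodel.centroid is None:
        return None
    row = source.row(gene)
    if row is None:
        return None
    if np.std(row) == 0 or np.std(submodel.centroid) == 0:
        return None
    return float(np.corrcoef(row, submodel.centroid)[0, 1])


def score_network(gene: str, submodel: NetworkSubModel, source: NetworkSource) -> float | None:
    """Total edge weight between the candidate and the seed set."""
    return source.seed_weight(gene, submodel.seed_set)


def score_similarity(
    gene: str, submodel: SimilaritySubModel, source: SimilaritySource
) -> float | None:
    """Best similarity score between the candidate and any other seed."""
    nbrs = source.neighbors(gene)
    if not nbrs:
        return None
    best = None
    for s in submodel.seed_set:
        if s == gene:
            continue  # self-evidence excluded
        v = nbrs.get(s)
        if v is not None and (best is None or v > best):
            best = v
    return best


@dataclass
class SourceRanking:
    """Per-source candidate ranking with mid-ranks and rank ratios.

    ``ranks`` are descending-score mid-ranks over the scored genes only;
    ``ratios`` are rank / number-of-scored-genes, so the worst scored
    gene always has ratio 1.  ``missing`` holds the candidates with no
    usable data in this source.
    """

    source_name: str
    genes: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray
    ratios: np.ndarray
    missing: frozenset[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_scored(self) -> int:
        return len(self.genes)

    def ratio(self, gene: str) -> float | None:
        i = self._index.get(gene)
        return None if i is None else float(self.ratios[i])

    def to_frame(self) -> pd.DataFrame:
        scored = pd.DataFrame(
            {
                "gene": self.genes,
                "score": self.scores,
                "rank": self.ranks,
                "rank_ratio": self.ratios,
                "status": "scored",
            }
        )
        miss = pd.DataFrame(
            {
                "gene": sorted(self.missing),
                "score": np.nan,
                "rank": np.nan,
                "rank_ratio": np.nan,
                "status": "missing",
            }
        )
        out = pd.concat([scored, miss], ignore_index=True) if len(miss) else scored
        return out


def rank_candidates(
    scores: Mapping[str, float],
    source_name: str = "",
    missing: Iterable[str] = (),
) -> SourceRanking:
    """Turn gene -> score into descending-score mid-ranks and ratios."""
    if not scores:
        raise ValidationError(f"rank_candidates({source_name!r}): no scored genes")
    genes = tuple(sorted(scores))
    vals = np.array([scores[g] for g in genes], dtype=float)
    ranks = stats.rankdata(-vals, method="average")
    ratios = ranks / len(genes)
    return SourceRanking(
        source_name=source_name,
        genes=genes,
        scores=vals,
        ranks=ranks,
        ratios=ratios,
        missing=frozenset(missing),
    )


_SCORERS = {
    AnnotationSource: (AnnotationSubModel, score_annotation),
    ProfileSource: (ProfileSubModel, score_profile),
    NetworkSource: (NetworkSubModel, score_network),
    SimilaritySource: (SimilaritySubModel, score_similarity),
}


def score_and_rank(source, submodel, candidates: Iterable[str]) -> SourceRanking:
    """Score every candidate against one source and rank the scorable ones.

    Candidates the source cannot score are recorded as missing; if no
    candidate is scorable the ranking is empty-scored (all missing).
    """
    for src_type, (sub_type, scorer) in _SCORERS.items():
        if isinstance(source, src_type):
            if not isinstance(submodel, sub_type):
                raise TypeError(
                    f"sub-model type {type(submodel).__name__} does not match "
                    f"source type {src_type.__name__}"
                )
            break
    else:
        raise TypeError(f"unknown source type: {type(source).__name__}")

    candidates = list(dict.fromkeys(candidates))
    scores: dict[str, float] = {}
    missing: list[str] = []
    for g in candidates:
        s = scorer(g, submodel, source)
        if s is None:
            missing.append(g)
        else:
            scores[g] = s
    if not scores:
        return SourceRanking(
            source_name=source.name,
            genes=(),
            scores=np.empty(0),
            ranks=np.empty(0),
            ratios=np.empty(0),
            missing=frozenset(missing),
        )
    out = rank_candidates(scores, source_name=source.name, missing=missing)
    return out
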