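"""Evidence-source types and their on-disk formats.

A prioritization run works inside a fixed gene universe (:class:`Genome`)
and draws evidence from four kinds of sources:

* :class:`AnnotationSource` — term-to-gene-set annotations (GMT format),
  e.g. functional ontologies or pathway memberships;
* :class:`ProfileSource` — a real-valued genes x conditions matrix,
  e.g. an expression compendium;
* :class:`NetworkSource` — an undirected, optionally weighted interaction
  network (edge-list TSV);
* :class:`SimilaritySource` — precomputed pairwise gene-gene similarity
  scores (e.g. sequence similarity), stored as symmetric pair triples.

Gene identifiers are opaque, case-sensitive strings; no cross-namespace
mapping is attempted.  Genes that fall outside the genome are dropped
with a logged warning; inputs that become empty after filtering raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "AnnotationSource",
    "ProfileSource",
    "NetworkSource",
    "SimilaritySource",
    "read_gene_list",
    "read_gmt",
    "read_profile_tsv",
    "read_edge_list",
    "read_pair_scores",
    "write_gene_list",
    "write_gmt",
    "write_profile_tsv",
    "write_edge_list",
    "write_pair_scores",
]


class Genome:
    """The universe of gene identifiers for a run.

    Parameters
    ----------
    genes
        Unique, non-empty identifiers.  Iteration order is the insertion
        order and is deterministic for a given input.
    species_label
        Free-text tag (e.g. ``"H. sapiens"``).
    """

    def __init__(self, genes: Iterable[str], species_label: str = "unspecified"):
        seen: dict[str, None] = {}
        for g in genes:
            if not isinstance(g, str) or not g.strip():
                raise ValidationError(f"empty or non-string gene identifier: {g!r}")
            if g in seen:
                raise ValidationError(f"duplicate gene identifier: {g!r}")
            seen[g] = None
        if not seen:
            raise ValidationError("genome is empty")
        self.genes: tuple[str, ...] = tuple(seen)
        self.species_label = species_label
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:
        return f"Genome({len(self)} genes, species={self.species_label!r})"

    def index(self, gene: str) -> int:
        return self._index[gene]

    @classmethod
    def from_file(cls, path: str | Path, species_label: str = "unspecified") -> "Genome":
        genes = _read_id_lines(path)
        if not genes:
            raise FormatError(f"{path}: no gene identifiers found")
        return cls(genes, species_label=species_label)


def _read_id_lines(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line)
    return out


def read_gene_list(path: str | Path, genome: Genome) -> set[str]:
    """Read a plain-text gene list (one id per line, ``#`` comments).

    Identifiers outside ``genome`` are dropped with a logged warning;
    an empty intersection raises :class:`ValidationError`.
    """
    raw = _read_id_lines(path)
    kept = {g for g in raw if g in genome}
    dropped = len(set(raw)) - len(kept)
    if dropped:
        logger.warning("%s: %d identifier(s) not in genome dropped", path, dropped)
    if not kept:
        raise ValidationError(f"{path}: no gene identifiers remain after genome filtering")
    return kept


def write_gene_list(path: str | Path, genes: Iterable[str], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


@dataclass
class AnnotationSource:
    """Term -> gene-set annotations within a genome.

    ``category`` is a free-text tag used by the benchmark's leakage
    exclusion rule (a source whose category matches the gold standard's
    category is withheld from the run).
    """

    name: str
    term_to_genes: dict[str, frozenset[str]]
    term_descriptions: dict[str, str] = field(default_factory=dict)
    category: str = ""
    _gene_to_terms: dict[str, tuple[str, ...]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValidationError(f"annotation source {self.name!r}: empty term {term!r}")
            self.term_to_genes[term] = frozenset(genes)

    @property
    def gene_to_terms(self) -> dict[str, tuple[str, ...]]:
        """Inverted index (built lazily, cached)."""
        if self._gene_to_terms is None:
            inv: dict[str, list[str]] = {}
            for term in sorted(self.term_to_genes):
                for g in self.term_to_genes[term]:
                    inv.setdefault(g, []).append(term)
            self._gene_to_terms = {g: tuple(ts) for g, ts in inv.items()}
        return self._gene_to_terms

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)


@dataclass
class ProfileSource:
    """Genes x conditions real-valued profile matrix."""

    name: str
    genes: tuple[str, ...]
    matrix: np.ndarray
    condition_labels: tuple[str, ...]
    category: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.genes), len(self.condition_labels)):
            raise ValidationError(
                f"profile source {self.name!r}: matrix shape {self.matrix.shape} "
                f"does not match {len(self.genes)} genes x {len(self.condition_labels)} conditions"
            )
        if self.matrix.shape[1] < 2:
            raise ValidationError(f"profile source {self.name!r}: needs >= 2 conditions")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"profile source {self.name!r}: duplicate gene rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError(f"profile source {self.name!r}: non-finite values in matrix")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray | None:
        i = self._index.get(gene)
        return None if i is None else self.matrix[i]

    def __contains__(self, gene: object) -> bool:
        return gene in self._index


@dataclass
class NetworkSource:
    """Undirected weighted interaction network (no self-loops)."""

    name: str
    graph: nx.Graph
    category: str = ""

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str, float]],
        category: str = "",
    ) -> "NetworkSource":
        """Build from (u, v, weight) triples.

        Self-loops are dropped with a warning; duplicate edges are
        collapsed with their weights summed.
        """
        g = nx.Graph()
        n_self = 0
        for u, v, w in edges:
            if u == v:
                n_self += 1
                continue
            if w <= 0:
                raise ValidationError(f"network {name!r}: non-positive weight on edge ({u}, {v})")
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=float(w))
        if n_self:
            logger.warning("network %r: %d self-loop(s) dropped", name, n_self)
        return cls(name=name, graph=g, category=category)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def seed_weight(self, gene: str, seeds: frozenset[str]) -> float | None:
        """Total edge weight between ``gene`` and ``seeds``; None if absent."""
        if gene not in self.graph:
            return None
        adj = self.graph.adj[gene]
        return float(sum(d["weight"] for nbr, d in adj.items() if nbr in seeds))


@dataclass
class SimilaritySource:
    """Symmetric, non-negative pairwise gene-gene similarity scores."""

    name: str
    pair_scores: dict[tuple[str, str], float]
    category: str = ""
    _neighbors: dict[str, dict[str, float]] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), s in self.pair_scores.items():
            if a == b:
                raise ValidationError(f"similarity {self.name!r}: self-pair ({a}, {b})")
            if s < 0:
                raise ValidationError(f"similarity {self.name!r}: negative score for ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            if key in canon and canon[key] != s:
                raise ValidationError(
                    f"similarity {self.name!r}: asymmetric duplicate pair {key} "
                    f"(scores {canon[key]} and {s})"
                )
            canon[key] = float(s)
        self.pair_scores = canon
        nbrs: dict[str, dict[str, float]] = {}
        for (a, b), s in canon.items():
            nbrs.setdefault(a, {})[b] = s
            nbrs.setdefault(b, {})[a] = s
        self._neighbors = nbrs

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._neighbors)

    def neighbors(self, gene: str) -> Mapping[str, float]:
        return self._neighbors.get(gene, {})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    genome: Genome,
    name: str | None = None,
    category: str = "",
) -> AnnotationSource:
    """Read a GMT gene-set file (term <TAB> description <TAB> gene ...).

    Member genes outside the genome are dropped; terms left empty after
    filtering are dropped with a warning.  Duplicate term ids raise.
    """
    term_to_genes: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_dropped_genes = 0
    n_dropped_terms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3")
            term, desc, *members = fields
            if term in term_to_genes:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            members = [m for m in members if m]
            kept = frozenset(m for m in members if m in genome)
            n_dropped_genes += len(set(members)) - len(kept)
            if not kept:
                n_dropped_terms += 1
                continue
            term_to_genes[term] = kept
            descriptions[term] = desc
    if n_dropped_genes:
        logger.warning("%s: %d gene(s) outside genome dropped", path, n_dropped_genes)
    if n_dropped_terms:
        logger.warning("%s: %d term(s) empty after genome filtering dropped", path, n_dropped_terms)
    return AnnotationSource(
        name=name or Path(path).stem,
        term_to_genes=term_to_genes,
        term_descriptions=descriptions,
        category=category,
    )


def write_gmt(path: str | Path, source: AnnotationSource | Mapping[str, Iterable[str]]) -> None:
    if isinstance(source, AnnotationSource):
        term_to_genes = source.term_to_genes
        descriptions = source.term_descriptions
    else:
        term_to_genes = {t: frozenset(gs) for t, gs in source.items()}
        descriptions = {}
    with open(path, "w") as fh:
        for term in sorted(term_to_genes):
            desc = descriptions.get(term, "na")
            members = "\t".join(sorted(term_to_genes[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def read_profile_tsv(
    path: str | Path,
    genome: Genome | None = None,
    name: str | None = None,
    category: str = "",
) -> ProfileSource:
    """Read a headered profile TSV: ``gene <TAB> cond1 <TAB> cond2 ...``."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: cannot parse profile TSV ({exc})") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene row(s): {dups[:5]}")
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell in profile matrix ({exc})") from exc
    genes = [str(g) for g in df.index]
    if genome is not None:
        keep = [i for i, g in enumerate(genes) if g in genome]
        if len(keep) < len(genes):
            logger.warning("%s: %d profile row(s) outside genome dropped", path, len(genes) - len(keep))
        genes = [genes[i] for i in keep]
        mat = mat[keep]
    if not genes:
        raise ValidationError(f"{path}: no profile rows remain after genome filtering")
    return ProfileSource(
        name=name or Path(path).stem,
        genes=tuple(genes),
        matrix=mat,
        condition_labels=tuple(str(c) for c in df.columns),
        category=category,
    )


def write_profile_tsv(path: str | Path, source: ProfileSource) -> None:
    df = pd.DataFrame(source.matrix, index=list(source.genes), columns=list(source.condition_labels))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def _read_pair_lines(path: str | Path, n_min: int, n_max: int):
    """Yield (lineno, fields) for a headered pair TSV, skipping the header."""
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                continue
            if not n_min <= len(fields) <= n_max:
                raise FormatError(f"{path}:{lineno}: expected {n_min}-{n_max} fields, got {len(fields)}")
            yield lineno, fields


def read_edge_list(
    path: str | Path,
    genome: Genome | None = None,
    name: str | None = None,
    category: str = "",
) -> NetworkSource:
    """Read a headered edge-list TSV: ``geneA <TAB> geneB [<TAB> weight]``."""
    edges: list[tuple[str, str, float]] = []
    n_outside = 0
    for lineno, fields in _read_pair_lines(path, 2, 3):
        a, b = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from exc
        else:
            w = 1.0
        if genome is not None and (a not in genome or b not in genome):
            n_outside += 1
            continue
        edges.append((a, b, w))
    if n_outside:
        logger.warning("%s: %d edge(s) with genes outside genome dropped", path, n_outside)
    return NetworkSource.from_edges(name or Path(path).stem, edges, category=category)


def write_edge_list(path: str | Path, source: NetworkSource) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tweight\n")
        for u, v, d in sorted(source.graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = (u, v) if u < v else (v, u)
            fh.write(f"{a}\t{b}\t{d['weight']:.10g}\n")


def read_pair_scores(
    path: str | Path,
    genome: Genome | None = None,
    name: str | None = None,
    category: str = "",
) -> SimilaritySource:
    """Read a headered similarity TSV: ``geneA <TAB> geneB <TAB> score``."""
    pair_scores: dict[tuple[str, str], float] = {}
    n_outside = 0
    n_self = 0
    for lineno, fields in _read_pair_lines(path, 3, 3):
        a, b = fields[0], fields[1]
        try:
            s = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from exc
        if s < 0:
            raise ValidationError(f"{path}:{lineno}: negative similarity score {s}")
        if a == b:
            n_self += 1
            continue
        if genome is not None and (a not in genome or b not in genome):
            n_outside += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in pair_scores and pair_scores[key] != s:
            raise ValidationError(f"{path}:{lineno}: asymmetric duplicate pair {key}")
        pair_scores[key] = s
    if n_self:
        logger.warning("%s: %d self-pair(s) dropped", path, n_self)
    if n_outside:
        logger.warning("%s: %d pair(s) with genes outside genome dropped", path, n_outside)
    return SimilaritySource(name=name or Path(path).stem, pair_scores=pair_scores, category=category)


def write_pair_scores(path: str | Path, source: SimilaritySource) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tscore\n")
        for (a, b), s in sorted(source.pair_scores.items()):
            fh.write(f"{a}\t{b}\t{s:.10g}\n")
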