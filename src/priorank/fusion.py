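"""Order-statistics fusion of per-source rankings into a global ranking.

Each candidate gene carries one rank ratio r = rank / n_scored per
source in which it could be scored.  Under the null hypothesis that the
gene is unrelated to the seeds, its ratios behave like independent
Uniform(0, 1) draws.  The Q statistic is the joint probability that N
iid uniform order statistics fall componentwise below the gene's sorted
ratios — small Q means consistently good ranks across sources.

Because Q's null distribution depends on N, and genes differ in how
many sources cover them, each gene's Q is referred to a Monte-Carlo
null calibrated *for its own N*.  This is what lets a gene scored in
two sources be compared fairly with a gene scored in five.

The Q recursion (ratios sorted ascending, r(1) <= ... <= r(N)):

    V_0 = 1
    V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} * r(N-k+1)^i / i!
    Q   = N! * V_N

For N=1 this reduces to Q = r; for N=2, Q = 2ab - a^2 with a <= b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scoring import SourceRanking

__all__ = [
    "q_statistic",
    "NullDistribution",
    "calibrate_null",
    "q_to_pvalue",
    "fuse",
    "FusedResult",
]

_RATIO_FLOOR = 1e-12  # numerical guard: ratios clipped to [floor, 1]


def _check_ratios(ratios: np.ndarray) -> np.ndarray:
    if ratios.ndim != 1 or ratios.size == 0:
        raise ValidationError("q_statistic: need at least one ratio")
    if np.any(ratios <= 0) or np.any(ratios > 1):
        raise ValidationError(f"q_statistic: ratios must lie in (0, 1], got {ratios}")
    return np.clip(ratios, _RATIO_FLOOR, 1.0)


def q_statistic(ratios: Sequence[float]) -> float:
    """Joint uniform order-statistic probability for one ratio vector."""
    r = _check_ratios(np.asarray(ratios, dtype=float))
    return float(_q_batch(np.sort(r)[None, :])[0])


def _q_batch(sorted_ratios: np.ndarray) -> np.ndarray:
    """Vectorised Q over rows of an (m, N) array of ascending ratios.

    The alternating recursion is run in linear space (stable for the
    source counts seen in practice); the final N! factor is applied in
    log space so large N cannot overflow.
    """
    m, n = sorted_ratios.shape
    # V[k] for each row; inv_fact[i] = 1/i!
    inv_fact = np.array([1.0 / math.factorial(i) for i in range(n + 1)])
    v = [np.ones(m)]
    for k in range(1, n + 1):
        rr = sorted_ratios[:, n - k]  # r_(N-k+1), 0-indexed
        acc = np.zeros(m)
        rpow = np.ones(m)
        sign = 1.0
        for i in range(1, k + 1):
            rpow = rpow * rr
            acc += sign * v[k - i] * rpow * inv_fact[i]
            sign = -sign
        v.append(acc)
    vn = np.clip(v[n], 1e-320, None)  # roundoff can graze zero for tiny ratios
    log_q = math.lgamma(n + 1) + np.log(vn)
    return np.minimum(np.exp(log_q), 1.0)


@dataclass(frozen=True)
class NullDistribution:
    """Sorted Monte-Carlo sample of Q under N iid Uniform(0,1) ratios."""

    n_sources: int
    draws: int
    seed: int
    sorted_q: np.ndarray = field(repr=False, compare=False)

    def pvalue(self, q: float | np.ndarray) -> np.ndarray:
        """Empirical upper bound p = (1 + #{null Q <= q}) / (draws + 1)."""
        count = np.searchsorted(self.sorted_q, q, side="right")
        return (1.0 + count) / (self.draws + 1.0)


_NULL_CACHE: dict[tuple[int, int, int], NullDistribution] = {}


def calibrate_null(n_sources: int, draws: int = 100_000, seed: int = 0) -> NullDistribution:
    """Monte-Carlo null of Q for genes scored in ``n_sources`` sources.

    Cached per (N, draws, seed); with the same arguments the null is
    bit-identical across calls and processes.
    """
    if n_sources < 1:
        raise ValidationError("calibrate_null: n_sources must be >= 1")
    if draws < 10_000:
        raise ValidationError("calibrate_null: need at least 10^4 draws")
    key = (n_sources, draws, seed)
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(np.random.SeedSequence((seed, n_sources)))
    u = np.sort(rng.random((draws, n_sources)), axis=1)
    null = NullDistribution(n_sources, draws, seed, np.sort(_q_batch(u)))
    _NULL_CACHE[key] = null
    return null


def q_to_pvalue(q: float, n_sources: int, null: NullDistribution) -> float:
    """Significance of an observed Q against its per-N empirical null."""
    if null.n_sources != n_sources:
        raise ValidationError(
            f"q_to_pvalue: null calibrated for N={null.n_sources}, gene has N={n_sources}"
        )
    return float(null.pvalue(q))


@dataclass
class FusedResult:
    """Global ranking produced by order-statistics fusion.

    ``table`` has one row per candidate, sorted by ascending p-value
    (ties broken by Q, then gene id), with columns ``gene``,
    ``global_rank``, ``p_value``, ``Q``, ``N`` followed by one
    rank-ratio column per source (NaN where the gene was missing).
    Genes with no data in any source (N=0) are appended last with
    p-value 1 and ``no_data=True``.
    """

    table: pd.DataFrame
    source_names: tuple[str, ...]
    null_draws: int
    null_seed: int

    def rank_of(self, gene: str) -> int:
        row = self.table.loc[self.table["gene"] == gene, "global_rank"]
        if row.empty:
            raise KeyError(gene)
        return int(row.iloc[0])

    def pvalue_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene"] == gene, "p_value"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def fuse(
    rankings: Sequence[SourceRanking],
    candidates: Iterable[str],
    draws: int = 100_000,
    seed: int = 0,
) -> FusedResult:
    """Fuse per-source rankings into a significance-annotated global ranking.

    For each candidate the rank ratios of the sources that scored it are
    combined into Q (over its own N), and Q is converted to a p-value
    using the Monte-Carlo null for that N.  The output is sorted by
    ascending p-value; the result does not depend on the order of
    ``rankings`` (beyond the order of the ratio columns) nor on gene
    labels.
    """
    rankings = list(rankings)
    if not rankings:
        raise ValidationError("fuse: need at least one source ranking")
    candidates = sorted(dict.fromkeys(candidates))
    if not candidates:
        raise ValidationError("fuse: empty candidate set")

    ratio_cols: dict[str, np.ndarray] = {}
    ratio_mat = np.full((len(candidates), len(rankings)), np.nan)
    for j, rk in enumerate(rankings):
        for i, g in enumerate(candidates):
            r = rk.ratio(g)
            if r is not None:
                ratio_mat[i, j] = r
        ratio_cols[rk.source_name] = ratio_mat[:, j]

    n_per_gene = np.sum(~np.isnan(ratio_mat), axis=1)
    if not n_per_gene.any():
        raise ValidationError("fuse: every candidate is missing in every source")

    q_vals = np.full(len(candidates), np.nan)
    p_vals = np.ones(len(candidates))
    for n in sorted(set(n_per_gene[n_per_gene > 0].astype(int))):
        idx = np.flatnonzero(n_per_gene == n)
        rows = ratio_mat[idx]
        sorted_r = np.sort(np.clip(rows[~np.isnan(rows)].reshape(len(idx), n), _RATIO_FLOOR, 1.0), axis=1)
        qs = _q_batch(sorted_r)
        null = calibrate_null(n, draws=draws, seed=seed)
        q_vals[idx] = qs
        p_vals[idx] = null.pvalue(qs)

    no_data = n_per_gene == 0
    table = pd.DataFrame(
        {
            "gene": candidates,
            "p_value": p_vals,
            "Q": q_vals,
            "N": n_per_gene.astype(int),
            "no_data": no_data,
        }
    )
    for name, col in ratio_cols.items():
        table[f"r:{name}"] = col
    # deterministic order: data-bearing genes by (p, Q, gene); N=0 appended last
    table = table.sort_values(
        by=["no_data", "p_value", "Q", "gene"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    table.insert(1, "global_rank", np.arange(1, len(table) + 1))
    return FusedResult(
        table=table,
        source_names=tuple(rk.source_name for rk in rankings),
        null_draws=draws,
        null_seed=seed,
    )
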