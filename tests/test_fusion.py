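"""Order-statistics Q, its Monte-Carlo null, and ranking fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import priorank as pr
from priorank.errors import ValidationError

ratio_vectors = st.lists(
    st.floats(1e-6, 1.0, exclude_max=False), min_size=1, max_size=6
)


def mc_event_probability(ratios, n_draws, rng) -> tuple[float, float]:
    """Oracle: P(all N uniform order statistics <= sorted ratios), with SE."""
    r = np.sort(np.asarray(ratios, dtype=float))
    u = np.sort(rng.random((n_draws, len(r))), axis=1)
    hits = np.all(u <= r, axis=1).mean()
    se = np.sqrt(max(hits * (1 - hits), 1e-12) / n_draws)
    return hits, se


class TestQStatistic:
    def test_single_ratio_is_identity(self):
        assert pr.q_statistic([0.3]) == pytest.approx(0.3, abs=1e-12)

    def test_all_ones_is_certain(self):
        for n in (1, 2, 5, 10):
            assert pr.q_statistic([1.0] * n) == pytest.approx(1.0, abs=1e-12)

    def test_two_source_closed_form(self):
        # joint cdf of two uniform order statistics: 2ab - a^2 (a <= b)
        assert pr.q_statistic([0.1, 0.2]) == pytest.approx(0.03, abs=1e-12)
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = np.sort(rng.random(2))
            assert pr.q_statistic([a, b]) == pytest.approx(2 * a * b - a * a, abs=1e-12)

    def test_order_of_input_does_not_matter(self):
        assert pr.q_statistic([0.7, 0.2, 0.5]) == pytest.approx(
            pr.q_statistic([0.2, 0.5, 0.7]), abs=1e-15
        )

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1], []])
    def test_invalid_ratios_raise(self, bad):
        with pytest.raises(ValidationError):
            pr.q_statistic(bad)

    def test_matches_monte_carlo_event_oracle(self):
        rng = np.random.default_rng(42)
        for n in range(1, 5):
            for _ in range(3):
                r = rng.random(n)
                phat, se = mc_event_probability(r, 200_000, rng)
                assert pr.q_statistic(r) == pytest.approx(phat, abs=max(3 * se, 1e-6))

    @given(ratio_vectors, st.data())
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_ratio(self, ratios, data):
        i = data.draw(st.integers(0, len(ratios) - 1))
        bumped = list(ratios)
        bumped[i] = data.draw(st.floats(ratios[i], 1.0))
        assert pr.q_statistic(bumped) >= pr.q_statistic(ratios) - 1e-9

    def test_numerically_stable_for_many_sources(self):
        rng = np.random.default_rng(0)
        q = pr.q_statistic(rng.random(64))
        assert 0 < q <= 1


class TestCalibrateNull:
    def test_single_source_null_is_uniform(self):
        null = pr.calibrate_null(1, draws=100_000, seed=0)
        d = stats.kstest(null.sorted_q, "uniform").statistic
        assert d < 0.01

    def test_fixed_seed_is_bit_identical(self):
        a = pr.calibrate_null(3, draws=10_000, seed=9)
        pr.fusion._NULL_CACHE.clear()
        b = pr.calibrate_null(3, draws=10_000, seed=9)
        assert np.array_equal(a.sorted_q, b.sorted_q)

    def test_two_source_null_matches_event_simulation(self):
        # empirical P(Q <= 0.03) vs the brute-force probability of the
        # event over uniform pairs, within 3 binomial SEs
        null = pr.calibrate_null(2, draws=100_000, seed=0)
        p_emp = float(null.pvalue(0.03))
        rng = np.random.default_rng(7)
        u = rng.random((400_000, 2))
        a, b = np.minimum(u[:, 0], u[:, 1]), np.maximum(u[:, 0], u[:, 1])
        p_oracle = float(np.mean(2 * a * b - a * a <= 0.03))
        se = np.sqrt(p_oracle * (1 - p_oracle) / 400_000) + np.sqrt(
            p_emp * (1 - p_emp) / null.draws
        )
        assert p_emp == pytest.approx(p_oracle, abs=3 * se)

    def test_too_few_draws_raise(self):
        with pytest.raises(ValidationError):
            pr.calibrate_null(2, draws=100)


class TestQToPvalue:
    def test_maximal_q_gives_p_near_one(self):
        null = pr.calibrate_null(3, draws=10_000, seed=0)
        assert pr.q_to_pvalue(1.0, 3, null) == pytest.approx(1.0, abs=1e-3)

    def test_single_source_p_recovers_ratio(self):
        null = pr.calibrate_null(1, draws=100_000, seed=0)
        for r in (0.05, 0.3, 0.8):
            assert pr.q_to_pvalue(r, 1, null) == pytest.approx(r, abs=2 / np.sqrt(null.draws))

    def test_monotone_in_q(self):
        null = pr.calibrate_null(2, draws=10_000, seed=0)
        ps = [pr.q_to_pvalue(q, 2, null) for q in (0.001, 0.01, 0.1, 0.5, 1.0)]
        assert ps == sorted(ps)

    def test_n_mismatch_raises(self):
        null = pr.calibrate_null(2, draws=10_000, seed=0)
        with pytest.raises(ValidationError):
            pr.q_to_pvalue(0.5, 3, null)


def _ranking_from_ratios(name, gene_ratios):
    """Build a SourceRanking whose rank ratios are as prescribed."""
    scores = {g: 1.0 - r for g, r in gene_ratios.items()}
    return pr.rank_candidates(scores, source_name=name)


class TestFuse:
    def test_single_source_preserves_order(self):
        rk = pr.rank_candidates({"a": 5.0, "b": 3.0, "c": 1.0}, source_name="s")
        fused = pr.fuse([rk], ["a", "b", "c"], draws=10_000)
        assert list(fused.table["gene"]) == ["a", "b", "c"]

    def test_few_good_ranks_beat_many_mediocre_ranks(self):
        # gene scored in 2 sources at ratio 0.01 vs gene scored in 5 at 0.5
        rankings = []
        for j in range(2):
            scores = {"good": 100.0, **{f"f{j}{i}": float(i) for i in range(99)}}
            rankings.append(pr.rank_candidates(scores, source_name=f"a{j}"))
        for j in range(5):
            scores = {"mediocre": 50.0, **{f"g{j}{i}": float(i) for i in range(99)}}
            rankings.append(pr.rank_candidates(scores, source_name=f"b{j}"))
        fused = pr.fuse(rankings, ["good", "mediocre"], draws=50_000)
        assert fused.pvalue_of("good") < fused.pvalue_of("mediocre")
        assert fused.rank_of("good") == 1

    def test_invariant_to_source_ordering(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        rks = [
            pr.rank_candidates(dict(zip(genes, rng.random(30))), source_name=f"s{j}")
            for j in range(4)
        ]
        f1 = pr.fuse(rks, genes, draws=10_000)
        f2 = pr.fuse(rks[::-1], genes, draws=10_000)
        assert list(f1.table["gene"]) == list(f2.table["gene"])
        assert np.allclose(f1.table["p_value"], f2.table["p_value"])

    def test_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        scores = [rng.random(20) for _ in range(3)]
        f1 = pr.fuse(
            [pr.rank_candidates(dict(zip(genes, s)), source_name=f"s{j}")
             for j, s in enumerate(scores)],
            genes, draws=10_000,
        )
        relabel = {g: f"zz{i:02d}" for i, g in enumerate(genes)}
        f2 = pr.fuse(
            [pr.rank_candidates({relabel[g]: v for g, v in zip(genes, s)}, source_name=f"s{j}")
             for j, s in enumerate(scores)],
            list(relabel.values()), draws=10_000,
        )
        order1 = [relabel[g] for g in f1.table["gene"]]
        assert order1 == list(f2.table["gene"])

    def test_gene_with_no_data_is_appended_last_with_p_one(self):
        rk = pr.rank_candidates({"a": 2.0, "b": 1.0}, source_name="s", missing={"zzz", "aaa"})
        fused = pr.fuse([rk], ["a", "b", "zzz", "aaa"], draws=10_000)
        tail = fused.table.tail(2)
        assert set(tail["gene"]) == {"zzz", "aaa"}
        assert (tail["p_value"] == 1.0).all()
        assert tail["no_data"].all()
        assert (tail["N"] == 0).all()

    def test_all_genes_missing_everywhere_raises(self):
        rk = pr.SourceRanking("s", (), np.empty(0), np.empty(0), np.empty(0), frozenset({"a"}))
        with pytest.raises(ValidationError):
            pr.fuse([rk], ["a"], draws=10_000)

    def test_per_gene_n_varies_with_coverage(self):
        r1 = pr.rank_candidates({"a": 1.0, "b": 2.0}, source_name="s1", missing={"c"})
        r2 = pr.rank_candidates({"a": 1.0, "c": 2.0}, source_name="s2", missing={"b"})
        fused = pr.fuse([r1, r2], ["a", "b", "c"], draws=10_000)
        n = dict(zip(fused.table["gene"], fused.table["N"]))
        assert n == {"a": 2, "b": 1, "c": 1}
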