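import math
import random
from fractions import Fraction

import pytest
from scipy.stats import mannwhitneyu

from wmwexact.dp_core import (
    Frontier,
    TailSpec,
    advance_layer,
    apply_prune_filters,
    count_tail,
    exact_wmw_p,
    merge_tie_block,
    two_sided_p,
)
from wmwexact.oracle import brute_force_p, brute_force_tail
from wmwexact.ranks import build_ranked_data

from conftest import random_instance


def composed_count(data, size, threshold2):
    """Tail count via the public layer ops: merge each tie block, then prune."""
    tail = TailSpec(size=size, threshold2=threshold2)
    frontier = Frontier.root()
    consumed = 0
    for rank2, t in data.tie_runs:
        frontier = merge_tie_block(frontier, rank2, t)
        consumed += t
        frontier = apply_prune_filters(
            frontier, consumed, tail, list(data.ranks2[consumed:])
        )
    return tail.tally


class TestAdvanceLayer:
    def test_root_spawns_included_arm(self):
        f = advance_layer(Frontier.root(), 2)
        assert f.entries == {(0, 0): 1, (1, 2): 1}
        assert f.layer_index == 1

    def test_paths_meeting_at_one_key_are_merged(self):
        # two layer-3 parents share the child (2, 5) when rank 4 arrives
        f = Frontier(entries={(2, 5): 1, (1, 1): 1}, layer_index=3)
        out = advance_layer(f, 4)
        assert out.entries[(2, 5)] == 2

    def test_unpruned_counts_sum_to_two_to_the_i(self, seeded_rng):
        ranks2 = sorted(seeded_rng.sample(range(1, 100), 8))
        f = Frontier.root()
        for i, r2 in enumerate(ranks2, start=1):
            f = advance_layer(f, r2)
            assert f.total_count() == 2**i


class TestMergeTieBlock:
    def test_pascal_triangle_from_root(self):
        f = merge_tie_block(Frontier.root(), 5, 3)
        assert f.entries == {(i, 5 * i): math.comb(3, i) for i in range(4)}
        assert f.layer_index == 3

    def test_t1_equals_single_advance(self, seeded_rng):
        f = Frontier(
            entries={(0, 0): 1, (1, 3): 2, (2, 8): 5}, layer_index=3
        )
        assert merge_tie_block(f, 7, 1).entries == advance_layer(f, 7).entries

    @pytest.mark.parametrize("t", [2, 3, 4, 5])
    def test_equals_repeated_advance(self, t, seeded_rng):
        for _ in range(20):
            entries = {
                (seeded_rng.randint(0, 4), seeded_rng.randint(0, 30)):
                seeded_rng.randint(1, 9)
                for _ in range(seeded_rng.randint(1, 6))
            }
            rank2 = seeded_rng.randint(1, 10)
            merged = merge_tie_block(Frontier(dict(entries)), rank2, t)
            stepped = Frontier(dict(entries))
            for _ in range(t):
                stepped = advance_layer(stepped, rank2)
            assert merged.entries == stepped.entries
            assert merged.layer_index == stepped.layer_index


class TestPruneFilters:
    def test_oversized_subset_removed(self):
        tail = TailSpec(size=2, threshold2=100)
        f = Frontier(entries={(3, 9): 4}, layer_index=3)
        assert apply_prune_filters(f, 3, tail, [8]).entries == {}

    def test_unreachable_size_removed(self):
        # m=3, N=5, i=4: k=1 can grow to at most 2
        tail = TailSpec(size=3, threshold2=1000)
        f = Frontier(entries={(1, 2): 1}, layer_index=4)
        assert apply_prune_filters(f, 4, tail, [10]).entries == {}

    def test_threshold_unreachable_removed(self):
        tail = TailSpec(size=2, threshold2=6)
        f = Frontier(entries={(1, 6): 1}, layer_index=2)
        assert apply_prune_filters(f, 2, tail, [6, 8]).entries == {}

    def test_completed_subsets_are_tallied_then_retired(self):
        tail = TailSpec(size=2, threshold2=6)
        f = Frontier(entries={(2, 6): 3, (2, 7): 1, (1, 2): 1}, layer_index=3)
        out = apply_prune_filters(f, 3, tail, [8])
        assert tail.tally == 3  # (2,7) exceeds the threshold, discarded
        assert out.entries == {}  # (1,2): 2+8 > 6 fails the completion bound


class TestCountTail:
    def test_smallest_rank_only(self):
        data, _ = build_ranked_data([1], [2])
        assert count_tail(data, TailSpec(size=1, threshold2=2)) == 1

    def test_lowest_pair_only(self):
        data, _ = build_ranked_data([1, 2], [3, 4])
        assert count_tail(data, TailSpec(size=2, threshold2=6)) == 1

    def test_max_threshold_counts_all_subsets(self, seeded_rng):
        for _ in range(20):
            x, y = random_instance(seeded_rng, max_n=10)
            data, _ = build_ranked_data(x, y)
            thr = sum(data.ranks2)
            assert count_tail(data, TailSpec(data.m, thr)) == math.comb(
                data.total, data.m
            )

    def test_matches_composition_of_layer_ops(self, seeded_rng):
        for _ in range(100):
            x, y = random_instance(seeded_rng, max_n=10)
            data, sums = build_ranked_data(x, y)
            for size, thr in ((data.m, sums.rX2), (data.n, sums.rY2)):
                assert count_tail(data, TailSpec(size, thr)) == composed_count(
                    data, size, thr
                )


class TestTwoSidedP:
    @pytest.mark.parametrize(
        "cx, cy, total, expected",
        [
            (1, 2, 2, Fraction(1)),
            (1, 6, 6, Fraction(1, 3)),
            (3, 3, 6, Fraction(1)),  # capped
        ],
    )
    def test_values(self, cx, cy, total, expected):
        assert two_sided_p(cx, cy, total) == expected

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            two_sided_p(1, 1, 0)
        with pytest.raises(ValueError):
            two_sided_p(0, 1, 5)


class TestExactWmwP:
    def test_tiny_cases(self):
        assert exact_wmw_p([1], [2]).p == 1.0
        assert exact_wmw_p([1, 2], [3, 4]).p_exact == Fraction(1, 3)
        assert exact_wmw_p([4, 4, 4], [4, 4]).p == 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            exact_wmw_p([], [1.0])
        with pytest.raises(ValueError):
            exact_wmw_p([1.0], [float("inf")])

    def test_symmetry_and_monotone_invariance(self, seeded_rng):
        for _ in range(50):
            x, y = random_instance(seeded_rng)
            a = exact_wmw_p(x, y)
            b = exact_wmw_p(y, x)
            assert a.p_exact == b.p_exact
            assert (a.count_x, a.count_y) == (b.count_y, b.count_x)
            c = exact_wmw_p([math.exp(v / 50) for v in x],
                            [math.exp(v / 50) for v in y])
            assert c.p_exact == a.p_exact

    def test_strategies_and_worker_counts_bit_identical(self, seeded_rng):
        for _ in range(60):
            x, y = random_instance(seeded_rng)
            base = exact_wmw_p(x, y, two_pass=True)
            for kwargs in ({}, {"workers": 4}, {"two_pass": True, "workers": 3}):
                alt = exact_wmw_p(x, y, **kwargs)
                assert (alt.count_x, alt.count_y, alt.total) == (
                    base.count_x, base.count_y, base.total
                )

    def test_complement_symmetry_against_oracle(self, seeded_rng):
        """#{size-m, sum2 <= q} + #{size-m, sum2 >= q+1} == C(N, m) for all q."""
        for _ in range(20):
            x, y = random_instance(seeded_rng, max_n=9)
            data, _ = build_ranked_data(x, y)
            n_tot, m = data.total, data.m
            total = math.comb(n_tot, m)
            for q in range(0, n_tot * (n_tot + 1) + 2, 3):
                le = brute_force_tail(data, m, q)
                ge = total - le
                if q >= 1:
                    assert count_tail(data, TailSpec(m, q)) == le
                # size-m subsets with sum2 >= q+1 biject onto size-n
                # complements with sum2 <= N(N+1) - (q+1)
                thr_c = n_tot * (n_tot + 1) - (q + 1)
                if thr_c >= 1:
                    assert count_tail(data, TailSpec(data.n, thr_c)) == ge

    def test_untied_matches_classical_exact_distribution(self, seeded_rng):
        """For untied data the exact P must match the classical rank-sum null."""
        for _ in range(60):
            n_tot = seeded_rng.randint(4, 20)
            m = seeded_rng.randint(2, n_tot - 2)
            vals = seeded_rng.sample(range(10_000), n_tot)
            x, y = vals[:m], vals[m:]
            ours = exact_wmw_p(x, y).p
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)
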