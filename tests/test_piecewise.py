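"""Candidate cost functions, level sets, and interval-set algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import segdp as sd
from segdp.piecewise import IntervalSet


def grid_members(iset, grid):
    return np.array([iset.contains(m) for m in grid])


class TestGaussianCandidate:
    def test_add_observation_updates_coefficients(self):
        cand = sd.GaussianCandidate(tau=0, a=0.0, b=0.0, c=5.0)
        out = cand.add_observation(2.0)
        # adds (y-mu)^2/2 = mu^2/2 - 2 mu + 2
        assert (out.a, out.b, out.c) == (0.5, -2.0, 7.0)

    def test_adding_y_contributes_zero_at_mu_equals_y(self):
        cand = sd.GaussianCandidate(tau=0)
        out = cand.add_observation(3.3)
        assert out(3.3) == pytest.approx(cand(3.3))

    def test_minimiser_is_sample_mean(self, rng):
        ys = rng.normal(size=11)
        cand = sd.GaussianCandidate(tau=0, c=4.0)
        for y in ys:
            cand = cand.add_observation(y)
        mu_hat, val = cand.minimum()
        assert mu_hat == pytest.approx(ys.mean(), rel=1e-9)
        # grid oracle
        grid = np.linspace(ys.mean() - 2, ys.mean() + 2, 20001)
        assert val == pytest.approx(cand(grid).min(), abs=1e-6)

    def test_vertex_example(self):
        cand = sd.GaussianCandidate(tau=0, a=0.5, b=-2.0, c=7.0)
        assert cand.minimum() == pytest.approx((2.0, 5.0))

    def test_flat_function_minimum(self):
        assert sd.GaussianCandidate(tau=0, c=3.0).minimum()[1] == 3.0

    def test_level_set_roots(self):
        parabola = sd.GaussianCandidate(tau=0, a=1.0)   # mu^2
        ls = parabola.level_set(1.0)
        assert ls.intervals == ((-1.0, 1.0),)
        lifted = sd.GaussianCandidate(tau=0, a=1.0, c=2.0)  # mu^2 + 2
        assert lifted.level_set(1.0).is_empty

    def test_level_set_endpoints_hit_threshold(self, rng):
        for _ in range(20):
            cand = sd.GaussianCandidate(tau=0, a=float(rng.uniform(0.1, 4)),
                                        b=float(rng.normal()),
                                        c=float(rng.normal()))
            thr = cand.minimum()[1] + float(rng.uniform(0.1, 5))
            (lo, hi), = cand.level_set(thr).intervals
            for endpoint in (lo, hi):
                assert abs(cand(endpoint) - thr) <= 1e-6 * (1 + abs(thr))


class TestPoissonCandidate:
    def test_add_observation_counts(self):
        cand = sd.PoissonCandidate(tau=0, offset=1.0)
        out = cand.add_observation(3.0).add_observation(0.0)
        assert (out.count, out.sum_y, out.offset) == (2.0, 3.0, 1.0)

    def test_minimum_at_mean_rate(self):
        cand = sd.PoissonCandidate(tau=0, count=4.0, sum_y=8.0)
        mu_hat, val = cand.minimum()
        assert mu_hat == pytest.approx(2.0)
        assert val == pytest.approx(8.0 - 8.0 * np.log(2.0))

    def test_level_set_endpoints_by_bisection_oracle(self, rng):
        for _ in range(10):
            cand = sd.PoissonCandidate(tau=0, count=float(rng.integers(1, 9)),
                                       sum_y=float(rng.integers(1, 30)),
                                       offset=float(rng.normal()))
            thr = cand.minimum()[1] + float(rng.uniform(0.2, 4))
            (lo, hi), = cand.level_set(thr).intervals
            assert cand(lo) == pytest.approx(thr, rel=1e-8, abs=1e-8)
            assert cand(hi) == pytest.approx(thr, rel=1e-8, abs=1e-8)

    def test_all_zero_counts_level_set_touches_origin(self):
        cand = sd.PoissonCandidate(tau=0, count=3.0, sum_y=0.0, offset=1.0)
        (lo, hi), = cand.level_set(2.5).intervals
        assert lo == 0.0
        assert hi == pytest.approx(0.5)


class TestIntervalSet:
    def test_intersect_examples(self):
        a = IntervalSet.from_pairs([(-1, 1)])
        assert sd.intersect(a, IntervalSet.from_pairs([(0, 2)])).intervals == \
            ((0.0, 1.0),)
        assert sd.intersect(a, IntervalSet.from_pairs([(2, 3)])).is_empty

    def test_complement_examples(self):
        dom = (-10.0, 10.0)
        covering = [IntervalSet.from_pairs([(-10, 0)]),
                    IntervalSet.from_pairs([(-1, 10)])]
        assert sd.complement_of_union(covering, dom).is_empty
        assert sd.complement_of_union([], dom).intervals == ((-10.0, 10.0),)

    def test_rejects_bad_intervals(self):
        with pytest.raises(ValueError):
            IntervalSet.from_pairs([(2, 1)])
        with pytest.raises(ValueError):
            IntervalSet.from_pairs([(0, 2), (1, 3)])

    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(0, 10)),
                    min_size=0, max_size=4),
           st.lists(st.tuples(st.floats(-20, 20), st.floats(0, 10)),
                    min_size=0, max_size=4))
    def test_intersection_agrees_with_grid_membership(self, raw_a, raw_b):
        def build(raw):
            pairs, cursor = [], -25.0
            for lo, width in sorted(raw):
                lo = max(lo, cursor + 0.5)
                pairs.append((lo, lo + width))
                cursor = lo + width
            return IntervalSet.from_pairs(pairs)

        a, b = build(raw_a), build(raw_b)
        out = sd.intersect(a, b)
        grid = np.linspace(-25, 35, 601)
        np.testing.assert_array_equal(
            grid_members(out, grid),
            grid_members(a, grid) & grid_members(b, grid))

    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(0, 10)),
                    min_size=0, max_size=5))
    def test_complement_agrees_with_grid_membership(self, raw):
        sets = [IntervalSet.from_pairs([(lo, lo + w)]) for lo, w in raw]
        dom = (-30.0, 30.0)
        comp = sd.complement_of_union(sets, dom)
        grid = np.linspace(-30, 30, 601)
        in_union = np.zeros(grid.size, dtype=bool)
        for s in sets:
            in_union |= grid_members(s, grid)
        # away from endpoints the complement is exactly the non-members
        boundary = np.zeros(grid.size, dtype=bool)
        eps = 1e-9
        for s in list(sets) + [comp]:
            for lo, hi in s.intervals:
                boundary |= (np.abs(grid - lo) < eps) | (np.abs(grid - hi) < eps)
        interior = ~boundary
        np.testing.assert_array_equal(
            grid_members(comp, grid)[interior], ~in_union[interior])


class TestPartitionProperty:
    """During a functional-pruning run the live optimality sets tile the
    domain: pairwise disjoint, union = D, and each candidate really is the
    pointwise minimum on its own set."""

    def test_fpop_candidates_partition_domain(self, rng):
        y = rng.normal(size=60)
        y[30:] += 4.0
        ts = sd.TimeSeries.from_values(y)
        model = sd.GaussianMeanCost()
        beta = 2 * math.log(60)
        # replay FPOP with CandidateCost objects to inspect the sets
        cands = [sd.GaussianCandidate(tau=0, c=0.0)]
        F = [-beta]
        for t in range(1, ts.n + 1):
            cands = [c.add_observation(y[t - 1]) for c in cands]
            vals = [c.minimum()[1] for c in cands]
            F.append(min(vals))
            thr = F[t] + beta
            levels = [c.level_set(thr) for c in cands]
            survivors = []
            for c, lev in zip(cands, levels):
                new_set = sd.intersect(c.set, lev)
                if not new_set.is_empty:
                    survivors.append(sd.GaussianCandidate(
                        tau=c.tau, a=c.a, b=c.b, c=c.c, set=new_set))
            comp = sd.complement_of_union(levels)
            if not comp.is_empty:
                survivors.append(sd.GaussianCandidate(tau=t, c=thr, set=comp))
            cands = survivors

            if t in (20, 40, 60):
                # clipped to a window, the live sets tile it exactly:
                # disjoint and jointly covering D
                W = 20.0
                clipped = sum(max(0.0, min(hi_i, W) - max(lo_i, -W))
                              for c in cands for lo_i, hi_i in c.set.intervals)
                assert clipped == pytest.approx(2 * W, rel=1e-9)
                # optimality on a sample of each candidate's own set
                for c in cands:
                    for lo_i, hi_i in c.set.intervals:
                        if not np.isfinite(lo_i) or not np.isfinite(hi_i):
                            continue
                        for mu in np.linspace(lo_i, hi_i, 5)[1:-1]:
                            mine = float(c(mu))
                            others = [float(o(mu)) for o in cands if o is not c]
                            assert mine <= min(others) + 1e-9 * (1 + abs(mine))

        # cross-check the replay against the production solver
        res = sd.fpop(ts, model, beta)
        np.testing.assert_allclose(F, res.F, rtol=1e-9, atol=1e-9)
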