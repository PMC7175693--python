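"""MAD standardisation, penalty construction, model selection over k, and
pruning diagnostics."""

import numpy as np
import pytest

import segdp as sd
from conftest import random_series


class TestMadStandardise:
    def test_consistency_on_pure_noise(self):
        ts = sd.generate(sd.SignalSpec(n=10_000, changepoints=(), means=(0.0,),
                                       sigma=1.0, seed=42))
        _, sigma_hat = sd.mad_standardise(ts)
        assert 0.95 <= sigma_hat <= 1.05

    def test_scale_equivariance(self, rng):
        ts = sd.TimeSeries.from_values(rng.normal(size=500))
        _, s1 = sd.mad_standardise(ts)
        _, s7 = sd.mad_standardise(sd.TimeSeries.from_values(7 * ts.values))
        assert s7 == pytest.approx(7 * s1, rel=1e-12)

    def test_shift_invariance(self, rng):
        ts = sd.TimeSeries.from_values(rng.normal(size=500))
        _, s1 = sd.mad_standardise(ts)
        _, s2 = sd.mad_standardise(sd.TimeSeries.from_values(ts.values + 100))
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_robust_to_sparse_jumps(self):
        """A few large mean shifts barely move the difference-based estimate."""
        ts = sd.generate(sd.SignalSpec(n=1000,
                                       changepoints=(200, 400, 600, 800),
                                       means=(0, 50, 0, 50, 0), sigma=1.0,
                                       seed=5))
        _, sigma_hat = sd.mad_standardise(ts)
        assert 0.9 <= sigma_hat <= 1.1

    def test_degenerate_signal_rejected(self):
        with pytest.raises(ValueError):
            sd.mad_standardise(sd.TimeSeries.from_values([1.0] * 50))

    def test_standardised_series_has_unit_scale(self, rng):
        ts = sd.TimeSeries.from_values(3.0 * rng.normal(size=2000))
        std, _ = sd.mad_standardise(ts)
        _, sigma_again = sd.mad_standardise(std)
        assert sigma_again == pytest.approx(1.0, rel=1e-9)


class TestPenaltySpec:
    def test_logn_form(self):
        assert sd.PenaltySpec("const_times_logn", 2.0).value(100) == \
            pytest.approx(2 * np.log(100))

    def test_parse_strings(self):
        assert sd.parse_penalty("2logn").value(50) == pytest.approx(2 * np.log(50))
        assert sd.parse_penalty("logn").constant == 1.0
        assert sd.parse_penalty("2.5*log(n)").constant == 2.5
        assert sd.parse_penalty(3.7).value(999) == 3.7
        assert sd.parse_penalty("4.2").value(10) == 4.2
        with pytest.raises(ValueError):
            sd.parse_penalty("two log n")

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            sd.PenaltySpec("explicit", -1.0)


class TestSelectK:
    def test_zero_penalty_picks_last_strict_minimum(self):
        C = np.array([10.0, 4.0, 2.0, 1.0])
        assert sd.select_k(C, 0.0, n=50) == 3

    def test_ties_go_to_smallest_k(self):
        C = np.array([10.0, 2.0, 2.0, 2.0])
        assert sd.select_k(C, 0.0, n=50) == 1

    def test_toy_step_with_unit_penalty(self, gaussian, toy_step):
        res = sd.segment_neighbourhood(toy_step, gaussian, K=3)
        assert sd.select_k(res.C[:, -1], 1.0, n=6) == 1

    def test_huge_penalty_picks_zero(self, gaussian, rng):
        ts = random_series(rng, 50, n_changes=2)
        res = sd.segment_neighbourhood(ts, gaussian, K=4)
        assert sd.select_k(res.C[:, -1], 1e9, n=50) == 0

    def test_reproduces_penalised_change_count(self, gaussian, rng):
        """Selecting k with f = beta k matches the penalised solver's count."""
        ts = random_series(rng, 120, n_changes=3)
        res = sd.segment_neighbourhood(ts, gaussian, K=8)
        for beta in [np.log(120), 2 * np.log(120)]:
            k_hat = sd.select_k(res.C[:, -1], beta, n=120)
            assert k_hat == sd.fpop(ts, gaussian, beta).changepoints.size


class TestVerifyDominance:
    def test_fpop_vs_pelt(self, gaussian, rng):
        ts = random_series(rng, 100, n_changes=2)
        beta = 2 * np.log(100)
        fp = sd.fpop(ts, gaussian, beta, keep_candidate_sets=True)
        pl = sd.pelt(ts, gaussian, beta, keep_candidate_sets=True)
        assert sd.verify_dominance(sd.PruningTrace.from_penalised(fp),
                                   sd.PruningTrace.from_penalised(pl))

    def test_solver_against_itself(self, gaussian, rng):
        ts = random_series(rng, 50)
        fp = sd.fpop(ts, gaussian, 5.0, keep_candidate_sets=True)
        tr = sd.PruningTrace.from_penalised(fp)
        assert sd.verify_dominance(tr, tr)

    def test_mismatched_traces_rejected(self, gaussian, rng):
        fp1 = sd.fpop(random_series(rng, 40), gaussian, 5.0,
                      keep_candidate_sets=True)
        fp2 = sd.fpop(random_series(rng, 60), gaussian, 5.0,
                      keep_candidate_sets=True)
        with pytest.raises(ValueError):
            sd.verify_dominance(sd.PruningTrace.from_penalised(fp1),
                                sd.PruningTrace.from_penalised(fp2))

    def test_trace_requires_recorded_sets(self, gaussian, rng):
        res = sd.fpop(random_series(rng, 30), gaussian, 5.0)
        with pytest.raises(ValueError):
            sd.PruningTrace.from_penalised(res)


class TestCandidateCountExperiment:
    def test_penalised_curves(self):
        df = sd.candidate_count_experiment(replicates=25, seed=11,
                                           problem="penalised")
        fpop_curve = df[df.solver == "fpop"].sort_values("step")["mean_count"]
        pelt_curve = df[df.solver == "pelt"].sort_values("step")["mean_count"]
        # functional pruning dominates pointwise, and by a clear margin at peak
        assert np.all(fpop_curve.to_numpy() <= pelt_curve.to_numpy() + 1e-12)
        assert fpop_curve.max() < pelt_curve.max()

    def test_constrained_curves(self):
        df = sd.candidate_count_experiment(replicates=10, seed=3,
                                           problem="constrained", K=4)
        for k in range(2, 5):
            sub = df[df.k == k]
            pdpa_curve = sub[sub.solver == "pdpa"].sort_values("step")["mean_count"]
            snip_curve = sub[sub.solver == "snip"].sort_values("step")["mean_count"]
            assert np.all(pdpa_curve.to_numpy() <= snip_curve.to_numpy() + 1e-12)

    def test_unknown_problem_rejected(self):
        with pytest.raises(ValueError):
            sd.candidate_count_experiment(problem="both")
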