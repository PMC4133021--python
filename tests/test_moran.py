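import numpy as np
import pytest

from symdrift import (
    MutationPathway,
    PopulationParams,
    estimate_risk_curve,
    moran_event,
    simulate_moran,
)
from symdrift.config import build_chain
from symdrift.moran import fixation_probability_mc
from symdrift.oracle import moran_absorption_probability


class TestEvent:
    def test_total_population_conserved(self, rng):
        pw = MutationPathway(rates=(0.1, 0.2))
        pp = PopulationParams(N=0, s=0.7, L=1.0, model="moran")
        counts = np.array([5, 3, 0], dtype=np.int64)
        for _ in range(300):
            counts = moran_event(counts, pw, pp, rng=rng)
            assert counts.sum() == 8
            assert (counts >= 0).all()

    def test_frozen_without_symmetry_or_mutation(self, rng):
        pw = MutationPathway(rates=(0.0,))
        pp = PopulationParams(N=0, s=0.0, L=1.0, model="moran")
        counts = np.array([4, 2], dtype=np.int64)
        out = moran_event(counts, pw, pp, rng=rng)
        assert (out == counts).all()

    def test_single_cell_pool_stays_single(self, rng):
        pw = MutationPathway(rates=(0.3,))
        pp = PopulationParams(N=1, s=1.0, L=1.0, model="moran")
        counts = np.array([1, 0], dtype=np.int64)
        for _ in range(50):
            counts = moran_event(counts, pw, pp, rng=rng)
            assert counts.sum() == 1


class TestNeutralDrift:
    def test_single_labeled_cell_fixes_with_probability_one_over_N(self):
        # classical neutral Moran result, via the pair-event semantics
        N, reps = 10, 120_000
        f = fixation_probability_mc(N, n_rep=reps, rng=13)
        se = np.sqrt((1 / N) * (1 - 1 / N) / reps)
        assert abs(f - 1.0 / N) < 3.0 * se


class TestFirstPassage:
    def test_zero_rates_never_succeed(self, rng):
        pw = MutationPathway(rates=(0.0,))
        pp = PopulationParams(N=20, s=1.0, L=500.0, model="moran")
        assert not simulate_moran(pw, pp, rng=rng).success

    def test_matches_exact_chain_tiny_pool(self, rng):
        # N=2, K=1, u=0.2: risk at L vs the uniformized event chain
        pw = MutationPathway(rates=(0.2,))
        pp = PopulationParams(N=2, s=0.6, L=10.0, model="moran")
        est = estimate_risk_curve(pw, pp, n_success_target=40_000,
                                  max_runs=40_000, rng=rng)
        exact = moran_absorption_probability((0.2,), 2, 10.0, 0.6)
        R, se = est.at(10.0)
        assert abs(R - exact) < 3.0 * max(se, 1e-4)

    def test_budget_exhaustion_is_flagged(self, rng):
        pw = MutationPathway(rates=(1e-4, 1e-3))
        pp = PopulationParams(N=500, s=1.0, L=5000.0, model="moran")
        res = simulate_moran(pw, pp, rng=rng, max_events=50)
        assert res.budget_exceeded and not res.success


class TestModelConcordance:
    def test_moran_and_branching_risks_agree_at_large_N(self, rng):
        # N >> s L / 2 so whole-pool extinction is negligible: the two
        # models must produce the same symmetric risk within MC error
        pw = MutationPathway(rates=(1e-5, 1e-3))
        runs = 1200
        risks = {}
        for model in ("moran", "branching"):
            pp = PopulationParams(N=2000, s=1.0, L=500.0, model=model)
            est = estimate_risk_curve(pw, pp, n_success_target=runs,
                                      max_runs=runs, rng=rng)
            risks[model] = est.at(500.0)
        (r1, se1), (r2, se2) = risks["moran"], risks["branching"]
        assert abs(r1 - r2) < 2.0 * np.hypot(se1, se2)

    def test_asymmetric_limit_matches_closed_form(self, rng):
        from symdrift import asymmetric_risk_closed_form

        pw = MutationPathway(rates=(1e-3,))
        pp = PopulationParams(N=50, s=0.0, L=200.0, model="moran")
        est = estimate_risk_curve(pw, pp, n_success_target=4000,
                                  max_runs=4000, rng=rng)
        R, se = est.at(200.0)
        exact = asymmetric_risk_closed_form((1e-3,), 50, 200)
        # continuous-time vs discrete-generation lineages differ at O(u)
        assert abs(R - exact) < 3.0 * se + 0.01


class TestSelection:
    def test_weak_selection_leaves_pf_unchanged(self, rng):
        # |selection coefficient| < 1/N is invisible to drift
        pw = MutationPathway(rates=(2e-4, 5e-3))
        pf = {}
        for tag, w in (("neutral", None), ("weak", (1.0, 1.0 + 0.002, 1.0))):
            pps = PopulationParams(N=100, s=1.0, L=400.0, model="moran",
                                   fitness=w)
            ppa = PopulationParams(N=100, s=0.0, L=400.0, model="moran",
                                   fitness=w)
            from symdrift import protection_factor

            asym = estimate_risk_curve(pw, ppa, n_success_target=600,
                                       max_runs=1500, rng=rng)
            sym = estimate_risk_curve(pw, pps, n_success_target=600,
                                      max_runs=1500, rng=rng)
            pf[tag] = protection_factor(asym, sym)
        diff = abs(pf["neutral"].PF - pf["weak"].PF)
        assert diff < 3.0 * np.hypot(pf["neutral"].SE, pf["weak"].SE)
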