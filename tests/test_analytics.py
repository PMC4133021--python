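import numpy as np
import pytest

from symdrift import (
    MutationPathway,
    PopulationParams,
    asymmetric_risk_closed_form,
    classify_regimes,
    clonal_drift_time,
    estimate_risk_curve,
    latency_distribution,
    lineage_mutation_probability,
    piecewise_pf,
    progression_time,
    scaled_metrics,
    scaling_curve,
    simulate_branching,
    stage_means,
    two_stage_symmetric_risk,
    unordered_two_locus_risk,
)
from symdrift.analytics import sequential_fixation_risk, success_hazard_integral
from symdrift.config import build_chain


def _clone_fate_mc(u, s, n, rng, L=50_000):
    """Brute-force fate of one fresh clone: (success fraction, mean time)."""
    pw = MutationPathway(rates=(u,))
    pp = PopulationParams(N=1, s=s, L=L)
    chain = build_chain(pw)
    succ, times = 0, []
    for _ in range(n):
        r = simulate_branching(pw, pp, rng=rng, chain=chain)
        if r.success:
            succ += 1
            times.append(r.T_K)
    return succ / n, float(np.mean(times))


class TestStageMeans:
    def test_initial_condition(self):
        n = stage_means((1e-3, 1e-2), 500, 0.0)
        assert n[0] == 500 and n[1] == 0 and n[2] == 0

    def test_leading_order_single_stage(self):
        # n_1(t) ~ N u0 t while u0 t << 1
        n = stage_means((1e-6,), 1e4, 100.0)
        assert n[1] == pytest.approx(1e4 * 1e-6 * 100, rel=1e-3)

    def test_mass_conserved(self):
        n = stage_means((1e-3, 1e-2, 0.05), 100, 300.0)
        assert n.sum() == pytest.approx(100.0, rel=1e-9)

    def test_matches_asymmetric_simulation_mean(self, rng):
        # mean stage-1 occupancy at t=1000 vs the flux solution
        N, u0, L, reps = 10_000, 1e-6, 1000.0, 120
        pw = MutationPathway(rates=(u0, 0.0))
        pp = PopulationParams(N=N, s=0.0, L=L)
        chain = build_chain(pw)
        vals = []
        for _ in range(reps):
            r = simulate_branching(pw, pp, rng=rng, chain=chain,
                                   record_trajectory=True)
            vals.append(r.trajectory[-1, 1])
        mean_pred = stage_means((u0, 0.0), N, L)[1]
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - mean_pred) < 3.0 * se


class TestCloneFate:
    def test_zero_rate_gives_zero_probability(self):
        assert lineage_mutation_probability(0.0, 1.0) == 0.0

    def test_asymmetric_limit_flagged(self):
        with pytest.warns(UserWarning):
            assert lineage_mutation_probability(1e-3, 0.0) == 1.0

    def test_leading_order_sqrt_form(self):
        # p ~ sqrt(2u/s) for u << s, so clones extinguish while u << s
        for u, s in [(1e-6, 1.0), (1e-5, 0.5)]:
            p = lineage_mutation_probability(u, s)
            assert p == pytest.approx(np.sqrt(2 * u / s), rel=0.01)

    @pytest.mark.parametrize("u,s", [(1e-3, 1.0), (1e-2, 1.0), (1e-3, 0.1)])
    def test_probability_matches_clone_simulation(self, u, s, rng):
        n = 60_000
        p_mc, _ = _clone_fate_mc(u, s, n, rng)
        p = lineage_mutation_probability(u, s)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_mc - p) < 3.0 * se + 2e-4

    @pytest.mark.parametrize("u,s", [(1e-3, 1.0), (1e-3, 0.1)])
    def test_drift_time_matches_clone_simulation(self, u, s, rng):
        _, tau_mc = _clone_fate_mc(u, s, 40_000, rng)
        tau = clonal_drift_time(u, s)
        assert tau == pytest.approx(tau_mc, rel=0.10)

    def test_drift_time_leading_order(self):
        u, s = 1e-6, 1.0
        assert clonal_drift_time(u, s) == pytest.approx(
            np.log(2) * np.sqrt(2 / (s * u)), rel=0.01
        )

    def test_hazard_integral_limits(self):
        u, s = 1e-3, 1.0
        # early: u t^2/2; late: p (t - tau)
        assert success_hazard_integral(3.0, u, s) == pytest.approx(
            u * 9 / 2, rel=0.05
        )
        # the integral's late-time slope is the continuous-limit success
        # probability (the discrete fixed point differs at O(sqrt(u)))
        p_cont = (np.sqrt(u * u + 2 * s * u) - u) / s
        tau = clonal_drift_time(u, s)
        t = 5000.0
        assert success_hazard_integral(t, u, s) == pytest.approx(
            p_cont * (t - tau), rel=0.02
        )


class TestAsymmetricClosedForm:
    def test_zero_rates(self):
        assert asymmetric_risk_closed_form((0.0, 0.0), 100, 500) == 0.0

    def test_geometric(self):
        assert asymmetric_risk_closed_form((0.1,), 1, 50) == pytest.approx(
            1 - 0.9**50, rel=1e-12
        )

    def test_matches_branching_simulation(self, rng):
        # slow-then-fast pathway in a large pool
        N, L = 10_000, 500
        pw = MutationPathway(rates=(1e-6, 1e-2))
        pp = PopulationParams(N=N, s=0.0, L=L)
        est = estimate_risk_curve(pw, pp, n_success_target=800,
                                  max_runs=1600, rng=rng)
        R, se = est.at(L)
        exact = asymmetric_risk_closed_form((1e-6, 1e-2), N, L)
        assert abs(R - exact) < 3.0 * se

    def test_monotone_in_time_rates_and_N(self):
        base = asymmetric_risk_closed_form((1e-4, 1e-3), 1000, 1000)
        assert asymmetric_risk_closed_form((1e-4, 1e-3), 1000, 2000) > base
        assert asymmetric_risk_closed_form((2e-4, 1e-3), 1000, 1000) > base
        assert asymmetric_risk_closed_form((1e-4, 1e-3), 2000, 1000) > base


class TestTwoStageRisk:
    def test_reference_point_against_moran(self, rng):
        # N=1e3, u0=1e-6, u1=1e-3, L=1e3
        pw = MutationPathway(rates=(1e-6, 1e-3))
        pp = PopulationParams(N=1000, s=1.0, L=1000.0, model="moran")
        est = estimate_risk_curve(pw, pp, n_success_target=300,
                                  max_runs=6000, rng=rng)
        R, se = est.at(1000.0)
        pred = two_stage_symmetric_risk(1000, 1e-6, 1e-3, 1000.0)
        assert abs(R - pred) < 3.0 * se + 0.1 * pred

    def test_reduces_to_asymmetric_form_at_s0(self):
        r = two_stage_symmetric_risk(1000, 1e-6, 1e-3, 1000.0, s=0.0)
        exact = asymmetric_risk_closed_form((1e-6, 1e-3), 1000, 1000)
        assert r == pytest.approx(exact, rel=0.02)


class TestRegimesAndPF:
    def test_regime_labels(self):
        reg = classify_regimes(1000, 1e-6, 1e-3, 1000.0)
        assert reg.symmetric == "ST"
        reg2 = classify_regimes(10, 1e-6, 1e-4, 1000.0)
        assert reg2.symmetric == "SF"

    def test_progression_time_sequential_fixation(self):
        # post-fixation waiting dominates: 1/(N u) = 1e3 cycles
        tau = progression_time(10, 1e-4, s=1.0, regime="SF")
        assert 1.0e3 <= tau <= 1.3e3

    def test_progression_time_requires_regime(self):
        with pytest.raises(ValueError):
            progression_time(10, 1e-4)

    def test_progression_time_fast_mutation_limit(self):
        # u -> 1: progression within a few cell cycles
        assert progression_time(100, 0.9, s=1.0, regime="ST") < 3.0

    def test_pf_vanishes_in_slowly_cycling_tissue(self):
        res = piecewise_pf(1000, 1e-2, 1e-3, 20.0)
        assert res.PF == pytest.approx(1.0, abs=0.25)

    def test_pf_vanishes_for_tiny_secondary_rate(self):
        # u1 << 1/L^2 removes all protection
        res = piecewise_pf(1000, 1e-6, 1e-8, 1000.0)
        assert res.PF == pytest.approx(1.0, abs=0.15)

    def test_protected_point_accuracy_vs_simulation(self, rng):
        # protected reference point: analytic PF within 40% of simulated
        from symdrift import protection_factor

        pw = MutationPathway(rates=(1e-6, 1e-3))
        ppa = PopulationParams(N=1000, s=0.0, L=1000.0, model="moran")
        pps = PopulationParams(N=1000, s=1.0, L=1000.0, model="moran")
        asym = estimate_risk_curve(pw, ppa, n_success_target=400,
                                   max_runs=2000, rng=rng)
        sym = estimate_risk_curve(pw, pps, n_success_target=400,
                                  max_runs=4000, rng=rng)
        pf_sim = protection_factor(asym, sym)
        res = piecewise_pf(1000, 1e-6, 1e-3, 1000.0)
        assert pf_sim.PF > 2.0
        assert abs(res.PF - pf_sim.PF) / pf_sim.PF < 0.40


class TestScaledMetrics:
    def test_zero_rate_scales_to_zero(self):
        m = scaled_metrics((1e-6, 0.0), 1000, 1000.0)
        assert m.u_hat[1] == 0.0

    def test_highly_protected_pathway_has_stochastic_stages(self):
        # slow-slow-fast-fast four-step pathway at ~50% lifetime risk:
        # stages 1..3 are all extinction-dominated under full symmetry
        rates = (1e-7, 1e-4, 5e-3, 5e-3)
        L = 1000.0
        # pick N so the asymmetric lifetime risk is ~50%
        lo, hi = 1.0, 1e9
        for _ in range(60):
            N = np.sqrt(lo * hi)
            if asymmetric_risk_closed_form(rates, N, L) < 0.5:
                lo = N
            else:
                hi = N
        m = scaled_metrics(rates, N, L, s=1.0)
        assert m.n_stochastic == 3
        assert (m.theta[1:] < 1.0).all()

    def test_deterministic_stage_tracks_mean(self):
        # theta >= 1 stages follow the flux solution
        m = scaled_metrics((1e-2, 1e-6), 10_000, 1000.0)
        assert m.theta[1] >= 1.0
        assert m.n_stochastic == 0

    def test_scaling_collapse_on_half_risk_surface(self):
        # theta ~ K ln2 / sqrt(u_hat) when the lifetime risk is ~50%
        L, N = 1000.0, 10_000
        for u1 in (1e-4, 1e-3):
            lo, hi = 1e-12, 1e-2
            for _ in range(80):
                u0 = np.sqrt(lo * hi)
                if asymmetric_risk_closed_form((u0, u1), N, L) < 0.5:
                    lo = u0
                else:
                    hi = u0
            m = scaled_metrics((u0, u1), N, L, s=1.0)
            pred = scaling_curve(m.u_hat[1], K=2)
            assert m.theta[1] == pytest.approx(pred, rel=0.35)


class TestUnorderedLoci:
    def test_identical_rates_double_the_ordered_route(self):
        # two equal independent loci: twice the single-route risk at
        # leading order (route multiplicity)
        a, N, L = 1e-4, 100, 200
        r_unord = unordered_two_locus_risk(a, a, N, L, s=0.0)
        q_ord = asymmetric_risk_closed_form((a, a), N, L)
        assert r_unord == pytest.approx(2.0 * q_ord, rel=0.05)

    def test_fast_slow_pair_shows_little_protection(self, rng):
        # rates 1e-6 and 1e-2 in a 1e4-cell pool: most double mutants come
        # via the unprotected fast-slow route, so symmetric and asymmetric
        # risks nearly coincide at the ~50% asymmetric-risk time
        N, L = 10_000, 2000.0
        pw = MutationPathway(mode="unordered_independent",
                             locus_rates={"A": 1e-6, "B": 1e-2})
        asym = estimate_risk_curve(
            pw, PopulationParams(N=N, s=0.0, L=L),
            n_success_target=300, max_runs=700, rng=rng)
        sym = estimate_risk_curve(
            pw, PopulationParams(N=N, s=1.0, L=L),
            n_success_target=300, max_runs=700, rng=rng)
        from symdrift import protection_factor

        pf = protection_factor(asym, sym)
        assert pf.PF < 1.6

    def test_symmetric_formula_matches_branching(self, rng):
        # composite route formula vs simulation along the rising curve
        N, L = 10_000, 2000.0
        pw = MutationPathway(mode="unordered_independent",
                             locus_rates={"A": 1e-6, "B": 1e-2})
        pp = PopulationParams(N=N, s=1.0, L=L)
        est = estimate_risk_curve(pw, pp, n_success_target=1200,
                                  max_runs=1200, rng=rng)
        for tq in (100.0, 200.0, 400.0):
            R, se = est.at(tq)
            pred = unordered_two_locus_risk(1e-6, 1e-2, N, L, s=1.0, t=tq)
            assert abs(R - pred) < 3.0 * se + 0.15 * pred, tq


class TestLatency:
    def test_vanishing_hazard_concentrates_on_no_event(self):
        t, pmf = latency_distribution(1000, 1e-9, 1e-9, 500, "ST")
        assert pmf.sum() < 1e-3

    def test_increasing_rates_are_overdispersed_at_matched_mean(self):
        # match the mean first-passage time, compare variances
        N, L = 10_000, 20_000
        t_inc, p_inc = latency_distribution(N, 1e-6, 1e-2, L, "ST")
        mean_inc = (t_inc * p_inc).sum() / p_inc.sum()
        # decreasing pair tuned to the same mean (Rayleigh-like form)
        u0d = 1e-4
        u1d = np.pi / (2.0 * mean_inc**2 * N * u0d)
        t_dec, p_dec = latency_distribution(N, u0d, u1d, L, "deterministic")
        mean_dec = (t_dec * p_dec).sum() / p_dec.sum()
        assert mean_dec == pytest.approx(mean_inc, rel=0.05)
        var_inc = ((t_inc - mean_inc) ** 2 * p_inc).sum() / p_inc.sum()
        var_dec = ((t_dec - mean_dec) ** 2 * p_dec).sum() / p_dec.sum()
        assert var_inc > 1.5 * var_dec

    def test_tunneling_pmf_matches_simulated_latencies(self, rng):
        from scipy.stats import ks_2samp

        N, L = 10_000, 20_000
        pw = MutationPathway(rates=(1e-6, 1e-2))
        pp = PopulationParams(N=N, s=1.0, L=L)
        chain = build_chain(pw)
        times = []
        while len(times) < 500:
            r = simulate_branching(pw, pp, rng=rng, chain=chain)
            if r.success:
                times.append(r.T_K)
        t, pmf = latency_distribution(N, 1e-6, 1e-2, L, "ST")
        pmf = pmf / pmf.sum()
        model_draws = np.random.default_rng(0).choice(t, size=4000, p=pmf)
        stat, pval = ks_2samp(times, model_draws)
        assert stat < 0.08
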