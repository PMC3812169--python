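"""Agent-based simulator: update semantics, conservation laws, oracles."""

import math

import numpy as np
import pytest

from stemtunnel import (
    ModelParams,
    PopulationState,
    abm_step,
    estimate_hit_probability,
    moran_fixation_fraction,
    run_hit_times,
    run_until_double_hit,
    transition_probabilities,
    tunneling_rate,
)


def make(**kw):
    base = dict(N=100, S_target=20, nu=1.0, r=1.0, u1=1e-3, u2=1e-3,
                p_stem=0.5, T_max=2000)
    base.update(kw)
    return ModelParams(**base)


class TestAbmStep:
    def test_population_conserved(self):
        p = make()
        rng = np.random.default_rng(0)
        st = PopulationState.initial(p)
        for _ in range(3000):
            if st.hit:
                break
            abm_step(st, p, rng)
            if not st.hit:
                assert st.S0 + st.S1 + st.D0 + st.D1 == p.N

    def test_no_mutation_channel_stays_wild_type(self):
        p = make(u1=0.0, u2=0.0)
        rng = np.random.default_rng(1)
        st = PopulationState.initial(p)
        for _ in range(2000):
            abm_step(st, p, rng)
        assert st.S1 == 0 and st.D1 == 0 and not st.hit

    def test_asymmetric_divisions_preserve_stem_count(self):
        p = make(nu=0.0, u1=5e-3)
        rng = np.random.default_rng(2)
        st = PopulationState.initial(p)
        for _ in range(3000):
            if st.hit:
                break
            s_before = st.S0 + st.S1
            abm_step(st, p, rng)
            if not st.hit:
                assert st.S0 + st.S1 == s_before

    def test_stepping_an_absorbed_state_errors(self):
        p = make()
        st = PopulationState.initial(p)
        st.hit = True
        with pytest.raises(ValueError):
            abm_step(st, p, np.random.default_rng(0))

    @pytest.mark.parametrize("m,n", [(0, 1), (1, 0)])
    def test_one_step_frequencies_match_analytic_classes(self, m, n):
        """Empirical one-update class frequencies vs the reduced chain.

        Compound symmetric-pair outcomes (class ``other``) span two
        elementary updates and cannot be observed after a single step, so
        the mass of all m-raising / compound outcomes (m_up + hit + other)
        is compared pooled; the elementary classes are compared one by one.
        """
        p = ModelParams(N=50, S_target=10, nu=1.0, r=1.0, u1=1e-2, u2=1e-2,
                        T_max=100)
        ts = transition_probabilities(m, n, p)
        rng = np.random.default_rng(42)
        nrep = 100_000
        counts = dict(n_up=0, n_down=0, diff_pair=0, pooled=0)
        for _ in range(nrep):
            st = PopulationState(S0=10 - m, S1=m, D0=40 - n, D1=n,
                                 t_updates=0, hit=False)
            abm_step(st, p, rng)
            dm, dn = st.S1 - m, st.D1 - n
            if st.hit or dm >= 1:
                counts["pooled"] += 1
            elif dm == 0 and dn == 1:
                counts["n_up"] += 1
            elif dm == 0 and dn == -1:
                counts["n_down"] += 1
            elif dm == -1 and dn == 2:
                counts["diff_pair"] += 1
        expected = dict(n_up=ts.n_up, n_down=ts.n_down, diff_pair=ts.diff_pair,
                        pooled=ts.m_up + ts.hit + ts.other)
        for cls, exp in expected.items():
            emp = counts[cls] / nrep
            se = math.sqrt(max(exp * (1 - exp), 1e-12) / nrep)
            assert abs(emp - exp) <= 3 * se + 1e-9, (cls, emp, exp)


class TestKernelMatchesReferenceStep:
    def test_hit_fraction_agrees_between_kernel_and_python_step(self):
        """The JIT kernel and the pure-Python reference step implement the
        same process: their hit fractions agree within Monte-Carlo error."""
        p = ModelParams(N=30, S_target=6, nu=0.7, r=1.2, u1=1e-2, u2=1e-2,
                        p_stem=0.3, T_max=400)
        n = 2000
        hits_py = 0
        rng = np.random.default_rng(77)
        for _ in range(n):
            st = PopulationState.initial(p)
            for _ in range(p.T_max):
                abm_step(st, p, rng)
                if st.hit:
                    break
            hits_py += st.hit
        hits_k = sum(run_until_double_hit(p, seed=s).hit
                     for s in range(1000, 1000 + n))
        f_py, f_k = hits_py / n, hits_k / n
        pool = 0.5 * (f_py + f_k)
        se = math.sqrt(2 * pool * (1 - pool) / n)
        assert abs(f_py - f_k) <= 3 * se


class TestRunUntilDoubleHit:
    def test_no_first_hit_channel_never_absorbs(self):
        res = run_until_double_hit(make(u1=0.0, T_max=5000), seed=5)
        assert not res.hit and res.t_updates == 5000

    def test_certain_mutations_absorb_quickly(self):
        res = run_until_double_hit(
            ModelParams(N=10, S_target=2, nu=1.0, r=1.0, u1=1.0, u2=1.0,
                        T_max=1000), seed=6)
        assert res.hit and res.t_updates <= 10

    def test_censored_runs_stop_exactly_at_horizon(self):
        p = make(u1=1e-6, u2=1e-6, T_max=500)
        for seed in range(5):
            res = run_until_double_hit(p, seed=seed)
            assert res.t_updates == 500 or res.hit

    def test_compartment_of_hit_recorded(self):
        hits = set()
        p = ModelParams(N=30, S_target=6, nu=1.0, r=1.0, u1=5e-2, u2=5e-2,
                        T_max=3000)
        for seed in range(40):
            res = run_until_double_hit(p, seed=seed)
            if res.hit:
                hits.add(res.compartment_of_hit)
        assert hits <= {"stem", "TA"} and hits


class TestEstimateHitProbability:
    def test_deterministic_given_master_seed(self):
        p = make(T_max=500)
        a = estimate_hit_probability(p, runs_per_batch=100, n_batches=3,
                                     master_seed=9)
        b = estimate_hit_probability(p, runs_per_batch=100, n_batches=3,
                                     master_seed=9)
        assert a.p_hat == b.p_hat and a.sd == b.sd
        assert np.array_equal(a.batch_fractions, b.batch_fractions)

    def test_no_first_hit_gives_zero(self):
        s = estimate_hit_probability(make(u1=0.0, T_max=300),
                                     runs_per_batch=50, n_batches=2,
                                     master_seed=0)
        assert s.p_hat == 0.0 and s.sd == 0.0

    def test_hit_probability_non_increasing_in_nu(self):
        p = ModelParams(N=100, S_target=30, nu=0.0, r=1.0, u1=1e-3, u2=1e-2,
                        T_max=10_000)
        stats = [estimate_hit_probability(p.with_(nu=v), 1000, 10,
                                          master_seed=40 + i)
                 for i, v in enumerate([0.0, 0.25, 0.5, 0.75, 1.0])]
        for a, b in zip(stats, stats[1:]):
            assert b.p_hat <= a.p_hat + 3 * (a.sd + b.sd)

    def test_ordering_against_homogeneous_model(self):
        """Purely asymmetric tissue beats the homogeneous model to the double
        hit; the fully symmetric tissue at r=1 is slower than homogeneous."""
        p = ModelParams(N=100, S_target=30, nu=0.0, r=1.0, u1=1e-3, u2=1e-2,
                        T_max=10_000)
        s_asym = estimate_hit_probability(p, 1000, 10, master_seed=51)
        s_sym = estimate_hit_probability(p.with_(nu=1.0), 1000, 10,
                                         master_seed=52)
        s_hom = estimate_hit_probability(p.with_(S_target=0), 1000, 10,
                                         master_seed=53)
        assert s_asym.p_hat - s_hom.p_hat > 3 * (s_asym.sd + s_hom.sd)
        assert s_hom.p_hat - s_sym.p_hat > 3 * (s_hom.sd + s_sym.sd)


class TestHomeostasis:
    @staticmethod
    def _exact_stationary_mean(s_target: int) -> float:
        """Mean of the exact stationary law of the S birth-death walk.

        With u1 = 0 and nu = 1 the stem count moves +1 at relative rate
        S (1 - S/2S_t) and -1 at rate S * S/2S_t (the stem-divider choice
        factor cancels), giving detailed-balance weights on {1, ..., 2S_t}.
        """
        log_pi, vals = [0.0], [1]
        for s in range(1, 2 * s_target):
            up = s * (1.0 - s / (2.0 * s_target))
            down = (s + 1) * ((s + 1) / (2.0 * s_target))
            log_pi.append(log_pi[-1] + math.log(up / down))
            vals.append(s + 1)
        w = np.exp(np.array(log_pi) - max(log_pi))
        w /= w.sum()
        return float(np.dot(vals, w))

    def test_time_average_matches_stationary_oracle(self):
        p = ModelParams(N=200, S_target=40, nu=1.0, r=1.0, u1=0.0, u2=0.0,
                        T_max=10)
        rng = np.random.default_rng(3)
        st = PopulationState.initial(p)
        vals = np.empty(120_000)
        for i in range(120_000):
            abm_step(st, p, rng)
            vals[i] = st.S0 + st.S1
        burn = vals[20_000:]
        batch_means = burn.reshape(20, -1).mean(axis=1)
        se = batch_means.std(ddof=1) / math.sqrt(20)
        exact = self._exact_stationary_mean(40)
        assert abs(burn.mean() - exact) <= 3 * se
        # loose homeostasis: the long-run average sits near the target
        assert abs(burn.mean() - 40) <= 0.05 * 40


class TestMoranFixation:
    @staticmethod
    def _variant_fixation(n: int, r: float) -> float:
        """Fixation probability of the death-first Moran variant.

        One cell dies uniformly; the divider is fitness-chosen among the
        remaining n-1, so the down/up ratio from i mutants is
        (r i + n - i - 1) / (r (r (i-1) + n - i)) rather than 1/r.
        """
        prod, total = 1.0, 1.0
        for i in range(1, n):
            prod *= (r * i + n - i - 1) / (r * (r * (i - 1) + n - i))
            total += prod
        return 1.0 / total

    def test_neutral_fixation_is_one_over_n(self):
        f = moran_fixation_fraction(20, 1.0, n_runs=20_000, master_seed=3)
        se = math.sqrt(0.05 * 0.95 / 20_000)
        assert abs(f - 1 / 20) <= 3 * se

    @pytest.mark.parametrize("r", [1.2, 0.8])
    def test_selected_fixation_matches_variant_formula(self, r):
        f = moran_fixation_fraction(20, r, n_runs=20_000, master_seed=3)
        exact = self._variant_fixation(20, r)
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(f - exact) <= 3 * se


class TestWaitingTimeLaw:
    def test_hit_times_exponential_mean_and_cv(self):
        """First-hit times at small rates: mean 1/R_total, unit CV."""
        p = ModelParams(N=100, S_target=20, nu=1.0, r=1.0, u1=3e-4, u2=1e-2,
                        T_max=1_000_000)
        rate = tunneling_rate(p)[0]
        times, hit = run_hit_times(p, n_runs=1500, master_seed=22)
        t_hit = times[hit]
        n = len(t_hit)
        assert hit.mean() > 0.99
        mean, sd = t_hit.mean(), t_hit.std(ddof=1)
        assert abs(mean - 1.0 / rate) <= 3 * sd / math.sqrt(n)
        cv = sd / mean
        assert abs(cv - 1.0) <= 3.0 / math.sqrt(n)
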