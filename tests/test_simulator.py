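"""Wright-Fisher engine: update rule, rate draws, migration, treatment,
gene-level pooling, and exactness of the event-driven implementation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lethalpop.demography import constant_size_model
from lethalpop.simulate import (
    GeneConfig,
    SelectionParams,
    SiteConfig,
    _post_selection_freq,
    _ztrunc_binomial,
    apply_treatment,
    draw_mutation_rate,
    migrate,
    paired_treatment_comparison,
    simulate_gene,
    simulate_site,
    wf_step,
)


class TestMutationRateDraws:
    def test_sigma_zero_is_degenerate(self, rng):
        assert draw_mutation_rate(1.5e-8, 0.0, rng) == 1.5e-8
        assert np.all(draw_mutation_rate(1.5e-8, 0.0, rng, 5) == 1.5e-8)

    def test_mean_preserving_offset(self, rng):
        m = draw_mutation_rate(1.5e-8, 0.57, rng, 1_000_000)
        assert m.mean() == pytest.approx(1.5e-8, rel=0.01)

    def test_median_matches_closed_form(self, rng):
        m = draw_mutation_rate(1.5e-8, 0.57, rng, 1_000_000)
        med_expected = 1.5e-8 * 10 ** (-0.57**2 * math.log(10) / 2)
        assert med_expected == pytest.approx(6.34e-9, rel=1e-3)
        assert np.median(m) == pytest.approx(med_expected, rel=0.01)

    def test_domain_errors(self, rng):
        with pytest.raises(ValueError):
            draw_mutation_rate(0.0, 0.5, rng)
        with pytest.raises(ValueError):
            draw_mutation_rate(1e-8, -1.0, rng)


class TestWfStep:
    def test_absorbing_at_zero_without_mutation(self, rng):
        q = np.zeros(1000)
        for _ in range(50):
            q = wf_step(q, 100, 0.0, SelectionParams(), rng)
            assert np.all(q == 0.0)

    def test_lethality_corner_all_homozygotes_die(self, rng):
        # q = 1 with s = 1, h = 0: no heterozygotes exist, allele goes extinct
        q = wf_step(np.ones(100), 50, 0.0, SelectionParams(s=1.0, h=0.0), rng)
        assert np.all(q == 0.0)

    def test_frequencies_stay_in_unit_interval(self, rng):
        q = rng.random(500)
        for _ in range(30):
            q = wf_step(q, 40, 1e-3, SelectionParams(s=0.6, h=0.1), rng)
            assert np.all((q >= 0) & (q <= 1))

    def test_selection_free_step_preserves_mean(self, rng):
        # s = 0: drift is a martingale, E[q'] = q after mutation only
        q0 = 0.3
        q = wf_step(np.full(200_000, q0), 1_000, 0.0, SelectionParams(s=0.0), rng)
        assert q.mean() == pytest.approx(q0, abs=3 * math.sqrt(q0 * (1 - q0) / 2000) / math.sqrt(200_000))


class TestSelectionOperator:
    def test_recessive_lethal_removes_homozygotes(self):
        # q_s = q(1-q) w_Aa / wbar for h = 0, s = 1
        q = 0.2
        expected = (q * (1 - q)) / ((1 - q) ** 2 + 2 * q * (1 - q))
        assert _post_selection_freq(q, 1.0, 0.0) == pytest.approx(expected)

    def test_neutral_identity(self):
        q = np.linspace(0, 1, 11)
        assert _post_selection_freq(q, 0.0, 0.0) == pytest.approx(q)

    def test_degenerate_mean_fitness_resolves_to_extinction(self):
        assert _post_selection_freq(1.0, 1.0, 0.0) == 0.0


class TestMigration:
    def test_zero_rate_identity(self):
        assert migrate(0.2, 0.05, 0.0, 0.0) == (0.2, 0.05)

    def test_full_mixing_limit(self):
        qa, qe = migrate(0.2, 0.0, 0.499999, 0.499999)
        assert qa == pytest.approx(0.1, rel=1e-4)
        assert qe == pytest.approx(0.1, rel=1e-4)

    def test_equal_frequencies_are_fixed_point(self):
        qa, qe = migrate(0.37, 0.37, 0.2, 0.05)
        assert qa == pytest.approx(0.37)
        assert qe == pytest.approx(0.37)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            migrate(0.1, 0.1, 0.5, 0.1)


class TestTruncatedBinomialSampler:
    def test_matches_conditional_mean(self, rng):
        n2, q = 1_000, 2e-3
        draws = _ztrunc_binomial(n2, np.full(200_000, q), rng)
        assert np.all(draws >= 1)
        cond_mean = n2 * q / (1 - (1 - q) ** n2)
        assert draws.mean() == pytest.approx(cond_mean, rel=0.01)


class TestExactChainOracle:
    def test_stationary_mean_matches_exact_markov_chain(self):
        """A scaled-up tiny instance (2N = 20, u = 1e-3, recessive lethal) has
        a tractable 21-state transition matrix; the simulator's long-run mean
        frequency must match the exact stationary mean within 2%."""
        n2, u = 20, 1e-3
        k = np.arange(n2 + 1)
        q_m = k / n2 + (1 - k / n2) * u
        q_s = _post_selection_freq(q_m, 1.0, 0.0)
        T = sps.binom.pmf(k[None, :], n2, q_s[:, None])
        evals, evecs = np.linalg.eig(T.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        pi /= pi.sum()
        mean_exact = float(pi @ (k / n2))

        rng = np.random.default_rng(1)
        sel = SelectionParams()
        q = np.zeros(30_000)
        for _ in range(1_500):
            q = wf_step(q, n2 // 2, u, sel, rng)
        acc = 0.0
        for _ in range(1_500):
            q = wf_step(q, n2 // 2, u, sel, rng)
            acc += q.mean()
        assert acc / 1_500 == pytest.approx(mean_exact, rel=0.02)


class TestEventDrivenExactness:
    def test_engine_agrees_with_naive_iteration(self):
        """The dormancy-skipping engine and generation-by-generation wf_step
        iteration sample the same process: their equilibrium means and
        segregating fractions agree within Monte-Carlo error."""
        N, u, R = 300, 2e-5, 6_000
        model = constant_size_model(N)
        df = simulate_site(
            model,
            SiteConfig(u=u, sigma=0.0, rate_mode="fixed", replicates=R, seed=99),
        )
        rng = np.random.default_rng(990)
        sel = SelectionParams()
        q = np.zeros(R)
        for _ in range(model.total_generations):
            q = wf_step(q, N, u, sel, rng)
        se = math.sqrt(df.q_EUR.var() / R + q.var() / R)
        assert df.q_EUR.mean() == pytest.approx(q.mean(), abs=3 * se)
        se_seg = math.sqrt(2 * 0.25 / R)
        assert df.segregating.mean() == pytest.approx((q > 0).mean(), abs=3 * se_seg)


class TestMonotonicity:
    @pytest.fixture(scope="class")
    def tiny_runs(self):
        model = constant_size_model(2_000)
        cfg = SiteConfig(u=2e-5, sigma=0.0, rate_mode="fixed", replicates=6_000, seed=7)

        def run(s, h):
            return float(simulate_site(model, cfg, SelectionParams(s=s, h=h)).q_EUR.mean())

        return run

    def test_mean_frequency_non_increasing_in_h(self, tiny_runs):
        m = [tiny_runs(1.0, h) for h in (0.0, 0.01, 0.5)]
        assert m[0] > m[2]  # strong dominance clearly suppresses the allele
        assert m[0] >= m[1] * 0.9  # weak dominance: allow Monte-Carlo slack
        assert m[1] >= m[2]

    def test_mean_frequency_non_increasing_in_s(self, tiny_runs):
        assert tiny_runs(0.3, 0.0) > tiny_runs(1.0, 0.0)


class TestReproducibility:
    def test_same_seed_same_output(self):
        model = constant_size_model(400, 20)
        cfg = SiteConfig(u=1e-5, sigma=0.57, replicates=500, seed=42)
        a = simulate_site(model, cfg)
        b = simulate_site(model, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        model = constant_size_model(400, 20)
        a = simulate_site(model, SiteConfig(u=1e-5, replicates=500, seed=1))
        b = simulate_site(model, SiteConfig(u=1e-5, replicates=500, seed=2))
        assert not a.q_EUR.equals(b.q_EUR)


class TestGeneLevel:
    def test_single_site_gene_identical_to_site_run(self):
        model = constant_size_model(400, 20)
        site = simulate_site(model, SiteConfig(u=1e-5, sigma=0.57, replicates=400, seed=5))
        gene = simulate_gene(model, GeneConfig(site_rates=(1e-5,), sigma=0.57,
                                               replicates=400, seed=5))
        pd.testing.assert_frame_equal(site, gene)

    def test_fixed_rates_sum_exactly(self):
        model = constant_size_model(300, 10)
        gene = simulate_gene(
            model,
            GeneConfig(site_rates=(1e-5, 2e-5, 3e-5), rate_mode="fixed",
                       replicates=50, seed=3),
        )
        assert gene.drawn_rate.to_numpy() == pytest.approx(np.full(50, 6e-5))

    def test_empty_rate_list_rejected(self):
        with pytest.raises(ValueError):
            GeneConfig(site_rates=())


class TestTreatment:
    def test_schedule(self):
        sched = apply_treatment(SelectionParams(s=1.0, treatment_generations=3), 10)
        assert list(sched) == [0.0] * 3 + [1.0] * 7

    def test_schedule_rejects_overlong_window(self):
        with pytest.raises(ValueError):
            apply_treatment(SelectionParams(treatment_generations=11), 10)

    def test_no_treatment_window_is_plain_run(self):
        model = constant_size_model(400, 20)
        cfg = SiteConfig(u=1e-5, replicates=300, seed=8)
        plain = simulate_site(model, cfg, SelectionParams())
        zero_window = simulate_site(model, cfg, SelectionParams(treatment_generations=0))
        pd.testing.assert_frame_equal(plain, zero_window)

    def test_already_neutral_alleles_unaffected(self):
        # s = 0 in both branches: the paired endings are byte-identical
        model = constant_size_model(400, 20)
        cfg = SiteConfig(u=1e-5, replicates=500, seed=9)
        table = paired_treatment_comparison(model, cfg, SelectionParams(s=0.0),
                                            treatment_generations=3, n_groups=2)
        assert np.all(table.mean_control == table.mean_treated)


class TestDistributionVsEquivalentConstantSize:
    def test_same_mean_different_shape(self, tennessen_run):
        """A constant population sized to reproduce the demographic model's
        mean frequency still has a distinguishably different frequency
        distribution (two-sample test rejects)."""
        from lethalpop.analytic import equivalent_constant_N

        _, mean_h0, q_tennessen = tennessen_run
        n_eq = equivalent_constant_N(mean_h0, 1.5e-8, 1.0)
        cfg = SiteConfig(u=1.5e-8, sigma=0.57, rate_mode="lognormal",
                         replicates=15_000, seed=35651)
        q_const = simulate_site(constant_size_model(n_eq), cfg).q_EUR.to_numpy()

        se = math.sqrt(q_const.var() / q_const.size + q_tennessen.var() / q_tennessen.size)
        assert q_const.mean() == pytest.approx(q_tennessen.mean(), abs=3 * se)
        ks = sps.ks_2samp(q_const, q_tennessen)
        assert ks.pvalue < 1e-4
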