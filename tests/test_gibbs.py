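import numpy as np
import pytest
from scipy import integrate, stats

import wgreg as w
from wgreg.datatypes import GenotypeMatrix, GroupAssignment, GroupedPhenotypes
from wgreg.gibbs import (
    MCMCState,
    spike_slab_log_odds,
    update_effect_brr,
    update_variances,
    _sweep_term,
)
from wgreg.model import (
    BayesBPrior,
    BRRPrior,
    ErrorPrior,
    MCMCSettings,
    ModelConfig,
)


def _problem(rng, n_k, p, mode="across"):
    n = sum(n_k)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    geno = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        markers=[f"m{j}" for j in range(p)],
        dosages=X, standardized=True,
    )
    labels = np.repeat(np.arange(1, len(n_k) + 1), n_k)
    groups = GroupAssignment(labels=labels, q=len(n_k))
    y = GroupedPhenotypes(values=rng.normal(size=n), group=labels, q=len(n_k))
    layout = w.build_design(geno, groups, mode)
    return y, layout


def _state(y, layout, *, sigma2, effect_priors, prior="BRR"):
    cfg = ModelConfig(
        mode=layout.mode, prior=prior,
        error_priors=[ErrorPrior(S=1.0, df=5.0, fixed=s) for s in sigma2],
        effect_priors=effect_priors,
        mcmc=MCMCSettings(iterations=10, burnin=1, thin=1, seed=0),
    )
    return MCMCState(y, layout, cfg)


class TestBRRCoordinateUpdate:
    def test_flat_prior_limit_is_ols_coordinate(self, rng):
        """With an (improper) infinite prior variance and one group, the
        conditional mean is the ordinary least-squares single-coordinate
        solution."""
        y, layout = _problem(rng, [30], 1)
        st_ = _state(y, layout, sigma2=[1.0],
                     effect_priors={"main": BRRPrior(S=1, df=5, fixed=np.inf)})
        x = layout.X[:, 0]
        e0 = st_.e.copy()
        draw_rng = np.random.default_rng(99)
        z = np.random.default_rng(99).standard_normal(1)
        update_effect_brr(st_, "main", 0, draw_rng)
        c = x @ x
        expected = (x @ e0) / c + z[0] / np.sqrt(c)
        assert np.isclose(st_.beta["main"][0], expected, atol=1e-12)

    def test_zero_prior_variance_pins_effect_at_zero(self, rng):
        y, layout = _problem(rng, [20], 2)
        st_ = _state(y, layout, sigma2=[1.0],
                     effect_priors={"main": BRRPrior(S=1, df=5, fixed=0.0)})
        st_.beta["main"][:] = [2.0, -1.0]
        st_.e = st_.exact_residual()
        update_effect_brr(st_, "main", 0, np.random.default_rng(0))
        assert st_.beta["main"][0] == 0.0

    def test_heterogeneous_variance_main_update_is_wls(self, rng):
        """For the main block with sigma1 != sigma2 the conditional equals
        the precision-weighted least-squares coordinate solution; checked
        against numerical integration of the 1-marker posterior."""
        y, layout = _problem(rng, [12, 15], 1, mode="interaction")
        v = 0.37
        s1, s2 = 0.5, 2.0
        st_ = _state(
            y, layout, sigma2=[s1, s2],
            effect_priors={"main": BRRPrior(S=1, df=5, fixed=v),
                           "group_1": BRRPrior(S=1, df=5, fixed=0.0),
                           "group_2": BRRPrior(S=1, df=5, fixed=0.0)},
        )
        x = layout.X[:, 0]
        e0 = st_.e.copy()
        lab = layout.labels_sorted
        c = ((x[lab == 1] ** 2).sum() / s1 + (x[lab == 2] ** 2).sum() / s2
             + 1.0 / v)
        rhs = (x[lab == 1] @ e0[lab == 1]) / s1 + (x[lab == 2] @ e0[lab == 2]) / s2
        z = np.random.default_rng(7).standard_normal(1)
        update_effect_brr(st_, "main", 0, np.random.default_rng(7))
        assert np.isclose(st_.beta["main"][0], rhs / c + z[0] / np.sqrt(c),
                          atol=1e-10)
        # quadrature oracle for the conditional mean (log-normalized to keep
        # the integrand well scaled)
        sd = np.where(lab == 1, np.sqrt(s1), np.sqrt(s2))
        m0 = rhs / c

        def logpost(b):
            return (stats.norm.logpdf(e0, b * x, sd).sum()
                    + stats.norm.logpdf(b, 0, np.sqrt(v)))

        ref = logpost(m0)
        post = lambda b: np.exp(logpost(b) - ref)
        num = integrate.quad(lambda b: b * post(b), -5, 5, epsabs=1e-13)[0]
        den = integrate.quad(post, -5, 5, epsabs=1e-13)[0]
        assert np.isclose(num / den, m0, atol=1e-8)


class TestSpikeSlab:
    def test_log_odds_matches_quadrature(self, rng):
        """Inclusion log-odds on a 1-marker, n=5 toy against brute-force
        numeric marginal likelihoods."""
        n = 5
        x = rng.normal(size=n)
        r = rng.normal(size=n)
        sigma2, v, pi = 0.8, 0.6, 0.3
        c0 = (x @ x) / sigma2
        rhs0 = (x @ r) / sigma2
        impl = spike_slab_log_odds(c0, rhs0, v, pi)

        def like(b):
            return np.exp(stats.norm.logpdf(r, b * x, np.sqrt(sigma2)).sum()
                          + stats.norm.logpdf(b, 0, np.sqrt(v)))

        m1 = integrate.quad(like, -8, 8, epsabs=1e-14, epsrel=1e-12)[0]
        m0 = np.exp(stats.norm.logpdf(r, 0.0, np.sqrt(sigma2)).sum())
        oracle = np.log(pi / (1 - pi)) + np.log(m1) - np.log(m0)
        assert np.isclose(impl, oracle, atol=1e-6)

    def test_no_signal_limit_inclusion_probability_is_pi(self):
        # orthogonal marker, tiny slab variance: posterior inclusion ~ pi
        pi = 0.3
        lo = spike_slab_log_odds(c0=50.0, rhs0=0.0, marker_var=1e-10, pi=pi)
        assert np.isclose(1 / (1 + np.exp(-lo)), pi, atol=1e-6)

    def test_pi_one_boundary_includes_every_marker(self, rng):
        y, layout = _problem(rng, [25], 10)
        st_ = _state(y, layout, sigma2=[1.0], prior="BayesB",
                     effect_priors={"main": BayesBPrior(scale_shape=1.1,
                                                        scale_rate=10.0)})
        st_.pi["main"] = 1.0
        _sweep_term(st_, "main", np.random.default_rng(3))
        assert st_.delta["main"].all()


class TestVarianceUpdates:
    def test_sigma2_conditional_matches_closed_form(self, rng):
        """With effects held fixed, the sampled residual variances average to
        the analytic scaled-inverse-chi-square posterior mean."""
        y, layout = _problem(rng, [40], 0)
        S, df = 1.5, 4.0
        cfg = ModelConfig(
            mode="across", prior="BRR",
            error_priors=[ErrorPrior(S=S, df=df)],
            effect_priors={"main": BRRPrior(S=1.0, df=5.0, fixed=1.0)},
            mcmc=MCMCSettings(iterations=10, burnin=1, thin=1, seed=0),
        )
        st_ = MCMCState(y, layout, cfg)
        gen = np.random.default_rng(11)
        draws = []
        for _ in range(4000):
            update_variances(st_, gen)
            draws.append(st_.sigma2[0])
        sse = float(st_.e @ st_.e)
        n = layout.n
        analytic = (S * df + sse) / (df + n - 2)
        draws = np.asarray(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - analytic) < 4 * se

    def test_pi_posterior_with_no_inclusions_is_beta_1_p_plus_1(self, rng):
        y, layout = _problem(rng, [20], 30)
        st_ = _state(y, layout, sigma2=[1.0], prior="BayesB",
                     effect_priors={"main": BayesBPrior(scale_shape=1.1,
                                                        scale_rate=10.0,
                                                        pi_a=1.0, pi_b=1.0)})
        st_.delta["main"][:] = 0
        gen = np.random.default_rng(4)
        draws = np.array([
            (update_variances(st_, gen), st_.pi["main"])[1] for _ in range(4000)
        ])
        p = 30
        expected_mean = 1.0 / (p + 2)  # Beta(1, p+1)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected_mean) < 4 * se


class TestFit:
    def test_identical_seed_gives_bit_identical_chain(self, rng):
        geno, std, groups, phen, _ = w.simulate_dataset(
            [40, 40], 25, 0.3, [0.1, 0.1], seed=5)
        layout = w.build_design(std, groups, "interaction")
        cfg = w.ModelConfig(mode="interaction", prior="BRR",
                            mcmc=MCMCSettings(iterations=200, burnin=50,
                                              thin=2, seed=77))
        a = w.fit(phen, layout, cfg)
        b = w.fit(phen, layout, cfg)
        assert a.samples.equals(b.samples)
        np.testing.assert_array_equal(a.effect_mean["main"], b.effect_mean["main"])
        np.testing.assert_array_equal(a.genetic_value_mean, b.genetic_value_mean)

    def test_nonfinite_residual_aborts_with_iteration(self, rng):
        y, layout = _problem(rng, [10], 2)
        y.values[0] = np.inf  # bypasses the NaN entry guard, blows up in-run
        cfg = ModelConfig(
            mode="across", prior="BRR",
            error_priors=[ErrorPrior(S=1.0, df=5.0)],
            effect_priors={"main": BRRPrior(S=1.0, df=5.0)},
            mcmc=MCMCSettings(iterations=10, burnin=1, thin=1, seed=0),
        )
        with pytest.raises(RuntimeError, match="iteration"):
            w.fit(y, layout, cfg)

    def test_incremental_residual_stays_consistent(self, rng):
        y, layout = _problem(rng, [30, 30], 15, mode="interaction")
        st_ = _state(
            y, layout, sigma2=[1.0, 1.0],
            effect_priors={t: BRRPrior(S=0.01, df=5) for t in layout.term_names()},
        )
        gen = np.random.default_rng(8)
        for _ in range(200):
            for t in layout.term_names():
                _sweep_term(st_, t, gen)
            update_variances(st_, gen)
        assert np.max(np.abs(st_.e - st_.exact_residual())) < 1e-8

    def test_zero_interaction_truth_shrinks_interaction_blocks(self):
        """When the generator has no group-specific deviations, the fitted
        interaction variances collapse relative to the main variance.

        The posterior for an interaction variance has an estimation-noise
        floor of about p * sigma2 / n_k, so the simulation uses a large
        n/p ratio for the floor to sit well below the main variance.
        """
        geno, std, groups, phen, truth = w.simulate_dataset(
            [1500, 1500], 60, 0.5, [0.0, 0.0], sigma2=[0.5, 0.5], seed=21)
        layout = w.build_design(std, groups, "interaction")
        cfg = w.ModelConfig(mode="interaction", prior="BRR",
                            mcmc=MCMCSettings(iterations=3000, burnin=1000,
                                              thin=5, seed=9))
        s = w.fit(phen, layout, cfg)
        gv = {t: s.samples[f"genvar_{t}"].mean() for t in ("main", "group_1", "group_2")}
        assert gv["group_1"] < 0.2 * gv["main"]
        assert gv["group_2"] < 0.2 * gv["main"]

    def test_error_variance_ordering_across_vs_interaction(self):
        """On data with strongly heterogeneous effects the across-group model
        fits worse: its residual-variance posterior means are at least those
        of the interaction model."""
        geno, std, groups, phen, truth = w.simulate_dataset(
            [300, 300], 100, 0.05, [0.45, 0.45], sigma2=[0.5, 0.5], seed=31)
        mc = MCMCSettings(iterations=2500, burnin=1000, thin=5, seed=13)
        fits = {}
        for mode in ("across", "interaction"):
            layout = w.build_design(std, groups, mode)
            fits[mode] = w.fit(phen, layout,
                               w.ModelConfig(mode=mode, prior="BRR", mcmc=mc))
        assert (fits["across"].sigma2_mean >=
                fits["interaction"].sigma2_mean - 0.02).all()

    def test_pinned_variance_limits_reproduce_reduced_models(self):
        """Pinning the main-block variance near zero reproduces stratified
        predictions; pinning the interaction blocks near zero reproduces the
        across-group predictions (within Monte-Carlo error)."""
        geno, std, groups, phen, truth = w.simulate_dataset(
            [150, 150], 60, 0.2, [0.2, 0.2], sigma2=[0.6, 0.6], seed=41)
        mc = MCMCSettings(iterations=4000, burnin=1500, thin=5, seed=3)
        v = 0.2 / 60  # per-marker variance matching the truth scale
        inter = w.build_design(std, groups, "interaction")

        def fit_fixed(main_v, int_v):
            cfg = ModelConfig(
                mode="interaction", prior="BRR",
                error_priors=[ErrorPrior(S=1, df=5, fixed=0.6)] * 2,
                effect_priors={"main": BRRPrior(S=1, df=5, fixed=main_v),
                               "group_1": BRRPrior(S=1, df=5, fixed=int_v),
                               "group_2": BRRPrior(S=1, df=5, fixed=int_v)},
                mcmc=mc,
            )
            return w.fit(phen, inter, cfg)

        def fit_reduced(mode):
            layout = w.build_design(std, groups, mode)
            terms = {t: BRRPrior(S=1, df=5, fixed=v) for t in layout.term_names()}
            cfg = ModelConfig(
                mode=mode, prior="BRR",
                error_priors=[ErrorPrior(S=1, df=5, fixed=0.6)] * 2,
                effect_priors=terms, mcmc=mc,
            )
            return w.fit(phen, layout, cfg)

        tiny = 1e-10
        g_strat_like = fit_fixed(tiny, v).genetic_value_mean
        g_strat = fit_reduced("stratified").genetic_value_mean
        assert np.corrcoef(g_strat_like, g_strat)[0, 1] > 0.99
        g_across_like = fit_fixed(v, tiny).genetic_value_mean
        g_across = fit_reduced("across").genetic_value_mean
        assert np.corrcoef(g_across_like, g_across)[0, 1] > 0.99

    def test_bayesb_summary_reports_inclusion_and_scale(self, rng):
        geno, std, groups, phen, _ = w.simulate_dataset(
            [60, 60], 30, 0.3, [0.1, 0.1], seed=6)
        layout = w.build_design(std, groups, "across")
        cfg = w.ModelConfig(mode="across", prior="BayesB",
                            mcmc=MCMCSettings(iterations=300, burnin=100,
                                              thin=2, seed=1))
        s = w.fit(phen, layout, cfg)
        frame = s.to_frame()
        stems = set(frame["parameter"])
        assert {"probin", "scale", "genvar"} <= stems
        assert s.inclusion_prob is not None
        assert ((s.inclusion_prob["main"] >= 0) & (s.inclusion_prob["main"] <= 1)).all()
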