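"""Estimation engine: MPLE closed forms, sampler calibration, MCMC-MLE
against enumeration oracles, diagnostics, and the decay grid."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import neuroergm as ne
from neuroergm import (
    AttrTable,
    DegeneracyError,
    Edges,
    EstimationError,
    Gwesp,
    ModelSpec,
    Network,
    NodeCov,
    NodeMix,
    SamplerControl,
    approx_loglik_ratio,
    fit_mcmc_mle,
    fit_mple,
    mcmc_diagnostics,
    sample_networks,
    select_gwesp_decay,
)
from conftest import make_random_network
from oracles import brute_stats, enumeration_mle, enumeration_logZ


class TestMPLE:
    def test_edges_only_equals_logit_density(self, florentine):
        net, _ = florentine
        fit = fit_mple(ModelSpec([Edges()]), net)
        assert fit.theta[0] == pytest.approx(math.log(0.125 / 0.875), abs=1e-8)

    def test_half_density_gives_zero(self):
        # 4 nodes, 3 of 6 dyads present
        net = Network.from_edges("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        fit = fit_mple(ModelSpec([Edges()]), net)
        assert fit.theta[0] == pytest.approx(0.0, abs=1e-8)

    def test_dyad_independent_equals_enumeration_mle(self):
        """For edges+nodecov+nodemix the pseudolikelihood IS the likelihood."""
        net = Network.from_edges(
            "abcde",
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("b", "e")],
        )
        rng = np.random.default_rng(7)
        x = dict(zip(net.node_labels, rng.normal(size=5)))
        g = {"a": "u", "b": "u", "c": "v", "d": "v", "e": "u"}
        at = AttrTable({"x": x, "g": g}, categorical={"g": ["u", "v"]})
        spec = ModelSpec([Edges(), NodeCov("x"), NodeMix("g", include=(("u", "u"),))])
        fit = fit_mple(spec, net, at)

        xs = np.array([x[k] for k in net.node_labels])
        codes = [0, 0, 1, 1, 0]
        exact = enumeration_mle(
            net.adjacency.astype(int).tolist(),
            lambda a: brute_stats(a, [("edges",), ("nodecov",), ("nodemix",)],
                                  x=xs, codes=codes, cells=[(0, 0)]),
            k=3,
        )
        assert np.allclose(fit.theta, exact, atol=1e-6)

    def test_rank_deficiency_names_offender(self, florentine):
        net, _ = florentine
        x = dict(zip(net.node_labels, np.arange(16.0)))
        at = AttrTable({"x": x, "x2": {k: 2 * v for k, v in x.items()}})
        spec = ModelSpec([Edges(), NodeCov("x"), NodeCov("x2")])
        with pytest.raises(EstimationError, match="nodecov.x2"):
            fit_mple(spec, net, at)

    def test_summary_has_stars(self, florentine):
        net, _ = florentine
        s = fit_mple(ModelSpec([Edges()]), net).summary()
        assert list(s.columns) == ["estimate", "se", "t", "p", "signif"]
        assert s.loc["edges", "signif"] == "***"


class TestSampler:
    def test_seed_determinism(self):
        spec = ModelSpec([Edges(), Gwesp(0.45)])
        kw = dict(n_nodes=10, control=SamplerControl(samples=50, seed=42))
        a = sample_networks(spec, [-1.0, 0.3], **kw)
        b = sample_networks(spec, [-1.0, 0.3], **kw)
        assert a.stats.equals(b.stats)
        assert all(x == y for x, y in zip(a.networks, b.networks))

    def test_different_seeds_differ(self):
        spec = ModelSpec([Edges()])
        a = sample_networks(spec, [0.0], n_nodes=10,
                            control=SamplerControl(samples=50, seed=1))
        b = sample_networks(spec, [0.0], n_nodes=10,
                            control=SamplerControl(samples=50, seed=2))
        assert not a.stats.equals(b.stats)

    @pytest.mark.parametrize("proposal", ["uniform", "tnt", "mixture"])
    def test_edges_only_occupancy_matches_sigmoid(self, proposal):
        """Independent-Bernoulli closed form validates the Hastings ratios."""
        theta = -1.2
        s = sample_networks(
            ModelSpec([Edges()]), [theta], n_nodes=12,
            control=SamplerControl(samples=3000, seed=5, proposal=proposal),
            return_networks=False, track_occupancy=True,
        )
        p = expit(theta)
        se = math.sqrt(p * (1 - p) / (3000 * 66)) * 4  # generous: correlated draws
        assert s.mean_occupancy == pytest.approx(p, abs=max(5 * se, 0.01))

    def test_null_model_occupancy_near_half(self):
        s = sample_networks(
            ModelSpec([Edges(), Gwesp(0.45)]), [0.0, 0.0], n_nodes=10,
            control=SamplerControl(samples=3000, seed=8),
            return_networks=False, track_occupancy=True,
        )
        assert s.mean_occupancy == pytest.approx(0.5, abs=0.01)

    def test_invalid_control_rejected(self):
        with pytest.raises(ValueError):
            SamplerControl(samples=0)
        with pytest.raises(ValueError):
            SamplerControl(burn_in=-1)
        with pytest.raises(ValueError):
            SamplerControl(proposal="flip")

    def test_free_dyads_freeze_the_rest(self, florentine):
        net, _ = florentine
        frozen = net.edges()[:5]
        free = [d for d in ne.terms.all_dyads(net.n) if d not in set(frozen)]
        s = sample_networks(
            ModelSpec([Edges()]), [-3.0], start=net, free_dyads=free,
            control=SamplerControl(samples=20, seed=0),
        )
        for y in s.networks:
            for i, j in frozen:
                assert y.adjacency[i, j]


class TestApproxLoglikRatio:
    def test_zero_at_same_theta(self):
        g = np.array([[3.0, 1.0], [4.0, 2.0]])
        assert approx_loglik_ratio([0.5, -1], [0.5, -1], g, [3.5, 1.5]) == 0.0

    def test_single_draw_algebra(self):
        g = np.array([[4.0]])
        val = approx_loglik_ratio([1.0], [0.25], g, [6.0])
        assert val == pytest.approx(0.75 * (6.0 - 4.0))

    def test_matches_enumeration_on_edges_model(self):
        """Monte Carlo estimate of log c(theta)/c(theta_s) vs exact, n=4."""
        spec = ModelSpec([Edges()])
        theta_s, theta = np.array([-0.5]), np.array([0.4])
        draws = sample_networks(spec, theta_s, n_nodes=4,
                                control=SamplerControl(samples=4000, seed=3),
                                return_networks=False)
        net = Network.from_edges("abcd", [("a", "b")])
        g_obs = np.array([1.0])
        est = approx_loglik_ratio(theta, theta_s, draws.stats, g_obs)
        logZ = enumeration_logZ(lambda a: brute_stats(a, [("edges",)]), theta, 4)
        logZs = enumeration_logZ(lambda a: brute_stats(a, [("edges",)]), theta_s, 4)
        exact = float((theta - theta_s) @ g_obs - (logZ - logZs))
        assert est == pytest.approx(exact, abs=0.05)


class TestMCMCMLE:
    def test_dyad_independent_matches_mple(self):
        net = make_random_network(21, 8, 0.4)
        rng = np.random.default_rng(2)
        at = AttrTable({"x": dict(zip(net.node_labels, rng.normal(size=8)))})
        spec = ModelSpec([Edges(), NodeCov("x")])
        mple = fit_mple(spec, net, at)
        mcmc = fit_mcmc_mle(spec, net, at,
                            control=SamplerControl(samples=2500, seed=4),
                            outer_tol=0.08)
        assert np.allclose(mcmc.theta, mple.theta, atol=0.02)

    def test_edges_gwesp_matches_enumeration_on_five_nodes(self):
        net = Network.from_edges(
            "abcde", [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")]
        )
        spec = ModelSpec([Edges(), Gwesp(0.8)])
        exact = enumeration_mle(
            net.adjacency.astype(int).tolist(),
            lambda a: brute_stats(a, [("edges",), ("gwesp", 0.8)]), k=2,
        )
        fit = fit_mcmc_mle(spec, net, control=SamplerControl(samples=3000, seed=11),
                           outer_tol=0.06)
        assert np.allclose(fit.theta, exact, atol=0.05)
        assert fit.converged

    def test_seed_determinism(self, florentine):
        net, _ = florentine
        spec = ModelSpec([Edges(), Gwesp(0.45)])
        kw = dict(control=SamplerControl(samples=500, seed=9))
        a = fit_mcmc_mle(spec, net, **kw)
        b = fit_mcmc_mle(spec, net, **kw)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.se, b.se)

    def test_empty_graph_rejected(self):
        with pytest.raises(EstimationError, match="empty or complete"):
            fit_mcmc_mle(ModelSpec([Edges()]), Network.empty("abcd"))

    def test_degenerate_start_raises_with_diagnostics(self, florentine):
        net, _ = florentine
        spec = ModelSpec([Edges(), Gwesp(0.8)])
        with pytest.raises(DegeneracyError, match="drifted"):
            fit_mcmc_mle(
                spec, net, theta_init=[3.0, 3.0],
                control=SamplerControl(samples=200, seed=1),
                max_iter=1,
            )


class TestDiagnostics:
    def test_constant_chain_at_observed_passes(self):
        stats = pd.DataFrame({"edges": [15.0] * 50, "gwesp": [13.0] * 50})
        d = mcmc_diagnostics(stats, [15.0, 13.0])
        assert d.ok
        assert (d.summary["deviation"] == 0).all()

    def test_drifted_chain_fails(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        stats = pd.DataFrame({"edges": x + 10.0})
        d = mcmc_diagnostics(stats, [0.0])
        assert not d.ok

    def test_needs_ten_draws(self):
        with pytest.raises(ValueError):
            mcmc_diagnostics(pd.DataFrame({"e": [1.0] * 5}), [1.0])

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.8])
    def test_ar1_autocorrelation_recovered(self, rho):
        rng = np.random.default_rng(12)
        x = np.zeros(6000)
        for t in range(1, len(x)):
            x[t] = rho * x[t - 1] + rng.normal()
        d = mcmc_diagnostics(pd.DataFrame({"s": x}), [0.0], sd_multiple=10)
        assert d.summary.loc["s", "lag1_autocorr"] == pytest.approx(rho, abs=0.1)


class TestDecayGrid:
    def test_default_grid_has_forty_values(self):
        g = ne.default_decay_grid()
        assert len(g) == 40
        assert g[0] == 0.05 and g[-1] == 2.0

    def test_single_point_grid_returns_it(self, florentine):
        net, _ = florentine
        best, fits = select_gwesp_decay(
            ModelSpec([Edges(), Gwesp(0.45)]), net, grid=[0.45],
            control=SamplerControl(samples=400, seed=2),
        )
        assert best == 0.45
        assert set(fits) == {0.45}

    def test_grid_must_be_positive(self, florentine):
        net, _ = florentine
        with pytest.raises(ValueError):
            select_gwesp_decay(ModelSpec([Edges(), Gwesp(0.45)]), net, grid=[0.0, 0.5])

    def test_selection_self_consistency(self):
        """Networks simulated at decay 0.5 in a dense, strongly transitive
        regime (where the decay is identifiable) are assigned a decay
        within +/-0.15 of the truth in >= 80% of seeded replicates."""
        true_decay = 0.5
        theta = np.array([-3.0, 0.8])
        gen_spec = ModelSpec([Edges(), Gwesp(true_decay)])
        grid = np.round(np.arange(1, 31) * 0.05, 2)
        hits = 0
        reps = 10
        for rep in range(reps):
            y = sample_networks(
                gen_spec, theta, n_nodes=50,
                control=SamplerControl(burn_in=30 * 1225, samples=1, seed=900 + rep),
            ).networks[0]
            best, _ = select_gwesp_decay(
                ModelSpec([Edges(), Gwesp(0.5)]), y, grid=grid,
                control=SamplerControl(samples=1000, interval=300, seed=rep),
                outer_tol=0.1, max_iter=4,
            )
            hits += abs(best - true_decay) <= 0.15
        assert hits >= 0.8 * reps, hits

    def test_per_decay_fits_cover_grid(self, florentine):
        net, _ = florentine
        grid = [0.4, 0.6, 0.8]
        best, fits = select_gwesp_decay(
            ModelSpec([Edges(), Gwesp(0.45)]), net, grid=grid,
            control=SamplerControl(samples=800, seed=3),
        )
        assert set(fits) == set(grid)
        assert best in grid
        lls = {t: f.loglik_ratio for t, f in fits.items() if f.converged}
        assert best == min(lls, key=lambda t: (-lls[t], t))
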