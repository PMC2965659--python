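"""Exponential random graph models: statistics, change statistics, the
Metropolis sampler, maximum-likelihood fitting, deviance and goodness of
fit."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binom, chisquare

from netcompare.ergm import (
    ErgmModel,
    _ChangeStats,
    akaike_weights,
    ergm_fit,
    ergm_gof,
    ergm_sample,
    ergm_statistics,
    exact_mle,
    null_deviance,
)
from netcompare.generators import ring_lattice
from netcompare.graph import Graph
from netcompare.motifs import directed_gnp

from conftest import complete_graph, random_digraph

ALL_LABELS = [
    "edges", "asym", "mutual", "triad_201", "triad_021C",
    "cycle_3", "instar_2", "outstar_2",
]


def brute_force_statistics(g: Graph, labels) -> np.ndarray:
    """Independent oracle: motif counts via networkx and explicit loops."""
    a = g.adjacency
    n = g.n_nodes
    census = nx.triadic_census(g.to_networkx())
    out = []
    for lab in labels:
        if lab == "edges":
            out.append(a.sum())
        elif lab == "mutual":
            out.append(sum(a[i, j] and a[j, i] for i in range(n) for j in range(i + 1, n)))
        elif lab == "asym":
            out.append(sum(bool(a[i, j]) != bool(a[j, i]) for i in range(n) for j in range(i + 1, n)))
        elif lab.startswith("triad_"):
            out.append(census[lab.removeprefix("triad_")])
        elif lab == "cycle_3":
            out.append(
                sum(
                    a[i, j] and a[j, k] and a[k, i]
                    for i, j, k in itertools.permutations(range(n), 3)
                ) // 3
            )
        elif lab.startswith("instar_"):
            s = int(lab.split("_")[1])
            out.append(sum(len(list(itertools.combinations(np.nonzero(a[:, j])[0], s)))
                           for j in range(n)))
        elif lab.startswith("outstar_"):
            s = int(lab.split("_")[1])
            out.append(sum(len(list(itertools.combinations(np.nonzero(a[i])[0], s)))
                           for i in range(n)))
    return np.array(out, dtype=float)


class TestStatistics:
    def test_complete_three_node_edges(self):
        assert ergm_statistics(complete_graph(3, directed=True), ["edges"])[0] == 6

    def test_shared_mutual_dyads_form_201(self):
        a = np.zeros((3, 3), dtype=np.int8)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1
        g = Graph(a, directed=True)
        assert ergm_statistics(g, ["triad_201"])[0] == 1

    def test_statistics_match_brute_force(self, rng):
        for _ in range(30):
            g = random_digraph(6, rng.uniform(0.2, 0.7), rng)
            ours = ergm_statistics(g, ALL_LABELS)
            oracle = brute_force_statistics(g, ALL_LABELS)
            assert np.array_equal(ours, oracle)

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown statistic"):
            ergm_statistics(random_digraph(4, 0.5, rng), ["heptagon"])


class TestChangeStatistics:
    def test_exact_for_random_toggles(self, rng):
        """Change statistics equal the recomputed-from-scratch difference
        for 1000 random (graph, toggle) pairs."""
        cs = _ChangeStats(ALL_LABELS)
        for _ in range(1000):
            n = int(rng.integers(4, 8))
            g = random_digraph(n, rng.uniform(0.2, 0.8), rng)
            a = g.adjacency.copy()
            i, j = rng.choice(n, size=2, replace=False)
            d = cs.delta(a, int(i), int(j))
            before = ergm_statistics(Graph(a.copy(), directed=True), ALL_LABELS)
            a[i, j] ^= 1
            after = ergm_statistics(Graph(a, directed=True), ALL_LABELS)
            assert np.array_equal(d, after - before)


class TestSampler:
    def test_theta_zero_density_half(self):
        model = ErgmModel(["edges"], np.array([0.0]))
        graphs, _ = ergm_sample(model, 15, n_burn=2000, n_keep=200, thin=50, seed=1)
        dens = np.array([g.density for g in graphs])
        se = np.sqrt(0.25 / (15 * 14)) / np.sqrt(len(dens) / 4)  # crude, autocorrelated
        assert abs(dens.mean() - 0.5) < max(3 * se, 0.02)

    def test_bernoulli_density_matches_logit(self):
        model = ErgmModel(["edges"], np.array([float(np.log(0.2 / 0.8))]))
        graphs, _ = ergm_sample(model, 15, n_burn=2000, n_keep=200, thin=50, seed=2)
        dens = np.mean([g.density for g in graphs])
        assert abs(dens - 0.2) < 0.02

    def test_same_seed_identical_sequence(self):
        model = ErgmModel(["edges", "mutual"], np.array([-0.5, 0.5]))
        g1, t1 = ergm_sample(model, 10, n_burn=500, n_keep=20, thin=10, seed=3)
        g2, t2 = ergm_sample(model, 10, n_burn=500, n_keep=20, thin=10, seed=3)
        assert np.array_equal(t1, t2)
        assert all(np.array_equal(x.adjacency, y.adjacency) for x, y in zip(g1, g2))

    def test_edges_chain_matches_binomial_law(self):
        """Detailed-balance proxy: at theta=0 the arc count follows
        Binomial(M, 1/2)."""
        model = ErgmModel(["edges"], np.array([0.0]))
        _, trace = ergm_sample(model, 5, n_burn=2000, n_keep=10_000, thin=7, seed=4)
        counts = trace[:, 0].astype(int)
        M = 20
        observed = np.bincount(counts, minlength=M + 1)
        expected = binom.pmf(np.arange(M + 1), M, 0.5) * len(counts)
        keep = expected > 5
        stat, p = chisquare(
            observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum()
        )
        assert p > 0.01


class TestFitting:
    def test_edges_mle_matches_logit_density(self):
        g = directed_gnp(30, 0.35, seed=5)
        fit = ergm_fit(g, ["edges"], seed=7, compute_loglik=False)
        d = g.density
        assert abs(fit.model.theta[0] - np.log(d / (1 - d))) < 3 * fit.std_errors[0]

    def test_exact_enumeration_matches_mcmc_on_n4(self, rng):
        from netcompare.motifs import dyad_census

        hits = 0
        attempts = 0
        while hits < 3 and attempts < 30:
            attempts += 1
            g = random_digraph(4, 0.5, rng)
            # all three dyad classes must be present: at a dyad-census
            # boundary the MLE diverges and no finite target exists
            if min(dyad_census(g)) == 0:
                continue
            th_exact = exact_mle(g, ["edges", "asym"])
            fit = ergm_fit(g, ["edges", "asym"], seed=50 + attempts, compute_loglik=False)
            assert np.max(np.abs(th_exact - fit.model.theta)) < 0.05
            hits += 1
        assert hits == 3

    def test_parameter_recovery(self):
        """Coefficients of a digraph simulated from a known model are
        recovered within 3 reported SEs."""
        truth = np.array([-1.0, 0.2])
        labels = ["asym", "triad_201"]
        model = ErgmModel(labels, truth)
        covered = 0
        trials = 4
        for t in range(trials):
            gs, _ = ergm_sample(model, 30, n_burn=20_000, n_keep=1, thin=100, seed=100 + t)
            fit = ergm_fit(gs[0], labels, seed=200 + t, compute_loglik=False)
            covered += bool(np.all(np.abs(fit.model.theta - truth) <= 3 * fit.std_errors))
        assert covered >= trials - 1

    def test_boundary_statistic_rejected(self):
        g = directed_gnp(10, 0.1, seed=8)
        with pytest.raises(ValueError, match="boundary"):
            ergm_fit(g, ["triad_300"], seed=9)

    def test_degenerate_star_model_flagged(self):
        """The explosive two-in-star model on a hub-concentrated digraph
        collapses; the fit must say so rather than report estimates."""
        n = 20
        a = np.zeros((n, n), dtype=np.int8)
        a[2:, 0] = 1
        a[2:, 1] = 1
        rng = np.random.default_rng(4)
        for _ in range(10):
            i, j = rng.integers(n, size=2)
            if i != j:
                a[i, j] = 1
        fit = ergm_fit(Graph(a, directed=True), ["edges", "instar_2"], seed=9,
                       compute_loglik=False)
        assert fit.degenerate
        assert "degeneracy" in fit.note
        assert np.isnan(fit.aic)


class TestDeviance:
    def test_null_deviance_thirty_nodes(self):
        dev, df = null_deviance(30)
        assert round(dev) == 1206
        assert df == 870

    def test_edges_model_deviance_matches_bernoulli_closed_form(self):
        g = directed_gnp(30, 0.35, seed=10)
        fit = ergm_fit(g, ["edges"], seed=11)
        d = g.density
        E, M = g.n_edges, 870
        exact = -2 * (E * np.log(d) + (M - E) * np.log(1 - d))
        # stochastic theta and MC error in the bridge estimate both contribute
        assert abs(fit.residual_deviance - exact) < max(10 * fit.loglik_mc_error, 8.0)
        assert fit.explained_deviance == pytest.approx(
            fit.null_deviance - fit.residual_deviance
        )
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik_estimate)

    def test_akaike_weights_normalize_and_rank(self):
        w = akaike_weights(np.array([0.0, 2.0, 10.0]))
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > w[1] > w[2]


class TestGoodnessOfFit:
    def test_well_specified_model_inside_envelope(self):
        g = directed_gnp(20, 0.3, seed=21)
        fit = ergm_fit(g, ["edges"], seed=22, compute_loglik=False)
        gof = ergm_gof(fit, g, n_sim=50, seed=23)
        assert bool(gof["statistics"]["inside"].all())
        # moment condition at the MLE: simulated statistic means sit at the
        # observed values up to MC error (autocorrelation inflates the
        # nominal SE of the mean, hence the 5x factor)
        sim = gof["statistics"]["simulated_mean"]
        mc_se = gof["statistics"]["simulated_sd"] / np.sqrt(gof["n_sim"])
        assert np.all(np.abs(sim - fit.observed) < 5 * mc_se)

    def test_misspecified_model_violates_triad_envelope(self):
        # mutual-lattice data: every undirected lattice edge as a mutual pair
        und = ring_lattice(20, 4).adjacency
        g = Graph(und.astype(np.int8), directed=True)
        fit = ergm_fit(g, ["edges"], seed=24, compute_loglik=False)
        gof = ergm_gof(fit, g, n_sim=50, seed=25)
        assert not bool(gof["triad_census"]["inside"].all())
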