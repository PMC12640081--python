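"""Bayesian MSC-I engine: densities, pruning likelihood, HPD intervals,
Savage-Dickey Bayes factors, and MCMC prior recovery."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import coalflow as cf
from coalflow import _kernel
from coalflow.bayes import (_genetree_to_arrays, _params_from_network,
                            msci_gene_tree_log_density, jc_log_likelihood)
from coalflow.io import LocusAlignment, encode_seq
from coalflow.simulate import GeneTree
from coalflow.trees import Node, Tree


def _two_tip_gene_tree(t, species=("B", "C")):
    root = Node()
    root.age = t
    for i, sp in enumerate(species):
        tip = Node(f"{sp}^1")
        tip.age = 0.0
        root.add_child(tip)
    tree = Tree(root)
    tree.set_lengths_from_ages()
    return GeneTree(tree, {f"{sp}^1": sp for sp in species})


class TestGeneTreeDensity:
    def test_two_lineage_closed_form(self):
        """Two lineages in one population coalescing at t:
        log(2/theta) - 2t/theta."""
        theta = 0.01
        net = cf.quartet_network(theta, "msci", "inflow", phi=0.0)
        # two A samples coalescing inside the A branch
        root = Node()
        root.age = 0.001
        for i in (1, 2):
            tip = Node(f"A^{i}")
            tip.age = 0.0
            root.add_child(tip)
        tree = Tree(root)
        tree.set_lengths_from_ages()
        gt = GeneTree(tree, {"A^1": "A", "A^2": "A"})
        ld = msci_gene_tree_log_density(gt, net)
        assert ld == pytest.approx(math.log(2 / theta) - 2 * 0.001 / theta)

    def test_incompatible_state_raises(self):
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.0)
        gt = _two_tip_gene_tree(0.001, ("A", "O"))  # below tau_R: impossible
        with pytest.raises(ValueError, match="incompatible"):
            msci_gene_tree_log_density(gt, net)

    def test_hybrid_path_symmetry_at_half(self):
        """At phi=0.5 both parent choices give the same density for a
        lineage that sits in the recipient branch at tau_X and coalesces
        above all boundaries."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.5)
        gt = _two_tip_gene_tree(0.04, ("B", "O"))
        b_tip = gt.tree.tips()[0]
        assert gt.tip_species[b_tip.name] == "B"
        gt.hybrid_flags[b_tip] = 0
        ld0 = msci_gene_tree_log_density(gt, net)
        gt.hybrid_flags[b_tip] = 1
        ld1 = msci_gene_tree_log_density(gt, net)
        assert ld0 == pytest.approx(ld1)

    def test_normalization_by_numerical_integration(self):
        """Integrating exp(log density) over the coalescence time and
        summing the two path flags gives 1 for a B+C pair."""
        net = cf.quartet_network(0.0025, "msci", "inflow", phi=0.2)
        e = net.introgression
        total = 0.0
        for f in (0, 1):
            def dens(t, f=f):
                gt = _two_tip_gene_tree(t)
                tip_b = next(tip for tip in gt.tree.tips()
                             if gt.tip_species[tip.name] == "B")
                gt.hybrid_flags[tip_b] = f
                try:
                    return math.exp(msci_gene_tree_log_density(gt, net))
                except ValueError:
                    return 0.0
            v, _ = quad(dens, 0, 0.2, limit=300,
                        points=[e.time, 0.0025, 0.005, 0.0075])
            total += v
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_kernel_matches_reference_implementation(self):
        """The compiled sufficient-statistics density equals the pure
        Python density on simulated gene trees, both directions."""
        for direction in ("inflow", "outflow"):
            net = cf.quartet_network(0.01, "msci", direction, phi=0.3)
            model = cf.MSCIModel(net)
            p = _params_from_network(model)
            rng = np.random.default_rng(101)
            nn = 2 * 8 - 1
            scratch = ([np.empty(nn, np.int64) for _ in range(4)]
                       + [np.empty(160, np.int64), np.empty(160), np.empty(160)])
            c = np.empty(7)
            A = np.empty(7)
            tip_pop = np.array(sorted([0, 0, 1, 1, 2, 2, 3, 3]), np.int64)
            for _ in range(60):
                gt = cf.simulate_gene_tree_msci(net, {s: 2 for s in "ABCO"}, rng)
                ld_py = msci_gene_tree_log_density(gt, net)
                parent, age, flag = _genetree_to_arrays(gt, model, 8)
                ok, n1, n0 = _kernel._locus_stats(
                    parent, age, flag, tip_pop, 8, p,
                    np.int64(model.donor_role), np.int64(model.recipient_role),
                    c, A, *scratch)
                assert ok
                ld_k = _kernel._ld_from_stats(c, A, p, n1, n0)
                assert ld_k == pytest.approx(ld_py, abs=1e-9)


class TestJCLikelihood:
    def _pair_alignment(self, s1, s2):
        return LocusAlignment("L1", ["x", "y"], ["A", "A"], ["1", "2"],
                              np.vstack([encode_seq(s1), encode_seq(s2)]))

    def _pair_tree(self, height):
        root = Node()
        root.age = height
        for nm in ("x", "y"):
            tip = Node(nm)
            tip.age = 0.0
            root.add_child(tip)
        t = Tree(root)
        t.set_lengths_from_ages()
        return t

    def test_identical_single_site(self):
        d = 0.1
        ll = jc_log_likelihood(self._pair_alignment("A", "A"),
                               self._pair_tree(d / 2))
        assert ll == pytest.approx(
            math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3))))

    def test_mismatching_single_site(self):
        d = 0.1
        ll = jc_log_likelihood(self._pair_alignment("A", "C"),
                               self._pair_tree(d / 2))
        assert ll == pytest.approx(
            math.log(0.25 * (0.25 - 0.25 * math.exp(-4 * d / 3))))

    def test_ambiguity_is_missing(self):
        ll = jc_log_likelihood(self._pair_alignment("N", "A"),
                               self._pair_tree(0.05))
        assert ll == pytest.approx(math.log(0.25))

    def test_empty_alignment(self):
        ll = jc_log_likelihood(self._pair_alignment("", ""),
                               self._pair_tree(0.05))
        assert ll == 0.0

    def test_rerooting_invariance(self, small_dataset):
        """JC is reversible: the pruning likelihood computed on the kernel's
        flattened tree equals the reference computation on the original
        rooted tree."""
        gt, aln = small_dataset[0]
        ll_ref = jc_log_likelihood(aln, gt)
        net = cf.quartet_network(0.0025, "msci", "inflow", phi=0.2)
        model = cf.MSCIModel(net)
        parent, age, _ = _genetree_to_arrays(gt, model, 8)
        from coalflow.bayes import _pack_locus
        tip_pop, patterns, weights = _pack_locus(aln, model)
        order = np.empty(15, np.int64)
        partial = np.empty((15, patterns.shape[1], 4))
        ll_k = _kernel._jc_loglik(parent, age, 8, patterns,
                                  patterns.shape[1], weights, order, partial)
        assert ll_k == pytest.approx(ll_ref, abs=1e-10)


class TestHPD:
    def test_constant_samples(self):
        assert cf.hpd_interval([2.0] * 10, 0.95) == (2.0, 2.0)

    def test_uniform_grid(self):
        lo, hi = cf.hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert hi - lo == pytest.approx(95.0)
        assert lo == 1.0  # leftmost window on ties

    def test_standard_normal(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = cf.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_matches_brute_force_enumeration(self, rng):
        x = np.sort(rng.exponential(1.0, 40))
        lo, hi = cf.hpd_interval(x, 0.9)
        npts = int(math.ceil(0.9 * 40)) + 1
        widths = [x[i + npts - 1] - x[i] for i in range(40 - npts + 1)]
        assert hi - lo == pytest.approx(min(widths))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cf.hpd_interval([], 0.95)


class TestSavageDickey:
    def test_identity_when_posterior_equals_prior(self):
        priors = cf.PriorSpec()
        phi = np.linspace(1e-4, 1, 10_000)  # uniform draws
        bf = cf.savage_dickey_bf(phi, priors, 0.01)
        assert bf.b10 == pytest.approx(1.0, rel=0.05)

    def test_direct_evaluation(self):
        priors = cf.PriorSpec()
        phi = np.concatenate([np.full(1, 0.005), np.full(9999, 0.5)])
        bf = cf.savage_dickey_bf(phi, priors, 0.01)
        assert bf.b10 == pytest.approx(0.01 / (1 / 10_000))

    def test_beta_posterior_oracle(self, rng):
        """Posterior ~ beta(2,2): B10 = eps / CDF_beta(2,2)(eps) within
        10% of the Monte-Carlo estimate."""
        priors = cf.PriorSpec()
        eps = 0.01
        exact = eps / stats.beta.cdf(eps, 2, 2)
        phi = rng.beta(2, 2, 2_000_000)
        bf = cf.savage_dickey_bf(phi, priors, eps)
        assert bf.b10 == pytest.approx(exact, rel=0.10)

    def test_cap_flag(self):
        priors = cf.PriorSpec()
        bf = cf.savage_dickey_bf(np.full(5000, 0.5), priors, 0.01)
        assert bf.capped and bf.b10 == pytest.approx(0.01 * 5000)

    def test_monotone_in_posterior_mass(self):
        priors = cf.PriorSpec()
        b = []
        for k in (1, 10, 100):
            phi = np.concatenate([np.full(k, 0.001), np.full(10_000 - k, 0.5)])
            b.append(cf.savage_dickey_bf(phi, priors, 0.01).b10)
        assert b[0] > b[1] > b[2]

    def test_epsilon_domain(self):
        with pytest.raises(ValueError):
            cf.savage_dickey_bf(np.array([0.5]), cf.PriorSpec(), 1.5)


class TestMcmc:
    def test_zero_loci_reproduces_prior(self):
        """With no data the sampler is a prior sampler: moments of phi,
        tau_R and theta match beta(1,1), G(2,266) and G(2,800)."""
        model = cf.MSCIModel(cf.quartet_network(0.0025, "msci", "inflow",
                                                phi=0.2))
        priors = cf.PriorSpec(2.0, 266.0, 2.0, 800.0)
        trace = cf.run_mcmc([], model, priors,
                            cf.McmcSettings(burnin=1000, samples=20_000,
                                            chains=3),
                            seed=1)
        df = trace.df
        assert df["phi"].mean() == pytest.approx(0.5, abs=0.02)
        assert df["phi"].std() == pytest.approx(math.sqrt(1 / 12), abs=0.02)
        assert df["tau_R"].mean() == pytest.approx(2 / 266, rel=0.10)
        for r in ("A", "B", "R"):
            assert df[f"theta_{r}"].mean() == pytest.approx(2 / 800, rel=0.05)
        # conditional uniform priors for the interior times
        assert (df["tau_T"] / df["tau_R"]).mean() == pytest.approx(1 / 3,
                                                                   abs=0.02)
        assert (df["tau_X"] / df["tau_T"]).mean() == pytest.approx(0.5,
                                                                   abs=0.02)

    def test_fixed_seed_identical_trace(self):
        model = cf.MSCIModel(cf.quartet_network(0.0025, "msci", "inflow",
                                                phi=0.2))
        priors = cf.PriorSpec()
        data = cf.simulate_dataset(model.network, {s: 1 for s in "ABCO"},
                                   5, 50, "msci", seed=3)
        alns = [a for _, a in data]
        settings = cf.McmcSettings(burnin=100, samples=200)
        t1 = cf.run_mcmc(alns, model, priors, settings, seed=7)
        t2 = cf.run_mcmc(alns, model, priors, settings, seed=7)
        assert t1.df.equals(t2.df)

    def test_posterior_concentrates_on_truth(self):
        """A short informative run pulls phi away from the prior mean
        toward the generating value and keeps tau_T near truth."""
        theta = 0.01
        net = cf.quartet_network(theta, "msci", "inflow", phi=0.2)
        data = cf.simulate_dataset(net, {s: 2 for s in "ABCO"}, 60, 500,
                                   "msci", seed=11)
        model = cf.MSCIModel(net)
        priors = cf.PriorSpec(2.0, 2 / (3 * theta), 2.0, 2 / theta)
        trace = cf.run_mcmc([a for _, a in data], model, priors,
                            cf.McmcSettings(burnin=800, samples=2000), seed=2)
        assert 0.02 < trace.posterior_mean("phi") < 0.55
        assert trace.posterior_mean("tau_T") == pytest.approx(theta, rel=0.5)
        assert trace.posterior_mean("log_likelihood") < 0
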