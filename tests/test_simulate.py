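"""Gene-tree and sequence simulation: closed-form checks, determinism, and
an equality-in-distribution comparison with msprime."""

import math

import numpy as np
import pytest

import coalflow as cf
from coalflow.simulate import GeneTree, simulate_jc_alignment
from coalflow.trees import Node, Tree


def _triplet_class(gt):
    tree = gt.tree.copy()
    for tip in tree.tips():
        tip.name = tip.name.split("^")[0]
    return cf.classify_triplet(tree, ("A", "B"), "O",
                               gene_flow_pair=("B", "C")).klass


def _class_freqs(net, mode, n_rep, seed, samples=None):
    rng = np.random.default_rng(seed)
    sim = (cf.simulate_gene_tree_msci if mode == "msci"
           else cf.simulate_gene_tree_mscm)
    samples = samples or {s: 1 for s in "ABCO"}
    out = {"con": 0, "dis1": 0, "dis2": 0}
    for _ in range(n_rep):
        out[_triplet_class(sim(net, samples, rng))] += 1
    return out


class TestMSCIClosedForms:
    N = 30_000

    def test_no_gene_flow_discordance(self):
        """With phi=0 the internal branch spans 2 coalescent units, so each
        discordant rooted triplet has probability e^(-2)/3."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.0)
        freqs = _class_freqs(net, "msci", self.N, seed=11)
        p = math.exp(-2) / 3
        se = math.sqrt(p * (1 - p) / self.N)
        for klass in ("dis1", "dis2"):
            assert abs(freqs[klass] / self.N - p) < 3 * se

    def test_full_introgression_topology(self):
        """With phi=1 every B lineage reparents into C at tau_X=theta/2, so
        P[((B,C),A)] = 1 - (2/3) e^(-3)."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=1.0)
        freqs = _class_freqs(net, "msci", self.N, seed=12)
        p = 1 - (2 / 3) * math.exp(-3)
        se = math.sqrt(p * (1 - p) / self.N)
        assert abs(freqs["dis2"] / self.N - p) < 3 * se

    def test_mixture_at_intermediate_phi(self):
        """P[((B,C),A)] is the phi-mixture of the two cases above; at
        phi=0.2 this is about 0.2294."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.2)
        freqs = _class_freqs(net, "msci", self.N, seed=13)
        p = 0.2 * (1 - (2 / 3) * math.exp(-3)) + 0.8 * math.exp(-2) / 3
        se = math.sqrt(p * (1 - p) / self.N)
        assert abs(freqs["dis2"] / self.N - p) < 3 * se

    def test_hybrid_flags_match_phi(self):
        """The logged reparenting indicator is Bernoulli(phi) for the B-tip
        lineage."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.3)
        rng = np.random.default_rng(14)
        hits = total = 0
        for _ in range(4000):
            gt = cf.simulate_gene_tree_msci(net, {s: 1 for s in "ABCO"}, rng)
            b_tip = next(t for t in gt.tree.tips()
                         if gt.tip_species[t.name] == "B")
            if b_tip in gt.hybrid_flags:
                total += 1
                hits += gt.hybrid_flags[b_tip]
        assert total == 4000  # the lone B lineage always crosses tau_X
        assert abs(hits / total - 0.3) < 3 * math.sqrt(0.3 * 0.7 / total)


class TestMSCM:
    def test_single_lineage_migration_probability(self):
        """One lineage in the recipient branch migrates at backward rate
        4M/theta, so P(>=1 jump over the band) = 1 - e^(-4 M dtau/theta)."""
        theta, M = 0.01, 0.1
        net = cf.quartet_network(theta, "mscm", "inflow", M=M)
        rng = np.random.default_rng(15)
        n = 30_000
        hits = sum(
            bool(cf.simulate_gene_tree_mscm(net, {"B": 1, "O": 1}, rng).migrations)
            for _ in range(n)
        )
        p = cf.expected_cumulative_introgression(M, theta, theta)
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_zero_rate_reduces_to_msc(self):
        theta = 0.01
        netm = cf.quartet_network(theta, "mscm", "inflow", M=0.0)
        neti = cf.quartet_network(theta, "msci", "inflow", phi=0.0)
        n = 8000
        fm = _class_freqs(netm, "mscm", n, seed=16)
        fi = _class_freqs(neti, "msci", n, seed=17)
        for k in fm:
            assert abs(fm[k] - fi[k]) / n < 0.02
        # and no migration events are ever logged
        rng = np.random.default_rng(18)
        gt = cf.simulate_gene_tree_mscm(netm, {s: 1 for s in "ABCO"}, rng)
        assert gt.migrations == []


class TestWithinSpeciesCoalescence:
    def test_mean_pairwise_time_is_half_theta(self):
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.0)
        rng = np.random.default_rng(19)
        ages = []
        for _ in range(4000):
            gt = cf.simulate_gene_tree_msci(net, {"A": 2, "O": 1}, rng)
            a_tips = [t for t in gt.tree.tips() if gt.tip_species[t.name] == "A"]
            anc = set()
            node = a_tips[0]
            while node is not None:
                anc.add(node)
                node = node.parent
            node = a_tips[1]
            while node not in anc:
                node = node.parent
            ages.append(node.age)
        mean = np.mean(ages)
        se = np.std(ages) / math.sqrt(len(ages))
        assert abs(mean - 0.005) < 3 * se


class TestJCSequenceEvolution:
    def _two_tip_tree(self, height):
        root = Node()
        root.age = height
        for nm in ("x", "y"):
            tip = Node(nm)
            tip.age = 0.0
            root.add_child(tip)
        t = Tree(root)
        t.set_lengths_from_ages()
        return GeneTree(t, {"x": "A", "y": "A"})

    def test_mismatch_fraction_closed_form(self, rng):
        gt = self._two_tip_tree(0.05)  # pairwise distance 0.1
        aln = simulate_jc_alignment(gt, 50_000, rng)
        b = aln.base_indices()
        p = 0.75 * (1 - math.exp(-0.4 / 3))
        mm = float((b[0] != b[1]).mean())
        assert abs(mm - p) < 3 * math.sqrt(p * (1 - p) / 50_000)

    def test_zero_length_branches_identical_sequences(self, rng):
        gt = self._two_tip_tree(0.0)
        aln = simulate_jc_alignment(gt, 200, rng)
        assert aln.sequence("x") == aln.sequence("y")

    def test_zero_sites(self, rng):
        gt = self._two_tip_tree(0.01)
        aln = simulate_jc_alignment(gt, 0, rng)
        assert aln.n_sites == 0 and aln.n_seqs == 2


class TestDataset:
    def test_same_seed_bitwise_identical(self, inflow_net):
        a = cf.simulate_dataset(inflow_net, {s: 1 for s in "ABCO"}, 3, 50,
                                "msci", seed=7)
        b = cf.simulate_dataset(inflow_net, {s: 1 for s in "ABCO"}, 3, 50,
                                "msci", seed=7)
        for (_, x), (_, y) in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_locus_substreams_independent_of_count(self, inflow_net):
        """Locus i is reproducible in isolation: the first loci of L=2 and
        L=5 datasets coincide."""
        a = cf.simulate_dataset(inflow_net, {s: 1 for s in "ABCO"}, 2, 40,
                                "msci", seed=8)
        b = cf.simulate_dataset(inflow_net, {s: 1 for s in "ABCO"}, 5, 40,
                                "msci", seed=8)
        assert np.array_equal(a[0][1].data, b[0][1].data)
        assert np.array_equal(a[1][1].data, b[1][1].data)

    def test_shapes(self, small_dataset):
        assert len(small_dataset) == 3
        for gt, aln in small_dataset:
            assert aln.n_seqs == 8 and aln.n_sites == 100
            assert len(gt.tree.tips()) == 8


class TestAgainstMsprime:
    def test_topology_frequencies_match_independent_simulator(self):
        """No-gene-flow quartet: rooted-triplet class frequencies and mean
        root age agree with msprime's coalescent on the same species tree."""
        msprime = pytest.importorskip("msprime")
        theta = 0.01
        n = 6000
        # msprime with ploidy=1 coalesces a pair at rate 1/Ne per
        # generation; mutational time with mu=1 needs Ne = theta/2 for the
        # MSC pairwise rate 2/theta
        demography = msprime.Demography()
        for pop in ("A", "B", "C", "O", "T", "S", "R"):
            demography.add_population(name=pop, initial_size=theta / 2)
        demography.add_population_split(time=theta, derived=["A", "B"],
                                        ancestral="T")
        demography.add_population_split(time=2 * theta, derived=["T", "C"],
                                        ancestral="S")
        demography.add_population_split(time=3 * theta, derived=["S", "O"],
                                        ancestral="R")
        freqs_ms = {"con": 0, "dis1": 0, "dis2": 0}
        roots_ms = []
        ts_iter = msprime.sim_ancestry(
            samples={p: 1 for p in "ABCO"}, demography=demography, ploidy=1,
            num_replicates=n, random_seed=99)
        for ts in ts_iter:
            t = ts.first()
            names = {j: ts.population(ts.node(j).population).metadata["name"]
                     for j in ts.samples()}
            a, b, c = (next(j for j in ts.samples() if names[j] == x)
                       for x in "ABC")
            tab = t.mrca(a, b)
            tac = t.mrca(a, c)
            tbc = t.mrca(b, c)
            if t.time(tab) < min(t.time(tac), t.time(tbc)):
                freqs_ms["con"] += 1
            elif t.time(tac) < t.time(tbc):
                freqs_ms["dis1"] += 1
            else:
                freqs_ms["dis2"] += 1
            roots_ms.append(t.time(t.root))
        net = cf.quartet_network(theta, "msci", "inflow", phi=0.0)
        freqs = {"con": 0, "dis1": 0, "dis2": 0}
        roots = []
        rng = np.random.default_rng(20)
        for _ in range(n):
            gt = cf.simulate_gene_tree_msci(net, {s: 1 for s in "ABCO"}, rng)
            freqs[_triplet_class(gt)] += 1
            roots.append(gt.tree.root.age)
        # chi-square on the three classes
        obs = np.array([freqs[k] for k in ("con", "dis1", "dis2")])
        exp = np.array([freqs_ms[k] for k in ("con", "dis1", "dis2")])
        from scipy.stats import chi2_contingency
        _, pval, _, _ = chi2_contingency(np.vstack([obs, exp]))
        assert pval > 0.001
        # mean root age within 4 combined standard errors
        se = math.hypot(np.std(roots) / math.sqrt(n),
                        np.std(roots_ms) / math.sqrt(n))
        assert abs(np.mean(roots) - np.mean(roots_ms)) < 4 * se


def test_invalid_inputs(inflow_net):
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        cf.simulate_gene_tree_mscm(inflow_net, {"A": 1}, rng)
    with pytest.raises(ValueError):
        cf.simulate_gene_tree_msci(inflow_net, {}, rng)
    with pytest.raises(ValueError):
        cf.simulate_dataset(inflow_net, {"A": 1}, 0, 10, "msci", 1)
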