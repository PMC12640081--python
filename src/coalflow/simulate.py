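"""Structured-coalescent simulation of gene trees on a species network, and
Jukes-Cantor sequence evolution along them.

Gene trees are simulated backward in time.  Within a population of size
theta, each pair of lineages coalesces at rate 2/theta per unit of
mutational time; a migration band (donor X -> recipient Y forward in time,
M migrants/generation) moves each lineage currently in Y into X at rate
4*M/theta_Y backward in time; at the time of a pulse introgression edge,
each lineage in the recipient branch independently reparents into the donor
branch with probability phi.  All event times are in expected substitutions
per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import LocusAlignment
from .network import SpeciesNetwork
from .trees import Node, Tree


@dataclass
class Migration:
    """A logged backward-in-time migration jump of one gene lineage."""

    node: Node  # the gene-tree node whose parent edge jumped
    time: float
    source: str  # population occupied before the jump (backward in time)
    dest: str


@dataclass
class GeneTree:
    """Ultrametric genealogy for one locus with its gene-flow event log.

    ``hybrid_flags`` records, for every gene-tree edge present in the
    recipient population at the introgression time, whether the lineage took
    the donor path (1) or stayed (0); keys are the child nodes of those
    edges.  ``migrations`` lists backward-in-time jumps under MSC-M.
    """

    tree: Tree
    tip_species: dict[str, str]
    hybrid_flags: dict[Node, int] = field(default_factory=dict)
    migrations: list[Migration] = field(default_factory=list)

    def label_for(self, species: str, individual: int) -> str:
        return f"{species}^{individual}"


def _sample_tips(net: SpeciesNetwork, samples_per_species: dict[str, int]):
    lineages: list[tuple[Node, str]] = []  # (gene-tree node, current population)
    tip_species: dict[str, str] = {}
    for sp in net.species():
        k = samples_per_species.get(sp, 0)
        if k < 0:
            raise ValueError(f"negative sample count for {sp!r}")
        for i in range(k):
            label = f"{sp}^{i + 1}"
            node = Node(label)
            node.age = 0.0
            lineages.append((node, sp))
            tip_species[label] = sp
    if not lineages:
        raise ValueError("no lineages sampled")
    return lineages, tip_species


def _finish(root: Node, tip_species, flags, migs) -> GeneTree:
    tree = Tree(root)
    tree.set_lengths_from_ages()
    root.length = None
    return GeneTree(tree, tip_species, flags, migs)


def simulate_gene_tree_msci(
    net: SpeciesNetwork,
    samples_per_species: dict[str, int],
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate one gene tree under the MSC with a single pulse introgression
    edge (or none).  ``samples_per_species`` maps extant species to their
    number of sampled haploid sequences."""
    if net.migration:
        raise ValueError("network has migration bands; use simulate_gene_tree_mscm")
    return _simulate(net, samples_per_species, rng)


def simulate_gene_tree_mscm(
    net: SpeciesNetwork,
    samples_per_species: dict[str, int],
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate one gene tree under the MSC with continuous migration."""
    if net.introgression is not None:
        raise ValueError("network has an introgression edge; use simulate_gene_tree_msci")
    return _simulate(net, samples_per_species, rng)


def _simulate(net, samples_per_species, rng) -> GeneTree:
    lineages, tip_species = _sample_tips(net, samples_per_species)
    flags: dict[Node, int] = {}
    migs: list[Migration] = []

    # epoch boundaries: species divergences, the pulse time, band endpoints
    divergences = sorted(
        (n.age, n) for n in net.tree.postorder() if not n.is_tip
    )
    boundaries: list[tuple[float, str, object]] = [
        (age, "div", node) for age, node in divergences
    ]
    if net.introgression is not None:
        boundaries.append((net.introgression.time, "pulse", net.introgression))
    band_intervals = [(band, *net.band_interval(band)) for band in net.migration]
    for band, lo, hi in band_intervals:
        boundaries.append((lo, "noop", None))
        if np.isfinite(hi):
            boundaries.append((hi, "noop", None))
    boundaries.sort(key=lambda b: b[0])

    t = 0.0
    bi = 0
    while len(lineages) > 1 or bi < len(boundaries):
        # rates in the current epoch
        counts: dict[str, int] = {}
        for _, pop in lineages:
            counts[pop] = counts.get(pop, 0) + 1
        coal_rates = {
            pop: k * (k - 1) / net.theta[pop] for pop, k in counts.items() if k > 1
        }
        mig_rates = []
        for band, lo, hi in band_intervals:
            if lo <= t < hi and counts.get(band.recipient, 0) > 0:
                rate = counts[band.recipient] * 4.0 * band.rate / net.theta[band.recipient]
                if rate > 0:
                    mig_rates.append((band, rate))
        total = sum(coal_rates.values()) + sum(r for _, r in mig_rates)

        t_next = boundaries[bi][0] if bi < len(boundaries) else np.inf
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf

        if t + wait < t_next:
            t += wait
            u = rng.uniform(0.0, total)
            acc = 0.0
            done = False
            for pop, rate in coal_rates.items():
                acc += rate
                if u < acc:
                    members = [i for i, (_, p) in enumerate(lineages) if p == pop]
                    i, j = rng.choice(len(members), size=2, replace=False)
                    a, pa = lineages[members[i]]
                    b, pb = lineages[members[j]]
                    parent = Node()
                    parent.age = t
                    parent.add_child(a)
                    parent.add_child(b)
                    keep = [
                        lineages[m] for m in range(len(lineages))
                        if m not in (members[i], members[j])
                    ]
                    keep.append((parent, pop))
                    lineages = keep
                    done = True
                    break
            if not done:
                for band, rate in mig_rates:
                    acc += rate
                    if u < acc:
                        members = [i for i, (_, p) in enumerate(lineages) if p == band.recipient]
                        m = members[rng.integers(len(members))]
                        node, _ = lineages[m]
                        lineages[m] = (node, band.donor)
                        migs.append(Migration(node, t, band.recipient, band.donor))
                        done = True
                        break
            assert done
        else:
            if bi >= len(boundaries):
                break
            t = t_next
            _, kind, obj = boundaries[bi]
            bi += 1
            if kind == "div":
                child_names = {c.name for c in obj.children}
                lineages = [
                    (node, obj.name if pop in child_names else pop)
                    for node, pop in lineages
                ]
            elif kind == "pulse":
                e = obj
                updated = []
                for node, pop in lineages:
                    if pop == e.recipient:
                        take = int(rng.random() < e.phi)
                        flags[node] = take
                        pop = e.donor if take else pop
                    updated.append((node, pop))
                lineages = updated
    root = lineages[0][0]
    return _finish(root, tip_species, flags, migs)


# -- sequence evolution ----------------------------------------------------

def simulate_jc_alignment(
    gtree: GeneTree, n_sites: int, rng: np.random.Generator, locus_id: str = "L1"
) -> LocusAlignment:
    """Evolve an alignment along a gene tree under Jukes-Cantor.

    The root state is uniform on {A,C,G,T}; along a branch of length d each
    site changes with probability (3/4)(1 - exp(-4d/3)), to each alternative
    base equally.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    tree = gtree.tree
    states: dict[Node, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=n_sites, dtype=np.uint8)
    }
    tip_rows = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        d = node.parent.age - node.age
        if d < 0:
            raise ValueError("negative branch length")
        p_change = 0.75 * -np.expm1(-4.0 * d / 3.0)
        parent_state = states[node.parent]
        state = parent_state.copy()
        if p_change > 0 and n_sites:
            hit = rng.random(n_sites) < p_change
            nhit = int(hit.sum())
            if nhit:
                state[hit] = (state[hit] + rng.integers(1, 4, size=nhit, dtype=np.uint8)) % 4
        if node.is_tip:
            tip_rows[node.name] = state
        else:
            states[node] = state
    labels = sorted(tip_rows)
    data = (
        np.vstack([np.uint8(1) << tip_rows[lab] for lab in labels])
        if labels else np.zeros((0, n_sites), np.uint8)
    )
    species = [gtree.tip_species[lab] for lab in labels]
    individuals = [lab.split("^", 1)[1] if "^" in lab else lab for lab in labels]
    return LocusAlignment(locus_id, labels, species, individuals, data)


# -- dataset-level simulation ----------------------------------------------

def locus_rng(seed: int, locus_index: int) -> np.random.Generator:
    """Per-locus substream: locus i is reproducible in isolation."""
    return np.random.default_rng([seed, locus_index])


def simulate_dataset(
    net: SpeciesNetwork,
    samples_per_species: dict[str, int],
    L: int,
    n_sites: int,
    mode: str = "msci",
    seed: int = 0,
) -> list[tuple[GeneTree, LocusAlignment]]:
    """Simulate ``L`` independent loci: gene trees plus JC alignments.

    Gene trees are retained for truth-aware evaluation.  The same seed gives
    bitwise-identical output.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    sim = {"msci": simulate_gene_tree_msci, "mscm": simulate_gene_tree_mscm}[mode]
    out = []
    for i in range(L):
        rng = locus_rng(seed, i)
        gt = sim(net, samples_per_species, rng)
        aln = simulate_jc_alignment(gt, n_sites, rng, locus_id=f"L{i + 1}")
        out.append((gt, aln))
    return out
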