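"""Full-likelihood Bayesian inference of introgression on a species quartet.

The model is the multispecies coalescent with one pulse introgression edge
(MSC-I) on the quartet (((A,B)T, C)S, O)R, with gene flow between the
nonsister tips B and C.  Gene trees are latent variables; the sampler
(:mod:`coalflow._kernel`) alternates gene-tree moves with parameter updates
and the test of gene flow is the Savage-Dickey ratio
B10 = P(phi < eps) / P(phi < eps | X) at a small eps.

This module also provides plain-Python implementations of the gene-tree
coalescent density and the JC pruning likelihood, which double as
independent cross-checks of the compiled kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernel
from .io import LocusAlignment
from .network import SpeciesNetwork
from .simulate import GeneTree, simulate_gene_tree_msci
from .trees import Node, Tree

ROLE_NAMES = ("A", "B", "C", "O", "T", "S", "R")


@dataclass
class PriorSpec:
    """Priors: tau_R ~ Gamma(tau_shape, tau_rate) (rate parameterization),
    the non-root divergence times flat on their ordering simplex given
    tau_R, the introgression time uniform on (0, tau_T), every branch
    theta ~ Gamma(theta_shape, theta_rate), and phi ~ Beta(phi_a, phi_b)."""

    tau_shape: float = 2.0
    tau_rate: float = 266.0
    theta_shape: float = 2.0
    theta_rate: float = 800.0
    phi_a: float = 1.0
    phi_b: float = 1.0

    def __post_init__(self):
        for v in (self.tau_shape, self.tau_rate, self.theta_shape,
                  self.theta_rate, self.phi_a, self.phi_b):
            if not v > 0:
                raise ValueError("prior hyperparameters must be > 0")

    def prior_phi_mass_below(self, eps: float) -> float:
        return float(stats.beta.cdf(eps, self.phi_a, self.phi_b))


@dataclass
class MSCIModel:
    """A quartet species network with exactly one introgression edge,
    mapped onto canonical roles A, B, C, O (tips), T, S, R (ancestors);
    the introgression edge runs between the nonsister tips B and C."""

    network: SpeciesNetwork
    roles: dict[str, str] = field(init=False)  # role -> species/branch name
    direction: str = field(init=False)  # "inflow" (C->B) or "outflow" (B->C)

    def __post_init__(self):
        net = self.network
        if net.introgression is None:
            raise ValueError("MSCIModel needs an introgression edge")
        if net.migration:
            raise ValueError("MSCIModel does not accept migration bands")
        root = net.tree.root
        if len(root.children) != 2:
            raise ValueError("quartet species tree must be binary")
        inner = [c for c in root.children if not c.is_tip]
        outer = [c for c in root.children if c.is_tip]
        if len(inner) != 1 or len(outer) != 1:
            raise ValueError("expected (((A,B),C),O) shape")
        s_node, o_tip = inner[0], outer[0]
        t_node = next((c for c in s_node.children if not c.is_tip), None)
        c_tip = next((c for c in s_node.children if c.is_tip), None)
        if t_node is None or c_tip is None or any(
            not c.is_tip for c in t_node.children
        ) or len(t_node.children) != 2:
            raise ValueError("expected (((A,B),C),O) shape")
        e = net.introgression
        pair = {e.donor, e.recipient}
        cherry = {c.name for c in t_node.children}
        if c_tip.name not in pair or not pair & cherry:
            raise ValueError(
                "introgression edge must connect the nonsister tips "
                f"(cherry {sorted(cherry)} and {c_tip.name})"
            )
        b_name = (pair & cherry).pop()
        a_name = (cherry - {b_name}).pop()
        self.roles = {
            "A": a_name, "B": b_name, "C": c_tip.name, "O": o_tip.name,
            "T": t_node.name, "S": s_node.name, "R": root.name,
        }
        self.direction = "inflow" if e.recipient == b_name else "outflow"

    @property
    def recipient_role(self) -> int:
        return 1 if self.direction == "inflow" else 2

    @property
    def donor_role(self) -> int:
        return 2 if self.direction == "inflow" else 1

    def role_of_species(self, species: str) -> int:
        for i, r in enumerate(ROLE_NAMES[:4]):
            if self.roles[r] == species:
                return i
        raise KeyError(f"species {species!r} not in model")

    def init_params(self, priors: PriorSpec) -> np.ndarray:
        """Deterministic warm start: prior means for tau_R and theta,
        evenly spaced internal times, phi at its prior mean."""
        tau_r = priors.tau_shape / priors.tau_rate
        th = priors.theta_shape / priors.theta_rate
        p = np.empty(12)
        p[_kernel.I_TAUT] = tau_r / 3.0
        p[_kernel.I_TAUS] = 2.0 * tau_r / 3.0
        p[_kernel.I_TAUR] = tau_r
        p[_kernel.I_TAUX] = tau_r / 6.0
        p[_kernel.I_PHI] = priors.phi_a / (priors.phi_a + priors.phi_b)
        p[_kernel.I_TH0:] = th
        return p


@dataclass
class McmcSettings:
    burnin: int = 2000
    samples: int = 4000
    thin: int = 1
    chains: int = 1


@dataclass
class PosteriorTrace:
    """Post-burn-in MCMC samples with seed provenance and acceptance rates."""

    df: pd.DataFrame
    seed: int
    settings: McmcSettings
    acceptance: dict[str, float]
    n_chains_used: int = 1
    n_chains_discarded: int = 0

    @property
    def phi(self) -> np.ndarray:
        return self.df["phi"].to_numpy()

    def posterior_mean(self, col: str) -> float:
        return float(self.df[col].mean())


def _params_from_network(model: MSCIModel) -> np.ndarray:
    net = model.network
    p = np.empty(12)
    p[_kernel.I_TAUT] = net.node(model.roles["T"]).age
    p[_kernel.I_TAUS] = net.node(model.roles["S"]).age
    p[_kernel.I_TAUR] = net.node(model.roles["R"]).age
    p[_kernel.I_TAUX] = net.introgression.time
    p[_kernel.I_PHI] = net.introgression.phi
    for i, r in enumerate(ROLE_NAMES):
        p[_kernel.I_TH0 + i] = net.theta[model.roles[r]]
    return p


def _network_at(model: MSCIModel, params: np.ndarray) -> SpeciesNetwork:
    """A copy of the model's network with parameter values ``params``."""
    from .network import IntrogressionEdge

    net = model.network
    tree = net.tree.copy()
    for role, tau_i in (("T", _kernel.I_TAUT), ("S", _kernel.I_TAUS),
                        ("R", _kernel.I_TAUR)):
        tree.find(model.roles[role]).age = float(params[tau_i])
    theta = {
        model.roles[r]: float(params[_kernel.I_TH0 + i])
        for i, r in enumerate(ROLE_NAMES)
    }
    e = net.introgression
    edge = IntrogressionEdge(e.donor, e.recipient,
                             float(params[_kernel.I_TAUX]),
                             float(params[_kernel.I_PHI]))
    return SpeciesNetwork(tree, theta, introgression=edge)


def _pack_locus(aln: LocusAlignment, model: MSCIModel):
    """Order sequences by (role, label) and compress site patterns."""
    entries = sorted(
        range(aln.n_seqs),
        key=lambda i: (model.role_of_species(aln.species[i]), aln.labels[i]),
    )
    tip_pop = np.array([model.role_of_species(aln.species[i]) for i in entries],
                       np.int64)
    mat = aln.data[entries]
    if mat.shape[1]:
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
    else:
        patterns = np.zeros((len(entries), 0), np.uint8)
        weights = np.zeros(0)
    return tip_pop, patterns, weights.astype(float)


def _genetree_to_arrays(gt: GeneTree, model: MSCIModel, k: int):
    """Flatten a simulated gene tree into kernel arrays, tips 0..k-1 ordered
    by (role, label) to match the packed alignment rows."""
    tree = gt.tree
    tips = sorted(
        tree.tips(),
        key=lambda n: (model.role_of_species(gt.tip_species[n.name]), n.name),
    )
    nn = 2 * k - 1
    idx = {t: i for i, t in enumerate(tips)}
    nxt = k
    for n in tree.postorder():
        if not n.is_tip:
            idx[n] = nxt
            nxt += 1
    parent = np.full(nn, -1, np.int64)
    age = np.zeros(nn)
    flag = np.zeros(nn, np.uint8)
    for n in tree.postorder():
        age[idx[n]] = n.age
        if n.parent is not None:
            parent[idx[n]] = idx[n.parent]
        flag[idx[n]] = gt.hybrid_flags.get(n, 0)
    return parent, age, flag


def run_mcmc(
    alignments: Sequence[LocusAlignment],
    model: MSCIModel,
    priors: PriorSpec,
    settings: Optional[McmcSettings] = None,
    seed: int = 0,
) -> PosteriorTrace:
    """Run the quartet MSC-I sampler on multi-locus data.

    With ``settings.chains > 1``, independent chains are run from seeds
    derived from ``seed``; chains whose posterior mean of phi strays from
    the across-chain median by more than three combined Monte-Carlo
    standard errors are discarded before traces are pooled.
    """
    settings = settings or McmcSettings()
    if settings.chains < 1:
        raise ValueError("need at least one chain")
    traces = []
    for c in range(settings.chains):
        traces.append(_run_single(alignments, model, priors, settings,
                                  seed + 1000003 * c))
    if settings.chains == 1:
        return traces[0]
    means = np.array([t.df["phi"].mean() for t in traces])
    mcse = np.array([
        t.df["phi"].std(ddof=1) / math.sqrt(max(_ess(t.phi), 1.0))
        for t in traces
    ])
    med = float(np.median(means))
    keep = [abs(m - med) <= 3.0 * max(s, 1e-12) for m, s in zip(means, mcse)]
    if not any(keep):
        keep = [True] * len(traces)
    kept = [t for t, k_ in zip(traces, keep) if k_]
    df = pd.concat([t.df for t in kept], ignore_index=True)
    return PosteriorTrace(df, seed, settings, kept[0].acceptance,
                          n_chains_used=len(kept),
                          n_chains_discarded=len(traces) - len(kept))


def _ess(x: np.ndarray, max_lag: int = 200) -> float:
    """Initial-positive-sequence effective sample size."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, min(max_lag, n - 1)):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return n / (1.0 + 2.0 * s)


def _run_single(alignments, model, priors, settings, seed) -> PosteriorTrace:
    k = None
    packed = []
    for aln in alignments:
        tip_pop_l, pat, wts = _pack_locus(aln, model)
        if k is None:
            k = len(tip_pop_l)
            tip_pop = tip_pop_l
        elif not np.array_equal(tip_pop, tip_pop_l):
            raise ValueError("all loci must share the same sampling configuration")
        packed.append((pat, wts))
    L = len(packed)
    if k is None:
        k = 4
        tip_pop = np.arange(4, dtype=np.int64)
    nn = 2 * k - 1
    maxpat = max((p.shape[1] for p, _ in packed), default=1) or 1
    tip_pat = np.zeros((max(L, 1), k, maxpat), np.uint8)
    pat_w = np.zeros((max(L, 1), maxpat))
    pat_n = np.zeros(max(L, 1), np.int64)
    for l, (pat, wts) in enumerate(packed):
        tip_pat[l, :, : pat.shape[1]] = pat
        pat_w[l, : len(wts)] = wts
        pat_n[l] = pat.shape[1]

    params0 = model.init_params(priors)
    counts: dict[str, int] = {}
    if L:
        for sp in alignments[0].species:
            counts[sp] = counts.get(sp, 0) + 1

    parent = np.zeros((max(L, 1), nn), np.int64)
    age = np.zeros((max(L, 1), nn))
    flag = np.zeros((max(L, 1), nn), np.uint8)
    init_net = _network_at(model, params0)
    for attempt in range(100):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 13, attempt])
        try:
            for l in range(L):
                gt = simulate_gene_tree_msci(init_net, counts, rng)
                parent[l], age[l], flag[l] = _genetree_to_arrays(gt, model, k)
            break
        except Exception:
            if attempt == 99:
                raise
    trace, acc, att = _kernel.run_chain(
        parent[:L], age[:L], flag[:L], tip_pop,
        tip_pat[:L], pat_w[:L], pat_n[:L],
        np.int64(model.donor_role), np.int64(model.recipient_role),
        priors.tau_shape, priors.tau_rate,
        priors.theta_shape, priors.theta_rate,
        priors.phi_a, priors.phi_b,
        params0,
        np.int64(settings.burnin), np.int64(settings.samples),
        np.int64(settings.thin), np.int64(seed & 0x7FFFFFFF),
    )
    cols = (["tau_T", "tau_S", "tau_R", "tau_X", "phi"]
            + [f"theta_{r}" for r in ROLE_NAMES]
            + ["log_coalescent", "log_likelihood"])
    df = pd.DataFrame(trace, columns=cols)
    move_names = ["gene_tree_age", "tau_X", "tau_T", "tau_S", "tau_R", "theta"]
    acceptance = {
        nm: (float(a) / float(t) if t else float("nan"))
        for nm, a, t in zip(move_names, acc, att)
    }
    return PosteriorTrace(df, seed, settings, acceptance)


# -- posterior summaries ---------------------------------------------------

def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding the requested
    posterior mass (the 95% HPD credible interval by default)."""
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n < 1:
        raise ValueError("need at least one sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    npts = min(n, int(math.ceil(mass * n)) + 1)
    widths = x[npts - 1:] - x[: n - npts + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + npts - 1])


@dataclass
class BayesFactor:
    """Savage-Dickey Bayes factor in favour of gene flow (phi > eps)."""

    b10: float
    epsilon: float
    prior_mass: float
    posterior_mass: float
    capped: bool = False

    @property
    def supports_gene_flow(self) -> bool:
        """Strong support for gene flow at the conventional 100 cut-off."""
        return self.b10 > 100.0


def savage_dickey_bf(
    trace, priors: PriorSpec, epsilon: float = 0.01
) -> BayesFactor:
    """B10 = P(phi < eps) / P(phi < eps | X).

    The posterior probability is the fraction of sampled phi values below
    eps; when no samples fall below eps the estimate is capped by
    substituting 1/N (flagged), since the trace cannot resolve smaller
    probabilities.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    phi = trace.phi if isinstance(trace, PosteriorTrace) else np.asarray(trace, float)
    n = len(phi)
    if n == 0:
        raise ValueError("empty trace")
    prior_mass = priors.prior_phi_mass_below(epsilon)
    post_count = int(np.sum(phi < epsilon))
    capped = post_count == 0
    post_mass = (post_count if post_count else 1) / n
    return BayesFactor(prior_mass / post_mass, epsilon, prior_mass,
                       post_count / n, capped)


# -- reference (pure-Python) density and likelihood ------------------------

def msci_gene_tree_log_density(gtree: GeneTree, net: SpeciesNetwork) -> float:
    """Coalescent log density of one gene tree under an MSC-I network.

    Product over populations of e^(-n(n-1) dt / theta) per inter-event
    interval and 2/theta per coalescence, times phi (or 1-phi) per lineage
    present in the recipient branch at the introgression time according to
    its logged path flag.  Raises ValueError if the gene tree is
    incompatible with the network (a coalescence between lineages in
    different populations).
    """
    tree = gtree.tree
    e = net.introgression
    events: list[tuple[float, str, object]] = [
        (n.age, "div", n) for n in net.tree.postorder() if not n.is_tip
    ]
    if e is not None:
        events.append((e.time, "pulse", e))
    events.sort(key=lambda t: t[0])

    def evolve(pop: str, flg: int, t0: float, t: float) -> str:
        for b, kind, obj in events:
            if t0 < b <= t:
                if kind == "pulse":
                    if pop == obj.recipient and flg == 1:
                        pop = obj.donor
                else:
                    if pop in {c.name for c in obj.children}:
                        pop = obj.name
        return pop

    start: dict[Node, str] = {}
    segs: list[tuple[str, float, float]] = []
    c_count: dict[str, int] = {}
    n1 = n0 = 0
    for n in tree.postorder():
        if n.is_tip:
            start[n] = gtree.tip_species[n.name]
        else:
            pops = {
                evolve(start[c], gtree.hybrid_flags.get(c, 0), c.age, n.age)
                for c in n.children
            }
            if len(pops) != 1:
                raise ValueError(
                    f"incompatible state: children of node at age {n.age} "
                    f"sit in populations {sorted(pops)}"
                )
            start[n] = pops.pop()
            c_count[start[n]] = c_count.get(start[n], 0) + 1
    for n in tree.postorder():
        if n.parent is None:
            continue
        t0, te = n.age, n.parent.age
        flg = gtree.hybrid_flags.get(n, 0)
        pop = start[n]
        cur = t0
        for b, kind, obj in events:
            if b <= cur:
                continue
            if b >= te:
                break
            segs.append((pop, cur, b))
            if kind == "pulse":
                if pop == obj.recipient and flg == 1:
                    pop = obj.donor
            else:
                if pop in {c.name for c in obj.children}:
                    pop = obj.name
            cur = b
        segs.append((pop, cur, te))
        if e is not None and t0 < e.time <= te and start[n] == e.recipient:
            if flg == 1:
                n1 += 1
            else:
                n0 += 1

    ld = 0.0
    for pop, cnt in c_count.items():
        ld += cnt * math.log(2.0 / net.theta[pop])
    A: dict[str, float] = {}
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[i][0] == segs[j][0]:
                lo = max(segs[i][1], segs[j][1])
                hi = min(segs[i][2], segs[j][2])
                if hi > lo:
                    A[segs[i][0]] = A.get(segs[i][0], 0.0) + 2.0 * (hi - lo)
    for pop, a in A.items():
        ld -= a / net.theta[pop]
    if e is not None and (n1 or n0):
        if (n1 and e.phi <= 0.0) or (n0 and e.phi >= 1.0):
            return -math.inf
        ld += n1 * math.log(e.phi) if n1 else 0.0
        ld += n0 * math.log(1.0 - e.phi) if n0 else 0.0
    return ld


def jc_log_likelihood(aln: LocusAlignment, gtree) -> float:
    """Felsenstein pruning log-likelihood under JC, with site-pattern
    compression; ambiguity codes contribute a partial likelihood of 1 for
    every compatible base."""
    tree = gtree.tree if isinstance(gtree, GeneTree) else gtree
    tips = tree.tips()
    if sorted(t.name for t in tips) != sorted(aln.labels):
        raise ValueError("gene-tree tips do not match alignment labels")
    rows = np.vstack([aln.data[aln.labels.index(t.name)] for t in tips])
    if rows.shape[1] == 0:
        return 0.0
    patterns, weights = np.unique(rows, axis=1, return_counts=True)
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    partial = {
        t: ((patterns[i][:, None] & bits[None, :]) > 0).astype(float)
        for i, t in enumerate(tips)
    }
    for n in tree.postorder():
        if n.is_tip:
            continue
        prod = np.ones((patterns.shape[1], 4))
        for c in n.children:
            d = n.age - c.age if n.age is not None else c.length
            ee = math.exp(-4.0 * d / 3.0)
            pv = partial.pop(c)
            prod *= 0.25 * (1 - ee) * pv.sum(axis=1, keepdims=True) + ee * pv
        partial[n] = prod
    site = 0.25 * partial[tree.root].sum(axis=1)
    return float(weights @ np.log(site))
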