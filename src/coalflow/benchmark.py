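"""Benchmark harness: simulate quartet datasets under the four gene-flow
models (inflow/outflow x pulse/continuous), run the Bayesian and summary
analysis arms, and tabulate power, bias, credible-interval width and
coverage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .bayes import (MSCIModel, McmcSettings, PriorSpec, hpd_interval,
                    run_mcmc, savage_dickey_bf)
from .genetree import classify_triplet, ml_gene_trees
from .network import expected_cumulative_introgression, quartet_network
from .summaries import TripletCounts, blt_test, d_statistic, dct_test, quibl_test

GENERATING_MODELS = ("inflow-I", "inflow-M", "outflow-I", "outflow-M")
ARMS = ("bayes", "dct", "blt", "quibl", "dstat")


@dataclass
class ExperimentConfig:
    """One benchmark run: generating models x data-size grid x arms.

    Defaults mirror the quartet study design: introgression probability
    phi = 0.2 at tau_X = theta/2 under the pulse model, migration rate
    M = 0.1 migrants/generation under the continuous model, divergence
    times (tau_T, tau_S, tau_R) = (1, 2, 3) * theta.
    """

    generating: tuple[str, ...] = ("inflow-I",)
    arms: tuple[str, ...] = ("dct",)
    L: tuple[int, ...] = (250,)
    S: tuple[int, ...] = (2,)
    n: tuple[int, ...] = (250,)
    theta: tuple[float, ...] = (0.0025,)
    replicates: int = 10
    seed: int = 0
    alpha: float = 0.01
    phi: float = 0.2
    M: float = 0.1
    bayes_settings: McmcSettings = field(
        default_factory=lambda: McmcSettings(burnin=1500, samples=8000)
    )
    bf_cutoff: float = 100.0
    use_true_gene_trees: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for g in self.generating:
            if g not in GENERATING_MODELS and g != "null":
                raise ValueError(f"unknown generating model {g!r}")
        for a in self.arms:
            if a not in ARMS:
                raise ValueError(f"unknown arm {a!r}")
        if not (self.generating and self.arms and self.L and self.S
                and self.n and self.theta):
            raise ValueError("grid must be nonempty")

    def settings(self):
        return list(product(self.generating, self.L, self.S, self.n, self.theta))


@dataclass
class MetricsTable:
    """Per-replicate raw results; aggregate with :func:`power_table` and
    :func:`estimation_table`."""

    replicates: pd.DataFrame
    config: ExperimentConfig


def _truth(gen: str, cfg: ExperimentConfig, theta: float) -> float:
    """True phi, or for continuous gene flow the expected cumulative
    introgression probability phi0 over the band (duration tau_T = theta)."""
    if gen == "null":
        return 0.0
    if gen.endswith("-I"):
        return cfg.phi
    return expected_cumulative_introgression(cfg.M, theta, theta)


def _simulate_setting(gen, L, S, n, theta, cfg, rep):
    from .simulate import simulate_dataset

    seed = int(np.random.SeedSequence(
        [cfg.seed, GENERATING_MODELS.index(gen) if gen != "null" else 9,
         L, S, n, int(theta * 1e6), rep]
    ).generate_state(1)[0] % (2**31))
    if gen == "null":
        net = quartet_network(theta, "msci", "inflow", phi=0.0)
        mode = "msci"
    else:
        direction = "inflow" if gen.startswith("inflow") else "outflow"
        mode = "msci" if gen.endswith("-I") else "mscm"
        net = quartet_network(theta, mode, direction, phi=cfg.phi, M=cfg.M)
    samples = {sp: S for sp in "ABCO"}
    data = simulate_dataset(net, samples, L, n, mode, seed)
    return net, data, seed


def run_replicate(gen, L, S, n, theta, cfg: ExperimentConfig, rep: int) -> list[dict]:
    net, data, seed = _simulate_setting(gen, L, S, n, theta, cfg, rep)
    gene_trees = [gt for gt, _ in data]
    alignments = [aln for _, aln in data]
    direction = "outflow" if gen.startswith("outflow") else "inflow"
    rows = []
    base = dict(generating=gen, L=L, S=S, n=n, theta=theta, replicate=rep,
                truth=_truth(gen, cfg, theta))

    needs_trees = bool({"dct", "blt", "quibl"} & set(cfg.arms))
    counts: Optional[TripletCounts] = None
    if needs_trees:
        if cfg.use_true_gene_trees:
            import numpy as _np

            classifications = []
            for i, gt in enumerate(gene_trees):
                rng = _np.random.default_rng([seed, 7, i])
                keep = {}
                for sp in "ABCO":
                    labs = [t for t, s in gt.tip_species.items() if s == sp]
                    keep[sp] = labs[int(rng.integers(len(labs)))]
                sub = _restrict(gt.tree, set(keep.values()))
                for t in sub.tips():
                    t.name = [sp for sp, lab in keep.items() if lab == t.name][0]
                classifications.append(classify_triplet(
                    sub, ("A", "B"), "O", gene_flow_pair=("B", "C"),
                    locus_id=f"L{i+1}"))
        else:
            fits = ml_gene_trees(alignments, ["A", "B", "C", "O"], seed=seed)
            classifications = [
                classify_triplet(f.tree(), ("A", "B"), "O",
                                 gene_flow_pair=("B", "C"),
                                 locus_id=f"L{i+1}", tie=f.tie)
                for i, f in enumerate(fits)
            ]
        counts = TripletCounts.from_classifications(classifications)
        counts_all = TripletCounts.from_classifications(classifications,
                                                        drop_ties=False)

    for arm in cfg.arms:
        row = dict(base, arm=arm, estimate=np.nan, p_or_bf=np.nan,
                   significant=False, ci_low=np.nan, ci_high=np.nan,
                   failed=False)
        try:
            if arm == "dct":
                phi_hat, p = dct_test(counts)
                row.update(estimate=phi_hat, p_or_bf=p,
                           significant=p < cfg.alpha)
            elif arm == "blt":
                p, direc = blt_test(counts.lengths_dis1, counts.lengths_dis2)
                row.update(p_or_bf=p, significant=p < cfg.alpha)
            elif arm == "quibl":
                from .genetree import jc_distance

                calls = quibl_test(counts_all, resolution=jc_distance(1.0 / n))
                row.update(significant=calls["triplet"],
                           p_or_bf=float(calls["triplet"]))
            elif arm == "dstat":
                D, z, p = d_statistic(alignments, ("A", "B", "C", "O"), seed=seed)
                row.update(estimate=D, p_or_bf=p, significant=p < cfg.alpha)
            elif arm == "bayes":
                inet = quartet_network(theta, "msci", direction, phi=cfg.phi)
                model = MSCIModel(inet)
                priors = PriorSpec(2.0, 2.0 / (3.0 * theta), 2.0, 2.0 / theta)
                trace = run_mcmc(alignments, model, priors, cfg.bayes_settings,
                                 seed=seed)
                bf = savage_dickey_bf(trace, priors)
                lo, hi = hpd_interval(trace.phi, 0.95)
                row.update(estimate=trace.posterior_mean("phi"),
                           p_or_bf=bf.b10,
                           significant=bf.b10 > cfg.bf_cutoff,
                           ci_low=lo, ci_high=hi)
        except Exception:
            row["failed"] = True
        rows.append(row)
    return rows


def _restrict(tree, keep: set):
    """Copy of a tree pruned to the given tip labels (suppressing unary
    nodes, summing lengths)."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder()):
            if node.is_tip and node.name not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_tip and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                child.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = child
                changed = True
    while len(t.root.children) == 1:
        t.root = t.root.children[0]
        t.root.parent = None
        t.root.length = None
    return t


def run_grid(cfg: ExperimentConfig, out_dir: Optional[str] = None) -> MetricsTable:
    """Run the full grid; deterministic given the base seed.  With
    ``out_dir``, per-replicate rows are checkpointed to replicates.tsv as
    they complete."""
    rows = []
    ckpt = None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        ckpt = os.path.join(out_dir, "replicates.tsv")
    for gen, L, S, n, theta in cfg.settings():
        for rep in range(cfg.replicates):
            new = run_replicate(gen, L, S, n, theta, cfg, rep)
            rows.extend(new)
            if ckpt:
                pd.DataFrame(rows).to_csv(ckpt, sep="\t", index=False)
    df = pd.DataFrame(rows)
    table = MetricsTable(df, cfg)
    if out_dir:
        power_table(table).to_csv(os.path.join(out_dir, "power.tsv"),
                                  sep="\t", index=False)
        estimation_table(table).to_csv(os.path.join(out_dir, "estimation.tsv"),
                                       sep="\t", index=False)
    return table


_KEYS = ["generating", "L", "S", "n", "theta", "arm"]


def power_table(metrics: MetricsTable) -> pd.DataFrame:
    """Percent of successful replicates rejecting no-gene-flow, per
    (setting, arm); rows with no successful replicate are flagged NA."""
    df = metrics.replicates
    out = []
    for key, grp in df.groupby(_KEYS):
        ok = grp[~grp["failed"]]
        out.append(dict(zip(_KEYS, key),
                        n_ok=len(ok), n_failed=int(grp["failed"].sum()),
                        power=(100.0 * ok["significant"].mean()
                               if len(ok) else np.nan)))
    return pd.DataFrame(out)


def estimation_table(metrics: MetricsTable) -> pd.DataFrame:
    """Mean estimate, bias against the generating truth (phi, or phi0 for
    continuous-gene-flow data analysed under the pulse model), and for the
    Bayesian arm the mean 95% HPD CI width and empirical coverage."""
    df = metrics.replicates
    out = []
    for key, grp in df.groupby(_KEYS):
        ok = grp[~grp["failed"]]
        est = ok["estimate"].dropna()
        truth = float(grp["truth"].iloc[0])
        rec = dict(zip(_KEYS, key), truth=truth,
                   mean_estimate=float(est.mean()) if len(est) else np.nan,
                   bias=float(est.mean() - truth) if len(est) else np.nan)
        if key[_KEYS.index("arm")] == "bayes" and len(ok):
            widths = (ok["ci_high"] - ok["ci_low"]).dropna()
            cover = ((ok["ci_low"] <= truth) & (truth <= ok["ci_high"])).mean()
            rec["mean_ci_width"] = float(widths.mean()) if len(widths) else np.nan
            rec["coverage"] = 100.0 * float(cover)
        out.append(rec)
    return pd.DataFrame(out)
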