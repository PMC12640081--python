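# Methods

## Models

**Species network.** A rooted binary species tree with node ages `tau` and
per-branch population sizes `theta`, both in expected substitutions per
site (`theta = 4*N*mu`). Gene flow is represented either as one pulse
introgression edge (donor branch, recipient branch, time `tau_X`,
probability `phi`; MSC-I) or as directed migration bands (rate `M` in
migrants per generation, active over the temporal overlap of donor and
recipient branches unless narrowed in the configuration; MSC-M). The
benchmark quartet is `(((A,B)T, C)S, O)R` with `tau_T, tau_S, tau_R =
(1, 2, 3)*theta`, gene flow between the nonsister tips B and C ("inflow"
C→B, "outflow" B→C), `phi = 0.2` at `tau_X = theta/2` under MSC-I, and
`M = 0.1` under MSC-M, with `theta` in {0.0025, 0.01}. These are the
generator's defaults; `L` in {250, 1000, 4000} loci, `S` in {2, 8}
sequences per species and `n` in {250, 1000} sites define the data-size
grid.

**Simulation.** Backward-in-time structured coalescent: within a
population each lineage pair coalesces at rate `2/theta`; a lineage in the
recipient of a band jumps into the donor at rate `4*M/theta_recipient`
(this parameterization makes the cumulative introgression probability of a
band exactly `phi0 = 1 - exp(-4*M*dtau/theta)`); at a pulse, each lineage
present in the recipient reparents into the donor independently with
probability `phi`, and the choice is logged per lineage. Sequences evolve
by Jukes–Cantor: uniform root state, change probability
`(3/4)(1-exp(-4d/3))` per branch of length `d`. Each locus uses an
independent, counter-derived RNG substream, so locus `i` is reproducible
in isolation. Extant species only are sampled.

What the generator does *not* emulate: intralocus recombination,
selection, mutation-rate variation among sites or loci, non-JC
substitution processes, sequencing error, or more than one introgression
edge. Passing tests therefore demonstrate correctness of the methods under
the model's own assumptions, not robustness to these realities.

## Per-locus gene trees for summary tests

Quartet gene trees are estimated by exhaustive ML under JC: for each of
the three unrooted topologies the five branch lengths are optimized by
L-BFGS-B (bounds `[1e-9, 5]`, analytic gradients, distance-based plus flat
multi-starts, log-likelihood tolerance ~1e-12), and the argmax is taken.
Topology ties (score gap < 1e-9) and effectively unresolved trees
(internal branch at the lower bound) are flagged; flagged loci are
excluded from topology counts. With `S > 1` sequences per species, one
sequence per species is drawn at random (seeded) per locus.

A caveat that matters downstream: with `n` sites, estimated branch
lengths are quantized near multiples of the one-substitution distance
(~`-0.75*ln(1 - 4/(3n))`). At `theta = 0.0025` and `n = 250` the true
internal branches are shorter than this resolution, so the length
distribution collapses onto a few spikes.

## Summary tests

* **DCT** — `phi_hat = (c_dis2 - c_dis1)/(c_con + c_dis1 + c_dis2)`,
  truncated to 0 when `c_dis1 > c_dis2`; significance by an exact
  two-sided binomial test of `c_dis2` against `c_dis1` with success
  probability 1/2 (the two discordant classes are equiprobable under ILS).
  The binomial is our choice of test statistic; exactness makes the test
  conservative at small discordant counts.
* **BLT** — two-sided Mann–Whitney U on the internal branch lengths of
  the two discordant classes; chosen over a t-test because the lengths are
  exponential-like. The reported direction is the smaller-mean class.
* **QuIBL-style mixture** — within a discordant class, internal branch
  lengths are modeled as `pi1*Exp(lam) + pi2*ShiftedExp(lam, C)`, fitted
  by EM with the shift `C` profiled on a 50-point grid over
  `[0, max length]`; model choice by BIC (`k = 1` vs `k = 3`). Three
  robustness decisions, all forced by the quantization noted above:
  (i) the likelihood is interval-censored at the measurement resolution
  of the lengths — the one-substitution JC distance for the alignment
  length, supplied by the caller (with a min-positive-value fallback) —
  whenever that resolution is material (> 5% of the mean length); without
  censoring, a shifted component can collapse onto a one-substitution
  spike and the density becomes unbounded; (ii) a positive call requires
  the fitted shift to span at least two measurement quanta — a smaller
  shift cannot be told apart from discretization; (iii) the triplet-level
  call requires the gene-flow class (dis2) to show a resolvable shifted
  component (`dBIC >= 10`, `pi2 >= 0.1`) while the other discordant class
  (dis1) shows neither a resolvable component nor strong unresolvable
  "mixture" evidence. dis1 can only contain ILS trees, so it serves as a
  negative control: a signal there marks estimation artifacts, not gene
  flow. The mixture data include the unresolved (tie-flagged) loci, whose
  near-zero lengths anchor the short end of the distribution. This is a
  concrete, testable variant; fidelity to the original QuIBL
  implementation is not claimed.
* **D-statistic** — `D = (nABBA - nBABA)/(nABBA + nBABA)` over all loci
  with the outgroup allele taken as ancestral, biallelic sites only; the
  standard error comes from a delete-one-locus jackknife and the p-value
  from a two-sided normal test.

## Bayesian MSC-I inference

The sampler targets the joint posterior of `(tau_T, tau_S, tau_R, tau_X,
phi, theta_1..7)` and per-locus latent gene trees on the quartet. The
gene-tree density is the product over populations of standard coalescent
factors (`exp(-k(k-1) dt / theta)` per interval, `2/theta` per
coalescence) times `phi^(flagged) (1-phi)^(unflagged)` over the lineages
present in the recipient branch at `tau_X`; the sequence likelihood is
Felsenstein pruning under JC on compressed site patterns. Donor and
recipient branches keep a single `theta` across the introgression time
point (the linked parameterization), which in this representation is
automatic because a branch is never split.

Priors: `tau_R ~ Gamma(shape, rate)` (defaults 2, 266), interior
divergence times flat on their ordering simplex given `tau_R` (density
`2/tau_R^2`), `tau_X | tau_T ~ U(0, tau_T)`, each branch
`theta ~ Gamma(2, 800)`, `phi ~ Beta(1, 1)`. In the benchmark the gamma
rates are set so the prior means equal the generating values.

Moves per sweep: for each locus a node-age slide (reflected in its
bracket), a nearest-neighbour interchange, a joint flag-flip plus
parent-age redraw (the flip alone is usually blocked because a lineage's
coalescence time is only compatible with its current path), and a
sequential MH scan over all path flags; then a Gibbs draw for `phi` from
`Beta(1 + n_donor, 1 + n_main)`, log-scale random walks for each `theta`
using per-population sufficient statistics, a reflected slide for
`tau_X`, rubber-band moves for `tau_T` and `tau_S` (gene-tree ages
between the flanking divergence times are remapped piecewise-linearly;
the Jacobian enters the Hastings ratio), and a multiplier move for
`tau_R` rescaling all older ages. Proposals that change which gene-tree
edges cross `tau_X` draw the new flags from `Bernoulli(phi)`; those
proposal factors cancel the matching `phi` terms of the target, so the
ratio keeps only the unchanged-edge terms. Step sizes are tuned toward
~30% acceptance during burn-in and frozen afterwards. Initialization is a
deterministic warm start (prior means; gene trees simulated from the
model at those values), re-drawn up to 100 times if a start is invalid.

Correctness was established by: exact normalization of the gene-tree
density under numerical integration; equality (to 1e-9) between the
compiled kernel and an independently written pure-Python density;
fixed-parameter gene-tree MCMC reproducing the simulator's distribution
(including `P(flag) = phi`); prior recovery of all parameter moments from
runs with zero loci; and posterior coverage on simulated data.

Summaries: 95% HPD intervals (shortest window over sorted samples) and
the Savage–Dickey ratio `B10 = P(phi < eps)/P(phi < eps | X)` at
`eps = 0.01`, with the posterior probability estimated as the fraction of
sampled `phi` below `eps`. When no sample falls below `eps` the estimate
is capped by substituting `1/N` and flagged; a trace must therefore hold
more than `100/eps` samples before `B10 > 100` is reachable, which sets
the minimum chain length used in power runs (12 000 recorded sweeps).
Multiple chains can be run and pooled; chains whose posterior mean of
`phi` strays more than three Monte-Carlo standard errors from the
across-chain median are discarded.

Known limitation: chains on outflow-model data mix more slowly in `phi`
than inflow chains (path flips are more often gated by gene-tree
compatibility), which is why the outflow runs below use the longest
chains. Effective sample sizes for `phi` of a few tens per 20 000 sweeps
are typical there; interval widths stabilize but retain a few percent of
run-to-run noise.

## Benchmark harness and desk-scale defaults

`benchmark.run_grid` simulates each (generating model, L, S, n, theta)
cell, runs the requested arms, and writes per-replicate rows plus power
and estimation tables. Decisions use `B10 > 100` for the Bayesian arm and
`p < 0.01` for summary arms; failed replicates are excluded from
denominators and counted. For data generated under migration the
estimation target for pulse-model analyses is `phi0` from the band.

Problem sizes in the shipped tests are desk-scale choices: Monte-Carlo
closed-form checks use 1e5 draws; the Bayesian power check runs 3
replicates of the least-informative setting with 12 000-sample chains;
parameter recovery averages 3 informative replicates; the inflow/outflow
width contrast uses 3 replicates per direction at L = 250 with two pooled
chains per replicate (10 000 samples each for inflow, 18 000 for the
slower-mixing outflow arm); null calibration uses 1000 replicates at the
gene-tree level. The acceptance script's outflow power target uses the
full L = 250, 20-replicate setting. Replicate counts are presets
(`paper` = 100, `desk` = 10) in the CLI harness.
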