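# coalflow

Simulation and detection of cross-species gene flow under the multispecies
coalescent (MSC), built to compare a full-likelihood Bayesian test of
introgression against the summary tests commonly used in phylogenomics.

When two species exchange migrants, gene trees at individual loci deviate
from the species tree in characteristic ways. Incomplete lineage sorting
(ILS) alone also produces discordance, so distinguishing gene flow from ILS
is a statistical problem. `coalflow` implements both sides of that problem
on a four-species quartet `(((A,B)T, C)S, O)R` with gene flow between the
nonsister tips B and C:

* **Simulation** — structured-coalescent gene trees under the MSC with
  either a pulse of introgression at time `tau_X` with probability `phi`
  (MSC-I) or continuous migration at rate `M` migrants/generation over a
  time interval (MSC-M), plus Jukes–Cantor sequence evolution. Times and
  population sizes are in expected substitutions/site (`theta = 4*N*mu`);
  the pairwise coalescent rate in a population is `2/theta` and the
  backward per-lineage migration rate is `4*M/theta`.
* **Summary tests** — per-locus quartet gene trees by exhaustive ML under
  JC, and on top of them the discordant-count test (DCT, with the estimator
  `phi_hat = (c_dis2 - c_dis1)/(c_con + c_dis1 + c_dis2)` truncated at 0),
  a branch-length test (BLT, Mann–Whitney on discordant-class internal
  branches), a QuIBL-style exponential-mixture test with BIC model choice,
  and the ABBA–BABA D-statistic with a per-locus block jackknife.
* **Bayesian inference** — a full-likelihood MSC-I sampler over latent
  gene trees (Felsenstein pruning under JC, Metropolis-within-Gibbs over
  gene-tree ages/topologies/introgression paths and the parameters
  `tau, theta, phi`), 95% HPD intervals, and the Savage–Dickey Bayes
  factor `B10 = P(phi < eps) / P(phi < eps | X)` with `eps = 0.01` and the
  conventional `B10 > 100` cut-off.
* **Benchmarking** — a grid harness that simulates under the four
  gene-flow models (inflow/outflow x pulse/continuous), runs every
  analysis arm, and tabulates power, bias, HPD width and coverage.
* **Conversion between the two gene-flow models** — the cumulative
  introgression probability implied by a migration band,
  `phi0 = 1 - exp(-4*M*dtau/theta)`.

## Worked example

Simulate an inflow-introgression dataset and run the Bayesian test and the
summary tests:

```python
import coalflow as cf

theta = 0.0025
net = cf.quartet_network(theta, "msci", "inflow", phi=0.2)  # tau_X = theta/2
data = cf.simulate_dataset(net, {s: 2 for s in "ABCO"}, L=250, n_sites=250,
                           mode="msci", seed=42)
alns = [aln for _, aln in data]

priors = cf.PriorSpec(2.0, 2 / (3 * theta), 2.0, 2 / theta)  # means at truth
trace = cf.run_mcmc(alns, cf.MSCIModel(net), priors,
                    cf.McmcSettings(burnin=2000, samples=12000), seed=5)
bf = cf.savage_dickey_bf(trace, priors)
lo, hi = cf.hpd_interval(trace.phi)
print(f"posterior mean phi = {trace.posterior_mean('phi'):.3f}, "
      f"95% HPD = ({lo:.3f}, {hi:.3f}), B10 = {bf.b10:.0f}")
```

With seed 42/5 this prints

```
posterior mean phi = 0.173, 95% HPD = (0.107, 0.236), B10 = 120
```

i.e. the posterior concentrates away from zero (the generating value is
0.2; at 250 short loci the interval is wide), and the Bayes factor exceeds
the 100 cut-off, so gene flow is detected. `B10 = 120` is the resolution
cap of a 12 000-sample trace: no sampled `phi` fell below `eps`
(`bf.capped` is `True`).

The same pipeline from a shell:

```bash
coalflow simulate --config net.yaml --loci 250 --sites 250 --samples 2 \
        --mode msci --seed 42 --out sim/
coalflow summary-tests --in sim/data.phy --taxa A,B,C,O --pair B,C \
        --alpha 0.01 --out results.tsv
coalflow bayes --aln sim/data.phy --model net.yaml --theta-prior 2,800 \
        --tau-prior 2,266 --burnin 2000 --samples 12000 --seed 5 --out trace.tsv
```

And the migration-to-introgression conversion:

```python
>>> cf.expected_cumulative_introgression(0.568, 0.0748 - 0.0260, 0.0692)
0.7985...
```

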