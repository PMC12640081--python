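"""Summary tests of gene flow on species triplets/quartets.

* DCT (discordant count test): compares the counts of the two discordant
  rooted-triplet topologies, which are equiprobable under incomplete
  lineage sorting alone; the printed estimator is
  phi_hat = (c_dis2 - c_dis1)/(c_con + c_dis1 + c_dis2), truncated to 0
  when c_dis1 > c_dis2.  Significance by an exact two-sided binomial test.
* BLT (branch length test): two-sample Mann-Whitney U contrast of the
  internal branch lengths of the two discordant classes (gene flow makes
  coalescence in the introgressed class more recent, shortening the
  subtending branch).
* A QuIBL-style test: the internal branch lengths of a discordant class
  are modeled as a mixture of an exponential (ILS) and a shifted
  exponential (introgression); model choice by BIC.
* The ABBA-BABA D-statistic on site-pattern counts with a per-locus
  block-jackknife standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genetree import TripletClassification
from .io import LocusAlignment


@dataclass
class TripletCounts:
    """Topology counts and per-class internal branch lengths for a focal
    rooted triplet."""

    c_con: int
    c_dis1: int
    c_dis2: int
    lengths_con: list[float] = field(default_factory=list)
    lengths_dis1: list[float] = field(default_factory=list)
    lengths_dis2: list[float] = field(default_factory=list)

    def __post_init__(self):
        for c, ls in (
            (self.c_con, self.lengths_con),
            (self.c_dis1, self.lengths_dis1),
            (self.c_dis2, self.lengths_dis2),
        ):
            if ls and len(ls) != c:
                raise ValueError("count does not match number of branch lengths")

    @classmethod
    def from_classifications(
        cls, classifications: Sequence[TripletClassification], drop_ties: bool = True
    ) -> "TripletCounts":
        """Collate per-locus classifications; tied/zero-length loci are
        excluded from the counts by default."""
        buckets = {"con": [], "dis1": [], "dis2": []}
        for c in classifications:
            if drop_ties and c.tie:
                continue
            buckets[c.klass].append(c.internal_length)
        return cls(
            len(buckets["con"]), len(buckets["dis1"]), len(buckets["dis2"]),
            buckets["con"], buckets["dis1"], buckets["dis2"],
        )


def dct_test(counts: TripletCounts) -> tuple[float, float]:
    """Discordant count test.

    Returns (phi_hat, p).  phi_hat = (c_dis2 - c_dis1)/(c_con + c_dis1 +
    c_dis2) with phi_hat = 0 whenever c_dis1 > c_dis2; p from an exact
    two-sided binomial test of c_dis2 successes in c_dis1 + c_dis2 trials
    at probability 1/2.
    """
    total = counts.c_con + counts.c_dis1 + counts.c_dis2
    if total < 1:
        raise ValueError("all-zero triplet counts")
    if counts.c_dis1 > counts.c_dis2:
        phi_hat = 0.0
    else:
        phi_hat = (counts.c_dis2 - counts.c_dis1) / total
    n_dis = counts.c_dis1 + counts.c_dis2
    if n_dis == 0:
        return phi_hat, 1.0
    p = stats.binomtest(counts.c_dis2, n_dis, 0.5, alternative="two-sided").pvalue
    return phi_hat, float(p)


def blt_test(
    lengths_dis1: Sequence[float], lengths_dis2: Sequence[float]
) -> tuple[float, Optional[str]]:
    """Branch length test: Mann-Whitney U on the internal branch lengths of
    the two discordant classes.  Returns (p, direction) where direction
    names the class with the smaller mean length (the candidate
    introgressed class), or None when the samples are indistinguishable.
    """
    x1, x2 = np.asarray(lengths_dis1, float), np.asarray(lengths_dis2, float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both discordant classes need at least one length")
    if np.array_equal(np.sort(x1), np.sort(x2)):
        return 1.0, None
    p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
    m1, m2 = x1.mean(), x2.mean()
    direction = None if m1 == m2 else ("dis1" if m1 < m2 else "dis2")
    return p, direction


# -- QuIBL-style exponential mixture --------------------------------------

@dataclass
class MixtureFit:
    """Fit of the internal-branch-length mixture: 1 component is a pure
    exponential Exp(lam); 2 components add a shifted exponential
    lam*exp(-lam*(t-C)) on t >= C with weight pi2."""

    components: int
    lam: float
    shift: float
    pi2: float
    loglik: float
    bic: float
    n: int
    converged: bool = True
    degenerate: bool = False


def _auto_delta(x: np.ndarray) -> float:
    """Measurement resolution of the branch lengths.  ML lengths from an
    n-site alignment are quantized near multiples of the one-substitution
    distance, and a mixture fitted as continuous densities would treat
    those spikes as spurious components.  The resolution is best supplied
    by the caller (the one-substitution JC distance for the alignment
    length); this fallback uses the smallest materially positive observed
    value, which sits at one quantum for quantized data and far below the
    mean for effectively continuous data."""
    pos = x[x > 1e-8]
    if pos.size == 0:
        return 0.0
    return float(pos.min())


def _bin_probs(x: np.ndarray, lam: float, C: float, delta: float) -> tuple:
    """Interval-censored component probabilities P(t in x +- delta/2) for
    the exponential and the C-shifted exponential; densities when delta=0."""
    if delta <= 0.0:
        p1 = lam * np.exp(-lam * x)
        p2 = np.where(x >= C, lam * np.exp(-lam * np.maximum(x - C, 0.0)), 0.0)
        return p1, p2
    lo = np.maximum(x - delta / 2.0, 0.0)
    hi = x + delta / 2.0
    p1 = np.exp(-lam * lo) - np.exp(-lam * hi)
    lo2 = np.maximum(lo - C, 0.0)
    hi2 = np.maximum(hi - C, 0.0)
    p2 = np.exp(-lam * lo2) - np.exp(-lam * hi2)
    return np.maximum(p1, 0.0), np.maximum(p2, 0.0)


def _mix_loglik(x, lam, pi2, C, delta) -> float:
    p1, p2 = _bin_probs(x, lam, C, delta)
    return float(np.log(np.maximum((1 - pi2) * p1 + pi2 * p2, 1e-300)).sum())


def _em_two_component(
    x: np.ndarray, C: float, delta: float,
    max_iter: int = 10_000, tol: float = 1e-10,
):
    """EM for the 2-component mixture at a fixed shift C; shared rate lam
    updated by a bounded 1-D maximization (generalized EM)."""
    from scipy.optimize import minimize_scalar

    if delta > 0.0:
        # the censored M-step needs numerical optimization; use realistic
        # tolerances so the generalized EM terminates
        max_iter = 200
        tol = 1e-7

    lam = 1.0 / max(x.mean(), 1e-12)
    pi2 = 0.3
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        p1, p2 = _bin_probs(x, lam, C, delta)
        denom = np.maximum((1 - pi2) * p1 + pi2 * p2, 1e-300)
        r = pi2 * p2 / denom
        pi2 = float(r.mean())
        if delta <= 0.0:
            t_eff = x.sum() - C * r.sum()
            lam = len(x) / max(t_eff, 1e-12)
        else:
            res = minimize_scalar(
                lambda lg: -(
                    ((1 - r) * np.log(np.maximum(
                        _bin_probs(x, math.exp(lg), C, delta)[0], 1e-300))
                     + r * np.log(np.maximum(
                        _bin_probs(x, math.exp(lg), C, delta)[1], 1e-300)))
                    .sum()),
                bounds=(math.log(1e-3 / max(x.mean(), 1e-9)),
                        math.log(1e4 / max(delta, 1e-9))),
                method="bounded", options={"xatol": 1e-4},
            )
            lam = math.exp(res.x)
        ll = _mix_loglik(x, lam, pi2, C, delta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return lam, pi2, ll, converged


def quibl_fit(
    lengths: Sequence[float],
    components: int = 2,
    n_grid: int = 50,
    delta: Optional[float] = None,
) -> MixtureFit:
    """Fit the branch-length mixture by EM, profiling the shift C over an
    evenly spaced grid on [0, max(length)].

    The likelihood is interval-censored at the measurement resolution
    ``delta`` (estimated from the data when None): each observed length is
    an interval of width delta, which keeps the fit honest on the
    quantized branch lengths that short alignments produce.  BIC =
    -2 logL + k ln(n) with k = 1 (lam) for one component and k = 3
    (lam, pi2, C) for two.
    """
    x = np.asarray(lengths, float)
    if np.any(x < 0):
        raise ValueError("branch lengths must be nonnegative")
    if x.size < 10:
        raise ValueError("need at least 10 branch lengths")
    n = x.size
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    if x.max() <= 0:
        # all-zero lengths: no scale to estimate
        return MixtureFit(1, math.inf, 0.0, 0.0, math.inf, -math.inf, n,
                          converged=True, degenerate=True)
    if delta is None:
        delta = _auto_delta(x)
    if delta <= 0.05 * x.mean():
        # resolution far below the length scale: censoring is immaterial
        # and the density likelihood (with its closed-form EM) is used
        delta = 0.0
    if components == 1:
        if delta <= 0.0:
            lam = 1.0 / x.mean()
        else:
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                lambda lg: -_mix_loglik(x, math.exp(lg), 0.0, 0.0, delta),
                bounds=(math.log(1e-3 / x.mean()),
                        math.log(1e4 / max(delta, 1e-9))),
                method="bounded", options={"xatol": 1e-6},
            )
            lam = math.exp(res.x)
        ll = _mix_loglik(x, lam, 0.0, 0.0, delta)
        return MixtureFit(1, lam, 0.0, 0.0, ll, -2 * ll + 1 * math.log(n), n)
    best = None
    for C in np.linspace(0.0, float(x.max()), n_grid):
        lam, pi2, ll, conv = _em_two_component(x, C, delta)
        if best is None or ll > best[2]:
            best = (lam, pi2, ll, conv, C)
    lam, pi2, ll, conv, C = best
    return MixtureFit(2, lam, C, pi2, ll, -2 * ll + 3 * math.log(n), n, converged=conv)


def quibl_test(
    counts: TripletCounts,
    delta_bic_threshold: float = 10.0,
    pi2_floor: float = 0.1,
    resolution: Optional[float] = None,
) -> dict[str, bool]:
    """Per-discordant-class introgression call: a class is significant when
    the 2-component fit beats the 1-component fit by at least
    ``delta_bic_threshold`` in BIC and the introgression weight pi2 clears
    ``pi2_floor``.

    The triplet-level call requires the dis2 (gene-flow-pair) class to show
    a shifted component while the dis1 class does not: dis1 can only carry
    incomplete-lineage-sorting trees, so any apparent mixture there marks
    branch-length estimation artifacts (e.g. the substitution-count
    quantization of short alignments), and a symmetric signal in both
    discordant classes is not evidence of gene flow.

    Pass counts collated with ``drop_ties=False`` so the unresolved
    (near-zero-length) trees anchor the short end of the length
    distribution; dropping them truncates the data and mimics a shifted
    component.
    """
    out = {}
    artifact = {}
    for name, lengths in (("dis1", counts.lengths_dis1), ("dis2", counts.lengths_dis2)):
        if len(lengths) < 10:
            out[name] = False
            artifact[name] = False
            continue
        f1 = quibl_fit(lengths, 1, delta=resolution)
        f2 = quibl_fit(lengths, 2, delta=resolution)
        if f1.degenerate or f2.degenerate:
            out[name] = False
            artifact[name] = False
            continue
        evidence = (f1.bic - f2.bic) >= delta_bic_threshold
        # a shift within ~one measurement quantum cannot be told apart from
        # branch-length discretization; require it to span two quanta
        quantum = (resolution if resolution is not None
                   else _auto_delta(np.asarray(lengths, float)))
        resolvable = f2.shift >= 2.0 * quantum
        artifact[name] = bool(evidence and not resolvable)
        out[name] = bool(evidence and f2.pi2 >= pi2_floor and resolvable)
    out["triplet"] = out["dis2"] and not out["dis1"] and not artifact["dis1"]
    return out


# -- ABBA-BABA -------------------------------------------------------------

def _pattern_counts(aln: LocusAlignment, taxa: Sequence[str]) -> tuple[int, int]:
    """ABBA/BABA counts for one locus given ordered taxa (P1, P2, P3, O).
    The outgroup allele is treated as ancestral; sites with ambiguity or
    more than two states are skipped."""
    idx = [aln.labels.index(t) for t in taxa]
    b = aln.base_indices()[idx]
    ok = (b < 4).all(axis=0)
    p1, p2, p3, o = b[:, ok].astype(np.int64)
    # biallelic check via a popcount over the set of observed bases
    seen = (1 << p1) | (1 << p2) | (1 << p3) | (1 << o)
    popcount = np.array([bin(v).count("1") for v in range(16)])
    two_state = popcount[seen] == 2
    abba = int(np.sum(two_state & (p1 == o) & (p2 == p3) & (p2 != o)))
    baba = int(np.sum(two_state & (p2 == o) & (p1 == p3) & (p1 != o)))
    return abba, baba


def d_statistic(
    alignments: Sequence[LocusAlignment],
    taxa: Sequence[str],
    by_species: bool = True,
    seed: int = 0,
) -> tuple[float, float, float]:
    """ABBA-BABA D over all loci with a per-locus block jackknife.

    ``taxa`` is the ordered quartet (P1, P2, P3, O); with ``by_species``
    one sequence per species is drawn (seeded) per locus.  Returns
    (D, z, p) with D = (nABBA - nBABA)/(nABBA + nBABA), z from the
    delete-one-block jackknife SE, and a two-sided normal p-value.
    """
    per_locus = []
    for i, aln in enumerate(alignments):
        if by_species:
            rng = np.random.default_rng([seed, 11, i])
            labels = []
            for sp in taxa:
                cands = [lab for lab, s in zip(aln.labels, aln.species) if s == sp]
                if not cands:
                    raise ValueError(f"no sequence for species {sp!r}")
                labels.append(cands[int(rng.integers(len(cands)))])
        else:
            labels = list(taxa)
        per_locus.append(_pattern_counts(aln, labels))
    counts = np.array(per_locus, float)
    tot = counts.sum(axis=0)
    n_inf = tot.sum()
    if n_inf == 0:
        raise ValueError("no informative (ABBA/BABA) sites")
    D = (tot[0] - tot[1]) / n_inf
    # weighted delete-one-locus jackknife (blocks contribute unequal numbers
    # of informative sites, so the unweighted variance underestimates)
    keep = counts.sum(axis=1) > 0
    blocks = counts[keep]
    B = len(blocks)
    if B < 2:
        return float(D), math.nan, math.nan
    m = blocks.sum(axis=1)
    h = n_inf / m
    loo = tot[None, :] - blocks
    with np.errstate(invalid="ignore"):
        D_j = (loo[:, 0] - loo[:, 1]) / np.maximum(loo.sum(axis=1), 1)
    pseudo = h * D - (h - 1.0) * D_j
    theta_jack = B * D - float(((1.0 - m / n_inf) * D_j).sum())
    var = float(np.sum((pseudo - theta_jack) ** 2 / (h - 1.0))) / B
    se = math.sqrt(max(var, 0.0))
    z = float(D / se) if se > 0 else 0.0
    # Exact-null p by per-locus sign flips: under ILS alone the ABBA and
    # BABA counts of a locus are exchangeable, so flipping blocks generates
    # the null of D.  The normal approximation to the jackknife z is
    # anti-conservative when only tens of loci carry informative sites.
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 13])
    n_resample = 2000
    signs = rng.choice(np.array([1.0, -1.0]), size=(n_resample, B))
    diffs = signs @ (blocks[:, 0] - blocks[:, 1])
    p = float((1 + np.sum(np.abs(diffs / n_inf) >= abs(D) - 1e-12))
              / (n_resample + 1))
    return float(D), z, p
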