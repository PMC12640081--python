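"""Per-locus gene-tree estimation for summary tests: exhaustive maximum
likelihood under Jukes-Cantor over the three unrooted quartet topologies,
plus classification of rooted triplets into concordant/discordant classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import LocusAlignment
from .trees import Node, Tree

_TIE_TOL = 1e-9


def jc_distance(p_mismatch: float) -> float:
    """Jukes-Cantor distance from an observed mismatch proportion:
    d = -(3/4) ln(1 - (4/3) p).  Raises for p >= 3/4 (saturation)."""
    if not 0.0 <= p_mismatch:
        raise ValueError("mismatch proportion must be >= 0")
    if p_mismatch >= 0.75:
        raise ValueError(f"JC distance undefined at p={p_mismatch} >= 3/4 (saturated)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p_mismatch)


def _tip_partials(aln: LocusAlignment, taxa: Sequence[str]):
    """Compress sites into patterns; return per-tip partial likelihoods
    (one-hot for definite bases, all-ones over compatible bases for
    ambiguity/gap codes) with pattern weights."""
    rows = []
    for t in taxa:
        if t not in aln.labels:
            raise ValueError(f"sequence {t!r} not in locus {aln.locus_id}")
        rows.append(aln.data[aln.labels.index(t)])
    mat = np.vstack(rows)  # (ntaxa, nsites) of bitmasks
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    # (ntaxa, npat, 4) partials
    partials = ((patterns[:, :, None] & bits[None, None, :]) > 0).astype(float)
    return partials, weights.astype(float)


def _jc_propagate(v: np.ndarray, d: float) -> np.ndarray:
    """Apply the JC transition matrix over branch length d to conditional
    likelihood vectors v of shape (..., 4)."""
    e = math.exp(-4.0 * d / 3.0)
    p_diff = 0.25 * (1.0 - e)
    return p_diff * v.sum(axis=-1, keepdims=True) + e * v


def _quartet_loglik(partials, weights, pairing, lengths) -> float:
    """Log-likelihood of an unrooted quartet ((i,j),(k,l)) with branch
    lengths (b_i, b_j, b_k, b_l, b_internal)."""
    (i, j), (k, l) = pairing
    lu = _jc_propagate(partials[i], lengths[0]) * _jc_propagate(partials[j], lengths[1])
    lv = _jc_propagate(partials[k], lengths[2]) * _jc_propagate(partials[l], lengths[3])
    lv = _jc_propagate(lv, lengths[4])
    site = 0.25 * (lu * lv).sum(axis=-1)
    if np.any(site <= 0):
        return -np.inf
    return float(weights @ np.log(site))


def _jc_dpropagate(v: np.ndarray, d: float) -> np.ndarray:
    """Derivative of :func:`_jc_propagate` with respect to d."""
    e = math.exp(-4.0 * d / 3.0)
    return (4.0 / 3.0) * e * (v.sum(axis=-1, keepdims=True) / 4.0 - v)


def _quartet_loglik_grad(partials, weights, pairing, lengths):
    """Log-likelihood and its analytic gradient in the 5 branch lengths."""
    (i, j), (k, l) = pairing
    u1 = _jc_propagate(partials[i], lengths[0])
    u2 = _jc_propagate(partials[j], lengths[1])
    U = u1 * u2
    v1 = _jc_propagate(partials[k], lengths[2])
    v2 = _jc_propagate(partials[l], lengths[3])
    V = v1 * v2
    W = _jc_propagate(V, lengths[4])
    site = 0.25 * (U * W).sum(axis=-1)
    if np.any(site <= 0):
        return -np.inf, np.zeros(5)
    inv = weights / site
    d_site = np.empty((5, len(site)))
    d_site[0] = 0.25 * (_jc_dpropagate(partials[i], lengths[0]) * u2 * W).sum(axis=-1)
    d_site[1] = 0.25 * (u1 * _jc_dpropagate(partials[j], lengths[1]) * W).sum(axis=-1)
    # propagation over the internal branch is linear in its input
    d_site[2] = 0.25 * (U * _jc_propagate(
        _jc_dpropagate(partials[k], lengths[2]) * v2, lengths[4])).sum(axis=-1)
    d_site[3] = 0.25 * (U * _jc_propagate(
        v1 * _jc_dpropagate(partials[l], lengths[3]), lengths[4])).sum(axis=-1)
    d_site[4] = 0.25 * (U * _jc_dpropagate(V, lengths[4])).sum(axis=-1)
    ll = float(weights @ np.log(site))
    return ll, d_site @ inv


_PAIRINGS = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
_BOUNDS = (1e-9, 5.0)


@dataclass
class QuartetML:
    """Result of exhaustive quartet ML: the best unrooted topology (index
    into the three pairings of the input taxa), all three maximized
    log-likelihoods, the best topology's branch lengths, and a tie flag."""

    taxa: tuple[str, str, str, str]
    best: int
    pairings: list
    lengths: np.ndarray  # (b1, b2, b3, b4, b_internal) of the best pairing
    loglik: np.ndarray  # (3,)
    tie: bool

    def tree(self, precision_guard: bool = True) -> Tree:
        """The best topology as an unrooted-style tree ((i,j),(k,l));."""
        (i, j), (k, l) = self.pairings[self.best]
        b = self.lengths
        root = Node()
        left = Node()
        left.length = b[4]
        for idx, bl in ((i, b[0]), (j, b[1])):
            tip = Node(self.taxa[idx], bl)
            left.add_child(tip)
        root.add_child(left)
        root.add_child(Node(self.taxa[k], b[2]))
        root.add_child(Node(self.taxa[l], b[3]))
        return Tree(root)


def _pair_distance(partials, weights, i, j) -> float:
    """JC distance between two (possibly ambiguous) sequences, saturating
    safely for use as an optimizer start point."""
    # match probability per site; ambiguity codes contribute fractionally
    match = (partials[i] * partials[j]).sum(axis=-1) / (
        partials[i].sum(axis=-1) * partials[j].sum(axis=-1)
    )
    p_mm = float(((1.0 - match) * weights).sum() / weights.sum())
    return jc_distance(min(p_mm, 0.70))


def quartet_ml_jc(aln: LocusAlignment, taxa: Sequence[str]) -> QuartetML:
    """Exhaustive ML under JC over the three unrooted quartet topologies.

    For each topology the five branch lengths are optimized by bounded
    quasi-Newton from a distance-based start (plus a fixed fallback start);
    returns the argmax and all three scores.  Topology ties (score gap
    below 1e-9) are flagged.
    """
    taxa = tuple(taxa)
    if len(taxa) != 4:
        raise ValueError("need exactly 4 taxa")
    partials, weights = _tip_partials(aln, taxa)
    if weights.sum() < 1:
        raise ValueError("alignment has no sites")

    d = {}
    for i in range(4):
        for j in range(i + 1, 4):
            d[i, j] = d[j, i] = _pair_distance(partials, weights, i, j)

    logls = np.empty(3)
    best_lengths = []
    for ti, ((i, j), (k, l)) in enumerate(_PAIRINGS):
        internal0 = max(
            (d[i, k] + d[j, l] + d[i, l] + d[j, k]) / 4.0 - (d[i, j] + d[k, l]) / 2.0,
            1e-4,
        )
        starts = [
            np.array([d[i, j] / 2, d[i, j] / 2, d[k, l] / 2, d[k, l] / 2, internal0]),
            np.full(5, 1e-3),
        ]
        def neg(x, ti=ti):
            ll, g = _quartet_loglik_grad(partials, weights, _PAIRINGS[ti], x)
            return -ll, -g

        best_val, best_x = -np.inf, None
        for x0 in starts:
            x0 = np.clip(x0, *_BOUNDS)
            res = minimize(
                neg, x0, jac=True, method="L-BFGS-B",
                bounds=[_BOUNDS] * 5,
                options={"ftol": 1e-12, "gtol": 1e-10},
            )
            if -res.fun > best_val:
                best_val, best_x = -res.fun, res.x
        logls[ti] = best_val
        best_lengths.append(best_x)

    order = np.argsort(-logls)
    tie = bool(logls[order[0]] - logls[order[1]] < _TIE_TOL)
    best = int(order[0])
    return QuartetML(taxa, best, _PAIRINGS, best_lengths[best], logls, tie)


# -- triplet classification ------------------------------------------------

@dataclass
class TripletClassification:
    """Rooted-triplet class of one locus: ``con`` if the declared sister
    pair is monophyletic among the three ingroup tips, ``dis2`` if the
    hypothesized gene-flow pair groups together, ``dis1`` otherwise."""

    triplet: tuple[str, str, str]
    sister_pair: tuple[str, str]
    outgroup: str
    klass: Optional[str]
    internal_length: float
    locus_id: str = ""
    tie: bool = False


def classify_triplet(
    tree: Tree,
    sister_pair: tuple[str, str],
    outgroup: str,
    gene_flow_pair: Optional[tuple[str, str]] = None,
    locus_id: str = "",
    tie: bool = False,
) -> TripletClassification:
    """Classify the rooted triplet induced by a tree containing the three
    focal tips and the outgroup.

    The tree is rooted at the outgroup; the class is read off the cherry of
    the induced quartet, and the internal length is the total length of the
    branches separating that cherry from the third tip (for an ultrametric
    gene tree this is the age gap between the two coalescences).
    """
    sisters = frozenset(sister_pair)
    if len(sisters) != 2:
        raise ValueError("sister_pair must name two distinct tips")
    ingroup = set(sister_pair)
    labels = set(tree.tip_labels())
    third = None
    # the third ingroup tip is whichever focal tip is neither sister nor outgroup
    focal = labels - {outgroup}
    if gene_flow_pair is not None:
        focal &= set(sister_pair) | set(gene_flow_pair)
    if len(focal) != 3:
        # fall back: tree restricted to exactly 4 tips
        focal = labels - {outgroup}
    if len(focal) != 3 or outgroup not in labels or not ingroup <= focal:
        raise ValueError("tree must contain the 3 focal tips and the outgroup")
    (third,) = focal - ingroup
    quartet = focal | {outgroup}

    # sum lengths of edges inducing a 2|2 split on the focal quartet
    split_len: dict[frozenset, float] = {}
    below: dict[Node, frozenset] = {}
    for n in tree.postorder():
        if n.is_tip:
            below[n] = frozenset({n.name} & quartet)
        else:
            below[n] = frozenset().union(*(below[c] for c in n.children))
        if n.parent is not None:
            s = below[n]
            if len(s) == 3:
                s = frozenset(quartet - s)
            if len(s) == 2:
                key = s if outgroup not in s else frozenset(quartet - s)
                length = n.length if n.length is not None else (
                    (n.parent.age - n.age) if n.age is not None else 0.0
                )
                split_len[key] = split_len.get(key, 0.0) + float(length)
    if not split_len:
        raise ValueError("focal quartet is unresolved (polytomy)")
    cherry = max(split_len, key=split_len.get)
    length = split_len[cherry]
    if cherry == sisters:
        klass = "con"
    elif gene_flow_pair is not None and cherry == frozenset(gene_flow_pair):
        klass = "dis2"
    elif gene_flow_pair is not None:
        klass = "dis1"
    else:
        # without a declared gene-flow pair, dis1/dis2 are ordered by the
        # lexicographically smaller non-sister partner of the third tip
        others = sorted(x for x in focal if x != third)
        klass = "dis1" if min(cherry - {third} or cherry) == others[0] else "dis2"
    if length <= 1e-8:  # at/below the ML optimizer's lower bound: unresolved
        tie = True
    return TripletClassification(
        tuple(sorted(focal)), tuple(sister_pair), outgroup, klass, max(length, 0.0),
        locus_id, tie,
    )


def pick_one_per_species(
    aln: LocusAlignment, species: Sequence[str], rng: np.random.Generator
) -> list[str]:
    """Choose one sequence label per species at random (seeded), mirroring
    the single-sequence subsampling used for triplet summary methods."""
    chosen = []
    for sp in species:
        cands = [lab for lab, s in zip(aln.labels, aln.species) if s == sp]
        if not cands:
            raise ValueError(f"no sequence for species {sp!r} in locus {aln.locus_id}")
        chosen.append(cands[int(rng.integers(len(cands)))])
    return chosen


def ml_gene_trees(
    alignments: Sequence[LocusAlignment],
    species: Sequence[str],
    seed: int = 0,
) -> list[QuartetML]:
    """Quartet ML gene trees for every locus, subsampling one sequence per
    species with a per-locus seeded draw."""
    out = []
    for i, aln in enumerate(alignments):
        rng = np.random.default_rng([seed, 7, i])
        taxa = pick_one_per_species(aln, species, rng)
        fit = quartet_ml_jc(aln, taxa)
        # relabel tips by species for downstream triplet work
        fit = QuartetML(
            tuple(species), fit.best, fit.pairings, fit.lengths, fit.loglik, fit.tie
        )
        out.append(fit)
    return out
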