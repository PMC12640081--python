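"""Species networks: a rooted species tree with divergence times (tau), per
branch population sizes (theta), and gene flow as either a single pulse
introgression edge (MSC-I) or continuous migration bands (MSC-M).

Units follow the bpp parameterization: tau and theta are both measured in
expected substitutions per site, with theta = 4*N*mu, so the pairwise
coalescent rate within a population of size theta is 2/theta and the
backward per-lineage migration rate implied by M migrants per generation
into a population of size theta is 4*M/theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .trees import Node, Tree, parse_newick


@dataclass(frozen=True)
class IntrogressionEdge:
    """A pulse of gene flow at a single time point.

    ``donor`` and ``recipient`` name species-tree branches (by the node below
    the branch).  At ``time``, looking backward in time, each gene lineage in
    the recipient branch independently traces into the donor branch with
    probability ``phi``.
    """

    donor: str
    recipient: str
    time: float
    phi: float


@dataclass(frozen=True)
class MigrationBand:
    """Continuous migration from ``donor`` into ``recipient`` (forward in
    time) at rate ``rate`` migrants per generation, active over the temporal
    overlap of the two branches unless narrowed by ``t_min``/``t_max``."""

    donor: str
    recipient: str
    rate: float
    t_min: Optional[float] = None
    t_max: Optional[float] = None


class NetworkError(ValueError):
    pass


@dataclass
class SpeciesNetwork:
    """Rooted species tree with node ages, per-branch theta and gene flow.

    ``tree`` nodes carry ``age`` (tips at 0).  ``theta`` maps a branch --
    identified by the name of the node beneath it -- to its population size;
    the root branch (the ancestral population above the root node) uses the
    root node's name.  Every node, including internal ones, must be named.
    """

    tree: Tree
    theta: dict[str, float]
    introgression: Optional[IntrogressionEdge] = None
    migration: list[MigrationBand] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structure helpers -------------------------------------------------
    def node(self, name: str) -> Node:
        return self.tree.find(name)

    def species(self) -> list[str]:
        return self.tree.tip_labels()

    def branch_interval(self, name: str) -> tuple[float, float]:
        """Time interval over which branch ``name`` exists (root: to +inf)."""
        n = self.node(name)
        top = math.inf if n.parent is None else n.parent.age
        return (n.age, top)

    def validate(self) -> None:
        names = [n.name for n in self.tree.postorder()]
        if any(not nm for nm in names):
            raise NetworkError("every species-network node must be named")
        if len(set(names)) != len(names):
            raise NetworkError("duplicate node names in species network")
        for n in self.tree.postorder():
            if n.age is None:
                raise NetworkError(f"node {n.name!r} has no age")
            if n.is_tip:
                if n.age != 0.0:
                    raise NetworkError(f"tip {n.name!r} must have age 0")
            else:
                for c in n.children:
                    if not n.age > c.age:
                        raise NetworkError(
                            f"ages must decrease root->tips ({n.name} vs {c.name})"
                        )
        for nm in names:
            th = self.theta.get(nm)
            if th is None or not th > 0:
                raise NetworkError(f"branch {nm!r} needs theta > 0")
        if self.introgression is not None and self.migration:
            raise NetworkError("a network carries introgression or migration, not both")
        if self.introgression is not None:
            e = self.introgression
            if not 0.0 <= e.phi <= 1.0:
                raise NetworkError("phi must be in [0, 1]")
            for br in (e.donor, e.recipient):
                lo, hi = self.branch_interval(br)
                if not (lo < e.time < hi):
                    raise NetworkError(
                        f"introgression time {e.time} outside branch {br!r} interval"
                    )
        for band in self.migration:
            if band.rate < 0:
                raise NetworkError("migration rate must be >= 0")
            lo1, hi1 = self.branch_interval(band.donor)
            lo2, hi2 = self.branch_interval(band.recipient)
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if not lo < hi:
                raise NetworkError(
                    f"migration band {band.donor}->{band.recipient}: branches do not overlap in time"
                )

    def band_interval(self, band: MigrationBand) -> tuple[float, float]:
        """Active time interval of a band: the overlap of the two branches,
        optionally narrowed by the band's own bounds."""
        lo1, hi1 = self.branch_interval(band.donor)
        lo2, hi2 = self.branch_interval(band.recipient)
        lo, hi = max(lo1, lo2), min(hi1, hi2)
        if band.t_min is not None:
            lo = max(lo, band.t_min)
        if band.t_max is not None:
            hi = min(hi, band.t_max)
        return lo, hi


def expected_cumulative_introgression(M: float, delta_tau: float, theta: float) -> float:
    """Expected cumulative introgression probability implied by a migration
    band: phi0 = 1 - exp(-4*M*delta_tau/theta).

    ``M`` is the population migration rate in migrants per generation,
    ``delta_tau`` the duration of the band and ``theta`` the recipient
    population size, both in expected substitutions per site.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if M < 0 or delta_tau < 0:
        raise ValueError("M and delta_tau must be >= 0")
    return -math.expm1(-4.0 * M * delta_tau / theta)


def quartet_network(
    theta: float = 0.0025,
    mode: str = "msci",
    direction: str = "inflow",
    phi: float = 0.2,
    M: float = 0.1,
    tau_x_factor: float = 0.5,
) -> SpeciesNetwork:
    """The benchmark quartet (((A,B)T,C)S,O)R with gene flow between the
    nonsister tips B and C.

    Divergence times are tau_R = 3*theta, tau_S = 2*theta, tau_T = theta and
    all branches share ``theta``.  Under MSC-I the pulse occurs at
    tau_X = tau_x_factor * theta with probability ``phi``; under MSC-M a band
    with rate ``M`` migrants/generation runs over the temporal overlap of the
    B and C branches, i.e. (0, tau_T).  ``direction`` is "inflow" (C -> B,
    into the deeper-nested lineage) or "outflow" (B -> C).
    """
    if direction not in ("inflow", "outflow"):
        raise ValueError("direction must be 'inflow' or 'outflow'")
    if mode not in ("msci", "mscm"):
        raise ValueError("mode must be 'msci' or 'mscm'")
    tree = parse_newick("(((A,B)T,C)S,O)R;")
    ages = {"A": 0.0, "B": 0.0, "C": 0.0, "O": 0.0, "T": theta, "S": 2 * theta, "R": 3 * theta}
    for n in tree.postorder():
        n.age = ages[n.name]
    thetas = {nm: theta for nm in ages}
    donor, recipient = ("C", "B") if direction == "inflow" else ("B", "C")
    if mode == "msci":
        return SpeciesNetwork(
            tree,
            thetas,
            introgression=IntrogressionEdge(donor, recipient, tau_x_factor * theta, phi),
        )
    return SpeciesNetwork(tree, thetas, migration=[MigrationBand(donor, recipient, M)])


# -- YAML configuration ---------------------------------------------------

def network_from_config(doc: dict) -> SpeciesNetwork:
    """Build a network from a parsed YAML/dict configuration.

    Expected keys: ``newick`` (topology with named internal nodes), ``tau``
    (mapping node name -> age), ``theta`` (scalar or mapping branch -> value),
    optional ``introgression`` {donor, recipient, time, phi} and
    ``migration`` [{donor, recipient, rate, t_min?, t_max?}, ...].
    """
    tree = parse_newick(doc["newick"])
    tau = dict(doc.get("tau", {}))
    for n in tree.postorder():
        n.age = 0.0 if n.is_tip else float(tau[n.name])
    th = doc["theta"]
    if isinstance(th, dict):
        theta = {k: float(v) for k, v in th.items()}
    else:
        theta = {n.name: float(th) for n in tree.postorder()}
    intro = None
    if doc.get("introgression"):
        d = doc["introgression"]
        intro = IntrogressionEdge(d["donor"], d["recipient"], float(d["time"]), float(d["phi"]))
    bands = [
        MigrationBand(
            d["donor"], d["recipient"], float(d["rate"]),
            d.get("t_min"), d.get("t_max"),
        )
        for d in doc.get("migration", [])
    ]
    return SpeciesNetwork(tree, theta, introgression=intro, migration=bands)


def load_network(path: str) -> SpeciesNetwork:
    with open(path) as fh:
        return network_from_config(yaml.safe_load(fh))
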