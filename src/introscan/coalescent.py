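"""An ms-style neutral coalescent simulator with demographic events.

Time is measured in units of 4N0 generations throughout (the ms
convention), so a sample of two lineages in a constant-size population has
expected TMRCA 0.5 and an ms command-line event like ``-eN 0.8 0.01`` transcribes
directly as ``DemographyEvent.size_change(0.8, 0.01)``.  Within a
population of relative size x each lineage pair coalesces at rate 2/x.
Loci are non-recombining; mutations follow the infinite-sites model,
either a fixed count S per locus (placed on branches with probability
proportional to branch length) or Poisson with E[S] = theta * a1(n) under
constant size (theta = 4*N0*mu per locus).

Three event kinds are supported, mirroring ms flags:

* ``size_change`` (-eN / -en): the named population (or all) rescales to
  relative size x at the event time.
* ``join`` (-ej): all lineages in *source* move to *destination* (a
  population split, viewed backward in time).
* ``pulse`` (-ev): each lineage in *source* independently moves to
  *destination* with the given probability (pulse admixture).

Events at equal times are applied in list order; the configurations built
here place pulses before joins at the same time so a coincident
join cannot silently erase a pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .popgen import tajimas_d


@dataclass(frozen=True)
class DemographyEvent:
    """One demographic event in coalescent (4N0) time units."""

    kind: str                      # size_change | join | pulse
    time: float
    population: int | None = None  # size_change target; None = all populations
    size: float | None = None      # size_change: new relative size x
    source: int | None = None      # join/pulse: source population (backward)
    dest: int | None = None        # join/pulse: destination population
    fraction: float | None = None  # pulse: move probability in [0, 1]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.kind == "size_change":
            if self.size is None or self.size <= 0:
                raise ValueError("size_change requires a positive relative size")
        elif self.kind == "join":
            if self.source is None or self.dest is None:
                raise ValueError("join requires source and dest populations")
        elif self.kind == "pulse":
            if self.source is None or self.dest is None:
                raise ValueError("pulse requires source and dest populations")
            if self.fraction is None or not (0.0 <= self.fraction <= 1.0):
                raise ValueError("pulse fraction must lie in [0, 1]")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @classmethod
    def size_change(cls, time: float, size: float, population: int | None = None):
        return cls(kind="size_change", time=time, population=population, size=size)

    @classmethod
    def join(cls, time: float, source: int, dest: int):
        return cls(kind="join", time=time, source=source, dest=dest)

    @classmethod
    def pulse(cls, time: float, source: int, dest: int, fraction: float):
        return cls(kind="pulse", time=time, source=source, dest=dest, fraction=fraction)


@dataclass
class SimConfig:
    """Sample sizes (haplotypes per population), events, and mutation model.

    Exactly one of *theta* (per locus) or *fixed_s* must be set.  With
    ``s_range`` set, S is drawn uniformly (inclusive) per locus instead.
    """

    sample_sizes: list[int]
    events: list[DemographyEvent] = field(default_factory=list)
    theta: float | None = None
    fixed_s: int | None = None
    s_range: tuple[int, int] | None = None
    n_loci: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.sample_sizes) < 2:
            raise ValueError("need at least 2 sampled haplotypes in total")
        models = sum(
            x is not None for x in (self.theta, self.fixed_s, self.s_range)
        )
        if models != 1:
            raise ValueError("set exactly one of theta, fixed_s, s_range")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.fixed_s is not None and self.fixed_s < 0:
            raise ValueError("fixed_s must be non-negative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be at least 1")
        self.events = sorted(self.events, key=lambda e: e.time)
        validate_connectivity(len(self.sample_sizes), self.sample_sizes, self.events)


def validate_connectivity(
    n_pops: int, sample_sizes: list[int], events: list[DemographyEvent]
) -> None:
    """Reject configurations whose sampled populations can never fully merge.

    Follows join events only (pulses are probabilistic and cannot guarantee
    a merge); all populations holding samples must end up in one component.
    """
    root = list(range(n_pops))

    def find(i: int) -> int:
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return i

    for e in events:
        if e.kind == "join":
            root[find(e.source)] = find(e.dest)
    sampled = [i for i, n in enumerate(sample_sizes) if n > 0]
    components = {find(i) for i in sampled}
    if len(components) > 1:
        raise ValueError(
            "sampled lineages stranded: populations "
            f"{sampled} never merge into one (missing join events)"
        )


@dataclass
class Genealogy:
    """A binary coalescent tree over n leaves.

    Nodes 0..n-1 are leaves; internal nodes are appended in coalescence
    order.  ``parent[i]`` is -1 for the root; ``time[i]`` is the node age in
    4N0 units.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        lengths = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                lengths[i] = self.time[p] - self.time[i]
        return lengths

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_matrix(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean descendant-leaf indicator per node."""
        desc = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        desc[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for i in np.argsort(self.time, kind="stable"):
            p = self.parent[int(i)]
            if p >= 0:
                desc[p] |= desc[int(i)]
        return desc

    def tmrca(self) -> float:
        return float(self.time[-1])


def simulate_genealogy(config: SimConfig, rng: np.random.Generator) -> Genealogy:
    """One Hudson coalescent genealogy under the configured demography."""
    sizes = config.sample_sizes
    n = sum(sizes)
    n_pops = len(sizes)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    # active lineages per population
    pops: list[list[int]] = [[] for _ in range(n_pops)]
    leaf = 0
    for p, k in enumerate(sizes):
        for _ in range(k):
            pops[p].append(leaf)
            leaf += 1
    rel_size = [1.0] * n_pops
    events = list(config.events)  # already time-sorted, stable
    next_node = n
    t = 0.0
    ev = 0
    n_active = n
    while n_active > 1:
        total_rate = sum(
            len(pops[p]) * (len(pops[p]) - 1) / rel_size[p] for p in range(n_pops)
        )
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = math.inf
        if ev < len(events) and events[ev].time <= t + wait:
            e = events[ev]
            ev += 1
            t = e.time
            if e.kind == "size_change":
                if e.population is None:
                    rel_size = [e.size] * n_pops
                else:
                    rel_size[e.population] = e.size
            elif e.kind == "join":
                pops[e.dest].extend(pops[e.source])
                pops[e.source] = []
            elif e.kind == "pulse":
                movers = [
                    lin for lin in pops[e.source] if rng.random() < e.fraction
                ]
                pops[e.source] = [
                    lin for lin in pops[e.source] if lin not in set(movers)
                ]
                pops[e.dest].extend(movers)
            continue
        if not math.isfinite(wait):
            raise RuntimeError(
                "no coalescence possible and no further events; lineages stranded"
            )
        t += wait
        # choose population proportional to its pair rate
        weights = [
            len(pops[p]) * (len(pops[p]) - 1) / rel_size[p] for p in range(n_pops)
        ]
        u = rng.random() * total_rate
        acc = 0.0
        chosen = 0
        for p, w in enumerate(weights):
            acc += w
            if u < acc:
                chosen = p
                break
        lineages = pops[chosen]
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        node = next_node
        next_node += 1
        parent[a] = node
        parent[b] = node
        time[node] = t
        pops[chosen] = [x for x in lineages if x not in (a, b)] + [node]
        n_active -= 1
    return Genealogy(n_leaves=n, parent=parent[:next_node], time=time[:next_node])


def place_mutations(
    tree: Genealogy,
    rng: np.random.Generator,
    theta: float | None = None,
    fixed_s: int | None = None,
) -> np.ndarray:
    """Infinite-sites mutations on the genealogy -> (n_leaves, S) 0/1 matrix.

    Fixed-S: exactly S mutations on branches chosen proportionally to
    length.  Theta: S ~ Poisson(theta * total length in 4N0 units), which
    gives the ms/Watterson expectation E[S] = theta * a1(n) at constant
    size.
    """
    if (theta is None) == (fixed_s is None):
        raise ValueError("set exactly one of theta, fixed_s")
    lengths = tree.branch_lengths()
    total = lengths.sum()
    if fixed_s is not None:
        if fixed_s > 0 and tree.n_leaves < 2:
            raise ValueError("cannot place mutations on a single-leaf tree")
        S = int(fixed_s)
    else:
        S = int(rng.poisson(theta * total))
    if S == 0:
        return np.empty((tree.n_leaves, 0), dtype=np.int8)
    probs = lengths / total
    branches = rng.choice(lengths.size, size=S, p=probs)
    desc = tree.leaf_matrix()
    return desc[branches].T.astype(np.int8)


@dataclass
class LocusSummary:
    """Summary statistics of one simulated locus."""

    S: int
    pi_sum: float
    tajd: float  # NaN when S = 0


def summarize_haplotypes(haps: np.ndarray) -> LocusSummary:
    """S, summed pairwise diversity, and Tajima's D from a 0/1 matrix."""
    n, S = haps.shape
    if S == 0:
        return LocusSummary(S=0, pi_sum=0.0, tajd=float("nan"))
    counts = haps.sum(axis=0).astype(np.float64)
    pairs = n * (n - 1) / 2.0
    pi_sum = float((counts * (n - counts) / pairs).sum())
    tajd = tajimas_d(S, pi_sum, n) if n >= 4 else float("nan")
    return LocusSummary(S=S, pi_sum=pi_sum, tajd=tajd)


def simulate_loci(config: SimConfig, rng: np.random.Generator | None = None):
    """Yield (Genealogy, haplotypes) for each locus of the configuration."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(config.n_loci):
        tree = simulate_genealogy(config, rng)
        if config.s_range is not None:
            s = int(rng.integers(config.s_range[0], config.s_range[1] + 1))
            haps = place_mutations(tree, rng, fixed_s=s)
        elif config.fixed_s is not None:
            haps = place_mutations(tree, rng, fixed_s=config.fixed_s)
        else:
            haps = place_mutations(tree, rng, theta=config.theta)
        yield tree, haps


def sweep_null_config(
    n_haplotypes: int,
    s_range: tuple[int, int] = (50, 300),
    n_loci: int = 10_000,
    bottleneck_time: float = 0.8,
    bottleneck_size: float = 0.01,
    pulse_fraction: float = 0.1,
    seed: int | None = None,
) -> SimConfig:
    """The bottleneck + admixture-pulse null model for Tajima's D.

    Two populations; all samples in population 0.  At the bottleneck time
    (default 0.8 in 4N0 units, ~10 kya for this system) every population
    shrinks 100-fold, and a 10% pulse from population 1 into population 0
    is applied just before the two populations merge (pulse first, then
    join, so the coincident join does not erase the pulse).  S per locus is
    uniform over *s_range*, emulating the observed spread of variant counts
    across 10-kb windows.
    """
    events = [
        DemographyEvent.size_change(bottleneck_time, bottleneck_size),
        DemographyEvent.pulse(bottleneck_time, 1, 0, pulse_fraction),
        DemographyEvent.join(bottleneck_time, 1, 0),
    ]
    return SimConfig(
        sample_sizes=[n_haplotypes, 0],
        events=events,
        s_range=s_range,
        n_loci=n_loci,
        seed=seed,
    )


def tajd_null_distribution(
    config: SimConfig,
    tail: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Simulated Tajima's D distribution and its lower-tail threshold.

    Loci with undefined D (S = 0) are excluded.  The threshold is the
    ceil(tail * m)-ranked smallest retained value; observed windows below
    it are selective-sweep candidates.
    """
    if not (0.0 < tail < 1.0):
        raise ValueError("tail must lie in (0, 1)")
    values = []
    for _, haps in simulate_loci(config, rng):
        d = summarize_haplotypes(haps).tajd
        if not math.isnan(d):
            values.append(d)
    if not values:
        raise ValueError("all simulated loci had S = 0; D distribution is empty")
    arr = np.sort(np.array(values))
    rank = max(1, math.ceil(tail * arr.size))
    return arr, float(arr[rank - 1])
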