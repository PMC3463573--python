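"""Neutral coalescent simulator for haploid samples.

Time is measured in units of N_e generations of the *current* population
(haploid scaling: one unit of time gives each lineage pair coalescence
rate 1).  The scaled mutation parameter theta = 2 * N_e * mu_hap is per
haplotype, so mutations fall on the genealogy as a Poisson process with
rate theta/2 per unit branch length and the expected pairwise difference
count under a constant-size history equals theta.

Two demographies are supported: constant size, and a sudden (stepwise)
expansion from theta0 to theta1 at scaled time ``t_event`` before the
present.  In mutational time the expansion age is tau = theta1 * t_event
(tau = 2 * mu_hap * t_generations).

Mutation models: finite sites (default; every mutation picks a uniform
site and a uniform different base, so homoplasy can occur) and infinite
sites (every mutation hits a fresh site — guaranteed tree-like data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .seq_io import Alignment

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Demography:
    """Population-size history seen backwards from the present."""

    model: str  # "constant" | "sudden_expansion"
    theta0: float
    theta1: float | None = None
    t_event: float | None = None  # scaled time (units of current N_e generations)

    def __post_init__(self) -> None:
        if self.model == "constant":
            if self.theta0 < 0:
                raise ConfigError("theta must be non-negative")
        elif self.model == "sudden_expansion":
            if self.theta1 is None or self.t_event is None:
                raise ConfigError("sudden_expansion requires theta1 and t_event")
            if min(self.theta0, self.theta1, self.t_event) < 0:
                raise ConfigError("demography parameters must be non-negative")
            if self.theta1 == 0:
                raise ConfigError("post-expansion theta1 must be positive")
        else:
            raise ConfigError(f"unknown demography model {self.model!r}")

    @classmethod
    def constant(cls, theta: float) -> "Demography":
        return cls(model="constant", theta0=theta)

    @classmethod
    def sudden_expansion(
        cls,
        theta0: float,
        theta1: float,
        tau: float | None = None,
        t_event: float | None = None,
    ) -> "Demography":
        """Expansion given either the scaled event time or mutational tau."""
        if (tau is None) == (t_event is None):
            raise ConfigError("give exactly one of tau or t_event")
        if t_event is None:
            t_event = tau / theta1
        return cls(
            model="sudden_expansion", theta0=theta0, theta1=theta1, t_event=t_event
        )

    @property
    def theta_current(self) -> float:
        return self.theta0 if self.model == "constant" else float(self.theta1)

    @property
    def tau(self) -> float | None:
        if self.model == "sudden_expansion":
            return float(self.theta1) * float(self.t_event)
        return None


@dataclass(frozen=True)
class Genealogy:
    """A binary coalescent tree: nodes 0..n-1 are leaves at time 0,
    nodes n..2n-2 are coalescences in time order; the last node is the root."""

    n: int
    parent: np.ndarray = field(repr=False)  # -1 at the root
    time: np.ndarray = field(repr=False)

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (index 0..2n-3)."""
        idx = np.arange(2 * self.n - 2)
        return self.time[self.parent[idx]] - self.time[idx]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_counts(self) -> np.ndarray:
        """Number of sampled leaves below each node."""
        counts = np.zeros(2 * self.n - 1, dtype=np.int64)
        counts[: self.n] = 1
        for v in range(2 * self.n - 2):  # children are always numbered before parents
            counts[self.parent[v]] += counts[v]
        return counts

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for v in range(2 * self.n - 2):
            ch[self.parent[v]].append(v)
        return ch


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genealogy(
    n: int, demography: Demography, seed: int | np.random.Generator
) -> Genealogy:
    """Draw one coalescent genealogy under the given size history."""
    if n < 2:
        raise ConfigError("need a sample of at least 2")
    rng = _as_rng(seed)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1, dtype=float)
    active = list(range(n))
    t = 0.0
    nxt = n
    expansion = demography.model == "sudden_expansion"
    # backwards in time the pre-event epoch has relative size r = theta0/theta1
    r = (demography.theta0 / demography.theta1) if expansion else 1.0
    ancient = False
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0
        if ancient:
            if r == 0.0:
                w = 0.0  # theta0 = 0: instantaneous coalescence before the event
            else:
                w = rng.exponential(r / rate)
        else:
            w = rng.exponential(1.0 / rate)
            if expansion and t + w > demography.t_event:
                # event reached before this coalescence: re-draw in old epoch
                t = float(demography.t_event)
                ancient = True
                continue
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n=n, parent=parent, time=time)


@dataclass(frozen=True)
class SimulatedSample:
    """Alignment plus the genealogy and mutation placements that produced it."""

    alignment: Alignment
    genealogy: Genealogy
    mutations: tuple[tuple[int, int], ...]  # (site, node-below-branch)
    seed: int | None
    n_collisions: int  # mutations that re-hit an already mutated site


def _place_mutations(
    gen: Genealogy,
    theta: float,
    rng: np.random.Generator,
    conditioning: str,
    s: int | None,
) -> np.ndarray:
    """Branch (node-below) index for each mutation event."""
    blen = gen.branch_lengths()
    total = blen.sum()
    if conditioning == "theta":
        n_mut = rng.poisson(theta / 2.0 * total)
    elif conditioning == "fixed_S":
        if s is None:
            raise ConfigError("fixed_S conditioning requires s")
        n_mut = s
    else:
        raise ConfigError(f"unknown conditioning {conditioning!r}")
    if n_mut == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(blen.size, size=n_mut, p=blen / total)


def simulate_alignment(
    n: int,
    L: int,
    demography: Demography,
    seed: int | np.random.Generator,
    conditioning: str = "theta",
    s: int | None = None,
    infinite_sites: bool = False,
) -> SimulatedSample:
    """Simulate an aligned haploid sample of n sequences of length L."""
    if L < 1:
        raise ConfigError("L must be >= 1")
    rng = _as_rng(seed)
    gen = simulate_genealogy(n, demography, rng)
    branches = _place_mutations(gen, demography.theta_current, rng, conditioning, s)
    n_mut = branches.size
    if infinite_sites:
        if n_mut > L:
            raise ConfigError(
                f"infinite-sites mode needs L >= number of mutations ({n_mut} > {L})"
            )
        sites = rng.permutation(L)[:n_mut]
    else:
        sites = rng.integers(0, L, size=n_mut)
    n_collisions = int(n_mut - np.unique(sites).size)

    # mutations on each branch, applied root-to-tip
    per_node: list[list[int]] = [[] for _ in range(2 * n - 1)]
    for m, v in enumerate(branches):
        per_node[v].append(m)
    root_seq = rng.choice(BASES, size=L)
    seq_of: dict[int, np.ndarray] = {gen.root: root_seq}
    children = gen.children()
    stack = [gen.root]
    while stack:
        v = stack.pop()
        base = seq_of[v]
        for c in children[v]:
            seq = base.copy()
            for m in sorted(per_node[c]):
                site = sites[m]
                cur = seq[site]
                options = BASES[BASES != cur]
                seq[site] = rng.choice(options)
            seq_of[c] = seq
            stack.append(c)
    ids = tuple(f"S{i + 1:03d}" for i in range(n))
    seq_strs = tuple(seq_of[i].tobytes().decode() for i in range(n))
    return SimulatedSample(
        alignment=Alignment(ids, seq_strs),
        genealogy=gen,
        mutations=tuple((int(sites[m]), int(branches[m])) for m in range(n_mut)),
        seed=None,
        n_collisions=n_collisions,
    )


def simulate_pi_k_s(
    n: int, s: int, rng: np.random.Generator
) -> tuple[float, int, int]:
    """Fast constant-size null replicate conditioned on S segregating sites.

    Places exactly ``s`` mutations uniformly on the genealogy under the
    infinite-sites model and returns (mean pairwise differences, number of
    distinct haplotypes, realised segregating sites) without building
    sequences.  Used for neutrality-test null distributions.
    """
    gen = simulate_genealogy(n, Demography.constant(0.0), rng)
    branches = _place_mutations(gen, 0.0, rng, "fixed_S", s)
    counts = gen.leaf_counts()
    c = counts[branches]
    npairs = n * (n - 1) / 2.0
    theta_pi = float((c * (n - c)).sum() / npairs)
    # haplotype partition: leaves sharing exactly the same mutation set
    muts_per_node: list[tuple[int, ...]] = [() for _ in range(2 * n - 1)]
    for m, v in enumerate(branches):
        muts_per_node[v] = muts_per_node[v] + (m,)
    sig: dict[int, frozenset[int]] = {gen.root: frozenset()}
    children = gen.children()
    stack = [gen.root]
    for v in stack:
        for ch in children[v]:
            sig[ch] = sig[v] | frozenset(muts_per_node[ch])
            stack.append(ch)
    k = len({sig[i] for i in range(n)})
    return theta_pi, k, int(s)


def simulate_pair_differences(
    demography: Demography, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised pairwise-difference counts for ``size`` independent pairs.

    Infinite-sites: the difference count is Poisson with mean theta * T2
    in scaled time.  Used as a Monte-Carlo oracle for the mismatch model.
    """
    if demography.model == "constant":
        t2 = rng.exponential(1.0, size=size)
        return rng.poisson(demography.theta0 * t2)
    te, th0, th1 = demography.t_event, demography.theta0, demography.theta1
    t2 = rng.exponential(1.0, size=size)
    deep = t2 > te
    # rescale the residual waiting time into the pre-event epoch (size ratio r)
    r = th0 / th1
    t2 = np.where(deep, te + (t2 - te) * r, t2)
    return rng.poisson(th1 * t2)
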