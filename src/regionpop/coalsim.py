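"""Hudson-style coalescent simulation under piecewise demography.

The simulator draws Kingman genealogies for a sample of ``n`` chromosomes
under a piecewise population-size history (constant or exponentially growing
epochs), drops infinite-sites mutations on branches at a region-scaled rate
``theta = 4*N0*mu_region`` (``N0`` = present-day diploid size), and derives
site-frequency-spectrum statistics from the result.  A structured variant
supports a symmetric island model and clean population splits, which also
serves as the source of "archaic" outgroup lineages.

Time is measured in generations before present throughout; conversion to
years uses the model's generation time (default 20 y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import diversity

__all__ = [
    "Epoch",
    "DemographicModel",
    "TwoDemeModel",
    "SCENARIOS",
    "scenario_model",
    "Genealogy",
    "SimulatedGenealogy",
    "simulate",
    "sample_genealogy",
    "sample_structured_genealogy",
    "null_pvalue",
    "allele_age_mc",
    "tmrca_expectation",
    "ne_from_theta",
]


# ---------------------------------------------------------------------------
# demography


@dataclass(frozen=True)
class Epoch:
    """One piece of a population-size history.

    ``size`` is the diploid size at the epoch's recent boundary ``start``
    (generations before present).  Going back in time within the epoch the
    size is ``size * exp(-growth * (t - start))``: ``growth > 0`` means the
    population was smaller in the past, i.e. it grew forward in time.
    """

    start: float
    size: float
    growth: float = 0.0

    def size_at(self, t: float) -> float:
        return self.size * math.exp(-self.growth * (t - self.start))


@dataclass(frozen=True)
class DemographicModel:
    epochs: tuple[Epoch, ...]
    generation_time: float = 20.0

    def __post_init__(self):
        starts = [e.start for e in self.epochs]
        if starts[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(e.size <= 0 for e in self.epochs):
            raise ValueError("population sizes must be positive")

    @property
    def present_size(self) -> float:
        return self.epochs[0].size

    @classmethod
    def constant(cls, N: float, generation_time: float = 20.0) -> "DemographicModel":
        return cls((Epoch(0.0, N),), generation_time)


def _growth_epochs(N_base: float, fold: float, onset_gen: float) -> tuple[Epoch, ...]:
    """Exponential f-fold growth from onset to the present over a constant base."""
    g = math.log(fold) / onset_gen
    return (Epoch(0.0, N_base * fold, g), Epoch(onset_gen, N_base))


def african_growth_model(fold: float, N_base: float = 10_000.0,
                         onset_years: float = 70_000.0,
                         generation_time: float = 20.0) -> DemographicModel:
    """f-fold exponential growth (f in {2,4,6,8,10}) starting 70 kya."""
    onset = onset_years / generation_time
    return DemographicModel(_growth_epochs(N_base, fold, onset), generation_time)


def ooa_bottleneck_model(fold: float, N_base: float = 10_000.0,
                         N_bottleneck: float = 2_000.0,
                         bottleneck_years: float = 60_000.0,
                         growth_years: float = 50_000.0,
                         generation_time: float = 20.0) -> DemographicModel:
    """Out-of-Africa style history: bottleneck to 2000 at 60 kya, then
    f-fold growth (f in {10,20,40}) from 50 kya to the present."""
    t_b = bottleneck_years / generation_time
    t_g = growth_years / generation_time
    g = math.log(fold) / t_g
    return DemographicModel(
        (Epoch(0.0, N_bottleneck * fold, g), Epoch(t_g, N_bottleneck), Epoch(t_b, N_base)),
        generation_time,
    )


#: the scenario families used for the demographic null distributions
SCENARIOS: dict[str, DemographicModel] = {"constant": DemographicModel.constant(10_000.0)}
for _f in (2, 4, 6, 8, 10):
    SCENARIOS[f"african:{_f}x"] = african_growth_model(_f)
for _f in (10, 20, 40):
    SCENARIOS[f"ooa:{_f}x"] = ooa_bottleneck_model(_f)


def scenario_model(name: str) -> DemographicModel:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")


@dataclass(frozen=True)
class TwoDemeModel:
    """Symmetric two-deme island model with an optional ancestral merge.

    ``M`` is the scaled co-location rate: a pair of lineages in different
    demes finds itself in the same deme at rate ``M/(4N)`` per generation
    (per-lineage migration rate ``M/(8N)``).  With this parameterization the
    equilibrium Weir-Cockerham F_ST equals ``1/(1+M)`` exactly, for any
    number of demes; see docs/methods.md.
    """

    N: float
    M: float = 0.0
    split_time: float | None = None
    N_ancestral: float | None = None
    generation_time: float = 20.0

    @property
    def lineage_migration_rate(self) -> float:
        return self.M / (8.0 * self.N)


# ---------------------------------------------------------------------------
# genealogies


@dataclass
class Genealogy:
    """A binary coalescent tree over ``n`` sampled chromosomes.

    Nodes ``0..n-1`` are leaves (time 0); internal nodes are appended in
    coalescence order so ``parent[i] > i`` for every non-root node.
    """

    n: int
    parent: np.ndarray  # int32, len 2n-1, root = -1
    time: np.ndarray    # float64 generations, len 2n-1
    leaf_deme: np.ndarray | None = None

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        return self.time[self.parent[:-1]] - self.time[:-1]

    def leaf_counts(self) -> np.ndarray:
        """Number of sampled leaves below each node."""
        counts = np.ones(2 * self.n - 1, dtype=np.int64)
        counts[self.n:] = 0
        par = self.parent
        for i in range(2 * self.n - 2):  # parent[i] > i ensures one pass
            counts[par[i]] += counts[i]
        return counts


@dataclass
class SimulatedGenealogy:
    """A genealogy plus the infinite-sites mutations dropped on it."""

    genealogy: Genealogy
    theta: float
    positions: np.ndarray        # float in (0,1): relative position in region
    derived_counts: np.ndarray   # int, per mutation
    matrix: np.ndarray           # uint8, n x S, 1 = derived
    mutation_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def S(self) -> int:
        return int(self.positions.size)


def _coal_waiting_time(t0: float, k: int, model: DemographicModel,
                       target: float) -> float:
    """Time of the next coalescence among k lineages, starting at t0,
    given an Exp(1) draw ``target`` (inverse integrated-hazard method)."""
    pairs = k * (k - 1) / 2.0
    epochs = model.epochs
    t = t0
    remaining = target
    for idx, ep in enumerate(epochs):
        end = epochs[idx + 1].start if idx + 1 < len(epochs) else math.inf
        if end <= t:
            continue
        lo = max(t, ep.start)
        if ep.growth == 0.0:
            rate = pairs / (2.0 * ep.size)
            if end < math.inf:
                cap = rate * (end - lo)
                if remaining > cap:
                    remaining -= cap
                    continue
            return lo + remaining / rate
        g = ep.growth
        c = pairs / (2.0 * ep.size * g)
        # integrated hazard from lo to x: c*(e^{g(x-start)} - e^{g(lo-start)})
        base = math.exp(g * (lo - ep.start))
        if end < math.inf:
            cap = c * (math.exp(g * (end - ep.start)) - base)
            if remaining > cap:
                remaining -= cap
                continue
        return ep.start + math.log(base + remaining / c) / g
    raise AssertionError("unreachable: last epoch is unbounded")


def sample_genealogy(n: int, model: DemographicModel,
                     rng: np.random.Generator) -> Genealogy:
    """Draw one Kingman genealogy under the piecewise demography."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes)
    active = list(range(n))
    targets = rng.exponential(size=n - 1)
    us = rng.random((n - 1, 2))
    t = 0.0
    constant = len(model.epochs) == 1 and model.epochs[0].growth == 0.0
    if constant:
        twoN = 2.0 * model.epochs[0].size
    for step in range(n - 1):
        k = n - step
        if constant:
            t += targets[step] * twoN / (k * (k - 1) / 2.0)
        else:
            t = _coal_waiting_time(t, k, model, targets[step])
        i = int(us[step, 0] * k)
        a = active.pop(i)
        j = int(us[step, 1] * (k - 1))
        b = active.pop(j)
        node = n + step
        parent[a] = node
        parent[b] = node
        time[node] = t
        active.append(node)
    return Genealogy(n=n, parent=parent, time=time)


def sample_structured_genealogy(n_per_deme: tuple[int, ...], model: TwoDemeModel,
                                rng: np.random.Generator) -> Genealogy:
    """Structured coalescent for a symmetric island model with d demes
    (one deme size ``model.N`` each), optionally merging into a single
    ancestral population at ``model.split_time``."""
    d = len(n_per_deme)
    n = int(sum(n_per_deme))
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes)
    leaf_deme = np.repeat(np.arange(d), n_per_deme).astype(np.int32)
    deme = list(leaf_deme)
    active = list(range(n))
    m = model.M * (d - 1) / (8.0 * model.N) if d > 1 else 0.0
    t = 0.0
    next_node = n
    merged = False
    N_anc = model.N_ancestral if model.N_ancestral is not None else model.N
    while len(active) > 1:
        if not merged and model.split_time is not None and t >= model.split_time:
            merged = True
        if merged:
            k = len(active)
            rate = k * (k - 1) / 2.0 / (2.0 * N_anc)
            t += rng.exponential() / rate
            i, j = rng.choice(k, size=2, replace=False)
        else:
            counts = np.bincount([deme[a] for a in active], minlength=d)
            coal_rates = counts * (counts - 1) / 2.0 / (2.0 * model.N)
            mig_rate = m * len(active)
            total = coal_rates.sum() + mig_rate
            if total == 0.0:
                # isolated singleton lineages: nothing can happen until the split
                if model.split_time is None:
                    raise RuntimeError("lineages can never coalesce (M=0, no split)")
                t = model.split_time
                merged = True
                continue
            dt = rng.exponential() / total
            if model.split_time is not None and t + dt >= model.split_time:
                t = model.split_time
                merged = True
                continue
            t += dt
            u = rng.random() * total
            if u < mig_rate:
                # a uniformly chosen lineage hops to a uniformly chosen other deme
                a = active[int(rng.integers(len(active)))]
                others = [x for x in range(d) if x != deme[a]]
                deme[a] = others[int(rng.integers(d - 1))]
                continue
            u -= mig_rate
            target_deme = int(np.searchsorted(np.cumsum(coal_rates), u, side="right"))
            idxs = [ii for ii, a in enumerate(active) if deme[a] == target_deme]
            i, j = rng.choice(len(idxs), size=2, replace=False)
            i, j = idxs[i], idxs[j]
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        parent[a] = parent[b] = next_node
        time[next_node] = t
        deme.append(deme[a])
        active.append(next_node)
        next_node += 1
    return Genealogy(n=n, parent=parent, time=time, leaf_deme=leaf_deme)


# ---------------------------------------------------------------------------
# mutations


def _drop_mutations(gen: Genealogy, theta: float, N_ref: float,
                    rng: np.random.Generator, matrix: bool = True) -> SimulatedGenealogy:
    """Poisson infinite-sites mutations at per-generation rate theta/(4*N_ref)
    per lineage, uniform positions on (0,1)."""
    mu = theta / (4.0 * N_ref)
    lens = gen.branch_lengths()
    hits = rng.poisson(lens * mu)
    S = int(hits.sum())
    nodes = np.repeat(np.arange(2 * gen.n - 2), hits)
    positions = rng.random(S)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    nodes = nodes[order]
    counts = gen.leaf_counts()
    derived = counts[nodes]
    if matrix:
        mat = np.zeros((gen.n, S), dtype=np.uint8)
        if S:
            below = _leaf_sets(gen)
            for col, node in enumerate(nodes):
                mat[below[node], col] = 1
    else:
        mat = np.empty((gen.n, 0), dtype=np.uint8)
    return SimulatedGenealogy(genealogy=gen, theta=theta, positions=positions,
                              derived_counts=derived.astype(np.int64),
                              matrix=mat, mutation_nodes=nodes)


def _leaf_sets(gen: Genealogy) -> list[np.ndarray]:
    """Leaf index arrays below each node."""
    sets: list[list[int]] = [[i] for i in range(gen.n)] + [[] for _ in range(gen.n - 1)]
    par = gen.parent
    for i in range(2 * gen.n - 2):
        sets[par[i]].extend(sets[i])
    return [np.asarray(s, dtype=np.int64) for s in sets]


def simulate(n: int, theta_region: float, model: DemographicModel,
             seed: int | np.random.Generator | None = None,
             build_matrix: bool = True) -> SimulatedGenealogy:
    """Neutral coalescent sample: genealogy plus infinite-sites mutations.

    ``theta_region`` is the region-total scaled mutation rate 4*N0*mu_region
    with N0 the model's present-day diploid size (ms convention).
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if theta_region <= 0:
        raise ValueError("theta must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = sample_genealogy(n, model, rng)
    return _drop_mutations(gen, theta_region, model.present_size, rng,
                           matrix=build_matrix)


# ---------------------------------------------------------------------------
# simulation-based inference


_STATS = {
    "D": lambda dc, n: diversity.tajimas_d_from_counts(dc, n),
    "H": lambda dc, n: diversity.fay_wu_h_from_counts(dc, n),
    "pi": lambda dc, n: diversity.pi_from_counts(dc, n),
    "S": lambda dc, n: float(dc.size),
}


def null_distribution(stat: str, n: int, theta_region: float,
                      model: DemographicModel, reps: int,
                      seed: int | np.random.Generator | None = None,
                      max_draws: int | None = None) -> np.ndarray:
    """``reps`` draws of a statistic under the neutral null.

    Replicates with S = 0 (statistic undefined) are discarded and redrawn
    until ``reps`` valid values are collected.
    """
    fn = _STATS[stat]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(reps)
    got = 0
    draws = 0
    limit = max_draws if max_draws is not None else 100 * reps + 1000
    while got < reps:
        if draws >= limit:
            raise RuntimeError("too many S=0 replicates; increase theta")
        sim = simulate(n, theta_region, model, rng, build_matrix=False)
        draws += 1
        if stat != "S" and sim.S == 0:
            continue
        out[got] = fn(sim.derived_counts, n)
        got += 1
    return out


def null_pvalue(observed: float, stat: str, n: int, theta_region: float,
                model: DemographicModel, reps: int = 10_000,
                tail: str = "lower", seed: int | np.random.Generator | None = None,
                return_null: bool = False):
    """Empirical p-value of an observed D or H against the simulated null.

    ``P_upper = (1 + #{sim >= obs}) / (reps + 1)`` and symmetrically for the
    lower tail; ``two-sided`` doubles the smaller tail (capped at 1).
    """
    import warnings
    if reps < 100:
        warnings.warn("fewer than 100 null replicates: p-value is coarse")
    null = null_distribution(stat, n, theta_region, model, reps, seed)
    p_up = (1 + np.count_nonzero(null >= observed)) / (reps + 1)
    p_lo = (1 + np.count_nonzero(null <= observed)) / (reps + 1)
    if tail == "upper":
        p = p_up
    elif tail == "lower":
        p = p_lo
    elif tail == "two-sided":
        p = min(1.0, 2.0 * min(p_up, p_lo))
    else:
        raise ValueError("tail must be upper, lower or two-sided")
    if return_null:
        return p, null
    return p


def allele_age_mc(i: int, n: int, model: DemographicModel,
                  reps: int = 100_000,
                  seed: int | np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo age (mean, sd in years) of a derived allele seen in
    ``i`` of ``n`` chromosomes.

    Over simulated genealogies, every branch subtending exactly ``i`` leaves
    is weighted by its length and a mutation age is drawn uniformly along
    it; the estimate is the branch-length-weighted mean of those ages.
    """
    if not 1 <= i <= n - 1:
        raise ValueError("derived count must be in [1, n-1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_sum = 0.0
    wa_sum = 0.0
    wa2_sum = 0.0
    for _ in range(reps):
        gen = sample_genealogy(n, model, rng)
        counts = gen.leaf_counts()[:-1]
        sel = np.nonzero(counts == i)[0]
        if sel.size == 0:
            continue
        lo = gen.time[sel]
        lens = gen.time[gen.parent[sel]] - lo
        ages = lo + rng.random(sel.size) * lens
        w_sum += lens.sum()
        wa_sum += (lens * ages).sum()
        wa2_sum += (lens * ages ** 2).sum()
    if w_sum == 0.0:
        raise RuntimeError(f"no branch with {i} descendants in any replicate")
    mean = wa_sum / w_sum
    var = max(wa2_sum / w_sum - mean ** 2, 0.0)
    gt = model.generation_time
    return mean * gt, math.sqrt(var) * gt


def tmrca_expectation(n: int, model: DemographicModel,
                      reps: int = 10_000,
                      seed: int | np.random.Generator | None = None) -> float:
    """Expected TMRCA in years: analytic ``4N(1-1/n)`` generations for a
    constant size, Monte-Carlo mean otherwise."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if len(model.epochs) == 1 and model.epochs[0].growth == 0.0:
        gens = 4.0 * model.epochs[0].size * (1.0 - 1.0 / n)
        return gens * model.generation_time
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = 0.0
    for _ in range(reps):
        total += sample_genealogy(n, model, rng).tmrca
    return total / reps * model.generation_time


def ne_from_theta(theta_per_site: float, mu_per_site: float) -> float:
    """Effective population size from the scaled mutation rate: Ne = theta/(4 mu)."""
    if theta_per_site <= 0 or mu_per_site <= 0:
        raise ValueError("theta and mu must be positive")
    return theta_per_site / (4.0 * mu_per_site)
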