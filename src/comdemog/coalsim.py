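"""Coalescent genealogy simulation under piecewise-constant demographies.

The demographic model is the one used throughout the package: a single
panmictic population of constant haploid size ``ne_present`` from the present
back to ``t_change_years`` before present, and constant size
``ne_present * ratio_ancestral`` earlier.  Genealogies are generated under the
continuous-time Kingman coalescent (pairwise merger rate ``1/N(t)`` per
generation), with node times recorded in generations before present.

A second simulator produces genealogies under exponential growth
``Theta(t) = Theta_present * exp(-g t)`` with time in mutational units, the
parameterization used by LAMARC-style growth estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographicScenario",
    "Genealogy",
    "ne_from_theta",
    "scenario_ratio_from_cells",
    "simulate_genealogy",
    "simulate_growth_genealogy",
    "simulate_stepping_stone_genealogy",
    "BUILTIN_SCENARIOS",
]


@dataclass(frozen=True)
class DemographicScenario:
    """One instantaneous size change at ``t_change_years`` before present.

    ``ne_present`` is the haploid effective size (gene copies); the ancestral
    size is ``ne_present * ratio_ancestral``.  ``generations_per_year``
    converts the change time to coalescent (generation) units: 1 for the
    moths, 1/30 for the Joshua tree.
    """

    ne_present: float
    ratio_ancestral: float = 1.0
    t_change_years: float = 13_000.0
    generations_per_year: float = 1.0

    def __post_init__(self) -> None:
        if self.ne_present <= 0:
            raise ValueError(f"ne_present must be > 0, got {self.ne_present}")
        if self.ratio_ancestral <= 0:
            raise ValueError(
                f"ratio_ancestral must be > 0, got {self.ratio_ancestral}"
            )
        if self.t_change_years < 0:
            raise ValueError(
                f"t_change_years must be >= 0, got {self.t_change_years}"
            )
        if self.generations_per_year <= 0:
            raise ValueError(
                f"generations_per_year must be > 0, got {self.generations_per_year}"
            )

    @property
    def t_change_generations(self) -> float:
        return self.t_change_years * self.generations_per_year

    @property
    def ne_ancestral(self) -> float:
        return self.ne_present * self.ratio_ancestral

    def size_at(self, t_generations: float) -> float:
        """Haploid population size ``t_generations`` before present."""
        if t_generations < self.t_change_generations:
            return self.ne_present
        return self.ne_ancestral


# Scenario size ratios derived from the palaeodistribution cell counts
# (past cells / current cells for each reconstruction).  "constant" is the
# literal no-change history used as the null in power analyses.
BUILTIN_SCENARIOS: dict[str, float] = {
    "constant": 1.0,
    "decline": 641 / 566,        # BRT, equal sensitivity/specificity
    "slight_growth": 434 / 509,  # MaxEnt, maximum sensitivity + specificity
    "doubling": 240 / 432,       # MaxEnt, equal sensitivity/specificity
}


class Genealogy:
    """A rooted binary ultrametric tree with node times (tips at time 0).

    Nodes ``0 .. n-1`` are tips, ``n .. 2n-2`` internal nodes in coalescence
    order (the root is node ``2n-2``).  ``units`` records the time scale
    ("generations" or "mutational").
    """

    def __init__(
        self,
        parent: np.ndarray,
        times: np.ndarray,
        labels: list[str] | None = None,
        units: str = "generations",
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.times = np.asarray(times, dtype=float)
        n_nodes = len(self.parent)
        if n_nodes % 2 != 1 or n_nodes < 3:
            raise ValueError("a binary coalescent tree has 2n-1 nodes, n >= 2")
        self.n_tips = (n_nodes + 1) // 2
        self.labels = labels or [f"t{i + 1}" for i in range(self.n_tips)]
        if len(self.labels) != self.n_tips:
            raise ValueError("labels must match tip count")
        self.units = units
        self._validate()

    def _validate(self) -> None:
        root = self.root
        for i in range(len(self.parent)):
            if i == root:
                continue
            p = self.parent[i]
            if self.times[p] <= self.times[i]:
                raise ValueError("node times must strictly increase root-ward")
        if not np.allclose(self.times[: self.n_tips], 0.0):
            raise ValueError("tips must be at time 0 (ultrametric)")

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(len(self.parent))}
        for i in range(len(self.parent)):
            if i != self.root:
                ch[self.parent[i]].append(i)
        return ch

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(len(self.parent))
        for i in range(len(self.parent)):
            if i != self.root:
                bl[i] = self.times[self.parent[i]] - self.times[i]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def external_branch_length(self) -> float:
        return float(self.branch_lengths()[: self.n_tips].sum())

    def waiting_times(self) -> list[tuple[int, float]]:
        """Intercoalescent intervals as ``(k_lineages, duration)`` pairs.

        Starts with ``n`` lineages at time 0; one entry per coalescence.
        """
        coal_times = np.sort(self.times[self.n_tips:])
        out = []
        prev = 0.0
        k = self.n_tips
        for t in coal_times:
            out.append((k, float(t - prev)))
            prev = t
            k -= 1
        return out

    def to_newick(self, precision: int = 10) -> str:
        ch = self.children()

        def rec(node: int) -> str:
            if node < self.n_tips:
                name = self.labels[node]
            else:
                kids = ",".join(rec(c) for c in ch[node])
                name = f"({kids})"
            if node == self.root:
                return name
            bl = self.times[self.parent[node]] - self.times[node]
            return f"{name}:{bl:.{precision}g}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Genealogy(n_tips={self.n_tips}, tmrca={self.tmrca:.4g}, "
            f"units={self.units!r})"
        )


def genealogy_from_newick(newick: str, units: str = "generations") -> Genealogy:
    """Parse a rooted ultrametric Newick tree into a :class:`Genealogy`.

    Branch lengths are interpreted on the scale given by ``units``.  Raises
    ``ValueError`` for non-ultrametric or non-binary trees.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=1e-4)
    leaves = [lf for lf in tree.leaf_node_iter()]
    n = len(leaves)
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    if any(len(nd.child_nodes()) != 2 for nd in internals):
        raise ValueError("tree must be strictly binary")
    internals.sort(key=lambda nd: nd.age)
    index = {}
    labels = []
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
        labels.append(lf.taxon.label if lf.taxon else f"t{i + 1}")
    for j, nd in enumerate(internals):
        index[id(nd)] = n + j
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        times[i] = nd.age
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
    return Genealogy(parent, times, labels=labels, units=units)


def ne_from_theta(theta: float, mu: float) -> float:
    """Haploid effective size from a per-site diversity parameter.

    Ne = Θ / (2µ), with µ the per-site per-generation neutral substitution
    rate.  This is the conversion used to set contemporary coalescent sizes
    from empirically estimated Θ.
    """
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return theta / (2.0 * mu)


def scenario_ratio_from_cells(current_cells: int, past_cells: int) -> float:
    """Ancestral:present size ratio from range-cell counts at two times."""
    if current_cells <= 0 or past_cells <= 0:
        raise ValueError("cell counts must be positive")
    return past_cells / current_cells


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genealogy(
    n: int, scenario: DemographicScenario, seed=None
) -> Genealogy:
    """Simulate a Kingman coalescent genealogy under ``scenario``.

    Pairwise coalescence rate is ``1/N(t)`` per generation per pair, with the
    instantaneous size change at the scenario's change time.  Returns node
    times in generations.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    rng = _resolve_rng(seed)
    t_change = scenario.t_change_generations
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)

    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        pairs = k * (k - 1) / 2.0
        while True:
            N = scenario.size_at(t)
            w = rng.exponential(N / pairs)
            if t < t_change <= t + w:
                # size change interrupts the exponential clock; restart the
                # memoryless draw at the change time with the ancestral size
                t = t_change
                continue
            t += w
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = next_node
        parent[b] = next_node
        times[next_node] = t
        active = [x for x in active if x not in (a, b)]
        active.append(next_node)
        next_node += 1
    return Genealogy(parent, times, units="generations")


def simulate_growth_genealogy(
    n: int, theta_present: float, g: float, seed=None
) -> Genealogy:
    """Coalescent genealogy under exponential growth, mutational time units.

    Looking into the past, the population-scaled diversity is
    ``Theta(u) = theta_present * exp(-g u)``, so the total coalescence hazard
    with k extant lineages is ``k (k-1) exp(g u) / theta_present``.  ``g = 0``
    reduces exactly to the constant-size coalescent.  Only ``g >= 0`` is
    supported: for negative g the integrated hazard is finite and the
    genealogy fails to coalesce with positive probability.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if theta_present <= 0:
        raise ValueError(f"theta_present must be > 0, got {theta_present}")
    if g < 0:
        raise ValueError("negative growth is improper for simulation (no MRCA)")
    rng = _resolve_rng(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)

    active = list(range(n))
    u = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        rate0 = k * (k - 1) / theta_present  # hazard at u under e^{g u} scaling
        e = rng.exponential(1.0)
        if g == 0.0:
            u += e / rate0
        else:
            # invert the integrated hazard rate0 * (e^{g(u+w)} - e^{g u}) / g = e
            u = math.log(math.exp(g * u) + g * e / rate0) / g
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = next_node
        parent[b] = next_node
        times[next_node] = u
        active = [x for x in active if x not in (a, b)]
        active.append(next_node)
        next_node += 1
    return Genealogy(parent, times, units="mutational")


def simulate_stepping_stone_genealogy(
    samples_per_deme: list[int],
    scenario: DemographicScenario,
    migration_rate: float,
    seed=None,
) -> tuple[Genealogy, list[int]]:
    """Structured coalescent on a 1-D stepping-stone chain of demes.

    Each deme has haploid size ``scenario.size_at(t)`` (the size change applies
    to every deme simultaneously).  A lineage in deme d migrates to each
    adjacent deme at rate ``migration_rate`` per generation; lineages in the
    same deme coalesce pairwise at rate ``1/N(t)``.  Returns the genealogy and
    the deme index of each tip.  Low migration produces strong isolation by
    distance, mimicking structured chloroplast data.
    """
    if len(samples_per_deme) < 1:
        raise ValueError("need at least one deme")
    if any(s < 0 for s in samples_per_deme):
        raise ValueError("negative sample counts")
    if migration_rate < 0:
        raise ValueError("migration_rate must be >= 0")
    n = int(sum(samples_per_deme))
    if n < 2:
        raise ValueError("need at least 2 samples in total")
    n_demes = len(samples_per_deme)
    if n_demes >= 2 and migration_rate == 0:
        raise ValueError("migration_rate must be > 0 with multiple demes")
    rng = _resolve_rng(seed)

    tip_demes: list[int] = []
    for d, s in enumerate(samples_per_deme):
        tip_demes.extend([d] * s)

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)

    lineage_deme = {i: tip_demes[i] for i in range(n)}
    t = 0.0
    t_change = scenario.t_change_generations
    next_node = n
    while len(lineage_deme) > 1:
        N = scenario.size_at(t)
        by_deme: dict[int, list[int]] = {}
        for lin, d in lineage_deme.items():
            by_deme.setdefault(d, []).append(lin)
        coal_rate = sum(
            len(v) * (len(v) - 1) / 2.0 / N for v in by_deme.values()
        )
        mig_rates = []
        for lin, d in lineage_deme.items():
            nbrs = [x for x in (d - 1, d + 1) if 0 <= x < n_demes]
            mig_rates.append((lin, d, nbrs, migration_rate * len(nbrs)))
        total_mig = sum(r for *_rest, r in mig_rates)
        total = coal_rate + total_mig
        if total == 0:  # pragma: no cover - guarded by preconditions
            raise RuntimeError("structured coalescent stalled")
        w = rng.exponential(1.0 / total)
        if t < t_change <= t + w:
            t = t_change
            continue
        t += w
        if rng.random() < coal_rate / total:
            demes = [d for d, v in by_deme.items() for _ in range(len(v) * (len(v) - 1) // 2)]
            d = demes[rng.integers(len(demes))]
            lins = by_deme[d]
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
            parent[a] = next_node
            parent[b] = next_node
            times[next_node] = t
            del lineage_deme[a], lineage_deme[b]
            lineage_deme[next_node] = d
            next_node += 1
        else:
            u = rng.random() * total_mig
            acc = 0.0
            for lin, d, nbrs, r in mig_rates:
                acc += r
                if u < acc:
                    lineage_deme[lin] = nbrs[rng.integers(len(nbrs))]
                    break
    return Genealogy(parent, times, units="generations"), tip_demes
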