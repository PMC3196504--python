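"""Nucleotide sequence evolution along genealogies.

Supports the three substitution-model families used for the study loci —
HKY (one transition/transversion ratio), TrN (separate purine and pyrimidine
transition rates), and K81 (Kimura three-substitution-type, printed with a
single kappa) — each optionally with discrete-Gamma rate variation among
sites.  Rate matrices are reversible, satisfy detailed balance with the
stationary base frequencies, and are scaled to one expected substitution per
site per unit time at stationarity, so branch lengths combine with the
per-site rate µ as expected numbers of substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .coalsim import Genealogy

__all__ = [
    "SubstitutionModel",
    "build_rate_matrix",
    "draw_site_rates",
    "discrete_gamma_rates",
    "evolve_sequences",
    "JC",
]

BASES = np.array(["A", "C", "G", "T"])
_IDX = {b: i for i, b in enumerate(BASES)}
# base order A, C, G, T; transitions are A<->G and C<->T


@dataclass(frozen=True)
class SubstitutionModel:
    """Parameters of a reversible nucleotide substitution model.

    ``kappa`` is the transition/transversion rate ratio (HKY, K81);
    ``rate_AG``/``rate_CT`` are the two transition rates of TrN relative to a
    transversion rate of 1.  ``kappa2`` optionally splits K81's two
    transversion classes (A<->C,G<->T vs A<->T,C<->G); by default both equal 1.
    ``alpha`` is the Gamma shape for among-site rate variation (None = equal
    rates), discretized into ``n_categories`` equal-probability categories.
    """

    family: str
    kappa: float | None = None
    rate_AG: float | None = None
    rate_CT: float | None = None
    kappa2: float = 1.0
    alpha: float | None = None
    n_categories: int = 4
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.family not in ("HKY", "TrN", "K81"):
            raise ValueError(f"unknown model family: {self.family!r}")
        freqs = np.asarray(self.base_freqs, float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-12 or (freqs <= 0).any():
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        if self.family in ("HKY", "K81"):
            if self.kappa is None or self.kappa <= 0:
                raise ValueError(f"{self.family} requires kappa > 0")
        if self.family == "TrN":
            if self.rate_AG is None or self.rate_CT is None:
                raise ValueError("TrN requires rate_AG and rate_CT")
            if self.rate_AG <= 0 or self.rate_CT <= 0:
                raise ValueError("TrN transition rates must be > 0")
        if self.kappa2 <= 0:
            raise ValueError("kappa2 must be > 0")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


JC = SubstitutionModel(family="HKY", kappa=1.0)


def _exchangeabilities(model: SubstitutionModel) -> np.ndarray:
    """Symmetric exchangeability matrix (A,C,G,T order)."""
    r = np.ones((4, 4))
    if model.family == "HKY":
        r[_IDX["A"], _IDX["G"]] = r[_IDX["G"], _IDX["A"]] = model.kappa
        r[_IDX["C"], _IDX["T"]] = r[_IDX["T"], _IDX["C"]] = model.kappa
    elif model.family == "TrN":
        r[_IDX["A"], _IDX["G"]] = r[_IDX["G"], _IDX["A"]] = model.rate_AG
        r[_IDX["C"], _IDX["T"]] = r[_IDX["T"], _IDX["C"]] = model.rate_CT
    else:  # K81: transitions kappa; transversion classes 1 and kappa2
        r[_IDX["A"], _IDX["G"]] = r[_IDX["G"], _IDX["A"]] = model.kappa
        r[_IDX["C"], _IDX["T"]] = r[_IDX["T"], _IDX["C"]] = model.kappa
        # A<->T and C<->G form the second transversion class
        r[_IDX["A"], _IDX["T"]] = r[_IDX["T"], _IDX["A"]] = model.kappa2
        r[_IDX["C"], _IDX["G"]] = r[_IDX["G"], _IDX["C"]] = model.kappa2
    np.fill_diagonal(r, 0.0)
    return r


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """4x4 instantaneous rate matrix Q (rows sum to zero).

    Q[i, j] = r[i, j] * pi[j] for i != j, scaled so the expected substitution
    rate at stationarity, -sum_i pi_i Q[i, i], equals 1.
    """
    pi = np.asarray(model.base_freqs, float)
    r = _exchangeabilities(model)
    q = r * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of the equal-probability discrete Gamma(alpha, 1/alpha).

    Category values are the conditional means within each probability bin
    (mean-preserving: the values average to exactly 1).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # conditional mean of Gamma(a, s) on (lo, hi] is
    # s * a * [F_{a+1}(hi) - F_{a+1}(lo)] / [F_a(hi) - F_a(lo)]; with bins of
    # equal probability 1/k the denominator is 1/k
    upper = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    means = (upper - lower) * k
    return means / means.mean()  # exact renormalization against ppf round-off


def draw_site_rates(
    alpha: float, n_sites: int, n_categories: int = 4, seed=None
) -> np.ndarray:
    """Assign each site a rate multiplier from the discrete Gamma."""
    rates = discrete_gamma_rates(alpha, n_categories)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cats = rng.integers(0, n_categories, size=n_sites)
    return rates[cats]


class _Propagator:
    """Eigendecomposition of Q for cheap transition matrices P(t) = e^{Qt}.

    Reversibility makes D^{1/2} Q D^{-1/2} symmetric, so the decomposition is
    real and numerically stable.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        self.w = w
        self.left = v / d[None, :].T  # D^{-1/2} V
        self.right = (v * d[:, None]).T  # V^T D^{1/2}

    def __call__(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def evolve_sequences(
    genealogy: Genealogy,
    model: SubstitutionModel,
    mu: float,
    n_sites: int,
    seed=None,
    labels: list[str] | None = None,
):
    """Simulate an alignment of ``n_sites`` down ``genealogy``.

    The root sequence is drawn from the stationary base frequencies; each site
    then evolves independently along each branch with transition matrix
    ``expm(Q * mu * r_site * branch_length)``, where ``r_site`` is the site's
    discrete-Gamma rate multiplier (drawn once per alignment and shared across
    branches).  ``mu`` is the per-site rate on the genealogy's time scale: per
    generation for generation-scaled trees, and 1.0 for genealogies already in
    mutational units.

    Returns a :class:`comdemog.synthio.HaplotypeAlignment` with placeholder
    metadata (one population, zeroed coordinates) that callers may replace.
    """
    from .synthio import HaplotypeAlignment, SampleMeta

    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.asarray(model.base_freqs, float)
    q = build_rate_matrix(model)
    prop = _Propagator(q, pi)

    if model.alpha is None:
        site_cat = np.zeros(n_sites, dtype=np.int64)
        cat_rates = np.ones(1)
    else:
        cat_rates = discrete_gamma_rates(model.alpha, model.n_categories)
        site_cat = rng.integers(0, model.n_categories, size=n_sites)

    n_nodes = len(genealogy.parent)
    states = np.empty((n_nodes, n_sites), dtype=np.int8)
    root = genealogy.root
    states[root] = rng.choice(4, size=n_sites, p=pi)

    # walk the tree root-ward -> tip-ward; node ids in a coalescent genealogy
    # are already ordered so that every parent has a higher id than its
    # children among internal nodes, but tips (low ids) hang anywhere, so use
    # an explicit traversal.
    ch = genealogy.children()
    stack = [root]
    order = []
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(ch[nd])

    for nd in order:
        if nd == root:
            continue
        t = genealogy.times[genealogy.parent[nd]] - genealogy.times[nd]
        parent_states = states[genealogy.parent[nd]]
        child = np.empty(n_sites, dtype=np.int8)
        for c, r in enumerate(cat_rates):
            mask = site_cat == c
            if not mask.any():
                continue
            p = prop(mu * r * t)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[nd] = child

    seqs = ["".join(BASES[states[i]]) for i in range(genealogy.n_tips)]
    names = labels if labels is not None else genealogy.labels
    meta = [
        SampleMeta(sample_id=names[i], population="pop1", region="region1",
                   latitude=0.0, longitude=0.0)
        for i in range(genealogy.n_tips)
    ]
    return HaplotypeAlignment(
        locus_name="simulated",
        sequences=seqs,
        sample_meta=meta,
        genome="mtDNA",
        provenance={"model": model.family, "mu": mu, "n_sites": n_sites},
    )
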