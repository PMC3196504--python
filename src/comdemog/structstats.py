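"""Population structure and neutrality statistics.

Hierarchical (two-level) AMOVA on haplotypic distances with Φ-statistics and
permutation significance, pairwise Φ_ST matrices, Mantel tests against
great-circle distances, the structure-gating rule used to decide whether a
dataset warrants spatial phylogeographic analysis, and the
McDonald–Kreitman test of neutral protein evolution.

AMOVA follows the Excoffier nested variance decomposition of squared
distances, with the number of pairwise nucleotide differences used directly
as the squared distance (standard haplotypic format), unequal-sample-size
coefficients, and negative variance components retained as computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .popstats import pairwise_differences
from .synthio import HaplotypeAlignment

__all__ = [
    "AmovaResult",
    "amova",
    "pairwise_fst",
    "global_fst",
    "great_circle_km",
    "mantel",
    "structure_gate",
    "mk_test",
    "MKResult",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class AmovaLevel:
    df: int
    ss: float
    variance: float
    pct_variation: float


@dataclass(frozen=True)
class AmovaResult:
    among_regions: AmovaLevel
    among_pops_within_regions: AmovaLevel
    within_pops: AmovaLevel
    f_ct: float | None
    f_sc: float | None
    f_st: float | None
    p_ct: float | None
    p_sc: float | None
    p_st: float | None
    n_permutations: int
    seed: int | None
    degenerate: bool = False


def _squared_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    from scipy.spatial.distance import squareform

    return squareform(pairwise_differences(aln))


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one group: sum of pair d² over group size."""
    if len(idx) == 0:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova_components(
    d2: np.ndarray, pops: np.ndarray, regions_of_pop: dict
) -> tuple:
    """Variance components (sigma_a, sigma_b, sigma_c) and SS/df per level."""
    n = d2.shape[0]
    pop_names = list(dict.fromkeys(pops))
    group_names = list(dict.fromkeys(regions_of_pop[p] for p in pop_names))
    n_pops = len(pop_names)
    n_groups = len(group_names)

    pop_idx = {p: np.flatnonzero(pops == p) for p in pop_names}
    group_pops = {
        g: [p for p in pop_names if regions_of_pop[p] == g] for g in group_names
    }
    group_idx = {
        g: np.concatenate([pop_idx[p] for p in group_pops[g]])
        for g in group_names
    }

    all_idx = np.arange(n)
    ss_total = _ss_within(d2, all_idx)
    ss_wp = sum(_ss_within(d2, pop_idx[p]) for p in pop_names)
    ss_wg = sum(_ss_within(d2, group_idx[g]) for g in group_names)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n - n_pops

    sizes = {p: len(pop_idx[p]) for p in pop_names}
    gsizes = {g: len(group_idx[g]) for g in group_names}

    # unequal-size coefficients of the nested design
    sum_sq_pop = sum(v**2 for v in sizes.values())
    n_prime = (
        (n - sum(sum(sizes[p] ** 2 for p in group_pops[g]) / gsizes[g]
                 for g in group_names)) / df_ap
        if df_ap > 0 else float("nan")
    )
    n_dprime = (
        (sum(sum(sizes[p] ** 2 for p in group_pops[g]) / gsizes[g]
             for g in group_names) - sum_sq_pop / n) / df_ag
        if df_ag > 0 else float("nan")
    )
    n_tprime = (
        (n - sum(v**2 for v in gsizes.values()) / n) / df_ag
        if df_ag > 0 else float("nan")
    )

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_b = (
        (ss_ap / df_ap - sigma_c) / n_prime if df_ap > 0 else 0.0
    )
    sigma_a = (
        (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
        if df_ag > 0 else 0.0
    )
    return (
        sigma_a, sigma_b, sigma_c,
        (df_ag, ss_ag), (df_ap, ss_ap), (df_wp, ss_wp),
    )


def amova(
    aln: HaplotypeAlignment,
    pops: list[str] | None = None,
    regions: dict[str, str] | None = None,
    n_perms: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA with permutation p-values.

    ``pops`` defaults to the alignment's population labels and ``regions`` to
    its population→region map.  Permutation schemes follow the statistic being
    tested: haplotypes among all populations for Φ_ST, haplotypes among
    populations within their region for Φ_SC, and whole populations among
    regions for Φ_CT.  p-values use the (extreme + 1)/(perms + 1) convention.
    """
    pops_arr = np.asarray(pops if pops is not None else aln.populations)
    if regions is None:
        regions = {}
        for m in aln.sample_meta:
            regions[m.population] = m.region
    pop_names = list(dict.fromkeys(pops_arr))
    if len(pop_names) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    d2 = _squared_distance_matrix(aln)
    n = d2.shape[0]

    sa, sb, sc, lag, lap, lwp = _amova_components(d2, pops_arr, regions)
    total = sa + sb + sc
    degenerate = False
    group_sizes = {}
    for p in pop_names:
        group_sizes.setdefault(regions[p], 0)
        group_sizes[regions[p]] += 1
    if any(v < 2 for v in group_sizes.values()):
        degenerate = True  # a region with a single population: F_CT unstable

    if total == 0:
        lvl = lambda dfss: AmovaLevel(dfss[0], dfss[1], 0.0, 0.0)
        return AmovaResult(
            among_regions=lvl(lag),
            among_pops_within_regions=lvl(lap),
            within_pops=lvl(lwp),
            f_ct=None, f_sc=None, f_st=None,
            p_ct=None, p_sc=None, p_st=None,
            n_permutations=0, seed=seed, degenerate=True,
        )

    f_ct = sa / total
    f_sc = sb / (sb + sc) if (sb + sc) != 0 else None
    f_st = (sa + sb) / total

    rng = np.random.default_rng(seed)

    def stats_for(pop_labels, region_map):
        a, b, c, *_ = _amova_components(d2, pop_labels, region_map)
        t = a + b + c
        return (
            a / t if t else 0.0,
            b / (b + c) if (b + c) else 0.0,
            (a + b) / t if t else 0.0,
        )

    ge_ct = ge_sc = ge_st = 0
    # Phi_ST: permute haplotypes among all populations
    for _ in range(n_perms):
        perm = rng.permutation(n)
        _, _, st = stats_for(pops_arr[perm], regions)
        if st >= f_st:
            ge_st += 1
    # Phi_SC: permute haplotypes among populations within each region
    region_of_sample = np.asarray([regions[p] for p in pops_arr])
    for _ in range(n_perms):
        perm_pops = pops_arr.copy()
        for g in set(region_of_sample):
            idx = np.flatnonzero(region_of_sample == g)
            perm_pops[idx] = pops_arr[idx][rng.permutation(len(idx))]
        _, sc_p, _ = stats_for(perm_pops, regions)
        if sc_p >= (f_sc if f_sc is not None else np.inf):
            ge_sc += 1
    # Phi_CT: permute whole populations among regions
    region_list = [regions[p] for p in pop_names]
    for _ in range(n_perms):
        shuffled = list(np.asarray(region_list)[rng.permutation(len(region_list))])
        rmap = dict(zip(pop_names, shuffled))
        ct_p, _, _ = stats_for(pops_arr, rmap)
        if ct_p >= f_ct:
            ge_ct += 1

    def pval(ge):
        return (ge + 1) / (n_perms + 1) if n_perms > 0 else None

    pct = lambda s: 100.0 * s / total
    return AmovaResult(
        among_regions=AmovaLevel(lag[0], lag[1], sa, pct(sa)),
        among_pops_within_regions=AmovaLevel(lap[0], lap[1], sb, pct(sb)),
        within_pops=AmovaLevel(lwp[0], lwp[1], sc, pct(sc)),
        f_ct=f_ct, f_sc=f_sc, f_st=f_st,
        p_ct=pval(ge_ct), p_sc=pval(ge_sc), p_st=pval(ge_st),
        n_permutations=n_perms, seed=seed, degenerate=degenerate,
    )


def _two_pop_phist(d2: np.ndarray, labels: np.ndarray, a: str, b: str) -> float:
    idx = np.flatnonzero((labels == a) | (labels == b))
    sub = d2[np.ix_(idx, idx)]
    sub_labels = labels[idx]
    n = len(idx)
    ss_total = sub.sum() / (2.0 * n)
    ss_wp = 0.0
    sizes = []
    for p in (a, b):
        pi = np.flatnonzero(sub_labels == p)
        sizes.append(len(pi))
        ss_wp += sub[np.ix_(pi, pi)].sum() / (2.0 * len(pi))
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = 1, n - 2
    n_c = (n - sum(s**2 for s in sizes) / n) / df_ap
    sigma_w = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    tot = sigma_a + sigma_w
    return sigma_a / tot if tot != 0 else 0.0


def pairwise_fst(
    aln: HaplotypeAlignment, pops: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Φ_ST matrix from two-population AMOVAs.

    Populations of size 1 are excluded with a warning.  Values may be slightly
    negative; the diagonal is exactly 0.  Returns (matrix, population order).
    """
    labels = np.asarray(pops if pops is not None else aln.populations)
    names = list(dict.fromkeys(labels))
    keep = []
    for p in names:
        if (labels == p).sum() >= 2:
            keep.append(p)
        else:
            logger.warning("excluding population %r with a single sample", p)
    if len(keep) < 2:
        raise ValueError("need at least 2 populations with n >= 2")
    d2 = _squared_distance_matrix(aln)
    k = len(keep)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = _two_pop_phist(d2, labels, keep[i], keep[j])
            out[i, j] = out[j, i] = v
    return out, keep


def global_fst(
    aln: HaplotypeAlignment, method: str = "amova", seed: int | None = None
) -> float:
    """Global Φ_ST: AMOVA-based (default) or mean of pairwise values.

    Both summaries are exposed because either reading is defensible for a
    printed "global F_ST"; the AMOVA Φ_ST is what the gating rule uses.
    """
    if method == "amova":
        pops = aln.populations
        regions = {p: "all" for p in pops}
        res = amova(aln, regions=regions, n_perms=0, seed=seed)
        if res.f_st is None:
            return 0.0
        return res.f_st
    if method == "mean_pairwise":
        m, _ = pairwise_fst(aln)
        iu = np.triu_indices(m.shape[0], k=1)
        return float(m[iu].mean())
    raise ValueError(f"unknown method: {method!r}")


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance, Earth radius 6371.0 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def mantel(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perms: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r is computed over upper-triangle entries; significance by jointly
    permuting rows and columns of the second matrix, one-tailed for r >=
    observed with ties counted as extreme.  The p-value uses the
    (extreme + 1)/(n_perms + 1) convention so it is never exactly zero.
    Returns (r, r², p).
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 populations")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perms):
        perm = rng.permutation(a.shape[0])
        yb = b[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, yb)[0, 1] >= r_obs:
            ge += 1
    p = (ge + 1) / (n_perms + 1)
    return r_obs, r_obs**2, p


def structure_gate(global_fst_value: float, mantel_p: float) -> bool:
    """Gate for spatially explicit analysis: strong, geographically
    structured differentiation.

    True iff global F_ST > 0.2 (great divergence) and the Mantel correlation
    of F_ST with geographic distance is significant at 0.05.
    """
    return global_fst_value > 0.2 and mantel_p < 0.05


# ---------------------------------------------------------------------------
# McDonald–Kreitman test

@dataclass(frozen=True)
class MKResult:
    fixed_nonsyn: int
    fixed_syn: int
    poly_nonsyn: int
    poly_syn: int
    odds_ratio: float | None
    p: float | None
    n_excluded_codons: int


def _translate(codon: str, table) -> str | None:
    if any(c not in "ACGT" for c in codon):
        return None
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def mk_test(
    ingroup_aln: HaplotypeAlignment,
    outgroup_seq: str,
    genetic_code: int = 1,
) -> MKResult:
    """McDonald–Kreitman 2×2 test of neutrality on a coding alignment.

    Codons are classified as polymorphic (variable within the ingroup) or
    fixed (invariant within the ingroup but different from the outgroup), and
    as synonymous or nonsynonymous.  Codons needing more than one nucleotide
    change, or both polymorphic and fixed, are excluded and counted.
    Significance is Fisher's exact two-tailed test on the resulting table;
    degenerate tables (an empty margin) are flagged with ``p = None``.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    L = ingroup_aln.length
    if L % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    if len(outgroup_seq) != L:
        raise ValueError("outgroup length must match the alignment")
    out_seq = outgroup_seq.upper()

    fixed = {"syn": 0, "nonsyn": 0}
    poly = {"syn": 0, "nonsyn": 0}
    excluded = 0

    # no internal stop codons allowed in any ingroup sequence
    for s in ingroup_aln.sequences:
        for j in range(0, L - 3, 3):
            aa = _translate(s[j: j + 3], table)
            if aa == "*":
                raise ValueError(f"internal stop codon at position {j}")

    for j in range(0, L, 3):
        in_codons = {s[j: j + 3] for s in ingroup_aln.sequences}
        in_codons = {c for c in in_codons if all(x in "ACGT" for x in c)}
        out_codon = out_seq[j: j + 3]
        if not in_codons:
            continue
        if len(in_codons) > 1:
            # polymorphic codon: require exactly two states one step apart
            if len(in_codons) == 2:
                c1, c2 = sorted(in_codons)
                ndiff = sum(a != b for a, b in zip(c1, c2))
                both_classes = (
                    all(x in "ACGT" for x in out_codon)
                    and out_codon not in in_codons
                )
                if ndiff != 1 or both_classes:
                    # multi-step polymorphism, or a codon that is both
                    # polymorphic and fixed vs the outgroup: excluded
                    excluded += 1
                else:
                    aa1, aa2 = _translate(c1, table), _translate(c2, table)
                    if aa1 is None or aa2 is None:
                        excluded += 1
                    else:
                        poly["syn" if aa1 == aa2 else "nonsyn"] += 1
            else:
                excluded += 1
            continue
        (codon,) = in_codons
        if all(x in "ACGT" for x in out_codon) and codon != out_codon:
            ndiff = sum(a != b for a, b in zip(codon, out_codon))
            if ndiff > 1:
                excluded += 1
                continue
            aa_in = _translate(codon, table)
            aa_out = _translate(out_codon, table)
            if aa_in is None or aa_out is None or aa_out == "*":
                excluded += 1
                continue
            fixed["syn" if aa_in == aa_out else "nonsyn"] += 1

    tbl = np.array(
        [[fixed["nonsyn"], fixed["syn"]], [poly["nonsyn"], poly["syn"]]]
    )
    if tbl[0].sum() == 0 or tbl[1].sum() == 0:
        return MKResult(
            fixed_nonsyn=int(tbl[0, 0]), fixed_syn=int(tbl[0, 1]),
            poly_nonsyn=int(tbl[1, 0]), poly_syn=int(tbl[1, 1]),
            odds_ratio=None, p=None, n_excluded_codons=excluded,
        )
    odds, p = sstats.fisher_exact(tbl, alternative="two-sided")
    return MKResult(
        fixed_nonsyn=int(tbl[0, 0]), fixed_syn=int(tbl[0, 1]),
        poly_nonsyn=int(tbl[1, 0]), poly_syn=int(tbl[1, 1]),
        odds_ratio=float(odds) if math.isfinite(odds) else None,
        p=float(p), n_excluded_codons=excluded,
    )
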