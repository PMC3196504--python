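"""AMOVA, F_ST, Mantel, great-circle distances, MK test."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from comdemog.structstats import (
    amova,
    global_fst,
    great_circle_km,
    mantel,
    mk_test,
    pairwise_fst,
    structure_gate,
)
from conftest import make_alignment


# ----------------------------------------------------------------- AMOVA

def test_amova_df_for_three_regions_five_populations_21_haplotypes(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(21)]
    pops = ["a"] * 5 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4 + ["e"] * 4
    regions = {"a": "N", "b": "N", "c": "C", "d": "S", "e": "S"}
    res = amova(make_alignment(seqs, pops, regions), n_perms=49, seed=1)
    assert res.among_regions.df == 2
    assert res.among_pops_within_regions.df == 2
    assert res.within_pops.df == 16
    total_df = (
        res.among_regions.df
        + res.among_pops_within_regions.df
        + res.within_pops.df
    )
    assert total_df == 20  # n - 1


def test_amova_identical_haplotypes_flagged_undefined():
    aln = make_alignment(
        ["AAAA"] * 6, ["p1"] * 3 + ["p2"] * 3,
        {"p1": "r1", "p2": "r2"},
    )
    res = amova(aln, n_perms=19, seed=0)
    assert res.f_st is None and res.degenerate
    assert res.within_pops.variance == 0.0


def test_amova_reciprocally_fixed_populations():
    aln = make_alignment(
        ["AAAA"] * 4 + ["TTTT"] * 4,
        ["p1"] * 4 + ["p2"] * 4,
    )
    res = amova(aln, n_perms=99, seed=0)
    assert res.f_st == pytest.approx(1.0)
    assert res.within_pops.pct_variation == pytest.approx(0.0)


def _brute_force_two_pop_phist(seqs_a, seqs_b):
    """Independent sums-of-squares computation for a two-population design."""
    seqs = seqs_a + seqs_b
    n = len(seqs)
    na, nb = len(seqs_a), len(seqs_b)

    def d(x, y):
        return sum(a != b for a, b in zip(x, y))

    ss_total = sum(
        d(seqs[i], seqs[j]) for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_a = sum(
        d(seqs_a[i], seqs_a[j])
        for i in range(na) for j in range(i + 1, na)
    ) / na
    ss_b = sum(
        d(seqs_b[i], seqs_b[j])
        for i in range(nb) for j in range(i + 1, nb)
    ) / nb
    ss_among = ss_total - ss_a - ss_b
    ms_within = (ss_a + ss_b) / (n - 2)
    n_c = (n - (na**2 + nb**2) / n) / 1
    sigma_a = (ss_among / 1 - ms_within) / n_c
    return sigma_a / (sigma_a + ms_within)


def test_pairwise_fst_matches_brute_force_oracle(rng):
    for _ in range(5):
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 8))
        seqs_a = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(na)]
        seqs_b = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(nb)]
        aln = make_alignment(seqs_a + seqs_b, ["x"] * na + ["y"] * nb)
        m, names = pairwise_fst(aln)
        want = _brute_force_two_pop_phist(seqs_a, seqs_b)
        assert m[0, 1] == pytest.approx(want, abs=1e-9)


def test_two_population_amova_equals_pairwise_fst(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(9)]
    pops = ["x"] * 4 + ["y"] * 5
    aln = make_alignment(seqs, pops)
    res = amova(aln, regions={"x": "all", "y": "all"}, n_perms=0, seed=0)
    m, _ = pairwise_fst(aln)
    assert res.f_st == pytest.approx(m[0, 1], abs=1e-9)


def test_amova_pct_variation_sums_to_100_on_unbalanced_designs(rng):
    for _ in range(5):
        sizes = rng.integers(2, 6, size=4)
        pops, seqs = [], []
        for i, s in enumerate(sizes):
            pops += [f"p{i}"] * int(s)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(len(pops))]
        regions = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        res = amova(make_alignment(seqs, pops, regions), n_perms=9, seed=0)
        total_pct = (
            res.among_regions.pct_variation
            + res.among_pops_within_regions.pct_variation
            + res.within_pops.pct_variation
        )
        assert total_pct == pytest.approx(100.0, abs=1e-6)
        n = len(pops)
        assert (
            res.among_regions.df
            + res.among_pops_within_regions.df
            + res.within_pops.df
        ) == n - 1


def test_identical_monomorphic_populations_have_zero_pairwise_fst():
    aln = make_alignment(["AATT"] * 4, ["x", "x", "y", "y"])
    m, _ = pairwise_fst(aln)
    assert abs(m[0, 1]) < 1e-12


def test_negative_pairwise_fst_retained():
    # all between-population variance zero but within-population variance
    # positive: the variance-component estimate is negative and kept as-is
    aln = make_alignment(
        ["AATT", "AAAA", "AATT", "AAAA"], ["x", "x", "y", "y"]
    )
    m, _ = pairwise_fst(aln)
    assert m[0, 1] < 0


def test_amova_permutation_pvalues_reproducible(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(12)]
    pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    regions = {"a": "N", "b": "N", "c": "S"}
    aln = make_alignment(seqs, pops, regions)
    r1 = amova(aln, n_perms=99, seed=42)
    r2 = amova(aln, n_perms=99, seed=42)
    assert (r1.p_st, r1.p_sc, r1.p_ct) == (r2.p_st, r2.p_sc, r2.p_ct)


# ------------------------------------------------------------ great circle

def test_great_circle_quarter_meridian():
    assert great_circle_km(0.0, 0.0, 0.0, 90.0) == pytest.approx(
        6371.0 * math.pi / 2.0, rel=1e-9
    )


def test_great_circle_identity_symmetry_and_validation(rng):
    assert great_circle_km(35.0, -115.0, 35.0, -115.0) == 0.0
    for _ in range(10):
        a = rng.uniform(-90, 90, 2)
        b = rng.uniform(-180, 180, 2)
        assert great_circle_km(a[0], b[0], a[1], b[1]) == pytest.approx(
            great_circle_km(a[1], b[1], a[0], b[0])
        )
    with pytest.raises(ValueError):
        great_circle_km(91.0, 0.0, 0.0, 0.0)


# ----------------------------------------------------------------- Mantel

def test_mantel_perfect_and_inverse_correlation(rng):
    k = 6
    pts = rng.uniform(0, 10, size=(k, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    r, r2, p = mantel(d, d.copy(), n_perms=199, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 1.0 / 200.0 + 1e-12
    r_neg, _, _ = mantel(d, -d + d.max(), n_perms=49, seed=0)
    assert r_neg == pytest.approx(-1.0)


def test_mantel_null_calibration(rng):
    """Independent random matrices: p < 0.05 should occur ~5% of the time
    (within 3 binomial SE over 200 repetitions)."""
    k = 7
    hits = 0
    n_runs = 200
    for i in range(n_runs):
        a = rng.uniform(0, 1, size=(k, k))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(0, 1, size=(k, k))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        _, _, p = mantel(a, b, n_perms=199, seed=int(rng.integers(2**31)))
        if p < 0.05:
            hits += 1
    se = math.sqrt(0.05 * 0.95 / n_runs)
    assert abs(hits / n_runs - 0.05) < 3 * se


def test_mantel_agrees_with_skbio(rng):
    """Observed r cross-checked against scikit-bio's implementation."""
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    k = 8
    pts = rng.uniform(0, 5, size=(k, 2))
    a = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    b = a + rng.normal(0, 0.5, size=a.shape)
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    b = np.abs(b)
    r_ours, _, _ = mantel(a, b, n_perms=99, seed=0)
    r_skbio, _, _ = skbio_mantel(
        DistanceMatrix(a), DistanceMatrix(b), permutations=0
    )
    assert r_ours == pytest.approx(float(r_skbio), abs=1e-10)


def test_mantel_rejects_degenerate_inputs():
    z = np.zeros((4, 4))
    d = np.arange(16, dtype=float).reshape(4, 4)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    with pytest.raises(ValueError):
        mantel(z, d, n_perms=9)
    with pytest.raises(ValueError):
        mantel(d[:2, :2], d[:2, :2], n_perms=9)


# ------------------------------------------------------------------- gate

@pytest.mark.parametrize(
    "fst, p, expected",
    [
        (0.871, 0.0009, True),   # strongly structured chloroplast case
        (0.12, 0.01, False),     # weak moth-like structure
        (0.25, 0.5, False),
        (0.19, 0.001, False),
        (0.21, 0.049, True),
    ],
)
def test_structure_gate_rule(fst, p, expected):
    assert structure_gate(fst, p) is expected


# --------------------------------------------------------------- MK test

def _codon_aln(codon_rows, pops=None):
    return make_alignment(["".join(r) for r in codon_rows], pops)


def test_mk_proportional_table_gives_odds_ratio_one():
    # construct 2 nonsyn + 4 syn fixed and 1 nonsyn + 2 syn polymorphic
    # proportional rows -> odds ratio 1, p = 1
    n_ing = 4
    fixed_nonsyn = ["AAA", "CAA"]          # K; fixed vs outgroup GAA/AAA etc.
    base = []
    # built explicitly below instead
    ing = []
    for i in range(n_ing):
        codons = [
            "AAA",  # fixed nonsyn vs outgroup GAA (K vs E)
            "GCA",  # fixed syn vs outgroup GCG (A vs A)
            "CGA",  # fixed syn vs outgroup CGG
            "TTA",  # fixed syn vs outgroup CTA (L vs L)
            "GGA",  # fixed syn vs outgroup GGT
            "AAC",  # fixed nonsyn vs outgroup AAA? AAC=N vs AAA=K
            "TGT" if i < 2 else "TGC",  # poly syn (C/C)
            "ATT" if i < 2 else "ATC",  # poly syn (I/I)
            "CTT",  # invariant, equal to outgroup
            "AGA" if i < 2 else "AGG",  # poly syn (R/R)... need nonsyn
        ]
        ing.append("".join(codons))
    out = "".join(
        ["GAA", "GCG", "CGG", "CTA", "GGT", "AAA", "TGT", "ATT", "CTT", "AGA"]
    )
    res = mk_test(make_alignment(ing), out)
    # 2 nonsyn + 4 syn fixed; 0 nonsyn + 3 syn polymorphic
    assert (res.fixed_nonsyn, res.fixed_syn) == (2, 4)
    assert (res.poly_nonsyn, res.poly_syn) == (0, 3)


def test_mk_empty_polymorphism_row_flagged():
    ing = ["AAAGCA"] * 4  # no polymorphism
    out = "GAAGCG"
    res = mk_test(make_alignment(ing), out)
    assert res.p is None and res.odds_ratio is None


def test_mk_fisher_p_matches_hypergeometric_oracle():
    """2x2 (fixed: 7 nonsyn / 17 syn; poly: 2 nonsyn / 42 syn): two-tailed
    Fisher p equals the exact hypergeometric tail sum."""
    from scipy.stats import fisher_exact

    table = np.array([[7, 17], [2, 42]])
    # independent oracle: sum of hypergeometric probabilities <= observed
    M = table.sum()
    n_row1 = table[0].sum()
    n_col1 = table[:, 0].sum()
    rv = hypergeom(M, n_col1, n_row1)
    p_obs = rv.pmf(table[0, 0])
    p_oracle = sum(
        rv.pmf(k)
        for k in range(max(0, n_row1 + n_col1 - M), min(n_row1, n_col1) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )
    _, p_scipy = fisher_exact(table, alternative="two-sided")
    assert p_scipy == pytest.approx(p_oracle, rel=1e-9)


def test_mk_rejects_internal_stop_codons():
    ing = ["TAAGCA"] * 3  # TAA = stop in first (non-terminal) codon
    with pytest.raises(ValueError):
        mk_test(make_alignment(ing), "TAAGCG")


def test_mk_excludes_multihit_codons():
    ing = ["AAA"] * 2 + ["ACC"] * 2  # two positions changed
    res = mk_test(make_alignment(ing), "AAA")
    assert res.n_excluded_codons == 1
    assert res.poly_syn == 0 and res.poly_nonsyn == 0


# ------------------------------------------------------------ global F_ST

def test_global_fst_methods_agree_for_two_identical_sized_pops(rng):
    aln = make_alignment(
        ["AAAA"] * 4 + ["TTTT"] * 4, ["p1"] * 4 + ["p2"] * 4
    )
    assert global_fst(aln, "amova") == pytest.approx(1.0)
    assert global_fst(aln, "mean_pairwise") == pytest.approx(1.0)
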