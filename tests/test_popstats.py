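"""Summary statistics: hand-enumerated examples, exact oracles, recovery."""

import math
from fractions import Fraction

import numpy as np
import pytest

from comdemog import coalsim, seqsim
from comdemog.popstats import (
    UndefinedStatisticError,
    expected_mismatch,
    fu_fs,
    mismatch_histogram,
    mismatch_tau,
    pairwise_differences,
    summary_stats,
    tajimas_d,
    tau_to_years,
)
from conftest import make_alignment, random_alignment


# --------------------------------------------------------------- summaries

def test_hand_enumerated_three_sequence_alignment(toy_alignment):
    ss = summary_stats(toy_alignment)
    assert ss.S == 2
    assert ss.k_hap == 3
    assert ss.pi == pytest.approx(4.0 / 3.0)  # pairs: 1 + 2 + 1 over 3


def test_monomorphic_alignment_flags_undefined_statistics():
    aln = make_alignment(["AAAA"] * 4)
    ss = summary_stats(aln)
    assert (ss.S, ss.pi, ss.k_hap) == (0, 0.0, 1)
    assert ss.fs is None and ss.tajima_d is None
    with pytest.raises(UndefinedStatisticError):
        fu_fs(aln)
    with pytest.raises(UndefinedStatisticError):
        tajimas_d(aln)


def test_duplicate_sequence_leaves_segregating_sites_unchanged(toy_alignment):
    ss = summary_stats(toy_alignment)
    dup = make_alignment(["AAA", "AAT", "ATT", "ATT"])
    assert summary_stats(dup).S == ss.S


def test_statistics_invariant_to_sequence_order(rng):
    aln = random_alignment(rng, 8, 40)
    perm = rng.permutation(8)
    shuffled = make_alignment([aln.sequences[i] for i in perm])
    a, b = summary_stats(aln), summary_stats(shuffled)
    assert a.S == b.S
    assert a.pi == pytest.approx(b.pi)
    assert a.k_hap == b.k_hap


def test_gapped_sites_excluded_per_pair():
    # pair (0,1): site 2 has a gap in seq0 -> only sites 0,1,3 compared
    aln = make_alignment(["AA-A", "AATA", "AATT"])
    d = pairwise_differences(aln)
    assert list(d) == [0, 1, 1]  # (0,1)=0, (0,2)=1, (1,2)=1


# --------------------------------------------------------------- Fu's Fs

from conftest import exact_fs_oracle as _exact_fs  # noqa: E402


def test_fs_matches_exact_rational_oracle_small_n():
    # n=4, theta=1.5, k=3 (spec worked example; |s(4,k)| = 6, 11, 6, 1)
    from comdemog.popstats import _fs_from_theta_k

    expected = _exact_fs(4, Fraction(3, 2), 3)
    assert _fs_from_theta_k(4, 1.5, 3) == pytest.approx(expected, abs=1e-9)


def test_fs_matches_oracle_over_random_cases(rng):
    """Exact Ewens-tail agreement to 1e-6 across 100 random (n, theta, k)."""
    from comdemog.popstats import _fs_from_theta_k

    for _ in range(100):
        n = int(rng.integers(3, 13))
        k = int(rng.integers(2, n + 1))
        num = int(rng.integers(1, 60))
        den = int(rng.integers(1, 12))
        theta = Fraction(num, den)
        got = _fs_from_theta_k(n, float(theta), k)
        want = _exact_fs(n, theta, k)
        if math.isinf(want) or math.isinf(got):
            assert got == want
        else:
            assert got == pytest.approx(want, abs=1e-6)


def test_fs_single_haplotype_guard_returns_positive_infinity():
    from comdemog.popstats import _fs_from_theta_k

    with pytest.warns(RuntimeWarning):
        assert _fs_from_theta_k(4, 2.0, 1) == math.inf


def test_fs_negative_for_star_like_data():
    # 20 sequences, every one a distinct singleton haplotype (S = 19)
    n, L = 20, 19
    seqs = []
    for i in range(n):
        s = ["A"] * L
        if i < L:
            s[i] = "T"
        seqs.append("".join(s))
    assert fu_fs(make_alignment(seqs)) < 0


def test_fs_exact_for_large_sample_sizes():
    """n = 80 must be computed without overflow (log-space Stirling)."""
    from comdemog.popstats import _fs_from_theta_k

    v = _fs_from_theta_k(80, 10.0, 60)
    assert math.isfinite(v)


# --------------------------------------------------------------- Tajima's D

def test_tajimas_d_undefined_for_three_sequences(toy_alignment):
    # both Tajima variance coefficients vanish at n = 3
    with pytest.raises(UndefinedStatisticError):
        tajimas_d(toy_alignment)


def test_tajimas_d_matches_textbook_coefficient_evaluation():
    # independent spreadsheet-style evaluation for n=4
    aln = make_alignment(["AAA", "AAT", "ATT", "AAA"])
    n, S = 4, 2
    pi = float(pairwise_differences(aln).mean())
    a1 = 1 + 1 / 2 + 1 / 3
    a2 = 1 + 1 / 4 + 1 / 9
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    assert tajimas_d(aln) == pytest.approx(expected)


def test_tajimas_d_sign_responds_to_frequency_spectrum():
    # singleton excess (negative D) vs intermediate-frequency excess (positive)
    n, L = 10, 30
    singletons = []
    for i in range(n):
        s = ["A"] * L
        if i < 8:
            s[i] = "T"
        singletons.append("".join(s))
    d_single = tajimas_d(make_alignment(singletons))

    balanced = []
    for i in range(n):
        s = ["A"] * L
        if i < n // 2:
            for j in range(8):
                s[j] = "T"
        balanced.append("".join(s))
    d_balanced = tajimas_d(make_alignment(balanced))
    assert d_single < 0 < d_balanced


# --------------------------------------------------------------- mismatch

def test_monomorphic_mismatch_gives_zero_tau():
    fit = mismatch_tau(make_alignment(["ACGT"] * 5))
    assert fit.tau_hat == 0.0 and fit.ssd == 0.0


def test_expected_mismatch_is_a_probability_distribution():
    f = expected_mismatch(3.0, 1.0, 1000.0, 200)
    assert np.all(f >= 0)
    assert f.sum() == pytest.approx(1.0, abs=1e-6)


def _grid_oracle(aln, tau_max, theta_max, n=120):
    """Brute-force fine-grid SSD minimizer (independent of the fit path)."""
    hist = mismatch_histogram(aln)
    obs = hist / hist.sum()
    best, best_ssd = (0.0, 0.0), np.inf
    for tau in np.linspace(0, tau_max, n):
        for th in np.linspace(0, theta_max, n // 2):
            f = expected_mismatch(tau, th, 1000.0 * max(th, 1.0), len(obs) - 1)
            ssd = ((obs - f) ** 2).sum()
            if ssd < best_ssd:
                best, best_ssd = (tau, th), ssd
    return best, best_ssd


def test_mismatch_fit_consistent_with_grid_search_oracle(rng):
    """On strongly expanded data the fit must do at least as well as a
    brute-force grid, and land near its tau."""
    scen = coalsim.DemographicScenario(
        ne_present=50_000.0, ratio_ancestral=0.01, t_change_years=10_000.0
    )
    gen = coalsim.simulate_genealogy(20, scen, seed=rng)
    aln = seqsim.evolve_sequences(gen, seqsim.JC, 1e-8, 1000, seed=rng)
    fit = mismatch_tau(aln)
    (tau_o, _), ssd_o = _grid_oracle(aln, 2 * max(fit.tau_hat, 1.0), 5.0)
    assert fit.ssd <= ssd_o + 1e-9
    assert fit.tau_hat == pytest.approx(tau_o, abs=max(0.25 * tau_o, 0.5))


def _near_star_genealogy(n: int, depth: float) -> coalsim.Genealogy:
    """Caterpillar with all coalescences within n generations of ``depth`` —
    effectively a star for depth >> n."""
    times = np.concatenate([np.zeros(n), depth - np.arange(n - 1, 0, -1.0)])
    par = np.empty(2 * n - 1, dtype=np.int64)
    for i in range(n):
        par[i] = n + max(i - 1, 0)
    for j in range(n, 2 * n - 2):
        par[j] = j + 1
    par[2 * n - 2] = -1
    return coalsim.Genealogy(par, times)


def test_mismatch_tau_recovers_known_expansion_time(rng):
    """Star genealogy of depth t: tau_true = 2 mu_locus t; the median
    estimate over replicates must land within 25%."""
    n, L, mu, depth = 12, 800, 2e-7, 40_000.0
    tau_true = 2.0 * mu * L * depth  # expected pairwise differences per locus
    gen = _near_star_genealogy(n, depth)
    taus = []
    for _ in range(60):
        aln = seqsim.evolve_sequences(gen, seqsim.JC, mu, L, seed=rng)
        taus.append(mismatch_tau(aln).tau_hat)
    assert np.median(taus) == pytest.approx(tau_true, rel=0.25)


# --------------------------------------------------------------- tau->years

@pytest.mark.parametrize(
    "tau, mu, expected, exact_3sf",
    [
        (0.462, 3.01e-5, 1.53e4, True),
        # the printed 4.58e5 is a hair below its own inputs' quotient
        # (0.862/1.88e-6 = 4.585e5), so only relative agreement is asserted
        (0.862, 1.88e-6, 4.58e5, False),
        (1.85, 8.82e-6, 2.10e5, True),
    ],
)
def test_tau_to_years_table_convention(tau, mu, expected, exact_3sf):
    got = tau_to_years(tau, mu, "paper_table")
    assert got == pytest.approx(expected, rel=5e-3)
    if exact_3sf:
        assert float(f"{got:.3g}") == pytest.approx(expected)


def test_tau_conventions_differ_by_exactly_two(rng):
    for _ in range(20):
        tau = float(rng.uniform(0, 5))
        mu = float(10 ** rng.uniform(-7, -4))
        assert tau_to_years(tau, mu, "paper_table") == pytest.approx(
            2 * tau_to_years(tau, mu, "classical")
        )


def test_tau_to_years_edge_cases():
    assert tau_to_years(0.0, 1e-5) == 0.0
    with pytest.raises(ValueError):
        tau_to_years(-1.0, 1e-5)
    with pytest.raises(ValueError):
        tau_to_years(1.0, 0.0)


def test_fs_and_d_centered_under_constant_size(rng):
    """Neutral constant-size simulation: Fs median near 0, D median near 0."""
    scen = coalsim.DemographicScenario(ne_present=1e6)
    model = seqsim.SubstitutionModel("HKY", kappa=2.0)
    fs_vals, d_vals = [], []
    reps = 0
    while len(fs_vals) < 200:
        gen = coalsim.simulate_genealogy(25, scen, seed=rng)
        aln = seqsim.evolve_sequences(gen, model, 2e-9, 1000, seed=rng)
        ss = summary_stats(aln)
        reps += 1
        if ss.fs is not None and math.isfinite(ss.fs):
            fs_vals.append(ss.fs)
            d_vals.append(ss.tajima_d)
    assert abs(np.median(fs_vals)) < 1.0
    assert abs(np.median(d_vals)) < 0.3
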