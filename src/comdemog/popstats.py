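"""Per-locus summary statistics for detecting and dating expansions.

Implements the segregating-sites/diversity summaries, Fu's Fs (via the Ewens
sampling distribution with exact Stirling numbers), Tajima's D, the
Rogers–Harpending mismatch-distribution fit for the expansion parameter τ,
and the τ → years conversion in both the convention the source tables print
(t = τ/µ) and the classical one (t = τ/2µ).

Gap/N handling: sites with a gap or N in either member of a pair are skipped
for that pair only (complete-case per site pair); distinct haplotypes are
counted on full strings including ambiguity characters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .synthio import HaplotypeAlignment

__all__ = [
    "SummaryStats",
    "MismatchFit",
    "summary_stats",
    "fu_fs",
    "tajimas_d",
    "mismatch_tau",
    "tau_to_years",
    "pairwise_differences",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """Statistic undefined for this input (e.g. no segregating sites)."""


@dataclass(frozen=True)
class SummaryStats:
    n: int
    S: int
    k_hap: int
    pi: float  # mean pairwise differences, per locus
    theta_w: float  # Watterson's estimate, per locus
    fs: float | None
    tajima_d: float | None


@dataclass(frozen=True)
class MismatchFit:
    mismatch: np.ndarray  # counts of pairwise differences 0..max
    tau_hat: float
    theta0_hat: float
    theta1_hat: float
    ssd: float


_MISSING = (b"-", b"N")


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    ok = np.ones(mat.shape, dtype=bool)
    for ch in _MISSING:
        ok &= mat != ch
    return ok


def pairwise_differences(aln: HaplotypeAlignment) -> np.ndarray:
    """Number of nucleotide differences for every pair (condensed order).

    Sites where either sequence has a gap or N are excluded for that pair.
    """
    mat = aln.as_matrix()
    ok = _valid_mask(mat)
    n = aln.n
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        both = ok[i] & ok[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        cnt = diff.sum(axis=1)
        out[k: k + len(cnt)] = cnt
        k += len(cnt)
    return out


def _segregating_sites(mat: np.ndarray) -> int:
    ok = _valid_mask(mat)
    s = 0
    for j in range(mat.shape[1]):
        col = mat[ok[:, j], j]
        if col.size >= 2 and len(np.unique(col)) >= 2:
            s += 1
    return s


def summary_stats(aln: HaplotypeAlignment) -> SummaryStats:
    """Standard per-locus summaries: n, S, haplotype count, π, θ_W, Fs, D.

    Fs and Tajima's D are ``None`` (flagged undefined) when S = 0.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.as_matrix()
    S = _segregating_sites(mat)
    diffs = pairwise_differences(aln)
    pi = float(diffs.mean())
    k_hap = len(set(aln.sequences))
    a1 = sum(1.0 / i for i in range(1, aln.n))
    theta_w = S / a1
    fs = d = None
    if S > 0:
        fs = fu_fs(aln)
        try:
            d = tajimas_d(aln)
        except UndefinedStatisticError:
            d = None
    return SummaryStats(
        n=aln.n, S=S, k_hap=k_hap, pi=pi, theta_w=theta_w, fs=fs, tajima_d=d
    )


@lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Exact integer recurrence |s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)|,
    converted to logs at the end (Python bigints keep it exact).
    """
    row = [1]  # n = 0
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    out = np.full(n + 1, -np.inf)
    for k, v in enumerate(row):
        if v > 0:
            out[k] = _log_bigint(v)
    return out


def _log_bigint(v: int) -> float:
    if v < 10**300:
        return math.log(v)
    shift = v.bit_length() - 900
    return math.log(v >> shift) + shift * math.log(2.0)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) under the Ewens sampling distribution, k=0..n."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling_first(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    return ls + k * math.log(theta) - log_rising


def fu_fs(aln: HaplotypeAlignment) -> float:
    """Fu's Fs: log-odds of observing at least the sampled haplotype count.

    With θ̂ = π (mean pairwise differences), S' = P(K >= k_obs | θ̂, n) under
    the Ewens sampling distribution and Fs = ln(S' / (1 - S')).  Strongly
    negative values indicate an excess of haplotypes, the signature of
    population expansion.  Returns ±inf (with a warning) when S' saturates
    numerically; raises for monomorphic data.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.as_matrix()
    if _segregating_sites(mat) == 0:
        raise UndefinedStatisticError("Fs undefined when S = 0")
    theta = float(pairwise_differences(aln).mean())
    k_obs = len(set(aln.sequences))
    return _fs_from_theta_k(aln.n, theta, k_obs)


def _fs_from_theta_k(n: int, theta: float, k_obs: int) -> float:
    if k_obs <= 1:
        warnings.warn("k_hap <= 1: S' = 1, Fs = +inf", RuntimeWarning)
        return math.inf
    logp = ewens_log_pmf(n, theta)
    # log S' = logsumexp over k >= k_obs
    tail = logp[k_obs:]
    m = tail.max()
    log_sp = m + math.log(np.exp(tail - m).sum())
    if log_sp >= 0.0:
        log_sp = -0.0
    sp = math.exp(log_sp)
    if sp < 1e-300:
        warnings.warn("S' underflow: Fs = -inf", RuntimeWarning)
        return -math.inf
    if sp > 1.0 - 1e-15:
        warnings.warn("S' saturated at 1: Fs = +inf", RuntimeWarning)
        return math.inf
    # ln(S'/(1-S')) computed from log S' for numerical range
    return log_sp - math.log1p(-sp)


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D with the canonical coefficient formulas."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.as_matrix()
    S = _segregating_sites(mat)
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined when S = 0")
    n = aln.n
    pi = float(pairwise_differences(aln).mean())
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        # n = 3 makes both coefficients vanish: D is undefined there
        raise UndefinedStatisticError("degenerate variance: D undefined")
    return (pi - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Mismatch distribution

def expected_mismatch(
    tau: float, theta0: float, theta1: float, max_diff: int
) -> np.ndarray:
    """Sudden-expansion expected mismatch frequencies F_0..F_max.

    Model of a pair's coalescence time: exponential hazard 1/θ1 back to the
    expansion at τ (mutational pair-time units), then hazard 1/θ0; differences
    given coalescence at t are Poisson(t).  Closed form:

        F_j = Ĝ_j(θ1) + e^{-τ(θ1+1)/θ1} Σ_{i<=j} (τ^i/i!) [Ĝ_{j-i}(θ0) - Ĝ_{j-i}(θ1)]

    with Ĝ the equilibrium geometric θ^j / (1+θ)^{j+1}.
    """
    j = np.arange(max_diff + 1)

    def geom(th: float) -> np.ndarray:
        if th == 0:
            out = np.zeros(max_diff + 1)
            out[0] = 1.0
            return out
        return np.exp(j * math.log(th) - (j + 1) * math.log1p(th))

    g1 = geom(theta1)
    g0 = geom(theta0)
    if tau == 0:
        return g0
    log_pois = j * math.log(tau) - gammaln(j + 1)
    pois = np.exp(log_pois)
    delta = g0 - g1
    conv = np.array(
        [np.dot(pois[: jj + 1], delta[jj::-1]) for jj in j]
    )
    scale = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else math.exp(-tau)
    f = g1 + scale * conv
    return np.clip(f, 0.0, None)


def mismatch_histogram(aln: HaplotypeAlignment) -> np.ndarray:
    diffs = pairwise_differences(aln).astype(int)
    return np.bincount(diffs)


def _mismatch_ssd(params, obs_freq: np.ndarray) -> float:
    tau, theta0 = params
    if tau < 0 or theta0 < 0:
        return np.inf
    theta1 = 1000.0 * max(theta0, 1.0)
    exp_f = expected_mismatch(tau, theta0, theta1, len(obs_freq) - 1)
    return float(((obs_freq - exp_f) ** 2).sum())


def mismatch_tau(aln: HaplotypeAlignment, n_grid: int = 40) -> MismatchFit:
    """Least-squares fit of the sudden-expansion mismatch curve.

    Fits (τ, θ0) to the observed pairwise-difference histogram with θ1 pinned
    at 10³·max(θ0, 1); a bounded coarse grid locates the basin and Nelder–Mead
    polishes the optimum.  Monomorphic data yield τ̂ = 0 exactly.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    hist = mismatch_histogram(aln)
    if len(hist) == 1:  # all sequences identical
        return MismatchFit(
            mismatch=hist, tau_hat=0.0, theta0_hat=0.0, theta1_hat=1000.0,
            ssd=0.0,
        )
    obs = hist / hist.sum()
    mean_diff = float(pairwise_differences(aln).mean())
    tau_grid = np.linspace(0.0, 2.0 * max(mean_diff, 1.0), n_grid)
    theta0_grid = np.linspace(0.0, max(mean_diff, 1.0), n_grid // 2)
    best, best_ssd = (0.0, 0.0), np.inf
    for t in tau_grid:
        for th in theta0_grid:
            ssd = _mismatch_ssd((t, th), obs)
            if ssd < best_ssd:
                best, best_ssd = (t, th), ssd
    res = optimize.minimize(
        _mismatch_ssd, x0=np.asarray(best), args=(obs,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    tau_hat, theta0_hat = (
        res.x if res.fun <= best_ssd else np.asarray(best)
    )
    tau_hat = max(float(tau_hat), 0.0)
    theta0_hat = max(float(theta0_hat), 0.0)
    return MismatchFit(
        mismatch=hist,
        tau_hat=tau_hat,
        theta0_hat=theta0_hat,
        theta1_hat=1000.0 * max(theta0_hat, 1.0),
        ssd=float(min(res.fun, best_ssd)),
    )


def tau_to_years(
    tau: float, mu_locus_per_year: float, convention: str = "paper_table"
) -> float:
    """Convert a mismatch τ to years since the size change.

    ``paper_table`` uses t = τ/µ (the convention the source's printed table
    follows); ``classical`` uses the textbook τ = 2µt, i.e. t = τ/(2µ).  µ is
    the per-locus (not per-site) mutation rate per year.  The two conventions
    differ by exactly a factor of two and are deliberately not reconciled.
    """
    if mu_locus_per_year <= 0:
        raise ValueError("mu_locus_per_year must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if convention == "paper_table":
        return tau / mu_locus_per_year
    if convention == "classical":
        return tau / (2.0 * mu_locus_per_year)
    raise ValueError(f"unknown convention: {convention!r}")
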