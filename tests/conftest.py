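import math
from fractions import Fraction

import numpy as np
import pytest

from comdemog.synthio import HaplotypeAlignment, SampleMeta


def exact_fs_oracle(n: int, theta: Fraction, k_obs: int) -> float:
    """Exact-rational Ewens-tail oracle for Fu's Fs (independent of the
    log-space implementation path)."""
    row = [Fraction(1)]
    for m in range(1, n + 1):
        new = [Fraction(0)] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    tail = sum(row[k] * theta**k / rising for k in range(k_obs, n + 1))
    sp = float(tail)
    if sp >= 1.0:
        return math.inf
    if sp <= 0.0:
        return -math.inf
    return math.log(sp / (1.0 - sp))


def make_alignment(seqs, pops=None, regions=None, coords=None, locus="L",
                   genome="mtDNA"):
    """Small helper: alignment from raw strings with simple metadata."""
    n = len(seqs)
    pops = pops or ["pop1"] * n
    if regions is None:
        regions = {p: "all" for p in pops}
    meta = []
    for i in range(n):
        lat, lon = (coords[i] if coords else (0.0, float(i % 90)))
        meta.append(
            SampleMeta(
                sample_id=f"s{i}", population=pops[i],
                region=regions[pops[i]], latitude=lat, longitude=lon,
            )
        )
    return HaplotypeAlignment(locus, seqs, meta, genome=genome)


@pytest.fixture
def toy_alignment():
    return make_alignment(["AAA", "AAT", "ATT"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_alignment(rng, n, length, n_states=4):
    bases = np.array(list("ACGT"))[:n_states]
    seqs = ["".join(rng.choice(bases, size=length)) for _ in range(n)]
    return make_alignment(seqs)
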