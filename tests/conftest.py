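"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from endopop.core_io import GroupAssignment, HaplotypeAlignment


def make_alignment(haplotypes, cM=None, chrom=None, ids=None, bp=None):
    """Build a small alignment from raw arrays (single chromosome default)."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    n, S = H.shape
    if cM is None:
        cM = np.arange(S, dtype=float)
    cM = np.asarray(cM, dtype=float)
    if chrom is None:
        chrom = ["chr1"] * S
    if bp is None:
        bp = (cM * 1e6).astype(np.int64) + np.arange(S) + 1
    if ids is None:
        ids = [f"h{i}" for i in range(n)]
    return HaplotypeAlignment(H, chrom, bp, ids, [], site_pos_cM=cM)


def lis_enumeration_oracle(donor_H, obs, cM, switch_rate, emission):
    """Exhaustive-path posterior marginals of the copying model.

    Sums over all D^S donor paths with uniform prior, stay-probability
    exp(-switch_rate*gap/100) transitions and symmetric emission flips;
    independent of the forward-backward implementation it checks.
    """
    D, S = donor_H.shape
    gaps = np.diff(cM)
    stay = np.exp(-switch_rate * gaps / 100.0)
    marg = np.zeros((S, D))
    total = 0.0
    for path in itertools.product(range(D), repeat=S):
        p = 1.0 / D
        for t in range(S):
            p *= (1 - emission) if donor_H[path[t], t] == obs[t] else emission
            if t > 0:
                p *= stay[t - 1] * (path[t] == path[t - 1]) + (1 - stay[t - 1]) / D
        total += p
        for t in range(S):
            marg[t, path[t]] += p
    return marg / total


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic 6-donor, 12-site, 2-group alignment with one recipient."""
    rng = np.random.default_rng(42)
    H = rng.integers(0, 2, (7, 12)).astype(np.uint8)
    cM = np.sort(rng.uniform(0, 20, 12))
    ids = [f"d{i}" for i in range(6)] + ["rec"]
    aln = make_alignment(H, cM=cM, ids=ids)
    groups = GroupAssignment({f"d{i}": ("g1" if i < 3 else "g2") for i in range(6)})
    return aln, groups
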