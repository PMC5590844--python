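"""Distances and ancestry-composition statistics on painting profiles.

A painting profile is a simplex vector f_k: the share of a recipient's
genome-wide copied DNA attributed to each donor group k.  Total variation
distance (TVD) compares two profiles directly; F_XY rescales TVD by the
chromosome-to-chromosome variability of each group's own profile, which
attenuates differences generated by recent drift rather than by distinct
ancestry.  The module also provides a simplex-constrained least-squares
mixture fit of a target profile onto surrogate profiles, and the f3
admixture statistic on allele frequencies with a block-jackknife Z score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)


@dataclass
class GroupProfiles:
    """Genome-wide and per-chromosome painting profiles for one group.

    ``per_chrom`` rows each sum to 1; ``snp_counts`` holds the number of
    sites L_i per chromosome used as weights in the TVD~ statistic.
    """

    genome_wide: pd.Series
    per_chrom: pd.DataFrame
    snp_counts: pd.Series

    def __post_init__(self) -> None:
        if abs(self.genome_wide.sum() - 1) > 1e-6:
            raise ValueError("genome-wide profile must sum to 1")
        if not self.per_chrom.index.equals(self.snp_counts.index):
            raise ValueError("per-chromosome slices and SNP counts must align")


def group_profiles(summaries) -> GroupProfiles:
    """Average member painting summaries (equal weights) into a group profile."""
    gw = pd.concat([s.profile for s in summaries], axis=1).mean(axis=1)
    pc = sum(s.per_chrom_profile for s in summaries) / len(summaries)
    return GroupProfiles(genome_wide=gw, per_chrom=pc,
                         snp_counts=summaries[0].chrom_sites)


def _check_aligned(x: pd.Series, y: pd.Series) -> None:
    if list(x.index) != list(y.index):
        raise ValueError("profiles are over different donor-group sets")


def tvd(x: pd.Series, y: pd.Series) -> float:
    """Total variation distance between two profiles: 0.5 * sum_k |f_kX - f_kY|."""
    _check_aligned(x, y)
    return 0.5 * float(np.abs(x.to_numpy(float) - y.to_numpy(float)).sum())


def tvd_tilde(x: GroupProfiles, y: pd.Series) -> float:
    """SNP-weighted TVD of X's per-chromosome profiles against Y's genome-wide profile.

    TVD~_X = 0.5 * sum_i (L_i / L) * sum_k |f_ikX - f_kY|.  Measures how far
    X's chromosomes scatter around Y; when every chromosome slice of X equals
    X's genome-wide row it reduces to tvd(X, Y).
    """
    if x.per_chrom.empty:
        raise ValueError("group profile is missing per-chromosome slices")
    y_vec = y.reindex(x.per_chrom.columns)
    if y_vec.isna().any():
        raise ValueError("profiles are over different donor-group sets")
    L = x.snp_counts.to_numpy(float)
    diffs = np.abs(x.per_chrom.to_numpy(float) - y_vec.to_numpy(float)[None, :]).sum(axis=1)
    return 0.5 * float((L / L.sum() * diffs).sum())


def fxy(x: GroupProfiles, y: GroupProfiles) -> float:
    """Drift-attenuated profile distance F_XY = TVD_XY / (0.5 (TVD~_X + TVD~_Y)).

    Equals 0 for identical genome-wide profiles and 1 when each group's
    chromosome slices are homogeneous (no within-group chromosome noise).
    """
    t = tvd(x.genome_wide, y.genome_wide)
    denom = 0.5 * (tvd_tilde(x, y.genome_wide) + tvd_tilde(y, x.genome_wide))
    if denom == 0:
        if t > 0:
            raise AssertionError("TVD > 0 with zero TVD~ denominator is impossible")
        logger.warning("F_XY denominator is zero with TVD = 0; returning 0")
        return 0.0
    return t / denom


@dataclass
class MixtureFit:
    """Simplex-constrained least-squares decomposition of a target profile."""

    weights: pd.Series
    residual: float


def fit_surrogate_mixture(target: pd.Series, surrogates: pd.DataFrame,
                          sparsity: float = 0.001) -> MixtureFit:
    """Fit target ~ sum_s w_s * surrogate_s with w >= 0, sum w = 1.

    Solved by non-negative least squares with a heavily weighted sum-to-one
    row; surrogates receiving weight below ``sparsity`` are dropped and the
    remaining weights renormalized.
    """
    if surrogates.shape[0] < 1:
        raise ValueError("need at least one surrogate profile")
    if list(surrogates.columns) != list(target.index):
        raise ValueError("target and surrogates are over different donor columns")
    A = surrogates.to_numpy(float).T                  # (K donors, S surrogates)
    b = target.to_numpy(float)
    lam = 1e4
    A_aug = np.vstack([A, lam * np.ones((1, A.shape[1]))])
    b_aug = np.concatenate([b, [lam]])
    w, _ = nnls(A_aug, b_aug)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate mixture fit: all weights zero")
    w = w / total
    w[w < sparsity] = 0.0
    w = w / w.sum()
    resid = float(np.linalg.norm(A @ w - b))
    return MixtureFit(weights=pd.Series(w, index=surrogates.index), residual=resid)


@dataclass
class F3Result:
    """f3 admixture statistic with block-jackknife uncertainty."""

    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


def f3_statistic(x_freq, a_freq, b_freq, *, n_chrom_x=None,
                 pos_cM=None, chrom=None, block_cM: float = 5.0,
                 correction: bool = True) -> F3Result:
    """f3(X; A, B) = mean_site [(x - a)(x - b) - hx / (nx - 1)] with jackknife SE.

    A significantly negative value (Z < -2) indicates that X is admixed
    between sources related to A and B.  ``n_chrom_x`` is the number of
    chromosomes sampled in X per site (scalar or array); the correction term
    hx / (nx - 1), hx = x(1 - x), removes the finite-sample bias of the
    squared-frequency product.  Jackknife blocks are contiguous cM windows.
    """
    x = np.asarray(x_freq, dtype=float)
    a = np.asarray(a_freq, dtype=float)
    b = np.asarray(b_freq, dtype=float)
    if not (x.shape == a.shape == b.shape):
        raise ValueError("frequency arrays must have identical shape")
    keep = np.isfinite(x) & np.isfinite(a) & np.isfinite(b)
    if correction:
        if n_chrom_x is None:
            raise ValueError("correction requires n_chrom_x")
        n = np.broadcast_to(np.asarray(n_chrom_x, dtype=float), x.shape)
        keep &= n >= 2
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d sites with missing data or zero sample size", dropped)
    if not keep.any():
        raise ValueError("all sites dropped")
    x, a, b = x[keep], a[keep], b[keep]
    vals = (x - a) * (x - b)
    if correction:
        n = n[keep]
        vals = vals - x * (1 - x) / (n - 1)

    if pos_cM is None:
        pos_cM = np.arange(len(vals), dtype=float) * block_cM  # one block per site
    else:
        pos_cM = np.asarray(pos_cM, dtype=float)[keep]
    if chrom is None:
        chrom = np.zeros(len(vals), dtype=int)
    else:
        chrom = np.asarray(chrom, dtype=object)[keep]

    block_keys = {}
    block_idx = np.empty(len(vals), dtype=int)
    for i in range(len(vals)):
        key = (chrom[i], int(pos_cM[i] // block_cM))
        block_idx[i] = block_keys.setdefault(key, len(block_keys))
    G = len(block_keys)
    if G < 2:
        raise ValueError("need at least 2 jackknife blocks; reduce block_cM")

    f3 = float(vals.mean())
    total = vals.sum()
    n_sites = len(vals)
    block_sums = np.bincount(block_idx, weights=vals, minlength=G)
    block_n = np.bincount(block_idx, minlength=G)
    loo = (total - block_sums) / (n_sites - block_n)
    se = float(np.sqrt((G - 1) / G * ((loo - loo.mean()) ** 2).sum()))
    z = f3 / se if se > 0 else np.nan
    return F3Result(f3=f3, se=se, z=float(z), n_blocks=G, n_sites=n_sites)
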