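"""EHH / XP-EHH selection scans with permutation-calibrated thresholds.

Extended haplotype homozygosity (EHH) at distance d from a core site is the
probability that two haplotypes drawn from a population are identical over
the whole stretch from the core to d.  iHH integrates the EHH decay away
from the core (both directions, trapezoid rule over genetic distance) until
EHH falls below a cutoff; XP-EHH compares two populations as
ln(iHH_A / iHH_B), normalized over the scan, so positive scores point to
extended haplotypes (candidate selection) in population A.

Genome-wide significance thresholds follow a label-permutation scheme:
diploid individuals are repeatedly re-partitioned at random into two groups
of the original sizes, the scan is re-run, and the empirical quantiles of
the pooled permuted score distribution serve as thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import HaplotypeAlignment
from .painting import _hap_rows

logger = logging.getLogger(__name__)


def _resolve_rows(aln: HaplotypeAlignment, idents) -> list[int]:
    rows: list[int] = []
    for ident in idents:
        rows.extend(_hap_rows(aln, ident))
    return rows


def _homozygosity(class_ids: np.ndarray) -> float:
    """Sum over haplotype classes of C(count, 2) / C(n, 2)."""
    n = len(class_ids)
    _, counts = np.unique(class_ids, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(aln: HaplotypeAlignment, core_site: int, haplotype_rows,
        direction: str = "right"):
    """EHH decay from a core site in one direction.

    Returns (distances_cM, ehh_values) starting at the core itself, where
    classes are defined by the core allele; at each further site haplotypes
    are partitioned by their full sequence spanning core -> site, so the
    series is non-increasing.
    """
    rows = np.asarray(haplotype_rows)
    if len(rows) < 2:
        raise ValueError("EHH requires at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    cM = aln.require_cM()
    chrom = aln.site_chrom[core_site]
    sites = np.flatnonzero(aln.chrom_mask(chrom))
    k0 = int(np.searchsorted(sites, core_site))
    order = sites[k0:] if direction == "right" else sites[k0::-1]
    H = aln.haplotypes[rows]
    classes = H[:, order[0]].astype(np.int64)
    dists = [0.0]
    values = [_homozygosity(classes)]
    for s in order[1:]:
        classes = classes * 2 + H[:, s]
        _, classes = np.unique(classes, return_inverse=True)
        dists.append(abs(float(cM[s] - cM[order[0]])))
        values.append(_homozygosity(classes))
    return np.asarray(dists), np.asarray(values)


def _ihh_one_side(H: np.ndarray, cM: np.ndarray, k0: int, step: int,
                  cutoff: float, max_gap_cM: float):
    """Integrated EHH away from the core; returns (ihh, flag or None)."""
    n = H.shape[0]
    denom = n * (n - 1)
    classes = H[:, k0].astype(np.int64)
    _, counts = np.unique(classes, return_counts=True)
    prev_ehh = float((counts * (counts - 1)).sum() / denom)
    prev_cm = cM[k0]
    ihh = 0.0
    k = k0
    while True:
        k_next = k + step
        if k_next < 0 or k_next >= H.shape[1]:
            return ihh, "edge"
        gap = abs(float(cM[k_next] - prev_cm))
        if gap > max_gap_cM:
            return ihh, "gap"
        classes = classes * 2 + H[:, k_next]
        _, classes, counts = np.unique(classes, return_inverse=True,
                                       return_counts=True)
        cur = float((counts * (counts - 1)).sum() / denom)
        ihh += 0.5 * (prev_ehh + cur) * gap
        if cur < cutoff:
            return ihh, None
        prev_ehh, prev_cm = cur, float(cM[k_next])
        k = k_next


@dataclass
class SelectionScan:
    """Per-core-site XP-EHH scores; sites flagged by edge/gap truncation or
    undefined ratios are excluded from normalization."""

    table: pd.DataFrame                # site, chrom, pos_bp, ihh_a, ihh_b, raw, norm, flag
    mean_raw: float
    sd_raw: float


def xpehh_scan(aln: HaplotypeAlignment, pop_a, pop_b,
               ehh_cutoff: float = 0.05, max_gap_cM: float = 0.2) -> SelectionScan:
    """XP-EHH scan across every site: ln(iHH_A / iHH_B), scan-normalized.

    Both populations use the pooled (all-haplotype) EHH definition with
    core-allele classes at the core.  Positive normalized scores indicate
    longer haplotypes (candidate selection) in ``pop_a``.
    """
    rows_a = np.asarray(_resolve_rows(aln, pop_a))
    rows_b = np.asarray(_resolve_rows(aln, pop_b))
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    cM = aln.require_cM()
    records = []
    for chrom in aln.chromosomes():
        sites = np.flatnonzero(aln.chrom_mask(chrom))
        Ha = aln.haplotypes[np.ix_(rows_a, sites)]
        Hb = aln.haplotypes[np.ix_(rows_b, sites)]
        c = cM[sites]
        for k in range(len(sites)):
            flag = None
            ihh_a = ihh_b = np.nan
            parts = {}
            for name, H in (("a", Ha), ("b", Hb)):
                left, fl = _ihh_one_side(H, c, k, -1, ehh_cutoff, max_gap_cM)
                right, fr = _ihh_one_side(H, c, k, +1, ehh_cutoff, max_gap_cM)
                parts[name] = left + right
                flag = flag or fl or fr
            ihh_a, ihh_b = parts["a"], parts["b"]
            if flag is None and ihh_b == 0:
                flag = "undefined"
            raw = math.log(ihh_a / ihh_b) if flag is None and ihh_a > 0 else np.nan
            if flag is None and ihh_a == 0:
                flag = "undefined"
            records.append((int(sites[k]), chrom, int(aln.site_pos_bp[sites[k]]),
                            ihh_a, ihh_b, raw, flag))
    df = pd.DataFrame(records, columns=["site", "chrom", "pos_bp",
                                        "ihh_a", "ihh_b", "raw", "flag"])
    valid = df["flag"].isna() & df["raw"].notna()
    if not valid.any():
        raise ValueError("no scorable sites in the scan")
    mean = float(df.loc[valid, "raw"].mean())
    sd = float(df.loc[valid, "raw"].std(ddof=0))
    if sd == 0:
        logger.warning("zero variance of raw scores; normalized scores set to 0")
        df["norm"] = np.where(valid, 0.0, np.nan)
    else:
        df["norm"] = np.where(valid, (df["raw"] - mean) / sd, np.nan)
    return SelectionScan(table=df, mean_raw=mean, sd_raw=sd)


@dataclass
class PermutationNull:
    """Pooled permuted XP-EHH scores and their empirical quantile thresholds."""

    pooled: np.ndarray
    lower: float
    upper: float
    quantiles: tuple
    n_permutations: int


def empirical_thresholds(pooled: np.ndarray, quantiles: tuple) -> tuple[float, float]:
    """(ceil(q N)-th smallest) empirical quantiles of the pooled null scores."""
    x = np.sort(pooled)
    N = len(x)
    lo_i = max(math.ceil(quantiles[0] * N), 1) - 1
    hi_i = max(math.ceil(quantiles[1] * N), 1) - 1
    return float(x[lo_i]), float(x[hi_i])


def permutation_thresholds(aln: HaplotypeAlignment, combined_ids,
                           group_sizes: tuple, n_permutations: int = 100,
                           quantiles: tuple = (0.0001, 0.9999), seed: int = 0,
                           ehh_cutoff: float = 0.05,
                           max_gap_cM: float = 0.2) -> PermutationNull:
    """Permutation null for XP-EHH: random re-partitions of the individuals.

    Diploid individuals move as units.  Each permutation splits the pooled
    individuals into groups of the original sizes, runs the scan, and all
    permuted normalized scores are pooled; thresholds are the empirical
    quantiles of that pooled distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n_a, n_b = group_sizes
    if n_a < 1 or n_b < 1 or n_a + n_b != len(combined_ids):
        raise ValueError("group sizes must be positive and sum to the pooled count")
    rng = np.random.default_rng(seed)
    ids = list(combined_ids)
    pooled = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(ids))
        grp_a = [ids[i] for i in perm[:n_a]]
        grp_b = [ids[i] for i in perm[n_a:]]
        scan = xpehh_scan(aln, grp_a, grp_b, ehh_cutoff, max_gap_cM)
        pooled.append(scan.table["norm"].dropna().to_numpy())
    pooled = np.concatenate(pooled)
    lower, upper = empirical_thresholds(pooled, quantiles)
    if lower > upper:
        raise AssertionError("lower threshold exceeds upper threshold")
    return PermutationNull(pooled=pooled, lower=lower, upper=upper,
                           quantiles=tuple(quantiles),
                           n_permutations=n_permutations)


def significant_sites(scan: SelectionScan, null: PermutationNull) -> pd.DataFrame:
    """Observed sites whose normalized score falls outside the null thresholds."""
    t = scan.table
    mask = t["norm"].notna() & ((t["norm"] < null.lower) | (t["norm"] > null.upper))
    return t[mask]
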