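"""Y-STR and haplogroup-frequency analyses.

Covers the classical uniparental toolbox for comparing populations on
Y-chromosome / mtDNA category data: Nei's unbiased gene diversity with its
variance, AMOVA Phi_ST on identity distances with a permutation test, the
Markov-chain exact test of population differentiation, principal-coordinates
ordination of 1 - F_ST similarity matrices, a grid posterior for two-source
admixture proportions from haplogroup frequencies, and coalescence (TMRCA)
dating of STR-defined clusters via the average squared difference (ASD)
from a modal haplotype under the single-step stepwise mutation model (SMM),
for which E[ASD] = mu * t.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: mutations observed / meioses surveyed in the pooled published Y-STR data
DEFAULT_MU = 15.0 / 7856.0
DEFAULT_GENERATION_TIME = 28.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class STRHaplotypeSet:
    """Repeat-count matrix over STR loci with haplogroup (and population) labels."""

    repeats: np.ndarray             # (n_chromosomes, n_loci) positive integers
    loci: list[str]
    haplogroups: list[str]
    populations: list[str] | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        if self.repeats.ndim != 2:
            raise ValueError("repeats must be a 2-D matrix")
        if (self.repeats <= 0).any():
            raise ValueError("repeat counts must be positive integers")
        if len(self.haplogroups) != self.repeats.shape[0]:
            raise ValueError("one haplogroup label per chromosome required")

    @property
    def n_chromosomes(self) -> int:
        return self.repeats.shape[0]

    def within(self, haplogroup: str) -> np.ndarray:
        rows = [i for i, h in enumerate(self.haplogroups) if h == haplogroup]
        if not rows:
            raise ValueError(f"no chromosomes in haplogroup {haplogroup!r}")
        return self.repeats[rows]


@dataclass
class HaplogroupCounts:
    """Population x category count table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> pd.Series:
        return self.table.sum(axis=1)

    def row(self, population) -> np.ndarray:
        return self.table.loc[population].to_numpy(np.int64)


@dataclass
class TMRCAEstimate:
    """ASD-based coalescence date of an STR cluster from its modal haplotype."""

    asd: float
    mu: float
    t_generations: float
    ci_generations: tuple
    n_chromosomes: int
    years: float | None = None
    ci_years: tuple | None = None


@dataclass
class AdmixturePosterior:
    """Grid posterior for the proportion p contributed by parental source A."""

    grid: np.ndarray
    mass: np.ndarray
    mode: float
    median: float
    mean: float
    ci: tuple


@dataclass
class ModalHaplotype:
    haplotype: tuple
    frequency: float
    below_threshold: bool           # True when frequency <= 0.5


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def gene_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased gene diversity h = n/(n-1) (1 - sum p_i^2) and its SE.

    The variance follows Nei's sampling formula
    V(h) = 2/(n(n-1)) { 2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity requires n >= 2")
    p = c / n
    j2 = float((p ** 2).sum())
    j3 = float((p ** 3).sum())
    h = n / (n - 1) * (1.0 - j2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (j3 - j2 ** 2) + j2 - j2 ** 2)
    return float(h), float(np.sqrt(max(var, 0.0)))


def diversity_z_test(h1: float, se1: float, h2: float, se2: float) -> tuple[float, float]:
    """Two-tailed z test for a difference between two gene-diversity values."""
    z = (h1 - h2) / math.sqrt(se1 ** 2 + se2 ** 2)
    return z, 2.0 * float(norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# AMOVA Phi_ST and permutation test
# ---------------------------------------------------------------------------

def _phi_from_counts(count_rows: np.ndarray) -> float:
    """AMOVA Phi_ST on identity (0/1) distances from population count vectors."""
    counts = np.asarray(count_rows, dtype=float)
    n_p = counts.sum(axis=1)
    N = n_p.sum()
    P = counts.shape[0]
    tot = counts.sum(axis=0)
    ssd_t = (N ** 2 - (tot ** 2).sum()) / (2.0 * N)
    ssd_w = float(((n_p ** 2 - (counts ** 2).sum(axis=1)) / (2.0 * n_p)).sum())
    ssd_a = ssd_t - ssd_w
    msd_a = ssd_a / (P - 1)
    msd_w = ssd_w / (N - P)
    n0 = (N - (n_p ** 2).sum() / N) / (P - 1)
    sigma_a = (msd_a - msd_w) / n0
    denom = sigma_a + msd_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(counts: HaplogroupCounts, n_permutations: int = 10000,
           seed: int = 0) -> tuple[float, float]:
    """Phi_ST between populations on identity distances, with permutation p.

    p is the +1-smoothed proportion of random relabellings of individuals
    across populations giving Phi_ST at least as large as observed; negative
    Phi_ST values are reported as computed, never clamped.
    """
    table = counts.table.to_numpy(np.int64)
    if table.shape[0] < 2:
        raise ValueError("Phi_ST requires at least two populations")
    n_p = table.sum(axis=1)
    if (n_p < 2).any():
        raise ValueError("each population needs n >= 2")
    obs = _phi_from_counts(table)
    rng = np.random.default_rng(seed)
    C = table.shape[1]
    # canonical column order makes the permutation stream (and hence p)
    # invariant to relabelling of the categories
    order = sorted(range(C), key=lambda c: tuple(table[:, c]))
    table = table[:, order]
    labels = np.repeat(np.tile(np.arange(C), table.shape[0]), table.ravel())
    splits = np.cumsum(n_p)[:-1]
    n_ge = 0
    for _ in range(n_permutations):
        rng.shuffle(labels)
        rows = [np.bincount(part, minlength=C) for part in np.split(labels, splits)]
        if _phi_from_counts(np.asarray(rows)) >= obs - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return obs, p


# ---------------------------------------------------------------------------
# Exact test of population differentiation
# ---------------------------------------------------------------------------

def exact_test(counts: HaplogroupCounts, n_steps: int = 10000, seed: int = 0,
               burn_in: int = 1000) -> float:
    """Markov-chain exact test of population differentiation.

    Explores contingency tables with the observed margins by repeatedly
    swapping the categories of two individuals drawn from different
    populations (for this proposal the Metropolis-Hastings acceptance ratio
    against the fixed-margins hypergeometric distribution is exactly 1, so
    every move is accepted).  p is the fraction of visited tables whose
    conditional probability does not exceed the observed table's.
    """
    table = counts.table.to_numpy(np.int64).copy()
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d empty populations and %d empty categories",
                       int((~row_ok).sum()), int((~col_ok).sum()))
        table = table[row_ok][:, col_ok]
    P, C = table.shape
    N = int(table.sum())
    if P < 2 or N < 2:
        raise ValueError("exact test needs >= 2 populations and table total >= 2")

    lg = gammaln(np.arange(N + 2, dtype=float))
    cells = [[int(table[p, c]) for c in range(C)] for p in range(P)]
    n_p = [sum(r) for r in cells]
    S = sum(lg[v + 1] for r in cells for v in r)    # logP = const - S
    S_obs = S
    rnd = random.Random(seed)
    pop_cum = np.cumsum(n_p)
    total = pop_cum[-1]

    def pick_pop(exclude: int = -1) -> int:
        if exclude < 0:
            x = rnd.random() * total
            for p in range(P):
                if x < pop_cum[p]:
                    return p
        rem = total - n_p[exclude]
        x = rnd.random() * rem
        acc = 0
        for p in range(P):
            if p == exclude:
                continue
            acc += n_p[p]
            if x < acc:
                return p
        return P - 1

    def pick_cat(p: int) -> int:
        x = rnd.random() * n_p[p]
        acc = 0
        row = cells[p]
        for c in range(C):
            acc += row[c]
            if x < acc:
                return c
        return C - 1

    hits = 0
    kept = 0
    for step in range(burn_in + n_steps):
        p1 = pick_pop()
        p2 = pick_pop(exclude=p1)
        c1 = pick_cat(p1)
        c2 = pick_cat(p2)
        if c1 != c2:
            # incremental update of S for the four changed cells
            for (p, c, delta) in ((p1, c1, -1), (p1, c2, +1),
                                  (p2, c2, -1), (p2, c1, +1)):
                S -= lg[cells[p][c] + 1]
                cells[p][c] += delta
                S += lg[cells[p][c] + 1]
        if step >= burn_in:
            kept += 1
            if S >= S_obs - 1e-9:
                hits += 1
    return hits / kept


# ---------------------------------------------------------------------------
# Principal coordinates of 1 - F_ST
# ---------------------------------------------------------------------------

def pco(fst: pd.DataFrame, n: pd.Series):
    """Classical principal-coordinates analysis of the 1 - F_ST similarity matrix.

    Off-diagonal similarity is 1 - F_ST; the self-similarity diagonal is
    n_i/(n_i - 1) (the Phi_ST-based distance of a population sample to a
    copy of itself).  Returns (coordinates, eigenvalues); axes with negative
    eigenvalues are reported in the eigenvalue vector but excluded from the
    coordinates.
    """
    F = fst.to_numpy(float)
    if not np.allclose(F, F.T, atol=1e-9):
        raise ValueError("F_ST matrix must be symmetric")
    n_vec = n.reindex(fst.index).to_numpy(float)
    if (n_vec < 2).any():
        raise ValueError("each population needs n >= 2")
    S = 1.0 - F
    np.fill_diagonal(S, n_vec / (n_vec - 1.0))
    m = S.shape[0]
    H = np.eye(m) - np.ones((m, m)) / m
    B = H @ S @ H
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    coords_df = pd.DataFrame(coords, index=fst.index,
                             columns=[f"PCo{i+1}" for i in range(int(pos.sum()))])
    return coords_df, vals


# ---------------------------------------------------------------------------
# Admixture-proportion grid posterior
# ---------------------------------------------------------------------------

def admixture_posterior(hybrid, parental_a, parental_b,
                        grid_size: int = 1001,
                        smoothing: float = 0.5) -> AdmixturePosterior:
    """Posterior for the source-A proportion p from haplogroup counts.

    The hybrid counts are modelled as multinomial with category frequencies
    p f_A + (1-p) f_B, where f_A and f_B are Jeffreys-smoothed parental
    frequency estimates; the prior on p is uniform on a regular grid.
    Drift after admixture is not modelled.
    """
    h = pd.Series(hybrid, dtype=float)
    a = pd.Series(parental_a, dtype=float).reindex(h.index, fill_value=0.0)
    b = pd.Series(parental_b, dtype=float).reindex(h.index, fill_value=0.0)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("parental samples must be non-empty")
    K = len(h)
    f_a = (a.to_numpy() + smoothing) / (a.sum() + smoothing * K)
    f_b = (b.to_numpy() + smoothing) / (b.sum() + smoothing * K)
    grid = np.linspace(0.0, 1.0, grid_size)
    mix = grid[:, None] * f_a[None, :] + (1 - grid[:, None]) * f_b[None, :]
    ll = (h.to_numpy()[None, :] * np.log(mix)).sum(axis=1)
    ll -= ll.max()
    mass = np.exp(ll)
    mass /= mass.sum()
    cdf = np.cumsum(mass)
    mode = float(grid[int(np.argmax(mass))])
    median = float(grid[int(np.searchsorted(cdf, 0.5))])
    mean = float((grid * mass).sum())
    ci = (float(grid[int(np.searchsorted(cdf, 0.025))]),
          float(grid[int(np.searchsorted(cdf, 0.975))]))
    return AdmixturePosterior(grid=grid, mass=mass, mode=mode, median=median,
                              mean=mean, ci=ci)


# ---------------------------------------------------------------------------
# Modal haplotype and ASD TMRCA
# ---------------------------------------------------------------------------

def modal_haplotype(strs: STRHaplotypeSet, within_haplogroup: str) -> ModalHaplotype:
    """Most frequent full STR haplotype within a haplogroup.

    A tie for the mode is a hard error (the ancestral state cannot be
    inferred); a winning frequency <= 0.5 is flagged so the caller can apply
    the high-frequency-modal restriction.
    """
    rows = strs.within(within_haplogroup)
    if rows.shape[0] < 2:
        raise ValueError("need >= 2 chromosomes in the haplogroup")
    haps, counts = np.unique(rows, axis=0, return_counts=True)
    best = counts.max()
    winners = haps[counts == best]
    if len(winners) > 1:
        listed = "; ".join(str(tuple(w)) for w in winners)
        raise ValueError(f"tie for the modal haplotype: {listed}")
    freq = best / rows.shape[0]
    return ModalHaplotype(haplotype=tuple(int(v) for v in winners[0]),
                          frequency=float(freq),
                          below_threshold=freq <= 0.5)


def _simulate_asd(n_cells: int, expected_mutations: float, n_iterations: int,
                  rng: np.random.Generator) -> np.ndarray:
    """ASD of simulated star-genealogy SMM datasets (one value per iteration)."""
    out = np.empty(n_iterations)
    chunk = max(1, int(5e6) // max(n_cells, 1))
    done = 0
    while done < n_iterations:
        k = min(chunk, n_iterations - done)
        m = rng.poisson(expected_mutations, size=(k, n_cells))
        up = rng.binomial(m, 0.5)
        d = 2 * up - m
        out[done:done + k] = (d.astype(float) ** 2).mean(axis=1)
        done += k
    return out


def asd_tmrca(strs: STRHaplotypeSet, modal, mu: float = DEFAULT_MU,
              n_iterations: int = 50000, seed: int = 0,
              pooled_partners: tuple | None = None,
              exclusions: tuple = (),
              mu_uncertainty: bool = False,
              generation_time: float | None = None) -> TMRCAEstimate:
    """Coalescence date of an STR cluster: t = ASD / mu generations.

    ASD is the mean squared repeat difference between the modal (ancestral)
    haplotype and all chromosomes, over every chromosome x locus cell.  The
    95% CI is a parametric Monte-Carlo: star-genealogy SMM datasets of the
    same size are simulated at the point estimate and the 2.5/97.5
    percentiles of their re-estimated dates are reported.  With
    ``pooled_partners`` = (strs2, modal2) a joint single-date estimate pools
    squared differences from both clusters against their own modals.  With
    ``mu_uncertainty`` each simulated date divides by a mutation rate drawn
    from the Jeffreys posterior for 15 mutations in 7,856 meioses.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    modal = np.asarray(modal, dtype=np.int64)

    def cluster_cells(s: STRHaplotypeSet, m: np.ndarray) -> np.ndarray:
        reps = s.repeats
        if exclusions and s.ids is not None:
            keep = [i for i, ident in enumerate(s.ids) if ident not in exclusions]
            reps = reps[keep]
        if reps.shape[1] != len(m):
            raise ValueError("chromosomes and modal haplotype share no common loci")
        return ((reps - m[None, :]).astype(float) ** 2).ravel()

    cells = cluster_cells(strs, modal)
    n_chrom = cells.size // len(modal)
    if pooled_partners is not None:
        strs2, modal2 = pooled_partners
        cells2 = cluster_cells(strs2, np.asarray(modal2, dtype=np.int64))
        n_chrom += cells2.size // len(np.asarray(modal2))
        cells = np.concatenate([cells, cells2])
    asd = float(cells.mean())
    t_hat = asd / mu

    rng = np.random.default_rng(seed)
    if t_hat == 0 or n_iterations == 0:
        ci = (0.0, 0.0) if t_hat == 0 else (t_hat, t_hat)
    else:
        asd_sim = _simulate_asd(cells.size, mu * t_hat, n_iterations, rng)
        if mu_uncertainty:
            mu_draws = rng.beta(15 + 0.5, 7856 - 15 + 0.5, size=n_iterations)
            t_sim = asd_sim / mu_draws
        else:
            t_sim = asd_sim / mu
        lo, hi = np.percentile(t_sim, [2.5, 97.5])
        ci = (float(lo), float(hi))
    est = TMRCAEstimate(asd=asd, mu=mu, t_generations=float(t_hat),
                        ci_generations=ci, n_chromosomes=int(n_chrom))
    if generation_time is not None:
        est.years, est.ci_years = generations_to_years(
            est.t_generations, est.ci_generations, generation_time)
    return est


def generations_to_years(t: float, ci: tuple | None = None,
                         generation_time: float = DEFAULT_GENERATION_TIME):
    """Convert a generation count (and CI) to years by exact multiplication."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    years = t * generation_time
    if ci is None:
        return years, None
    return years, (ci[0] * generation_time, ci[1] * generation_time)
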