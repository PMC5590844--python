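"""Generators for all pipeline inputs with known ground truth.

Every generator is a pure function of its arguments and seed.  The
haplotype generators emulate the structure the analyses assume rather than
a full demographic history: source panels differ by Balding-Nichols
frequency deviation around shared ancestral frequencies (so pairwise F_ST
is controlled by a single divergence parameter), and realistic haplotype
sharing is induced by a copying smoothing pass in which each final
haplotype is a recombinant mosaic of independently drawn founders.  Admixed
chromosomes are source mosaics with Poisson breakpoints at rate g per
Morgan, the signal the coancestry-curve dating recovers.  STR sets evolve
from a known ancestor under the single-step stepwise mutation model, and
haplogroup tables are multinomial draws from a two-source frequency
mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GroupAssignment, HaplotypeAlignment

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Bundle of generator settings (used by the command-line interface)."""

    seed: int = 0
    n_haplotypes: int = 50              # per population
    n_sites: int = 2000                 # total across chromosomes
    chrom_lengths_cM: tuple = (100.0,)
    divergence: float = 0.1             # Balding-Nichols F between source panels
    alpha: float = 0.25                 # admixture proportion from source A
    admixture_generations: float = 30.0
    n_admixed: int = 100
    str_mu: float = 15.0 / 7856.0
    str_t: int = 35
    str_n: int = 50
    str_ancestor: tuple = (14, 12, 23, 10, 11, 13)
    mix_p: float = 0.8
    mix_n: int = 200


def _site_coordinates(n_sites: int, chrom_lengths_cM, rng: np.random.Generator):
    """Uniform site positions per chromosome; strictly increasing bp, cM = map."""
    lengths = np.asarray(chrom_lengths_cM, dtype=float)
    per_chrom = np.maximum((n_sites * lengths / lengths.sum()).astype(int), 2)
    chroms, bp, cM = [], [], []
    for ci, (L, k) in enumerate(zip(lengths, per_chrom)):
        pos = np.sort(rng.uniform(0, L, size=k))
        b = (pos * 1e6).astype(np.int64) + 1
        b = np.maximum.accumulate(b + np.arange(k))     # force strict increase
        chroms.extend([f"chr{ci + 1}"] * k)
        bp.append(b)
        cM.append(pos)
    return (np.asarray(chroms, dtype=object), np.concatenate(bp),
            np.concatenate(cM), per_chrom)


def simulate_copying(founders: np.ndarray, cM: np.ndarray, n_out: int,
                     switch_rate: float, emission: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Mosaic haplotypes copied from a founder panel (one chromosome).

    Donor switches occur between adjacent sites with probability
    1 - exp(-switch_rate * gap / 100); alleles flip with probability
    ``emission``.  This is the generative counterpart of the painting
    model's transition/emission structure.
    """
    D, S = founders.shape
    out = np.empty((n_out, S), dtype=np.uint8)
    p_switch = 1.0 - np.exp(-switch_rate * np.diff(cM) / 100.0)
    for i in range(n_out):
        switches = rng.random(S - 1) < p_switch
        seg = np.concatenate([[0], np.cumsum(switches)])
        donors = rng.integers(0, D, size=seg[-1] + 1)
        hap = founders[donors[seg], np.arange(S)]
        if emission > 0:
            flip = rng.random(S) < emission
            hap = hap ^ flip
        out[i] = hap
    return out


def simulate_source_panels(n_populations: int = 2, n_haplotypes: int = 50,
                           n_sites: int = 2000, chrom_lengths_cM=(100.0,),
                           divergence: float = 0.1, seed: int = 0,
                           smoothing_rate: float = 20.0,
                           labels=None) -> tuple[HaplotypeAlignment, GroupAssignment]:
    """Phased haplotype panels from diverged source populations.

    Ancestral allele frequencies are uniform(0.05, 0.95); each population's
    frequencies are Balding-Nichols beta deviates with F = ``divergence``,
    so pairwise Weir-Cockerham F_ST between panels is approximately F.
    Haplotypes are drawn site-independently and then smoothed by a copying
    pass (rate ``smoothing_rate`` switches per Morgan) to induce local
    haplotype sharing.
    """
    if not 0 < divergence < 1:
        raise ValueError("divergence must lie in (0, 1)")
    if n_populations < 2:
        raise ValueError("need at least 2 populations")
    if n_sites < 10:
        raise ValueError("need at least 10 sites")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(n_populations)]
    chroms, bp, cM, _ = _site_coordinates(n_sites, chrom_lengths_cM, rng)
    S = len(bp)
    anc = rng.uniform(0.05, 0.95, size=S)
    F = divergence
    a_par = anc * (1 - F) / F
    b_par = (1 - anc) * (1 - F) / F
    haps, hap_ids, assign = [], [], {}
    for label in labels:
        freq = rng.beta(a_par, b_par)
        founders = (rng.random((n_haplotypes, S)) < freq).astype(np.uint8)
        smoothed = np.empty_like(founders)
        for chrom in pd.unique(chroms):
            m = chroms == chrom
            smoothed[:, m] = simulate_copying(founders[:, m], cM[m],
                                              n_haplotypes, smoothing_rate,
                                              0.0, rng)
        haps.append(smoothed)
        for i in range(n_haplotypes):
            ident = f"{label}_h{i}"
            hap_ids.append(ident)
            assign[ident] = label
    aln = HaplotypeAlignment(
        haplotypes=np.vstack(haps), site_chrom=chroms, site_pos_bp=bp,
        haplotype_ids=hap_ids, sample_ids=[], site_pos_cM=cM)
    return aln, GroupAssignment(assign, groups=list(labels))


def extract_group(aln: HaplotypeAlignment, groups: GroupAssignment,
                  label) -> HaplotypeAlignment:
    """Sub-alignment holding one group's haplotypes."""
    ids = [h for h in aln.haplotype_ids if groups.assignment.get(h) == label]
    return aln.subset_haplotypes(ids)


def simulate_admixed(panel_a: HaplotypeAlignment, panel_b: HaplotypeAlignment,
                     alpha: float, g: float, n: int, seed: int = 0,
                     id_prefix: str = "adm", return_truth: bool = False):
    """Admixed chromosomes: source mosaics with Poisson breakpoints.

    Each admixed haplotype switches source at Poisson(g per Morgan)
    breakpoints placed uniformly in genetic distance; each segment is
    labelled source A independently with probability ``alpha`` and copies a
    random haplotype from that source panel, so the expected source-A genome
    fraction is alpha and segment lengths are exponential with rate g/Morgan.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if g < 1:
        raise ValueError("g must be >= 1 generation")
    if panel_a.n_haplotypes == 0 or panel_b.n_haplotypes == 0:
        raise ValueError("source panels must be non-empty")
    if not np.array_equal(panel_a.site_pos_bp, panel_b.site_pos_bp):
        raise ValueError("source panels must share site coordinates")
    rng = np.random.default_rng(seed)
    cM = panel_a.require_cM()
    S = panel_a.n_sites
    haps = np.empty((n, S), dtype=np.uint8)
    n_breaks = np.zeros(n, dtype=int)
    source_lab = np.empty((n, S), dtype=np.uint8)
    for i in range(n):
        for chrom in panel_a.chromosomes():
            m = np.flatnonzero(panel_a.chrom_mask(chrom))
            c = cM[m]
            span = float(c[-1] - c[0])
            k = rng.poisson(g * span / 100.0)
            n_breaks[i] += k
            breaks = np.sort(rng.uniform(c[0], c[-1], size=k))
            seg = np.searchsorted(breaks, c)
            is_a = rng.random(k + 1) < alpha
            for s in range(k + 1):
                sites = m[seg == s]
                if len(sites) == 0:
                    continue
                panel = panel_a if is_a[s] else panel_b
                donor = rng.integers(0, panel.n_haplotypes)
                haps[i, sites] = panel.haplotypes[donor, sites]
                source_lab[i, sites] = 0 if is_a[s] else 1
    aln = HaplotypeAlignment(
        haplotypes=haps, site_chrom=panel_a.site_chrom,
        site_pos_bp=panel_a.site_pos_bp,
        haplotype_ids=[f"{id_prefix}_h{i}" for i in range(n)],
        sample_ids=[], site_pos_cM=cM)
    if return_truth:
        return aln, {"n_breakpoints": n_breaks, "source": source_lab}
    return aln


def simulate_admixture_study(seed: int = 0, n_chrom: int = 10,
                             chrom_cM: float = 100.0,
                             sites_per_chrom: int = 800,
                             n_donor_haplotypes: int = 40,
                             n_admixed: int = 100, alpha: float = 0.25,
                             g: float = 30.0, divergence: float = 0.3):
    """Two diverged donor panels plus admixed recipients in one alignment.

    Convenience wrapper for the dating workflow: returns the combined
    alignment (donor haplotypes first, admixed recipients appended), the
    donor group assignment, and the recipient ids.
    """
    aln, groups = simulate_source_panels(
        n_populations=2, n_haplotypes=n_donor_haplotypes,
        n_sites=sites_per_chrom * n_chrom,
        chrom_lengths_cM=(chrom_cM,) * n_chrom,
        divergence=divergence, seed=seed)
    pa = extract_group(aln, groups, "A")
    pb = extract_group(aln, groups, "B")
    adm = simulate_admixed(pa, pb, alpha=alpha, g=g, n=n_admixed,
                           seed=seed + 1_000_000)
    combined = HaplotypeAlignment(
        np.vstack([aln.haplotypes, adm.haplotypes]), aln.site_chrom,
        aln.site_pos_bp, aln.haplotype_ids + adm.haplotype_ids, [],
        site_pos_cM=aln.site_pos_cM)
    return combined, groups, list(adm.haplotype_ids)


def simulate_str(ancestor, mu: float, t: int, n: int, seed: int = 0,
                 haplogroup: str = "HG1", loci=None,
                 id_prefix: str = "chrom"):
    """STR haplotypes after t generations of single-step SMM on a star genealogy.

    Per generation and locus each chromosome mutates with probability mu,
    moving one repeat up or down with equal probability; a step that would
    drop the repeat below 1 is reflected upward (logged).  E[ASD from the
    ancestor] = mu * t.
    """
    from .uniparental import STRHaplotypeSet

    if t < 0:
        raise ValueError("t must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be positive")
    anc = np.asarray(ancestor, dtype=np.int64)
    rng = np.random.default_rng(seed)
    reps = np.tile(anc, (n, 1))
    n_reflect = 0
    for _ in range(int(t)):
        mutate = rng.random(reps.shape) < mu
        step = np.where(rng.random(reps.shape) < 0.5, 1, -1)
        bad = mutate & (reps + step < 1)
        n_reflect += int(bad.sum())
        step = np.where(bad, 1, step)
        reps = reps + mutate * step
    if n_reflect:
        logger.info("reflected %d below-one mutation steps upward", n_reflect)
    if loci is None:
        loci = [f"locus{j + 1}" for j in range(len(anc))]
    return STRHaplotypeSet(repeats=reps, loci=list(loci),
                           haplogroups=[haplogroup] * n,
                           ids=[f"{id_prefix}{i}" for i in range(n)])


def simulate_haplogroup_counts(f_a, f_b, p: float, n: int, seed: int = 0,
                               population: str = "admixed"):
    """Multinomial haplogroup counts from the mixture p*f_a + (1-p)*f_b."""
    from .uniparental import HaplogroupCounts

    f_a = pd.Series(f_a, dtype=float)
    f_b = pd.Series(f_b, dtype=float).reindex(f_a.index)
    if f_b.isna().any():
        raise ValueError("f_a and f_b must share the same category set")
    if abs(f_a.sum() - 1) > 1e-9 or abs(f_b.sum() - 1) > 1e-9:
        raise ValueError("probability vectors must sum to 1 within 1e-9")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mix = p * f_a.to_numpy() + (1 - p) * f_b.to_numpy()
    draw = rng.multinomial(n, mix) if n > 0 else np.zeros(len(mix), dtype=np.int64)
    table = pd.DataFrame([draw], index=[population], columns=f_a.index)
    return HaplogroupCounts(table)


def allele_frequencies(aln: HaplotypeAlignment, rows=None) -> np.ndarray:
    """Per-site alternate-allele frequency over a haplotype subset."""
    H = aln.haplotypes if rows is None else aln.haplotypes[np.asarray(rows)]
    return H.mean(axis=0)
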