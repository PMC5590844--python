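"""Shared data model and readers/writers for the pipeline's text formats.

The package works on phased biallelic haplotype matrices with genetic-map
(centimorgan) coordinates, plus the small TSV tables used by the uniparental
analyses (Y-STR repeat counts, haplogroup count tables, group labels).

Conventions: base-pair positions are 1-based as in VCF; cM values are
absolute map positions, so genetic distances are plain subtractions.
Missing or unphased genotypes are rejected, never imputed: the analyses
assume a complete, phased input panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Phased binary haplotype matrix with per-site genomic coordinates.

    Rows are haploid genomes (two consecutive rows per diploid sample when
    read from VCF); columns are biallelic sites ordered as in the source
    file.  ``site_pos_cM`` is ``None`` until :func:`annotate_cM` is applied.
    """

    haplotypes: np.ndarray            # (n_hap, n_sites) values in {0, 1}
    site_chrom: np.ndarray            # (n_sites,) chromosome label per site
    site_pos_bp: np.ndarray           # (n_sites,) 1-based bp position
    haplotype_ids: list[str]
    sample_ids: list[str]             # one per diploid pair of rows
    site_pos_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.site_chrom = np.asarray(self.site_chrom, dtype=object)
        self.site_pos_bp = np.asarray(self.site_pos_bp, dtype=np.int64)
        if self.site_pos_cM is not None:
            self.site_pos_cM = np.asarray(self.site_pos_cM, dtype=float)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        for chrom in self.chromosomes():
            pos = self.site_pos_bp[self.site_chrom == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"bp positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.site_chrom))

    def chrom_mask(self, chrom) -> np.ndarray:
        return np.asarray(self.site_chrom == chrom)

    def require_cM(self) -> np.ndarray:
        if self.site_pos_cM is None:
            raise ValueError("alignment has no cM coordinates; apply annotate_cM first")
        return self.site_pos_cM

    def subset_haplotypes(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        index = {h: i for i, h in enumerate(self.haplotype_ids)}
        rows = [index[i] for i in ids]
        return replace(
            self,
            haplotypes=self.haplotypes[rows],
            haplotype_ids=list(ids),
            sample_ids=[],
        )


@dataclass
class GeneticMap:
    """Cumulative genetic map for one chromosome: bp -> cM."""

    chrom: object
    pos_bp: np.ndarray
    map_cM: np.ndarray

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.map_cM = np.asarray(self.map_cM, dtype=float)
        if self.pos_bp.shape != self.map_cM.shape:
            raise ValueError("pos_bp and map_cM must have equal length")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("map bp positions must be strictly increasing")
        if self.map_cM[0] < 0 or np.any(np.diff(self.map_cM) < 0):
            raise ValueError("map_cM must be non-negative and non-decreasing")

    def interpolate(self, pos_bp: np.ndarray) -> np.ndarray:
        """Piecewise-linear cM at ``pos_bp``, extrapolating the end intervals."""
        pos_bp = np.asarray(pos_bp, dtype=float)
        out = np.interp(pos_bp, self.pos_bp, self.map_cM)
        if len(self.pos_bp) >= 2:
            lo_slope = (self.map_cM[1] - self.map_cM[0]) / (self.pos_bp[1] - self.pos_bp[0])
            hi_slope = (self.map_cM[-1] - self.map_cM[-2]) / (self.pos_bp[-1] - self.pos_bp[-2])
            below = pos_bp < self.pos_bp[0]
            above = pos_bp > self.pos_bp[-1]
            out[below] = self.map_cM[0] + (pos_bp[below] - self.pos_bp[0]) * lo_slope
            out[above] = self.map_cM[-1] + (pos_bp[above] - self.pos_bp[-1]) * hi_slope
        return out


@dataclass
class GroupAssignment:
    """Maps haplotype/sample identifiers to group labels."""

    assignment: dict
    groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = list(pd.unique(np.asarray(list(self.assignment.values()), dtype=object)))
        sizes = {g: 0 for g in self.groups}
        for g in self.assignment.values():
            if g not in sizes:
                raise ValueError(f"group {g!r} missing from group list")
            sizes[g] += 1
        self.sizes = sizes
        if any(n < 1 for n in sizes.values()):
            raise ValueError("every group must have at least one member")

    def group_of(self, ident):
        return self.assignment[ident]

    def members(self, group) -> list:
        return [i for i, g in self.assignment.items() if g == group]


# ---------------------------------------------------------------------------
# Haplotype readers / writers
# ---------------------------------------------------------------------------

def read_haplotypes(path, format: str = "vcf") -> HaplotypeAlignment:
    """Read a phased biallelic haplotype panel from VCF or the haps dialect.

    VCF genotypes must be phased (``|`` separator) and biallelic; unphased,
    missing or multi-allelic records are hard errors except X/Y/MT records,
    which are skipped with a warning (only autosomes are analysed).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "haps":
        return _read_haps(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path) -> HaplotypeAlignment:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, rows = [], [], []
    n_skipped = 0
    for variant in vcf:
        if variant.CHROM in _NON_AUTOSOMES:
            n_skipped += 1
            continue
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {variant.CHROM}:{variant.POS} is not supported"
            )
        alleles = np.empty(2 * len(samples), dtype=np.int16)
        for j, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[j]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[j]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            alleles[2 * j] = a
            alleles[2 * j + 1] = b
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        rows.append(alleles)
    if n_skipped:
        logger.warning("skipped %d non-autosomal VCF records", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic autosomal records in {path}")
    hap_ids = [f"{s}_{ab}" for s in samples for ab in "AB"]
    return HaplotypeAlignment(
        haplotypes=np.asarray(rows, dtype=np.uint8).T,
        site_chrom=np.asarray(chroms, dtype=object),
        site_pos_bp=np.asarray(positions, dtype=np.int64),
        haplotype_ids=hap_ids,
        sample_ids=samples,
    )


def _read_haps(path) -> HaplotypeAlignment:
    hap_ids: list[str] | None = None
    sample_ids: list[str] = []
    chroms, positions, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#haplotypes"):
                hap_ids = line.split()[1:]
                continue
            if line.startswith("#samples"):
                sample_ids = line.split()[1:]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            chrom, _site_id, bp = parts[0], parts[1], int(parts[2])
            alleles = parts[5:]
            chroms.append(chrom)
            positions.append(bp)
            rows.append([int(a) for a in alleles])
    if not rows:
        raise ValueError(f"no sites in haps file {path}")
    n_hap = len(rows[0])
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(n_hap)]
    return HaplotypeAlignment(
        haplotypes=np.asarray(rows, dtype=np.uint8).T,
        site_chrom=np.asarray(chroms, dtype=object),
        site_pos_bp=np.asarray(positions, dtype=np.int64),
        haplotype_ids=hap_ids,
        sample_ids=sample_ids,
    )


def write_haps(aln: HaplotypeAlignment, path) -> None:
    """Write the whitespace-separated haps dialect (one site per line)."""
    with open(path, "w") as fh:
        fh.write("#haplotypes " + " ".join(aln.haplotype_ids) + "\n")
        if aln.sample_ids:
            fh.write("#samples " + " ".join(aln.sample_ids) + "\n")
        for j in range(aln.n_sites):
            chrom = aln.site_chrom[j]
            bp = aln.site_pos_bp[j]
            cols = " ".join(str(int(a)) for a in aln.haplotypes[:, j])
            fh.write(f"{chrom} {chrom}:{bp} {bp} 0 1 {cols}\n")


def annotate_cM(aln: HaplotypeAlignment, maps: Mapping | Iterable[GeneticMap]) -> HaplotypeAlignment:
    """Fill ``site_pos_cM`` by piecewise-linear interpolation of the genetic map.

    ``maps`` is a mapping chrom -> :class:`GeneticMap` (or an iterable of
    maps).  Idempotent; a chromosome without a map is a hard error.
    """
    if not isinstance(maps, Mapping):
        maps = {m.chrom: m for m in maps}
    cM = np.empty(aln.n_sites, dtype=float)
    for chrom in aln.chromosomes():
        if chrom not in maps:
            raise ValueError(f"chromosome {chrom!r} absent from genetic map")
        mask = aln.chrom_mask(chrom)
        cM[mask] = maps[chrom].interpolate(aln.site_pos_bp[mask])
    return replace(aln, site_pos_cM=cM)


def read_genetic_map(path) -> dict:
    """Read a genetic map TSV (chrom, pos_bp, map_cM) into per-chromosome maps."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = GeneticMap(chrom, sub["pos_bp"].to_numpy(), sub["map_cm"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Small-table readers
# ---------------------------------------------------------------------------

def read_group_table(path) -> GroupAssignment:
    """Two-column TSV (id, group) -> :class:`GroupAssignment`."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("group table needs columns: id, group")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicated id {dup!r} in group table")
    return GroupAssignment(dict(zip(ids, df.iloc[:, 1].astype(str))))


def read_str_table(path):
    """Read a Y-STR repeat-count TSV: id, haplogroup[, population], loci...

    Every repeat count must be a positive integer; a missing cell or a
    duplicated id is a hard error (no imputation anywhere in the package).
    """
    from .uniparental import STRHaplotypeSet

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["id", "haplogroup"]:
        raise ValueError("STR table must start with columns: id, haplogroup")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated id {dup!r} in STR table")
    populations = None
    locus_start = 2
    if len(cols) > 2 and cols[2] == "population":
        populations = df["population"].tolist()
        locus_start = 3
    loci = cols[locus_start:]
    if not loci:
        raise ValueError("STR table has no STR locus columns")
    repeats = np.empty((len(df), len(loci)), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, val in enumerate(df[locus]):
            try:
                repeats[i, j] = int(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer repeat count at id {df['id'].iloc[i]!r}, locus {locus!r}"
                ) from None
    return STRHaplotypeSet(
        repeats=repeats,
        loci=loci,
        haplogroups=df["haplogroup"].tolist(),
        populations=populations,
        ids=df["id"].tolist(),
    )


def read_haplogroup_counts(path):
    """Population x category count TSV (first column = population)."""
    from .uniparental import HaplogroupCounts

    df = pd.read_csv(path, sep="\t", index_col=0)
    return HaplogroupCounts(df.astype(np.int64))


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
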