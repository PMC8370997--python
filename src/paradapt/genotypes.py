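"""Ploidy-aware genotype matrices, VCF ingestion and site filtering.

Genotypes are stored as allele dosages: for a tetraploid individual the
dosage at a biallelic SNP is the number of alternate alleles in the call,
an integer in 0..4. Missing calls are encoded as ``MISSING`` (-1).

The ingestion path applies the study-style per-genotype depth filter
(DP > ``min_depth`` per individual, failing calls set to missing) and the
per-site missingness cap (maximum fraction of filtered genotypes, MFFG):
sites where more than ``max_missing_fraction`` of individuals are missing
after the depth filter are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class SiteFilterConfig:
    """Site/genotype filtering thresholds.

    min_depth: per-individual read-depth requirement; genotypes with
        DP <= min_depth are set to missing (the study keeps DP > 8).
    max_missing_fraction: maximum fraction of missing genotypes per site
        (MFFG); sites above it are dropped.
    maf_min: stage-local minor-allele-frequency floor (0 disables).
    depth_mask_sd: sites with mean depth > global mean + this multiplier
        times the global SD are masked (putative duplicated regions).
    het_excess_threshold: sites where the fraction of heterozygous calls
        (dosage not in {0, ploidy}) exceeds this are masked (putative
        paralogous mis-assembly).
    """

    min_depth: int = 8
    max_missing_fraction: float = 0.2
    maf_min: float = 0.0
    depth_mask_sd: float = 2.0
    het_excess_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix for one cohort of polysomic individuals.

    Attributes
    ----------
    individuals : list of str
        Sample identifiers, order matches rows of ``dosage``.
    pop_of : dict
        Individual -> population identifier.
    ploidy : int
        Number of allele copies per individual (4 for autotetraploids).
    sites : pandas.DataFrame
        Columns chrom, pos (1-based), ref, alt; strictly sorted by
        (chrom, pos); one row per retained biallelic SNP.
    dosage : ndarray, shape (n_individuals, n_sites)
        Integer alt-allele counts in {0..ploidy} or MISSING.
    depth : ndarray or None
        Per-call read depth, same shape as dosage.
    """

    individuals: list[str]
    pop_of: dict[str, str]
    ploidy: int
    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("dosage shape does not match individuals x sites")
        valid = (self.dosage == MISSING) | (
            (self.dosage >= 0) & (self.dosage <= self.ploidy)
        )
        if not valid.all():
            raise ValueError("dosage values outside {0..ploidy} u {MISSING}")
        missing_pop = [i for i in self.individuals if i not in self.pop_of]
        if missing_pop:
            raise ValueError(f"individuals without population: {missing_pop}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.pop_of[ind], None)
        return list(seen)

    def individuals_of(self, pop: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``pop``."""
        return np.array(
            [k for k, ind in enumerate(self.individuals) if self.pop_of[ind] == pop],
            dtype=int,
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        return GenotypeMatrix(
            individuals=self.individuals,
            pop_of=self.pop_of,
            ploidy=self.ploidy,
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[:, index],
        )


def read_population_map(path: str) -> dict[str, str]:
    """Read a two-column individual<TAB>population map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["individual"], df["population"]))


def read_tetraploid_vcf(
    path: str,
    pop_of: dict[str, str],
    filter: SiteFilterConfig | None = None,
    ploidy: int = 4,
) -> GenotypeMatrix:
    """Read a multi-sample VCF with polysomic GT calls into a GenotypeMatrix.

    Only biallelic SNP records are retained. Per-genotype DP filtering and
    the MFFG site cap from ``filter`` are applied. A mixed-ploidy GT or an
    unsorted VCF raises ``ValueError`` naming the offending record.
    """
    from cyvcf2 import VCF

    if filter is None:
        filter = SiteFilterConfig()

    vcf = VCF(path, gts012=False)
    individuals = list(vcf.samples)
    n_ind = len(individuals)
    max_miss = filter.max_missing_fraction

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    have_depth = True
    last: tuple[str, int] | None = None
    chrom_seen: set[str] = set()

    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        if rec.ALT[0] not in "ACGT" or rec.REF not in "ACGT":
            continue
        key = (rec.CHROM, rec.POS)
        if last is not None:
            if rec.CHROM == last[0] and rec.POS < last[1]:
                raise ValueError(f"unsorted VCF at {rec.CHROM}:{rec.POS}")
            if rec.CHROM != last[0] and rec.CHROM in chrom_seen:
                raise ValueError(f"unsorted VCF: chromosome {rec.CHROM} interleaved")
        chrom_seen.add(rec.CHROM)
        last = key

        gts = rec.genotype.array()  # (n_ind, ploidy + 1), last col = phasing
        alleles = gts[:, :-1]
        if alleles.shape[1] != ploidy:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} has ploidy {alleles.shape[1]}, "
                f"expected {ploidy}"
            )
        miss = (alleles < 0).any(axis=1)
        dos = np.where(miss, MISSING, (alleles == 1).sum(axis=1)).astype(np.int16)

        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            have_depth = False
            dpcol = np.full(n_ind, -1, dtype=np.int32)
        else:
            dpcol = dp.reshape(-1).astype(np.int32)
            low = dpcol <= filter.min_depth
            dos[low] = MISSING
        if (dos == MISSING).mean() > max_miss:
            continue

        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dosage_cols.append(dos)
        depth_cols.append(dpcol)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.empty((n_ind, 0), dtype=np.int16)
    )
    depth = (
        np.stack(depth_cols, axis=1)
        if (depth_cols and have_depth)
        else None
    )
    pop_of = {ind: pop for ind, pop in pop_of.items() if ind in set(individuals)}
    return GenotypeMatrix(
        individuals=individuals,
        pop_of=pop_of,
        ploidy=ploidy,
        sites=sites,
        dosage=dosage,
        depth=depth,
    )


def depth_het_mask(gm: GenotypeMatrix, filter: SiteFilterConfig) -> np.ndarray:
    """Boolean site mask for excess-depth and excess-heterozygosity sites.

    A site is masked when its cross-individual mean depth exceeds the
    global mean by more than ``depth_mask_sd`` standard deviations (of the
    per-site means), or when the fraction of heterozygous calls (dosage
    not in {0, ploidy}) among non-missing calls exceeds
    ``het_excess_threshold``.
    """
    n_sites = gm.n_sites
    mask = np.zeros(n_sites, dtype=bool)

    if gm.depth is not None:
        site_mean = np.where(gm.depth >= 0, gm.depth, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            site_mean = np.nanmean(site_mean, axis=0)
        mu = np.nanmean(site_mean)
        sd = np.nanstd(site_mean)
        mask |= site_mean > mu + filter.depth_mask_sd * sd
    else:
        logger.warning("no depth data: applying heterozygosity mask only")

    obs = gm.dosage != MISSING
    het = obs & (gm.dosage != 0) & (gm.dosage != gm.ploidy)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_obs > 0, het.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    mask |= het_frac > filter.het_excess_threshold
    return mask


@dataclass
class AlleleFreqTable:
    """Per-population allele counts and frequencies at each site.

    alt_copies[p, k] is the summed alt dosage of population p at site k
    over non-missing individuals; sampled_copies[p, k] = ploidy times the
    non-missing count. freq = alt_copies / sampled_copies, NaN where no
    copies were sampled (undefined, excluded downstream).
    """

    populations: list[str]
    sites: pd.DataFrame
    alt_copies: np.ndarray
    sampled_copies: np.ndarray
    freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore", divide="ignore"):
            self.freq = np.where(
                self.sampled_copies > 0,
                self.alt_copies / np.maximum(self.sampled_copies, 1),
                np.nan,
            )

    def pop_index(self, pop: str) -> int:
        return self.populations.index(pop)


def allele_frequencies(gm: GenotypeMatrix, pops: list[str] | None = None) -> AlleleFreqTable:
    """Per-population alt-allele counts/frequencies from dosages."""
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    if pops is None:
        pops = gm.populations
    n_pops = len(pops)
    alt = np.zeros((n_pops, gm.n_sites), dtype=np.int64)
    tot = np.zeros((n_pops, gm.n_sites), dtype=np.int64)
    for p, pop in enumerate(pops):
        rows = gm.individuals_of(pop)
        sub = gm.dosage[rows]
        obs = sub != MISSING
        alt[p] = np.where(obs, sub, 0).sum(axis=0)
        tot[p] = gm.ploidy * obs.sum(axis=0)
    return AlleleFreqTable(
        populations=list(pops), sites=gm.sites.copy(), alt_copies=alt, sampled_copies=tot
    )
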