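"""Windowed differentiation and diversity statistics for polysomic samples.

F_ST uses Hudson's unbiased per-SNP estimator aggregated as a ratio of
averages over each fixed 1-kbp window (Bhatia-style aggregation), which is
robust to unequal and varying sample sizes. Nucleotide diversity and
Tajima's D are computed on a fixed number of allele copies per site
(six individuals = 24 copies for tetraploids by default) so that sample
size is homogeneous across populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFreqTable, GenotypeMatrix

logger = logging.getLogger(__name__)

TAJIMA_UNDEFINED = float("nan")


@dataclass
class DiversityStat:
    population: str
    pi: float
    tajimas_d: float
    n_sites: int
    downsample_individuals: int


def hudson_fst_components(
    p1: np.ndarray, p2: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson numerator and denominator.

    N = (p1-p2)^2 - p1(1-p1)/(a1-1) - p2(1-p2)/(a2-1)
    D = p1(1-p2) + p2(1-p1)

    a1, a2 are sampled allele-copy counts. SNPs with a <= 1 in either
    population yield NaN components (skipped by callers).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (a1 - 1)
            - p2 * (1 - p2) / (a2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (a1 <= 1) | (a2 <= 1)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def window_of(pos: np.ndarray, window_size: int) -> np.ndarray:
    """0-based window start for each 1-based position (windows anchored at 0)."""
    return ((np.asarray(pos) - 1) // window_size) * window_size


def hudson_fst_windows(
    af: AlleleFreqTable,
    pair: tuple[str, str],
    window_size: int = 1000,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Windowed Hudson F_ST for one population pair.

    Non-overlapping windows of ``window_size`` bp tile each chromosome from
    position 0. Only sites variable in at least one of the two populations
    (and with defined frequencies in both) count toward n_snps. Windows
    with fewer than ``min_snps`` such SNPs carry fst = NaN.

    Returns a DataFrame with columns chrom, start, end, n_snps, fst
    (0-based half-open coordinates).
    """
    i1, i2 = af.pop_index(pair[0]), af.pop_index(pair[1])
    p1, p2 = af.freq[i1], af.freq[i2]
    a1, a2 = af.sampled_copies[i1], af.sampled_copies[i2]

    defined = ~np.isnan(p1) & ~np.isnan(p2)
    variable = defined & (((p1 > 0) | (p2 > 0)) & ((p1 < 1) | (p2 < 1)))
    num, den = hudson_fst_components(p1, p2, a1, a2)
    usable = variable & ~np.isnan(num)
    skipped = variable & np.isnan(num)
    if skipped.any():
        logger.warning("%d SNPs skipped (a <= 1 allele copies)", int(skipped.sum()))

    sites = af.sites
    start = window_of(sites["pos"].to_numpy(), window_size)
    key = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "start": start,
            "num": np.where(usable, num, 0.0),
            "den": np.where(usable, den, 0.0),
            "n": usable.astype(int),
        }
    )
    agg = key.groupby(["chrom", "start"], sort=True).sum().reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(
            (agg["n"] >= min_snps) & (agg["den"] > 0),
            agg["num"] / agg["den"],
            np.nan,
        )
    return pd.DataFrame(
        {
            "chrom": agg["chrom"],
            "start": agg["start"].astype(int),
            "end": (agg["start"] + window_size).astype(int),
            "n_snps": agg["n"].astype(int),
            "fst": fst,
        }
    )


def _pop_counts(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies, sampled copies, non-missing individual count) per site."""
    rows = gm.individuals_of(pop)
    sub = gm.dosage[rows]
    obs = sub != MISSING
    alt = np.where(obs, sub, 0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    return alt, n_obs


def nucleotide_diversity(
    gm: GenotypeMatrix,
    pop: str,
    downsample_individuals: int = 6,
    seed: int | None = None,
    return_stat: bool = False,
) -> float | DiversityStat:
    """Per-site nucleotide diversity π for one population.

    Sites with fewer than ``downsample_individuals`` non-missing
    individuals are excluded from numerator and denominator; invariant
    sites among the retained ones enter the denominator. Per retained
    site, π is the unbiased pairwise-difference estimator
    2·alt·ref/(a(a−1)) on the available a allele copies — the exact
    expectation of the estimator over every possible
    ``downsample_individuals``-subset, hence deterministic (seed is
    accepted for interface symmetry but does not influence the value).
    """
    del seed  # estimator is the exact mean over subsamples; see docstring
    alt, n_obs = _pop_counts(gm, pop)
    keep = n_obs >= downsample_individuals
    a = gm.ploidy * n_obs[keep]
    alt_k = alt[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = 2.0 * alt_k * (a - alt_k) / (a * (a - 1.0))
    pi = float(per_site.mean()) if keep.sum() else 0.0
    if return_stat:
        return DiversityStat(
            population=pop,
            pi=pi,
            tajimas_d=TAJIMA_UNDEFINED,
            n_sites=int(keep.sum()),
            downsample_individuals=downsample_individuals,
        )
    return pi


def tajimas_d_from_counts(alt: np.ndarray, n_copies: int) -> float:
    """Tajima's D from per-site alt-copy counts at a fixed sample size.

    ``alt`` holds alt allele-copy counts (0..n_copies) at every included
    site; sites with 0 < alt < n_copies are segregating. Returns NaN when
    no site segregates.
    """
    alt = np.asarray(alt)
    n = int(n_copies)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return TAJIMA_UNDEFINED
    k = alt[seg].astype(float)
    pi_total = float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))))

    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi_total - S / a1) / np.sqrt(var)


def tajimas_d(
    gm: GenotypeMatrix,
    pop: str,
    downsample_individuals: int = 6,
    seed: int = 0,
) -> float:
    """Tajima's D for one population at a fixed downsampled size.

    Allele copies are downsampled per site to ploidy × downsample
    individuals by a seeded hypergeometric draw (without replacement) so
    the segregating-site count refers to one common sample size. Sites
    with fewer non-missing individuals are excluded. NaN when nothing
    segregates in the downsampled set.
    """
    alt, n_obs = _pop_counts(gm, pop)
    keep = n_obs >= downsample_individuals
    if not keep.any():
        return TAJIMA_UNDEFINED
    n_target = gm.ploidy * downsample_individuals
    a_full = gm.ploidy * n_obs[keep]
    alt_k = alt[keep]
    rng = np.random.default_rng(seed)
    need = a_full > n_target
    sub = alt_k.astype(np.int64).copy()
    if need.any():
        sub[need] = rng.hypergeometric(alt_k[need], a_full[need] - alt_k[need],
                                       n_target)
    return tajimas_d_from_counts(sub, n_target)


# --- fourfold-degenerate site calling -------------------------------------

_BASES = "ACGT"


def _fourfold_prefixes() -> set[str]:
    """Two-base codon prefixes whose third position is fourfold degenerate."""
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    prefixes = set()
    for b1 in _BASES:
        for b2 in _BASES:
            aas = {table[b1 + b2 + b3] for b3 in _BASES}
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(b1 + b2)
    return prefixes


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def fourfold_degenerate_sites(
    reference: str, annotation: str
) -> set[tuple[str, int]]:
    """Genomic positions (chrom, 1-based pos) of fourfold-degenerate sites.

    Walks every CDS chain in the GFF3 (grouped by parent transcript,
    phase- and strand-aware) and marks third codon positions whose codon
    prefix encodes the same amino acid for all four third bases.
    Positions claimed by CDS chains in conflicting frames are excluded.
    Transcripts whose phase-adjusted CDS length is not a multiple of 3
    are skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    fa = Fasta(reference)
    db = gffutils.create_db(
        annotation, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    prefixes = _fourfold_prefixes()

    fourfold: set[tuple[str, int]] = set()
    conflict: set[tuple[str, int]] = set()
    claimed: dict[tuple[str, int], bool] = {}

    cds_by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "cds"])[0]
        cds_by_parent.setdefault(parent, []).append(cds)

    for parent, parts in cds_by_parent.items():
        strand = parts[0].strand
        parts.sort(key=lambda c: c.start, reverse=(strand == "-"))
        coords: list[tuple[str, int]] = []
        seq_parts: list[str] = []
        for c in parts:
            s = str(fa[c.seqid][c.start - 1 : c.end])
            positions = list(range(c.start, c.end + 1))
            if strand == "-":
                s = s.translate(_COMPLEMENT)[::-1]
                positions = positions[::-1]
            seq_parts.append(s.upper())
            coords.extend((c.seqid, p) for p in positions)
        seq = "".join(seq_parts)
        phase = parts[0].frame
        offset = int(phase) if phase not in (None, ".") else 0
        seq = seq[offset:]
        coords = coords[offset:]
        if len(seq) % 3 != 0:
            logger.warning("CDS %s length %d not divisible by 3; skipped",
                           parent, len(seq))
            continue
        for i in range(0, len(seq) - 2, 3):
            codon_ff = seq[i : i + 2] in prefixes
            for j in range(3):
                pos = coords[i + j]
                is_ff = codon_ff and j == 2
                if pos in claimed and claimed[pos] != is_ff:
                    conflict.add(pos)
                claimed[pos] = is_ff
                if is_ff:
                    fourfold.add(pos)

    return fourfold - conflict
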