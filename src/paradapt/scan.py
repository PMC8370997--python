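"""Outlier-window candidate gene lists and multi-list intersection tests.

The scan identifies, per population pair, the 1-kbp windows in the upper
tail of the empirical F_ST distribution, maps them to overlapping gene
models (full gene spans: UTRs through stop codon), and combines lists
across pairs into parallel candidates. Significance of multi-list overlap
is assessed with the hypergeometric upper tail (two lists) or an exact
product-form computation plus a seeded Monte Carlo permutation oracle
(more than two lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AlleleFreqTable
from .diversity import hudson_fst_windows, window_of

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """One gene feature: full span, 0-based half-open internally."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")


def read_gene_models(gff3: str) -> list[GeneModel]:
    """Gene features from a GFF3 file (1-based inclusive -> half-open)."""
    genes: list[GeneModel] = []
    with open(gff3) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            genes.append(
                GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    return genes


@dataclass
class CandidateSet:
    pair: str
    source: str  # "SNP" | "TE"
    genes: set[str]
    quantile_used: float = 0.99

    def __post_init__(self) -> None:
        if not 0.5 < self.quantile_used < 1.0:
            raise ValueError("quantile must be in (0.5, 1)")


def outlier_windows(
    windows: pd.DataFrame, quantile: float = 0.99
) -> pd.DataFrame:
    """Windows with F_ST at or above the empirical upper quantile.

    Operates on the eligible windows only (defined fst, i.e. enough
    SNPs). Ties at the threshold are all included. With fewer than
    1/(1-quantile) eligible windows a warning is logged and the top-1
    window (with its ties) is returned.
    """
    ok = windows.dropna(subset=["fst"])
    if ok.empty:
        return ok
    n_needed = int(round(1.0 / (1.0 - quantile)))
    if len(ok) < n_needed:
        logger.warning(
            "only %d eligible windows for quantile %.2f; returning top-1",
            len(ok), quantile,
        )
        thr = ok["fst"].max()
    else:
        thr = float(np.quantile(ok["fst"].to_numpy(), quantile))
    return ok[ok["fst"] >= thr]


def genes_for_windows(
    windows: pd.DataFrame, annotation: list[GeneModel]
) -> set[str]:
    """Genes whose span overlaps >= 1 bp of >= 1 window."""
    if windows.empty:
        return set()
    out: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, w in windows.iterrows():
        by_chrom.setdefault(w["chrom"], []).append((int(w["start"]), int(w["end"])))
    for g in annotation:
        for s, e in by_chrom.get(g.chrom, ()):
            if g.start < e and s < g.end:
                out.add(g.gene_id)
                break
    return out


def parallel_candidates(
    sets: list[CandidateSet], min_pairs: int = 2
) -> dict[str, list[str]]:
    """Genes appearing in >= min_pairs candidate sets, with supporting pairs."""
    if len(sets) < 2:
        raise ValueError("need at least two candidate sets")
    support: dict[str, list[str]] = {}
    for cs in sets:
        for g in cs.genes:
            support.setdefault(g, []).append(cs.pair)
    return {g: pairs for g, pairs in support.items() if len(pairs) >= min_pairs}


@dataclass
class IntersectionResult:
    lists: list[str]
    universe_n: int
    observed: int
    expected: float
    p_value: float
    p_monte_carlo: float | None = None
    mc_se: float | None = None
    method: str = "hypergeometric"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")


def multiset_intersection_test(
    lists: dict[str, set] | list[set],
    universe_n: int,
    mc_reps: int = 0,
    seed: int = 0,
) -> IntersectionResult:
    """One-sided test that the total intersection of r gene lists is large.

    For two lists: exact hypergeometric upper tail P[X >= k]. For r > 2
    lists: exact tail of Binomial(N, prod(|L_i|/N)) — the product-form
    per-element inclusion probability under independent uniform draws —
    and, when mc_reps > 0, a seeded Monte Carlo permutation estimate. A
    discrepancy beyond 3 Monte Carlo standard errors logs a warning.
    Expected overlap is N * prod(|L_i|/N) in every case.
    """
    if isinstance(lists, dict):
        names = list(lists)
        sets = [set(lists[n]) for n in names]
    else:
        names = [f"L{i+1}" for i in range(len(lists))]
        sets = [set(s) for s in lists]
    if any(len(s) > universe_n for s in sets):
        raise ValueError("universe_n smaller than a list")
    sizes = [len(s) for s in sets]
    k = len(set.intersection(*sets)) if sets else 0
    pi = float(np.prod([m / universe_n for m in sizes]))
    expected = universe_n * pi

    if len(sets) == 2:
        p = float(stats.hypergeom.sf(k - 1, universe_n, sizes[0], sizes[1]))
        method = "hypergeometric"
    else:
        p = float(stats.binom.sf(k - 1, universe_n, pi))
        method = "binomial-product-form"
    p = min(max(p, np.nextafter(0, 1)), 1.0)

    p_mc = se = None
    if mc_reps > 0:
        rng = np.random.default_rng(seed)
        universe = np.arange(universe_n)
        hits = 0
        for _ in range(mc_reps):
            inter: np.ndarray | None = None
            for m in sizes:
                draw = rng.choice(universe, size=m, replace=False)
                inter = draw if inter is None else np.intersect1d(inter, draw)
                if inter.size < k:
                    break
            if inter is not None and inter.size >= k:
                hits += 1
        p_mc = (hits + 1) / (mc_reps + 1)
        se = float(np.sqrt(max(p_mc * (1 - p_mc), 1e-12) / mc_reps))
        if abs(p_mc - p) > 3 * max(se, 1e-12):
            logger.warning(
                "exact (%0.3g) and Monte Carlo (%0.3g +- %0.3g) intersection "
                "p-values disagree beyond 3 SE", p, p_mc, se,
            )
    return IntersectionResult(
        lists=names, universe_n=universe_n, observed=k,
        expected=expected, p_value=p, p_monte_carlo=p_mc, mc_se=se,
        method=method,
    )


@dataclass(frozen=True)
class TEVariant:
    """One transposable-element presence/absence variant."""

    chrom: str
    pos: int  # 1-based
    kind: str  # "insertion" | "deletion"


def read_te_variants(path: str) -> list[TEVariant]:
    """TSV with columns chrom, pos, kind (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    if "chrom" not in cols:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "kind"], comment="#")
    else:
        df.columns = cols
    return [TEVariant(str(r.chrom), int(r.pos), str(r.kind))
            for r in df.itertuples()]


def te_candidate_genes(
    te: list[TEVariant],
    af: AlleleFreqTable,
    annotation: list[GeneModel],
    pair: tuple[str, str],
    window_size: int = 1000,
    min_snps: int = 10,
    quantile: float = 0.99,
    flank_bp: int = 2000,
) -> CandidateSet:
    """TE-associated candidate genes for one population pair.

    SNP-based windowed F_ST is computed as usual but the window universe
    is restricted to windows containing >= 1 TE variant; the quantile
    threshold is taken within that restricted distribution. Genes overlap
    the +-flank_bp interval around each TE in an outlier window.
    """
    wins = hudson_fst_windows(af, pair, window_size, min_snps)
    te_keys = {(t.chrom, int(window_of(np.array([t.pos]), window_size)[0]))
               for t in te}
    in_te = wins.apply(lambda w: (w["chrom"], int(w["start"])) in te_keys, axis=1)
    te_wins = wins[in_te] if len(wins) else wins
    eligible = te_wins.dropna(subset=["fst"]) if len(te_wins) else te_wins
    pair_id = f"{pair[0]}-{pair[1]}"
    if eligible.empty:
        logger.warning("no TE-containing window with >= %d SNPs", min_snps)
        return CandidateSet(pair=pair_id, source="TE", genes=set(),
                            quantile_used=quantile)
    out_wins = outlier_windows(eligible, quantile)
    out_keys = {(r["chrom"], int(r["start"])) for _, r in out_wins.iterrows()}
    genes: set[str] = set()
    for t in te:
        wkey = (t.chrom, int(window_of(np.array([t.pos]), window_size)[0]))
        if wkey not in out_keys:
            continue
        lo, hi = t.pos - flank_bp, t.pos + flank_bp  # 1-based inclusive
        for g in annotation:
            if g.chrom == t.chrom and g.start < hi and lo - 1 < g.end:
                genes.add(g.gene_id)
    return CandidateSet(pair=pair_id, source="TE", genes=genes,
                        quantile_used=quantile)


def serpentine_adaptation_candidates(
    parallel: dict[str, list[str]] | set,
    gea_genes: set[str] | dict,
) -> dict[str, dict]:
    """Final refined candidates: parallel-differentiation ∩ association.

    Returns gene -> provenance (supporting pairs, supporting variables
    where available).
    """
    par_support = (
        parallel if isinstance(parallel, dict) else {g: [] for g in parallel}
    )
    gea_support = (
        gea_genes if isinstance(gea_genes, dict) else {g: [] for g in gea_genes}
    )
    out: dict[str, dict] = {}
    for g in set(par_support) & set(gea_support):
        out[g] = {"pairs": par_support[g], "env": gea_support[g]}
    return out
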