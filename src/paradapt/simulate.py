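"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_mvn_freqs` draws per-SNP population allele frequencies
  directly from the multivariate-normal covariance model used by the
  convergence classifier (mean eps from a neutral-SFS-like density,
  covariance eps(1-eps) F'(d) under a planted scenario, binomial
  sampling to the observed allele copies). This is the model-faithful
  path used for classifier calibration and recovery tests.

* :func:`simulate_wf_pairs` runs a forward Wright-Fisher simulation of
  allele frequencies on a population tree of n_pairs regional ancestors
  (splitting from a common pool at T_regional) that each split into a
  serpentine (S) and non-serpentine (N) population at T_pair. Drift is
  binomial on A = ploidy * Ne allele copies; mutation is a reversible
  per-site flux at rate mu. Selected loci are planted under three modes
  (independent de novo, shared standing variation, migration) with a
  deterministic additive selection step in the serpentine populations
  and a star-like hitchhiking overlay that transfers the swept
  haplotype's alleles to linked SNPs with probability y(d) (shared
  haplotype for standing/migration, per-population haplotypes for de
  novo). Distinct neutral SNPs are otherwise unlinked; the simulated SNP
  panel is a thinned representation of the genome (density
  ``snp_density`` per bp), so per-bp diversity scales with the panel
  density while per-SNP statistics are at study scale.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .convergence import CoancestryMatrix, ScenarioParams, scenario_coancestry, sweep_retention
from .genotypes import AlleleFreqTable

logger = logging.getLogger(__name__)


# --- model-faithful MVN generator -----------------------------------------

def neutral_sfs_eps(n_snps: int, rng: np.random.Generator,
                    lo: float = 0.02, hi: float = 0.98) -> np.ndarray:
    """Ancestral frequencies from a 1/x density truncated to [lo, hi]."""
    u = rng.uniform(size=n_snps)
    return lo * (hi / lo) ** u


def simulate_mvn_freqs(
    F0: CoancestryMatrix | np.ndarray,
    params: ScenarioParams,
    n_snps: int,
    positions: np.ndarray,
    site_position: float,
    copies: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Sample allele frequencies under the covariance model.

    Returns an (n_snps, M) matrix of sample frequencies at the given
    positions, with the planted scenario's selected site at
    ``site_position``. ``copies`` gives sampled allele copies per
    population (binomial sampling layer).
    """
    F = F0.F if isinstance(F0, CoancestryMatrix) else np.asarray(F0, float)
    M = F.shape[0]
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != n_snps:
        raise ValueError("positions length must equal n_snps")
    eps = neutral_sfs_eps(n_snps, rng)
    d = np.abs(positions - site_position)
    Fp = scenario_coancestry(F, d, params)  # (n_snps, M, M)
    # eigen-decompose per SNP; clip tiny negatives (PSD contract)
    w, V = np.linalg.eigh(Fp)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError("non-PSD scenario covariance in generator")
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)[:, None, :]
    z = rng.standard_normal((n_snps, M))
    scale = np.sqrt(eps * (1.0 - eps))
    p = eps[:, None] + scale[:, None] * np.einsum("kij,kj->ki", root, z)
    p = np.clip(p, 0.0, 1.0)
    a = np.asarray(copies, dtype=int)
    x = rng.binomial(a[None, :], p) / a[None, :]
    return x


# --- forward Wright-Fisher simulator --------------------------------------

MODES = ("IND", "STANDING", "MIG")


@dataclass
class PlantedLocus:
    """One selected gene: mode, parameters and the quartet it involves."""

    gene_index: int
    mode: str  # IND | STANDING | MIG
    quartet: tuple[int, int]  # indices of the two population pairs
    s: float = 0.05
    g: float = 0.01
    t: float = 500.0
    m: float = 1e-3
    dominance: float | None = None  # None = additive per-dosage

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown planted mode {self.mode!r}")


@dataclass
class SimConfig:
    """Study-shaped simulation conditions.

    Defaults mirror the study design: five serpentine/non-serpentine
    population pairs, eight tetraploid individuals per population,
    pair split times ~3,000 generations (within the 2,700-4,300 range of
    the system), regional splits predating them, mu = 4.3e-8 per bp per
    generation, and soil covariates with higher Mg/Ni/Co and lower Ca/Mg
    on serpentine.
    """

    n_pairs: int = 5
    n_individuals: int = 8
    ploidy: int = 4
    Ne: float = 30000.0
    T_regional: float = 4000.0
    T_pair: float = 3000.0
    mu: float = 4.3e-8
    # The fixture chromosome is a compressed stand-in for a ~50 Mbp
    # genome; per-bp recombination is scaled up by the same factor
    # (50 x 2e-8) so a sweep footprint 1/(r*tau) (~6 kbp at s=0.05)
    # occupies a realistic fraction of the simulated sequence. Downstream
    # model fits must use the same value.
    r_bp: float = 1e-6
    L: int = 1_000_000
    n_genes: int = 50
    gene_length: int = 4000
    snp_density: float = 0.04  # simulated SNP panel density per bp
    freq_min: float | None = None  # SFS truncation; None = 1/A
    planted: list[PlantedLocus] = field(default_factory=list)
    te_density: float = 2e-4  # TE variants per bp
    te_planted_fraction: float = 0.2
    env_effect: float = 1.0   # scales the S-vs-N soil contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_pair >= self.T_regional:
            raise ValueError("T_pair must be < T_regional")
        for rate in (self.mu, self.r_bp):
            if not 0 < rate < 1:
                raise ValueError("rates must be in (0, 1)")

    @property
    def copies(self) -> int:
        return int(self.ploidy * self.Ne)

    @property
    def sfs_min(self) -> float:
        return self.freq_min if self.freq_min is not None else 1.0 / self.copies

    def pi_target(self) -> float:
        """Analytic per-simulated-site diversity target.

        E[2p(1-p)] under the truncated 1/x initialisation, decayed by
        drift over T_regional generations: exp(-T_regional / A).
        """
        a, b = self.sfs_min, 1.0 - self.sfs_min
        C = 1.0 / np.log(b / a)
        e0 = 2.0 * C * (b - a - (b**2 - a**2) / 2.0)
        return float(e0 * np.exp(-self.T_regional / self.copies))

    def expected_neutral_fst(self) -> float:
        """Split-model expectation T_pair / (T_pair + A)."""
        return self.T_pair / (self.T_pair + self.copies)


def _drift(p: np.ndarray, A: int, mu: float, gens: int,
           rng: np.random.Generator, chunk: int = 1) -> np.ndarray:
    """Binomial Wright-Fisher drift with reversible mutation flux."""
    del chunk
    for _ in range(int(gens)):
        if mu > 0:
            p = p * (1.0 - mu) + (1.0 - p) * mu
        p = rng.binomial(A, p) / A
    return p


def _select_step(p: float, s: float, ploidy: int) -> float:
    """One generation of deterministic additive per-dosage selection.

    Marginal fitness of the allele is 1 + s per copy relative to the
    alternative, giving the haploid-equivalent update on allele
    frequency (adequate for additive dosage effects in polysomic
    populations).
    """
    del ploidy
    return p * (1.0 + s) / (1.0 + s * p)


def _sweep_forward(p0: float, s: float, A: int, gens: int, ploidy: int,
                   rng: np.random.Generator,
                   migrant: tuple[float, np.ndarray] | None = None
                   ) -> np.ndarray:
    """Trajectory of a selected allele: selection then binomial drift.

    ``migrant``: optional (m, source trajectory) adding m*(p_src - p)
    per generation before selection. Returns the full trajectory
    (gens + 1 values).
    """
    traj = np.empty(int(gens) + 1)
    traj[0] = p = p0
    for gen in range(int(gens)):
        if migrant is not None:
            m, src = migrant
            p = p + m * (src[gen] - p)
        p = _select_step(p, s, ploidy)
        p = rng.binomial(A, p) / A
        traj[gen + 1] = p
    return traj


@dataclass
class SimBundle:
    """Outputs of one forward simulation run."""

    config: SimConfig
    sites: pd.DataFrame            # chrom, pos
    freqs: np.ndarray              # (n_pops, n_snps) population freqs
    dosage: np.ndarray             # (n_individuals_total, n_snps)
    individuals: list[str]
    pop_of: dict[str, str]
    populations: list[str]
    genes: pd.DataFrame            # gene_id, chrom, start, end (0-based ho)
    env: pd.DataFrame
    te: pd.DataFrame
    truth: pd.DataFrame
    anc_freqs_at_split: np.ndarray  # (n_pairs, n_snps)


def pop_names(n_pairs: int) -> list[str]:
    out = []
    for i in range(1, n_pairs + 1):
        out += [f"S{i}", f"N{i}"]
    return out


def simulate_wf_pairs(cfg: SimConfig) -> SimBundle:
    """Forward-simulate the replicated S/N pair design. See module docs."""
    rng_root = np.random.default_rng(cfg.seed)
    streams = rng_root.spawn(6)
    rng_init, rng_drift, rng_sel, rng_sample, rng_env, rng_te = streams

    A = cfg.copies
    n_snps = int(round(cfg.L * cfg.snp_density))
    positions = np.sort(
        rng_init.choice(np.arange(1, cfg.L + 1), size=n_snps, replace=False)
    )
    chrom = "chr1"
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})

    # gene models: evenly spaced across the chromosome
    gaps = cfg.L // cfg.n_genes
    gene_rows = []
    for gi in range(cfg.n_genes):
        start = gi * gaps + (gaps - cfg.gene_length) // 2
        gene_rows.append(
            {"gene_id": f"gene{gi+1:03d}", "chrom": chrom,
             "start": start, "end": start + cfg.gene_length}
        )
    genes = pd.DataFrame(gene_rows)

    # ancestral frequencies, truncated 1/x SFS
    p_anc = neutral_sfs_eps(n_snps, rng_init, cfg.sfs_min, 1 - cfg.sfs_min)

    # regional ancestors drift independently T_regional - T_pair gens
    t_reg = int(cfg.T_regional - cfg.T_pair)
    p_regional = np.tile(p_anc, (cfg.n_pairs, 1))
    p_regional = _drift(p_regional, A, cfg.mu, t_reg, rng_drift)
    anc_at_split = p_regional.copy()

    # each pair splits into S and N; drift T_pair generations
    pops = pop_names(cfg.n_pairs)
    p_leaf = np.empty((2 * cfg.n_pairs, n_snps))
    for i in range(cfg.n_pairs):
        p_leaf[2 * i] = p_regional[i]      # S_i
        p_leaf[2 * i + 1] = p_regional[i]  # N_i
    p_leaf = _drift(p_leaf, A, cfg.mu, int(cfg.T_pair), rng_drift)

    # --- planted selected loci -------------------------------------------
    truth_rows = []
    for locus in cfg.planted:
        g = genes.iloc[locus.gene_index]
        pair_i, pair_j = locus.quartet
        sel_pops = [2 * pair_i, 2 * pair_j]  # S rows
        tau = np.log(A * locus.s) / locus.s
        gene_snps = np.flatnonzero(
            (positions > g["start"]) & (positions <= g["end"])
        )
        if gene_snps.size == 0:
            raise ValueError(f"no SNPs inside planted gene {g['gene_id']}")

        if locus.mode == "STANDING":
            site = int(gene_snps[gene_snps.size // 2])
            # shared ancestral allele standing at g for t generations in
            # both regional ancestors, then swept in the S populations;
            # the N populations carry it neutrally
            writes = _planted_standing(cfg, locus, site, sel_pops,
                                       anc_at_split, rng_sel)
            site_of_pop = {sp: site for sp in sel_pops}
        elif locus.mode == "MIG":
            site = int(gene_snps[gene_snps.size // 2])
            writes = _planted_migration(cfg, locus, site, sel_pops, rng_sel)
            site_of_pop = {sp: site for sp in sel_pops}
        else:  # IND: distinct de novo sites, one per selected population
            k = gene_snps.size
            sel_sites = [int(gene_snps[k // 3]), int(gene_snps[2 * k // 3])]
            if sel_sites[0] == sel_sites[1]:
                raise ValueError("IND planting needs >= 2 SNPs in the gene")
            writes = {}
            for sp, st in zip(sel_pops, sel_sites):
                writes[(sp, st)] = _denovo_sweep(
                    cfg, locus.s, int(cfg.T_pair), rng_sel
                )
            site_of_pop = dict(zip(sel_pops, sel_sites))

        # the planted allele is absent outside the populations written
        # below (it postdates, or did not spread beyond, the quartet)
        for st in {st for (_, st) in writes}:
            p_leaf[:, st] = 0.0
        for (prow, st), freq in writes.items():
            p_leaf[prow, st] = freq

        # star-like hitchhiking overlay in the swept populations: a SNP
        # at distance d keeps the swept haplotype's allele w.p. y(d)*q
        shared_hap_rng = np.random.default_rng(
            (cfg.seed, 7, locus.gene_index, 999)
        )
        h_shared = shared_hap_rng.binomial(
            1, anc_at_split[sel_pops[0] // 2]
        ).astype(float)
        for sp in sel_pops:
            st = site_of_pop[sp]
            q = p_leaf[sp, st]
            d = np.abs(positions - positions[st]).astype(float)
            y = np.exp(-cfg.r_bp * d * tau)
            if locus.mode == "IND":
                hap_rng = np.random.default_rng(
                    (cfg.seed, 7, locus.gene_index, sp)
                )
                h = hap_rng.binomial(1, anc_at_split[sp // 2]).astype(float)
            else:
                h = h_shared
            pull = y * q
            mask = np.arange(n_snps) != st
            p_leaf[sp, mask] = (
                pull[mask] * h[mask] + (1.0 - pull[mask]) * p_leaf[sp, mask]
            )

        for sp in sel_pops:
            st = site_of_pop[sp]
            truth_rows.append(
                {
                    "gene_id": g["gene_id"],
                    "mode": locus.mode,
                    "pop": pops[sp],
                    "site_pos": int(positions[st]),
                    "s": locus.s, "g": locus.g, "t": locus.t, "m": locus.m,
                    "pair_i": pair_i + 1, "pair_j": pair_j + 1,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "mode", "pop", "site_pos", "s", "g", "t", "m",
                 "pair_i", "pair_j"],
    )

    assert np.all((p_leaf >= 0) & (p_leaf <= 1)), "frequency out of [0,1]"

    # --- sample individuals ----------------------------------------------
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    dosage = np.empty((cfg.n_individuals * 2 * cfg.n_pairs, n_snps),
                      dtype=np.int16)
    row = 0
    for ip, pop in enumerate(pops):
        for k in range(cfg.n_individuals):
            name = f"{pop}_ind{k+1}"
            individuals.append(name)
            pop_of[name] = pop
            dosage[row] = rng_sample.binomial(cfg.ploidy, p_leaf[ip])
            row += 1

    env = _simulate_env(cfg, individuals, pop_of, rng_env)
    te = _simulate_te(cfg, genes, truth, rng_te)

    return SimBundle(
        config=cfg, sites=sites, freqs=p_leaf, dosage=dosage,
        individuals=individuals, pop_of=pop_of, populations=pops,
        genes=genes, env=env, te=te, truth=truth,
        anc_freqs_at_split=anc_at_split,
    )


def _denovo_sweep(cfg: SimConfig, s: float, gens: int,
                  rng: np.random.Generator, p0: float | None = None,
                  max_tries: int = 500) -> float:
    """Final frequency of a de novo sweep, conditioned on establishment.

    The allele enters at one copy (1/A); runs are retried with fresh
    randomness until the final frequency exceeds 0.5, mirroring that the
    sampled populations did adapt.
    """
    A = cfg.copies
    start = (1.0 / A) if p0 is None else p0
    for _ in range(max_tries):
        traj = _sweep_forward(start, s, A, gens, cfg.ploidy, rng)
        if traj[-1] > 0.5:
            return float(traj[-1])
    raise RuntimeError("planted sweep failed to establish; raise s or gens")


def _planted_standing(cfg, locus, site, sel_pops, anc_at_split, rng):
    """Standing-variant planting: returns {(pop_row, site): final freq}.

    The shared allele stands at frequency g for t generations before the
    pair split (neutral drift in each regional ancestor), then sweeps in
    each serpentine population; the paired non-serpentine populations
    carry it neutrally from the same standing frequency (single
    mutational origin).
    """
    A = cfg.copies
    for _ in range(500):
        g_end = float(_drift(np.array([locus.g]), A, 0.0, int(locus.t),
                             rng)[0])
        if g_end <= 0.0:
            continue
        finals = [
            _sweep_forward(g_end, locus.s, A, int(cfg.T_pair), cfg.ploidy,
                           rng)[-1]
            for _ in sel_pops
        ]
        if min(finals) > 0.5:
            out = {}
            for sp, q in zip(sel_pops, finals):
                out[(sp, site)] = float(q)
                p_n = float(_drift(np.array([g_end]), A, 0.0,
                                   int(cfg.T_pair), rng)[0])
                out[(sp + 1, site)] = p_n
                anc_at_split[sp // 2, site] = g_end
            return out
    raise RuntimeError("standing-variant planting failed to sweep")


def _planted_migration(cfg, locus, site, sel_pops, rng):
    """Migration planting: sweep in src, transfer at rate m to recipient."""
    A = cfg.copies
    src, rec = sel_pops
    for _ in range(500):
        src_traj = _sweep_forward(1.0 / A, locus.s, A, int(cfg.T_pair),
                                  cfg.ploidy, rng)
        if src_traj[-1] <= 0.5:
            continue
        rec_traj = _sweep_forward(0.0, locus.s, A, int(cfg.T_pair),
                                  cfg.ploidy, rng,
                                  migrant=(locus.m, src_traj))
        if rec_traj[-1] > 0.5:
            return {(src, site): float(src_traj[-1]),
                    (rec, site): float(rec_traj[-1])}
    raise RuntimeError("migration planting failed to sweep in recipient")


# soil chemistry: serpentine means vs non-serpentine means, study-shaped
_ENV_MEANS = {
    # variable: (N mean, S mean, pair-effect SD, individual SD)
    "CaMg": (4.0, 0.8, 0.4, 0.5),
    "Mg": (100.0, 300.0, 25.0, 30.0),
    "Ni": (5.0, 120.0, 15.0, 12.0),
    "Co": (2.0, 20.0, 2.5, 2.0),
}

ENV_VARIABLES = list(_ENV_MEANS)


def _simulate_env(cfg: SimConfig, individuals, pop_of, rng) -> pd.DataFrame:
    rows = []
    pair_effects = {
        v: rng.normal(0.0, sd_pair, size=cfg.n_pairs)
        for v, (_, _, sd_pair, _) in _ENV_MEANS.items()
    }
    for ind in individuals:
        pop = pop_of[ind]
        substrate = pop[0]
        pair = int(pop[1:]) - 1
        row = {"individual": ind, "pair": pair + 1, "substrate": substrate}
        for v, (mu_n, mu_s, _, sd_ind) in _ENV_MEANS.items():
            shift = (mu_s - mu_n) * cfg.env_effect
            mean = mu_n + (shift if substrate == "S" else 0.0)
            val = mean + pair_effects[v][pair] + rng.normal(0.0, sd_ind)
            row[v] = max(val, 0.01)
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_te(cfg: SimConfig, genes, truth, rng) -> pd.DataFrame:
    n_te = int(round(cfg.L * cfg.te_density))
    pos = rng.integers(1, cfg.L + 1, size=n_te)
    if len(truth) and cfg.te_planted_fraction > 0:
        n_pl = int(round(n_te * cfg.te_planted_fraction))
        planted_sites = truth["site_pos"].to_numpy()
        anchor = rng.choice(planted_sites, size=n_pl)
        pos[:n_pl] = np.clip(
            anchor + rng.integers(-400, 401, size=n_pl), 1, cfg.L
        )
    kinds = rng.choice(["insertion", "deletion"], size=n_te)
    df = pd.DataFrame({"chrom": "chr1", "pos": np.sort(pos), "kind": kinds})
    df["kind"] = kinds[np.argsort(pos, kind="stable")]
    return df


# --- fixture emission -----------------------------------------------------

def default_planted(n_genes: int = 50, n_pairs: int = 5) -> list[PlantedLocus]:
    """Study-shaped planting: mostly standing variation, one de novo."""
    quartets = [(0, 1), (1, 2), (2, 3), (3, 4), (2, 3)]
    modes = ["STANDING", "STANDING", "STANDING", "STANDING", "IND"]
    gene_idx = [5, 15, 25, 35, 45]
    out = []
    for gi, mode, q in zip(gene_idx, modes, quartets):
        q = (min(q[0], n_pairs - 2), min(q[1], n_pairs - 1))
        out.append(PlantedLocus(gene_index=min(gi, n_genes - 1), mode=mode,
                                quartet=q))
    return out


def tiny_config(seed: int = 0) -> SimConfig:
    """CI-scale bundle: 200 kbp, 10 genes, 2 population pairs."""
    return SimConfig(
        n_pairs=2, L=200_000, n_genes=10, seed=seed,
        planted=[
            PlantedLocus(gene_index=2, mode="STANDING", quartet=(0, 1)),
            PlantedLocus(gene_index=7, mode="IND", quartet=(0, 1)),
        ],
    )


def default_config(seed: int = 0) -> SimConfig:
    """Study-shaped bundle: 1 Mbp, 50 genes, 5 pairs, 4 standing + 1 de
    novo planted locus (the dominant-shared / single-exception design).

    Regional lineages diverge well before the recent pair splits
    (T_regional = 15,000 generations, within the autotetraploid
    lineage's history), so the five latent factors align with the five
    regional groups rather than with within-pair contrasts.
    """
    return SimConfig(seed=seed, planted=default_planted(),
                     T_regional=15000.0)


def neutral_config(seed: int = 0, n_pairs: int = 2, L: int = 50_000,
                   snp_density: float = 0.1) -> SimConfig:
    """Small neutral genome at full demographic scale, for estimator
    calibration (T_pair = 3000, A = 120,000)."""
    return SimConfig(n_pairs=n_pairs, L=L, n_genes=5,
                     snp_density=snp_density, planted=[], seed=seed)


def write_vcf(bundle: SimBundle, path: str) -> None:
    """Write a ploidy-4 VCF with GT and DP for every simulated site."""
    cfg = bundle.config
    rng = np.random.default_rng((cfg.seed, 11))
    n_ind = len(bundle.individuals)
    depth = rng.poisson(21, size=(n_ind, len(bundle.sites))) + 9
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={cfg.L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(bundle.individuals) + "\n"
        )
        gt_strings = [
            "/".join(["0"] * (cfg.ploidy - d) + ["1"] * d)
            for d in range(cfg.ploidy + 1)
        ]
        for k, (_, site) in enumerate(bundle.sites.iterrows()):
            calls = [
                f"{gt_strings[bundle.dosage[i, k]]}:{depth[i, k]}"
                for i in range(n_ind)
            ]
            fh.write(
                f"chr1\t{site['pos']}\t.\tA\tT\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(calls) + "\n"
            )


def write_gff3(bundle: SimBundle, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in bundle.genes.iterrows():
            fh.write(
                f"{g['chrom']}\tsim\tgene\t{g['start']+1}\t{g['end']}\t.\t+"
                f"\t.\tID={g['gene_id']}\n"
            )


def emit_fixture(size: str = "tiny", outdir: str = ".", seed: int = 0) -> dict:
    """Write a complete file bundle (VCF, GFF3, env/TE/truth TSVs, popmap).

    Returns a manifest dict with all paths, the seed and the config.
    """
    import os

    cfg = {"tiny": tiny_config, "default": default_config}[size](seed)
    bundle = simulate_wf_pairs(cfg)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "gff3": os.path.join(outdir, "annotation.gff3"),
        "env": os.path.join(outdir, "env.tsv"),
        "te": os.path.join(outdir, "te.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
    }
    write_vcf(bundle, paths["vcf"])
    write_gff3(bundle, paths["gff3"])
    bundle.env.to_csv(paths["env"], sep="\t", index=False)
    bundle.te.to_csv(paths["te"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["popmap"], "w") as fh:
        for ind in bundle.individuals:
            fh.write(f"{ind}\t{bundle.pop_of[ind]}\n")
    manifest = {
        "size": size, "seed": seed, "paths": paths,
        "config": {k: v for k, v in asdict(cfg).items() if k != "planted"},
        "planted": [asdict(p) for p in cfg.planted],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
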