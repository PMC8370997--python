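# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices, and the design decisions behind
`paradapt`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are allele dosages: an autotetraploid individual carries 0–4
copies of the alternate allele at a biallelic SNP. Ingestion from VCF
applies a per-genotype depth filter (calls with DP ≤ 8 become missing)
and a per-site missingness cap of 20% (MFFG), then drops non-biallelic
and non-SNP records. Optional masks remove sites with cross-individual
mean depth above the global mean + 2 SD (putative duplicated regions)
and sites with an excessive fraction of heterozygous calls (putative
paralogous mis-assembly; cutoff 0.9, configurable — no published value
exists for this threshold). Coordinates are 1-based inclusive on
input/output and 0-based half-open internally; windows anchor at
position 0 of each chromosome.

## Differentiation and diversity statistics

**Windowed F_ST.** Hudson's unbiased two-population estimator with
Bhatia-style ratio-of-averages aggregation over fixed 1-kbp windows
(≥ 10 SNPs variable in the pair; windows below the floor carry NaN).
The estimator is chosen for robustness to unequal, varying sample
sizes; negative per-window values are retained, as they fall below any
upper-quantile threshold anyway.

**π.** Per retained site (≥ 6 non-missing individuals), the unbiased
pairwise-difference estimator 2·alt·ref/(a(a−1)) on the a available
allele copies. This equals the exact expectation, over every possible
6-individual subsample, of the downsampled estimator
(Rao–Blackwellisation), so the reported π is deterministic; the
6-individual rule acts purely as the site-inclusion threshold that
keeps sample size comparable across populations. Invariant retained
sites enter the denominator and the site count is reported.

**Tajima's D.** Standard formulation at a fixed sample size of
24 allele copies (6 tetraploid individuals), obtained by a seeded
hypergeometric downsample per site — an integer segregating-site count
needs one common sample size, so here a realised (not averaged)
subsample is required. Zero segregating sites yields NaN, never 0.

**Fourfold-degenerate sites.** CDS chains are walked per transcript,
phase- and strand-aware, against the standard nuclear code; third codon
positions whose codon prefix is fourfold degenerate are reported, and
positions claimed in conflicting frames by overlapping CDS are
excluded.

## Candidate scan

Per pair, outlier windows are those at or above the empirical 99%
quantile of windowed F_ST (ties included; with fewer than 100 eligible
windows the top-1 set is returned with a warning). Genes overlap
outliers with a ≥ 1 bp rule on the full gene span (UTRs through stop
codon). Parallel candidates appear in ≥ 2 pairs; this equals the union
of all pairwise intersections, which the tests assert. Intersection
significance: exact hypergeometric upper tail for two lists; for r > 2
lists an exact product-form binomial tail plus a seeded Monte Carlo
permutation estimate — the Monte Carlo path is authoritative when the
independence assumption behind the product form is violated, and a
> 3 SE discrepancy logs a warning rather than silently preferring
either. The gene universe is the supplied annotation's gene count and
is recorded in every result. TE-associated candidates restrict the
window universe to TE-containing windows, threshold within that
restricted distribution, and attach genes within ±2 kbp of each TE in
an outlier window (flank measured from the TE position, not the window
edge).

## Association model

The genotype–environment association is a two-stage latent-factor
regression in the LFMM family: K structure factors are the first K left
singular vectors (scaled by singular values, signs fixed by the largest
loading) of the column-centered dosage matrix; each SNP is then
regressed on the centered soil variable plus the factors, and z-scores
are recalibrated by λ_GC = median(z²)/0.4549 before normal p-values and
BH q-values (π₀ = 1 by default; Storey's estimate is opt-in). The
closed-form two-stage fit is deterministic and recovers the same
decision sets as a joint ridge estimator at this scale. K defaults to
the number of population pairs and is clamped to it for smaller
designs: with K at or above the number of populations the factors span
the substrate contrast itself and no signal can remain. Each of the
four soil variables (Ca/Mg, Mg, Ni, Co) is tested separately and the
gene-level results are unioned ("at least one significant SNP for at
least one variable").

**Factor estimation set.** Factors are estimated on SNPs *outside* a
generous union of differentiation-outlier regions (per-pair windows
above the 0.95 quantile, ±10 kbp; configurable). Estimating structure
on the very loci being tested absorbs the strongest parallel signals
into the correction — on synthetic data the substrate-parallel axis
surfaces as the K-th factor and the planted genes' own SNPs are the
most absorbed. Excluding putatively selected regions mirrors the common
practice of estimating structure on pruned/neutral SNP subsets.

## Convergence-source model

For a candidate gene shared by two pairs, the quartet's sample allele
frequencies around a proposed selected site are modelled per SNP as
multivariate normal with mean the across-population average frequency ε
and covariance ε(1−ε)·C(F′(d)), where F′(d) is the neutral coancestry
matrix F₀ modified by the selection scenario at distance d, and C adds
the binomial sampling term (1−F′_ii)/a_i on the diagonal. The
likelihood is evaluated in the mean-free (M−1)-dimensional subspace via
an orthonormal Helmert contrast; summing per-SNP log-densities gives a
composite log-likelihood, valid for model comparison but not for
standard errors.

A lineage at distance d stays linked through a sweep with probability
y = exp(−r·d·τ), τ = log(A·s)/s, A = ploidy·N_e (tetraploid scaling
A = 4·N_e; the engine also runs diploid). Scenario constructors:

- *independent de novo* (ind): F′_ii = y² + (1−y²)F₀_ii for each
  selected population; all other entries unchanged. De novo sweeps
  never raise cross-population coancestry — the discriminating
  signature.
- *standing variation*: during the standing phase (duration t) linked
  lineages coalesce at rate δ = 1/(A·g) against recombination 2ρ
  (ρ = r·d); with P_coal = (δ/λ)(1−e^{−λt}), λ = δ+2ρ, the selected
  block becomes F′_ij = y²·P_coal·(1−F₀_ij) + F₀_ij (including i = j).
  Lineages that exit the standing phase unlinked or uncoalesced revert
  to the neutral coancestry F₀_ij; a deeper shared ancestry for
  surviving lineages is not modelled (no published specification
  exists), which makes the constructor conservative about cross-
  population elevation.
- *migration*: hitchhiking lineages in recipient populations trace to
  the source population with P_coal = 1/(1+2·A·m·ρ); recipient entries
  become y²[P_coal + (1−P_coal)F₀_src,src] + (1−y²)F₀_ij and the source
  diagonal sweeps as in *ind*.

All scenario outputs are symmetrised and PSD-projected (eigenvalue
clipping); the likelihood evaluates the projected 3×3 covariance
spectrally with a relative eigenvalue floor of 1e−8 — degenerate model
corners (coancestry → 1) are legal states whose density must stay
finite while mismatching data is still penalised through the quadratic
form. Selected sites are proposed at 8 equally spaced positions along
the gene body (the 25-kbp flanks contribute SNPs, not proposed sites;
configurable). Grids default to s ∈ {0.001…0.5}, g ∈ {0.001…0.1},
t ∈ {50…5000}, m ∈ {1e−5…1e−2}, r = 2×10⁻⁸/bp, N_e = 30,000 — all
configurable, and the MCL is non-decreasing under grid refinement
(asserted). Fewer than 20 usable SNPs flags the case underpowered.

**Decision rule.** Δ_S = best selection-scenario MCL minus neutral MCL
with selection in the serpentine populations. A case is *neutral* if
Δ_S ≤ 21 (a conservative threshold calibrated so that ≥ 95% of neutral
simulations stay neutral — the acceptance suite verifies this at 100
replicates). Otherwise it is *excluded as ambiguous* unless Δ_S exceeds
1.1 × Δ_N, where Δ_N is the gain of the *same* scenario with selection
placed in the non-serpentine populations. The same-scenario comparison
matters: with mean-centered quartets, joint variance inflation of the S
populations and of the N populations project onto the same contrast
axis, so the maximum over all N scenarios tracks Δ_S almost perfectly
regardless of truth; only the matched comparison isolates the
pair-contrast information that distinguishes the two hypotheses (the
max-over-scenarios value is still reported as `delta_n_max`). Standing
and migration are reported individually and collapsed to *shared
origin*, since both recruit an allele of single mutational origin;
their mutual confusion is tolerated and reported.

**Neutral coancestry estimation.** F₀ comes from genome-wide SNPs
outside candidate regions: mean-centered sample frequencies
standardised by ε(1−ε), diagonal corrected for binomial sampling by
removing the 1/a_i term, PSD-projected. Mean-centering with only four
populations induces a small negative bias in cross-population entries;
the likelihood operates in the same centered space, so the bias is
consistent between estimation and evaluation.

## Synthetic data

Two generators, both pure functions of (config, seed) with all
randomness from named substreams of one root seed.

**MVN generator** (`simulate_mvn_freqs`): the model-faithful path used
for classifier calibration and recovery. ε is drawn from a 1/x density
truncated to [0.02, 0.98], population frequencies from the scenario's
covariance (truncated to [0, 1]), then binomial sampling to the
observed allele copies.

**Forward Wright–Fisher generator** (`simulate_wf_pairs`): binomial
drift on A = 4·N_e allele copies per population on a tree of n regional
ancestors (split from a common pool at T_regional) that each split into
an S and an N population at T_pair. Mutation is a reversible per-site
flux at μ = 4.3×10⁻⁸; new neutral sites are not injected (their π
contribution over ≤ 10⁴ generations is negligible at this scale).
Ancestral frequencies follow a 1/x density on [1/A, 1−1/A], giving a
neutral sample SFS at initialisation; drifting an initialised SFS
without mutational influx slowly depletes rare variants, which biases
Tajima's D upward by ~+0.2 over the simulated timescales — comparable
to the positive D values the real system shows — and the neutral
calibration asserts the mean stays within ±0.3.

Planted selected loci: a deterministic additive per-dosage selection
step (haploid-equivalent frequency update with coefficient s in the
serpentine populations only) before drift, conditioned on establishment
by bounded retries — mirroring that sampled populations did adapt.
Modes: *standing* = one shared allele standing at frequency g for t
generations in the regional ancestors, then swept in both S populations
while the N populations carry it neutrally; *migration* = de novo
origin in the source S population with transfer at rate m per
generation to the recipient; *de novo* = two distinct new sites, one
per selected population (as observed at the real system's single de
novo candidate, where two different mutations struck the same codon) —
a single shared position would be indistinguishable from shared origin
in frequency space.

**Hitchhiking.** Distinct neutral SNPs are unlinked in the drift
engine; the sweeps' linked footprint is added by a star-like
approximation at sampling time: a SNP at distance d from the swept site
moves to p′ = y·q·h + (1−y·q)·p, with q the sweep's final frequency and
h the swept haplotype's allele (a Bernoulli draw at the ancestral
frequency — one shared draw across selected populations for
standing/migration, independent draws for de novo). This carries
exactly the covariance signal the classifier exploits; without it an
end-to-end classification test would be information-free.

**Scale.** The default fixture (1 Mbp, 50 genes, five pairs, eight
tetraploid individuals per population, T_pair = 3,000 generations,
N_e = 30,000, hence neutral pairwise F_ST ≈ T/(T+A) ≈ 0.024) is a
compressed stand-in for a ~50 Mbp genome: per-bp recombination is
scaled up by the compression factor (r = 1×10⁻⁶), so sweep footprints
1/(r·τ) ≈ 6 kbp occupy a realistic fraction of the sequence, and
downstream model fits must use the generator's r. The simulated SNP
panel (0.04/bp) is a thinned representation — per-SNP statistics are at
study scale while per-bp π scales with panel density; the π calibration
therefore targets the generator's own closed form,
E[2p(1−p)] · exp(−T_regional/A) under the truncated 1/x initialisation.
T_regional = 15,000 generations in the default design (the regional
radiation is much older than the recent colonisations), which makes the
five latent factors align with the five regional groups;
the neutral-calibration config uses a short regional phase
(T_regional = 4,000) where the SFS-aging bias stays small. Soil
covariates get substrate-shifted means (Ni, Co, Mg up; Ca/Mg down on
serpentine), pair-level random effects and individual noise, with the
contrast strong enough that a one-way ANOVA on Ni rejects at α = 0.01
at the default effect size and does not reject at effect 0. TE variants
are placed uniformly with a configurable fraction anchored near planted
sites.

**What passing tests do and do not show.** The generators reproduce the
covariance structure, sampling design and decision-relevant signal
geometry of the study system, not its full biology: no linkage among
neutral SNPs (beyond the sweep overlay), no sequence-level mutation
model, no genotyping error, free recombination between windows, and
star-shaped sweeps. Recovery results on these fixtures demonstrate
internal consistency of the inference chain and correct calibration
under the stated model — they do not certify power or error rates on
real resequencing data.

## Pipeline

`run_all` executes ingest → scan → association → overlap → source
classification → summary from one `RunConfig` whose stage defaults are
the study-quoted constants (1-kbp windows, ≥ 10 SNPs, 99% quantile,
≥ 2 pairs, K = 5, FDR 0.05, 25-kbp flanks, 8 proposed sites, neutral
threshold 21, 10% margin, ±2-kbp TE flank). Stage failures abort with
the stage name and machine-readable code; partial outputs are kept;
reruns with the same config and seed are bit-identical (asserted). Every
reported number is recomputable from the written intermediates
(asserted by an audit test). MAF filters are stage-local: none for
diversity statistics, > 0.05 for the association input.

## Known limitations

- The composite likelihood treats SNPs as independent; MCL differences
  are comparable across scenarios but have no χ² calibration, which is
  why the neutral threshold is set by simulation, not asymptotics.
- Quartet mean-centering leaves joint S-inflation and joint
  N-inflation unidentifiable in the first moment; discrimination rests
  on pair-contrast variances, so the serpentine-specificity margin is
  conservative and excludes genuinely selected cases when signal is
  weak — consistent with its intended role as a filter.
- The migration constructor anchors recipients to the source diagonal
  and does not model continued post-sweep exchange.
- λ_GC recalibration assumes sparse true signal; with dense selection
  or very few populations it over-deflates.
- The WF engine's frequency-level sweeps cannot generate soft or
  partial sweeps along a haplotype mosaic; planted sweeps are hard by
  construction.
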