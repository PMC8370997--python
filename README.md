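# paradapt

Detecting **parallel selection** across replicated population pairs and
classifying the **evolutionary source** of each repeatedly selected
allele — independent de novo mutation, shared ancestral standing
variation, or migration between adapted populations.

The package is aimed at population geneticists studying replicated
adaptation (for example autotetraploid plants that colonised toxic
serpentine soils several times independently). Its inputs are a
multi-sample VCF with polysomic (dosage) genotypes, a GFF3 gene
annotation, a per-individual soil-chemistry table, and optionally a
transposable-element presence/absence table. A forward Wright–Fisher
simulator generates study-shaped synthetic data so every stage runs and
can be validated without any download.

## The inference chain

1. **Divergence scan** (`paradapt.diversity`, `paradapt.scan`). Hudson's
   F_ST estimator, aggregated as a ratio of averages
   `F_ST = Σ_k N_k / Σ_k D_k` with per-SNP components

       N_k = (p1−p2)² − p1(1−p1)/(a1−1) − p2(1−p2)/(a2−1)
       D_k = p1(1−p2) + p2(1−p1)

   over non-overlapping 1-kbp windows with ≥ 10 SNPs, for each
   serpentine/non-serpentine (S/N) population pair. Genes overlapping
   the upper-1% windows are per-pair candidates; genes flagged in ≥ 2
   pairs are *parallel differentiation candidates*, with significance of
   multi-list overlap from the hypergeometric upper tail (plus a Monte
   Carlo permutation path for more than two lists).

2. **Genotype–environment association** (`paradapt.gea`).
   `LatentFactorModel(gm, env, K=5).fit("Ni")` regresses each SNP's
   dosage on a soil variable plus K latent structure factors (truncated
   SVD scores), recalibrates z-scores by the genomic inflation factor
   λ_GC = median(z²)/0.4549, and converts p-values to q-values
   (Benjamini–Hochberg; optional Storey π₀). Genes with ≥ 1 SNP at
   q < 0.05 for ≥ 1 of Ca/Mg, Mg, Ni, Co are association candidates.
   Intersecting them with the parallel candidates gives the final
   *serpentine adaptation candidates*.

3. **Source classification** (`paradapt.convergence`). For each
   candidate gene shared by two pairs (a quartet S_i, N_i, S_j, N_j),
   `ConvergenceModel(...).fit()` compares four models of allele-frequency
   covariance around a proposed selected site — neutral, independent de
   novo sweeps, sweeps on shared standing variation, and sweeps spread by
   migration — by maximum composite log-likelihood (MCL) over a parameter
   grid and 8 proposed site positions, with 25-kbp flanks. A case is
   non-neutral only if the best scenario beats neutral by > 21 MCL units
   and beats the same scenario with selection placed in the N populations
   by > 10%. Standing variation and migration collapse to *shared
   origin*.

## Worked example

```python
import numpy as np
from paradapt.simulate import emit_fixture
from paradapt.pipeline import RunConfig, run_all

man = emit_fixture(size="default", outdir="demo", seed=11)  # ~2.5 min
cfg = RunConfig(
    vcf=man["paths"]["vcf"], gff3=man["paths"]["gff3"],
    popmap=man["paths"]["popmap"], env=man["paths"]["env"],
    te=man["paths"]["te"], r_bp=man["config"]["r_bp"], seed=11,
)
report = run_all(cfg, outdir="demo/out")
print(report.candidate_counts)
print(sorted(report.parallel_candidates))
print(report.case_table[["gene_id", "delta_s", "delta_n",
                         "classification_collapsed"]])
```

Output from this exact run:

```
{'S1-N1': 1, 'S2-N2': 2, 'S3-N3': 3, 'S4-N4': 3, 'S5-N5': 1}
['gene006', 'gene016', 'gene026', 'gene036', 'gene046']
   gene_id     delta_s     delta_n classification_collapsed
0  gene016  329.668461  290.798162            shared_origin
1  gene026  366.803048  328.284749            shared_origin
2  gene036  276.014524  237.528802            shared_origin
3  gene046  293.556205  120.518926                  de_novo
```

The fixture plants four standing-variation genes and one gene with two
independent de novo mutations across five population pairs. The scan
finds all five as parallel candidates; the association filter retains
four; the classifier calls the standing genes *shared origin* (the MCL
gain for selection in serpentine populations, `delta_s`, exceeds both
the neutral threshold 21 and 1.1× the same scenario's gain for
non-serpentine populations, `delta_n`) and the de novo gene *de novo* —
the "shared origin dominant, single de novo exception" pattern the
replicated serpentine system shows.

The same chain is available from a shell:

```bash
paradapt simulate --size tiny --seed 7 --out demo_tiny
paradapt run-all --config cfg.yaml --out demo_tiny/out --seed 7
```

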