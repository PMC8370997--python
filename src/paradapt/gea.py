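"""Genotype-environment association with latent-factor confounder control.

The model is a two-stage latent-factor regression in the LFMM family:
population structure is summarised by the first K left singular vectors
of the column-centered dosage matrix (K = number of population pairs by
default); each SNP's dosage is then regressed on the centered
environmental variable plus the K factor scores, and z-scores are
recalibrated by the genomic inflation factor
lambda_GC = median(z^2) / 0.4549 before p-values are taken from the
standard normal. q-values are Benjamini-Hochberg step-up values with an
optional Storey pi0 estimate (pi0 = 1 by default, conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .scan import GeneModel

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi^2_1


def gea_site_filter(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep sites with zero missing genotypes and MAF > maf_min."""
    complete = (gm.dosage != MISSING).all(axis=0)
    total = gm.ploidy * len(gm.individuals)
    freq = gm.dosage.clip(min=0).sum(axis=0) / total
    maf = np.minimum(freq, 1.0 - freq)
    keep = complete & (maf > maf_min)
    if not keep.any():
        raise ValueError(
            f"no sites pass the association filter "
            f"(complete: {int(complete.sum())}, MAF>{maf_min}: "
            f"{int((maf > maf_min).sum())} of {gm.n_sites})"
        )
    return gm.take_sites(np.flatnonzero(keep))


def latent_factors(gm: GenotypeMatrix, K: int = 5) -> np.ndarray:
    """Structure scores: first K left singular vectors x singular values.

    Deterministic up to sign; signs are fixed by making the
    largest-magnitude loading of each factor positive.
    """
    n = len(gm.individuals)
    if K >= n:
        raise ValueError(f"K={K} must be < number of individuals ({n})")
    X = gm.dosage.astype(float)
    X -= X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :K] * s[:K]
    for j in range(K):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return scores


def qvalues(p: np.ndarray, pi0: float | None = 1.0) -> np.ndarray:
    """BH step-up q-values, optionally scaled by a Storey pi0 estimate.

    pi0=1 gives plain Benjamini-Hochberg adjusted values; pi0=None
    estimates pi0 by Storey's fixed-lambda method (lambda = 0.5).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    if pi0 is None:
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam) / (1.0 - lam)))
        pi0 = max(pi0, 1.0 / p.size)
    return np.minimum(q * pi0, 1.0)


@dataclass
class AssocResults:
    """Per-SNP association results for one environmental variable."""

    variable: str
    K: int
    sites: pd.DataFrame
    beta: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    lambda_gc: float

    def frame(self) -> pd.DataFrame:
        out = self.sites[["chrom", "pos"]].copy()
        out["beta"] = self.beta
        out["z"] = self.z
        out["p"] = self.p
        out["q"] = self.q
        return out

    def summary(self) -> str:
        n_sig = int((self.q < 0.05).sum())
        lines = [
            "Latent-factor genotype-environment association",
            f"  variable: {self.variable}",
            f"  SNPs tested: {len(self.p)}",
            f"  latent factors (K): {self.K}",
            f"  genomic inflation lambda_GC: {self.lambda_gc:.3f}",
            f"  SNPs with q < 0.05: {n_sig}",
        ]
        return "\n".join(lines)


class LatentFactorModel:
    """Latent-factor association model for one cohort.

    Parameters
    ----------
    gm : GenotypeMatrix
        Complete (no missing calls), MAF-filtered dosages; see
        :func:`gea_site_filter`.
    env : pandas.DataFrame
        One row per individual with at least columns ``individual`` and
        the environmental variables to test; must cover every individual
        in ``gm``.
    K : int
        Number of latent factors (population pairs in the study design).
    factor_sites : boolean ndarray, optional
        Mask over sites used to estimate the structure factors. Factors
        should reflect neutral ancestry, so callers typically exclude
        putatively selected regions (e.g. F_ST outlier windows): when
        the factors are estimated on the very loci being tested, the
        strongest parallel signals are absorbed into the correction.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        env: pd.DataFrame,
        K: int = 5,
        factor_sites: np.ndarray | None = None,
    ):
        missing = set(gm.individuals) - set(env["individual"])
        if missing:
            raise ValueError(f"env table lacks individuals: {sorted(missing)}")
        self.gm = gm
        self.env = env.set_index("individual").loc[gm.individuals].reset_index()
        self.K = K
        if K > 0:
            fgm = gm
            if factor_sites is not None and factor_sites.sum() > K:
                fgm = gm.take_sites(np.flatnonzero(factor_sites))
            self.factors = latent_factors(fgm, K)
        else:
            self.factors = None

    def fit(self, variable: str, pi0: float | None = 1.0) -> AssocResults:
        """Per-SNP regression of dosage on one environmental variable."""
        v = self.env[variable].to_numpy(dtype=float)
        if np.allclose(v, v[0]):
            raise ValueError(f"variable {variable!r} is constant")
        v = v - v.mean()
        n = len(v)
        if self.factors is not None:
            X = np.column_stack([np.ones(n), v, self.factors])
            # collinearity of the variable with structure factors
            r = np.corrcoef(
                np.column_stack([v[:, None], self.factors]), rowvar=False
            )[0, 1:]
            if np.max(np.abs(r)) > 0.999:
                logger.warning(
                    "variable %s nearly collinear with a latent factor "
                    "(|r|=%.4f); results flagged", variable, np.max(np.abs(r)),
                )
        else:
            X = np.column_stack([np.ones(n), v])
        Y = self.gm.dosage.astype(float)
        XtX_inv = np.linalg.pinv(X.T @ X)
        H = XtX_inv @ X.T
        B = H @ Y                       # (p+1, n_snps)
        resid = Y - X @ B
        dof = n - X.shape[1]
        if dof <= 0:
            raise ValueError("not enough individuals for the factor model")
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
        beta = B[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        z = np.nan_to_num(z)
        lam = float(np.median(z**2) / CHI2_MEDIAN_1DF)
        lam = max(lam, 1e-12)
        z_cal = z / np.sqrt(lam)
        p = stats.chi2.sf(z_cal**2, df=1)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        q = qvalues(p, pi0=pi0)
        return AssocResults(
            variable=variable, K=self.K, sites=self.gm.sites,
            beta=beta, z=z_cal, p=p, q=q, lambda_gc=lam,
        )

    def fit_all(
        self, variables: list[str], pi0: float | None = 1.0
    ) -> dict[str, AssocResults]:
        return {v: self.fit(v, pi0=pi0) for v in variables}


def gea_candidate_genes(
    assoc: list[AssocResults] | dict[str, AssocResults],
    annotation: list[GeneModel],
    fdr: float = 0.05,
) -> dict[str, list[tuple[str, int, str, float]]]:
    """Genes with >= 1 SNP at q < fdr for >= 1 variable.

    Returns gene -> provenance list of (chrom:pos, pos, variable, q).
    """
    if isinstance(assoc, dict):
        assoc = list(assoc.values())
    out: dict[str, list] = {}
    for res in assoc:
        sig = res.q < fdr
        if not sig.any():
            continue
        chroms = res.sites["chrom"].to_numpy()[sig]
        poss = res.sites["pos"].to_numpy()[sig]
        qs = res.q[sig]
        for g in annotation:
            inside = (chroms == g.chrom) & (poss > g.start) & (poss <= g.end)
            for pos, q in zip(poss[inside], qs[inside]):
                out.setdefault(g.gene_id, []).append(
                    (g.chrom, int(pos), res.variable, float(q))
                )
    return out
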