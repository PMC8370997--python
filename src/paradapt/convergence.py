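"""Classifying the evolutionary source of repeatedly selected alleles.

For a candidate gene shared by two population pairs (a quartet S_i, N_i,
S_j, N_j), we model the covariance of population allele frequencies
around a proposed selected site under four scenarios:

* ``neutral``   - no selection; covariance is the genome-wide neutral
  coancestry matrix F0.
* ``ind``       - independent de novo mutations in each selected
  population: hitchhiking inflates only the selected populations'
  own coancestry (diagonal), never the cross-population terms.
* ``standing``  - repeated sweeps on a shared ancestral variant that was
  standing at frequency g for t generations before selection: lineages
  that stay linked through the sweep may coalesce during the standing
  phase, which elevates cross-population coancestry between selected
  populations.
* ``migration`` - the swept allele was transferred from a source
  population at rate m; hitchhiking lineages in recipient populations
  trace back to the source.

A neutral lineage at distance d bp from the selected site stays linked
through the sweep with probability y = exp(-r*d*tau), where
tau = log(A*s)/s is the sweep duration and A = ploidy * Ne is the number
of allele copies (tetraploid scaling: A = 4*Ne).

Per SNP the sample frequency vector is modelled as multivariate normal
with mean the across-population average frequency eps and covariance
eps*(1-eps) * C(F'(d)), where C adds the binomial sampling term
(1-F'_ii)/a_i on the diagonal; the likelihood is evaluated in the
(M-1)-dimensional mean-free subspace. Summing log-densities over SNPs
treats them as independent - a composite likelihood, valid for model
comparison. The maximum composite log-likelihood (MCL) is taken over a
parameter grid and over proposed selected-site positions placed at equal
distance along the gene.

Decision rule: a case is non-neutral only when the best selection
scenario beats neutral by more than ``neutral_threshold`` (default 21
composite log-likelihood units, a conservative neutral-calibration
bound) AND the gain for selection in the serpentine populations exceeds
the gain for selection in the non-serpentine populations by more than
``serpentine_margin`` (10%). ``standing`` and ``migration`` are reported
individually and jointly collapsed to ``shared_origin`` because both
recruit an allele of single mutational origin.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AlleleFreqTable
from .scan import GeneModel

logger = logging.getLogger(__name__)

SCENARIOS = ("neutral", "ind", "standing", "migration")


@dataclass
class CoancestryMatrix:
    """Neutral coancestry among populations plus sampled copy counts."""

    populations: list[str]
    F: np.ndarray
    a: np.ndarray  # allele copies sampled per population

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.F.shape != (len(self.populations),) * 2:
            raise ValueError("F must be M x M")
        if not np.allclose(self.F, self.F.T, atol=1e-10):
            raise ValueError("F must be symmetric")

    def index(self, pop: str) -> int:
        return self.populations.index(pop)


def project_psd(F: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Nearest positive semidefinite matrix by eigenvalue clipping."""
    F = 0.5 * (F + F.T)
    w, V = np.linalg.eigh(F)
    if w.min() >= -tol:
        return F
    logger.info("projecting coancestry to PSD (min eig %.3g)", w.min())
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def neutral_coancestry(
    af: AlleleFreqTable,
    quartet: list[str],
    neutral_sites: np.ndarray | None = None,
    min_snps: int = 1000,
) -> CoancestryMatrix:
    """Estimate the neutral coancestry matrix from genome-wide SNPs.

    F_ij is the mean over SNPs of (x_i - eps)(x_j - eps) / (eps(1-eps)),
    with eps the unweighted across-population mean sample frequency. The
    diagonal is corrected for binomial sampling noise by removing the
    1/a_i term, and the matrix is projected to the nearest PSD matrix if
    needed.
    """
    idx = [af.pop_index(p) for p in quartet]
    x = af.freq[idx]
    a = af.sampled_copies[idx].astype(float)
    if neutral_sites is not None:
        x = x[:, neutral_sites]
        a = a[:, neutral_sites]
    ok = (~np.isnan(x)).all(axis=0)
    x, a = x[:, ok], a[:, ok]
    eps = x.mean(axis=0)
    poly = (eps > 0) & (eps < 1)
    x, a, eps = x[:, poly], a[:, poly], eps[poly]
    if x.shape[1] < min_snps:
        raise ValueError(
            f"only {x.shape[1]} usable neutral SNPs (< {min_snps})"
        )
    dev = (x - eps) / np.sqrt(eps * (1 - eps))
    F_hat = dev @ dev.T / dev.shape[1]
    inv_a = (1.0 / a).mean(axis=1)
    F = F_hat.copy()
    d = np.diag(F_hat).copy()
    d = (d - inv_a) / (1.0 - inv_a)
    np.fill_diagonal(F, np.clip(d, 0.0, 1.0))
    F = project_psd(F)
    np.fill_diagonal(F, np.clip(np.diag(F), 0.0, 1.0))
    a_typical = np.median(a, axis=1)
    return CoancestryMatrix(populations=list(quartet), F=F, a=a_typical)


@dataclass
class ScenarioParams:
    """Parameters of one selection scenario evaluation."""

    scenario: str
    s: float = 0.0
    g: float = 0.01
    t: float = 0.0
    m: float = 1e-3
    src: int | None = None  # index into the quartet (migration only)
    r_bp: float = 2e-8
    Ne: float = 30000.0
    ploidy: int = 4
    selected: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario != "neutral":
            if self.s <= 0:
                raise ValueError("s must be > 0 for selection scenarios")
            if self.copies * self.s <= 1:
                raise ValueError(
                    "A*s <= 1: sweep-duration approximation invalid"
                )
        if not 0 < self.g < 1:
            raise ValueError("g must be in (0, 1)")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1)")

    @property
    def copies(self) -> float:
        """Haploid-equivalent allele copy count A = ploidy * Ne."""
        return self.ploidy * self.Ne


def sweep_retention(d: np.ndarray | float, params: ScenarioParams) -> np.ndarray:
    """Probability a lineage d bp away stays linked through the sweep.

    y = exp(-r_bp * d * tau) with sweep duration tau = log(A*s)/s.
    """
    A = params.copies
    if A * params.s <= 1:
        raise ValueError("A*s <= 1: sweep-duration approximation invalid")
    tau = np.log(A * params.s) / params.s
    return np.exp(-params.r_bp * np.asarray(d, dtype=float) * tau)


def scenario_coancestry(
    F0: np.ndarray, d: np.ndarray | float, params: ScenarioParams,
    psd: bool = True,
) -> np.ndarray:
    """Coancestry matrix/matrices modified by a selection scenario.

    ``d`` may be scalar or an array of distances; returns shape
    (M, M) or (n_d, M, M). The neutral scenario returns F0 unchanged.
    Constructor closed forms:

    ind:       F'_ii = y^2 + (1 - y^2) F0_ii for selected i.
    standing:  exit rates delta = 1/(A g) (coalescence) and 2 rho with
               rho = r d (recombination) over the standing window t;
               P_coal = (delta/lambda)(1 - exp(-lambda t)); for selected
               i, j (including i = j)
               F'_ij = y^2 P_coal (1 - F0_ij) + F0_ij.
    migration: P_coal = 1 / (1 + 2 A m rho); recipient entries are pulled
               toward coalescence with the source lineage,
               F'_ij = y^2 [P_coal + (1 - P_coal) F0_src,src]
                       + (1 - y^2) F0_ij,
               the source diagonal sweeps as in ``ind``.
    """
    F0 = np.asarray(F0, dtype=float)
    M = F0.shape[0]
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    n_d = d_arr.shape[0]
    out = np.broadcast_to(F0, (n_d, M, M)).copy()
    if params.scenario == "neutral":
        return out if np.ndim(d) else out[0]

    sel = list(params.selected)
    if not sel:
        raise ValueError("selection scenario requires selected populations")
    y = sweep_retention(d_arr, params)  # (n_d,)
    y2 = y**2
    A = params.copies
    rho = params.r_bp * d_arr

    if params.scenario == "ind":
        for i in sel:
            out[:, i, i] = y2 + (1.0 - y2) * F0[i, i]
    elif params.scenario == "standing":
        delta = 1.0 / (A * params.g)
        lam = delta + 2.0 * rho
        with np.errstate(over="ignore"):
            p_coal = (delta / lam) * (1.0 - np.exp(-lam * params.t))
        for i in sel:
            for j in sel:
                out[:, i, j] = y2 * p_coal * (1.0 - F0[i, j]) + F0[i, j]
    elif params.scenario == "migration":
        src = params.src
        if src is None or src not in sel:
            raise ValueError("migration scenario needs src in selected")
        p_coal = 1.0 / (1.0 + 2.0 * A * params.m * rho)
        f_ss = F0[src, src]
        for i in sel:
            for j in sel:
                if i == src and j == src:
                    out[:, i, j] = y2 + (1.0 - y2) * f_ss
                else:
                    out[:, i, j] = (
                        y2 * (p_coal + (1.0 - p_coal) * f_ss)
                        + (1.0 - y2) * F0[i, j]
                    )
    # symmetry is preserved by construction; clip tiny negative
    # eigenvalues introduced by the asymmetric neutral couplings of the
    # near-identical selected rows (PSD projection). Callers whose
    # downstream evaluation floors the spectrum anyway may skip this.
    if psd:
        w, V = np.linalg.eigh(out)
        if w.min() < -1e-10:
            w = np.clip(w, 0.0, None)
            out = np.einsum("kij,kj,klj->kil", V, w, V)
            out = 0.5 * (out + np.transpose(out, (0, 2, 1)))
    return out if np.ndim(d) else out[0]


def _helmert(M: int) -> np.ndarray:
    """(M-1) x M orthonormal contrast matrix with rows orthogonal to 1."""
    H = np.zeros((M - 1, M))
    for i in range(1, M):
        H[i - 1, :i] = 1.0 / np.sqrt(i * (i + 1))
        H[i - 1, i] = -i / np.sqrt(i * (i + 1))
    return H


def default_grids() -> dict[str, list[float]]:
    return {
        "s": [0.001, 0.01, 0.05, 0.1, 0.5],
        "g": [0.001, 0.005, 0.01, 0.05, 0.1],
        "t": [50.0, 500.0, 1000.0, 5000.0],
        "m": [1e-5, 1e-4, 1e-3, 1e-2],
    }


@dataclass
class ScenarioFit:
    """MCL and argmax parameters for one scenario / one selected set."""

    scenario: str
    mcl: float
    best_params: ScenarioParams | None
    best_position: float
    profile: pd.DataFrame  # per proposed position: best log-likelihood


@dataclass
class ConvergenceResults:
    """Fitted composite-likelihood comparison for one candidate case."""

    gene_id: str
    quartet: list[str]
    fits_s: dict[str, ScenarioFit]
    fits_n: dict[str, ScenarioFit]
    neutral_threshold: float
    serpentine_margin: float
    n_snps: int
    underpowered: bool

    @property
    def delta_s(self) -> float:
        base = self.fits_s["neutral"].mcl
        return max(
            self.fits_s[s].mcl - base for s in SCENARIOS if s != "neutral"
        )

    @property
    def delta_n(self) -> float:
        """Gain of the best S scenario when selection is placed in the
        non-serpentine populations instead (same-scenario comparison:
        the serpentine-specificity rule contrasts the chosen scenario's
        MCL estimate with *this estimate* for the N populations)."""
        base = self.fits_n["neutral"].mcl
        return self.fits_n[self.best_scenario].mcl - base

    @property
    def delta_n_max(self) -> float:
        """Gain of the best of all scenarios for N-selected runs."""
        base = self.fits_n["neutral"].mcl
        return max(
            self.fits_n[s].mcl - base for s in SCENARIOS if s != "neutral"
        )

    @property
    def best_scenario(self) -> str:
        sel = {s: f.mcl for s, f in self.fits_s.items() if s != "neutral"}
        return max(sel, key=sel.get)

    @property
    def classification(self) -> str:
        return classify_case(
            self.delta_s,
            self.delta_n,
            self.best_scenario,
            neutral_threshold=self.neutral_threshold,
            serpentine_margin=self.serpentine_margin,
        )

    @property
    def classification_collapsed(self) -> str:
        c = self.classification
        if c in ("standing", "migration"):
            return "shared_origin"
        if c == "ind":
            return "de_novo"
        return c

    def mcl_table(self) -> pd.DataFrame:
        rows = []
        for run, fits in (("S", self.fits_s), ("N", self.fits_n)):
            for s in SCENARIOS:
                rows.append({"run": run, "scenario": s, "mcl": fits[s].mcl})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Convergence source classification: gene {self.gene_id}",
            f"  quartet: {', '.join(self.quartet)}",
            f"  SNPs used: {self.n_snps}"
            + ("  [underpowered]" if self.underpowered else ""),
            "  maximum composite log-likelihoods (S-selected / N-selected):",
        ]
        for s in SCENARIOS:
            lines.append(
                f"    {s:<10} {self.fits_s[s].mcl:14.3f} / "
                f"{self.fits_n[s].mcl:14.3f}"
            )
        lines += [
            f"  delta MCL (S) = {self.delta_s:.3f}, "
            f"delta MCL (N) = {self.delta_n:.3f}",
            f"  best selection scenario: {self.best_scenario}",
            f"  classification: {self.classification} "
            f"({self.classification_collapsed})",
        ]
        return "\n".join(lines)


class ConvergenceModel:
    """Composite-likelihood model for one candidate gene x quartet case.

    Parameters
    ----------
    freqs : ndarray (n_snps, 4)
        Sample allele frequencies for the quartet populations, SNPs
        restricted (by the constructor) to the gene span plus
        ``flank_bp`` on each side.
    positions : ndarray (n_snps,)
        1-based genomic positions of the SNPs.
    copies : ndarray (4,)
        Sampled allele copies per population.
    gene : GeneModel
    F0 : CoancestryMatrix or ndarray (4, 4)
        Neutral coancestry for the quartet.
    selected_s, selected_n : tuple of int
        Indices (into the quartet) of the serpentine populations and the
        non-serpentine populations.
    """

    def __init__(
        self,
        freqs: np.ndarray,
        positions: np.ndarray,
        copies: np.ndarray,
        gene: GeneModel,
        F0: CoancestryMatrix | np.ndarray,
        quartet: list[str] | None = None,
        selected_s: tuple[int, int] = (0, 2),
        selected_n: tuple[int, int] = (1, 3),
        r_bp: float = 2e-8,
        Ne: float = 30000.0,
        ploidy: int = 4,
        n_proposed_sites: int = 8,
        flank_bp: int = 25000,
        min_snps: int = 20,
    ):
        if isinstance(F0, CoancestryMatrix):
            quartet = quartet or F0.populations
            F0 = F0.F
        self.F0 = project_psd(np.asarray(F0, dtype=float))
        self.quartet = quartet or ["S1", "N1", "S2", "N2"]
        positions = np.asarray(positions)
        lo, hi = gene.start + 1 - flank_bp, gene.end + flank_bp
        keep = (positions >= lo) & (positions <= hi)
        freqs = np.asarray(freqs, dtype=float)[keep]
        positions = positions[keep]
        eps = freqs.mean(axis=1)
        poly = (eps > 0) & (eps < 1) & ~np.isnan(eps)
        self.freqs = freqs[poly]
        self.positions = positions[poly]
        self.eps = eps[poly]
        self.copies = np.asarray(copies, dtype=float)
        self.gene = gene
        self.selected_s = tuple(selected_s)
        self.selected_n = tuple(selected_n)
        self.r_bp = r_bp
        self.Ne = Ne
        self.ploidy = ploidy
        self.flank_bp = flank_bp
        self.site_positions = np.linspace(
            gene.start + 1, gene.end, n_proposed_sites
        )
        self.underpowered = len(self.positions) < min_snps
        if self.underpowered:
            logger.warning(
                "gene %s: only %d usable SNPs in the window (flagged "
                "underpowered)", gene.gene_id, len(self.positions),
            )
        self._L = _helmert(4)
        # centered data, constant across scenarios
        self._xstar = (self._L @ self.freqs.T).T  # (n_snps, 3)

    # -- likelihood machinery -------------------------------------------

    def _loglik_given_F(self, Fprime: np.ndarray) -> float:
        """Sum of mean-free MVN log-densities given per-SNP F' matrices.

        Fprime has shape (n_snps, 4, 4).
        """
        n = Fprime.shape[0]
        if n == 0:
            return 0.0
        C = Fprime.copy()
        diag = np.einsum("kii->ki", C)
        diag += (1.0 - diag) / self.copies  # binomial sampling term
        S = np.einsum("ij,kjl,ml->kim", self._L, C, self._L)
        scale = (self.eps * (1.0 - self.eps))[:, None, None]
        S = S * scale
        # spectral evaluation: near-degenerate model corners (coancestry
        # -> 1) are legal; a relative eigenvalue floor keeps the density
        # finite while the quadratic form still penalises mismatching data
        w, V = np.linalg.eigh(S)
        floor = 1e-8 * w[:, -1:]
        w = np.maximum(w, np.maximum(floor, 1e-300))
        proj = np.einsum("kji,kj->ki", V, self._xstar)
        quad = np.sum(proj**2 / w, axis=1)
        logdet = np.sum(np.log(w), axis=1)
        const = 3 * np.log(2 * np.pi)
        return float(-0.5 * np.sum(const + logdet + quad))

    def _param_list(
        self, scenario: str, selected: tuple[int, ...],
        grids: dict[str, list[float]],
    ) -> list[ScenarioParams]:
        base = dict(r_bp=self.r_bp, Ne=self.Ne, ploidy=self.ploidy,
                    selected=selected)
        valid_s = [
            s for s in grids["s"] if self.ploidy * self.Ne * s > 1
        ]
        if scenario == "ind":
            return [ScenarioParams("ind", s=s, **base) for s in valid_s]
        if scenario == "standing":
            return [
                ScenarioParams("standing", s=s, g=g, t=t, **base)
                for s, g, t in itertools.product(
                    valid_s, grids["g"], grids["t"]
                )
            ]
        if scenario == "migration":
            return [
                ScenarioParams("migration", s=s, m=m, src=src, **base)
                for s, m, src in itertools.product(
                    valid_s, grids["m"], selected
                )
            ]
        return [ScenarioParams("neutral", selected=selected)]

    def _fit_scenario(
        self, scenario: str, selected: tuple[int, ...],
        grids: dict[str, list[float]],
    ) -> ScenarioFit:
        if scenario == "neutral":
            F = np.broadcast_to(
                self.F0, (len(self.positions), 4, 4)
            ).copy()
            ll = self._loglik_given_F(F)
            profile = pd.DataFrame(
                {"position": self.site_positions,
                 "loglik": [ll] * len(self.site_positions)}
            )
            return ScenarioFit("neutral", ll, None, float("nan"), profile)

        params_list = self._param_list(scenario, selected, grids)
        best = -np.inf
        best_params: ScenarioParams | None = None
        best_pos = float("nan")
        prof = np.full(len(self.site_positions), -np.inf)
        for ip, site in enumerate(self.site_positions):
            d = np.abs(self.positions - site)
            for params in params_list:
                F = scenario_coancestry(self.F0, d, params, psd=False)
                ll = self._loglik_given_F(F)
                if ll > prof[ip]:
                    prof[ip] = ll
                if ll > best:
                    best, best_params, best_pos = ll, params, float(site)
        profile = pd.DataFrame(
            {"position": self.site_positions, "loglik": prof}
        )
        return ScenarioFit(scenario, best, best_params, best_pos, profile)

    def fit(
        self,
        grids: dict[str, list[float]] | None = None,
        neutral_threshold: float = 21.0,
        serpentine_margin: float = 0.10,
    ) -> ConvergenceResults:
        """Fit all four scenarios for both S-selected and N-selected runs."""
        grids = grids or default_grids()
        fits_s = {
            sc: self._fit_scenario(sc, self.selected_s, grids)
            for sc in SCENARIOS
        }
        fits_n = {
            sc: self._fit_scenario(sc, self.selected_n, grids)
            for sc in SCENARIOS
        }
        return ConvergenceResults(
            gene_id=self.gene.gene_id,
            quartet=self.quartet,
            fits_s=fits_s,
            fits_n=fits_n,
            neutral_threshold=neutral_threshold,
            serpentine_margin=serpentine_margin,
            n_snps=len(self.positions),
            underpowered=self.underpowered,
        )


def classify_case(
    delta_s: float,
    delta_n: float,
    best_scenario: str,
    neutral_threshold: float = 21.0,
    serpentine_margin: float = 0.10,
) -> str:
    """Decision rule mapping MCL gains to a source classification.

    neutral   when the S-selected gain does not exceed the neutral
              calibration threshold;
    ambiguous when it does, but does not exceed the N-selected gain by
              the required margin (selection signal not specific to the
              serpentine populations);
    otherwise the argmax selection scenario.
    """
    if not np.isfinite(delta_s):
        raise ValueError("delta_s must be finite")
    if delta_s <= neutral_threshold:
        return "neutral"
    if delta_s <= (1.0 + serpentine_margin) * max(delta_n, 0.0):
        return "ambiguous"
    return best_scenario


def summarize_sources(cases: list[ConvergenceResults]) -> pd.DataFrame:
    """Counts and proportions of classifications over a set of cases."""
    labels = [c.classification_collapsed for c in cases]
    counts = pd.Series(labels).value_counts()
    order = ["neutral", "ambiguous", "de_novo", "shared_origin"]
    rows = []
    n_informative = sum(
        counts.get(k, 0) for k in ("de_novo", "shared_origin")
    )
    for k in order:
        n = int(counts.get(k, 0))
        rows.append(
            {
                "classification": k,
                "n_cases": n,
                "prop_of_all": n / len(cases) if cases else 0.0,
                "prop_of_non_neutral": (
                    n / n_informative
                    if n_informative and k in ("de_novo", "shared_origin")
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
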