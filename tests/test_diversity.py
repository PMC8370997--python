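"""Windowed F_ST, nucleotide diversity, Tajima's D, fourfold-degenerate mask."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paradapt.genotypes import MISSING, AlleleFreqTable, allele_frequencies
from paradapt.diversity import (
    fourfold_degenerate_sites,
    hudson_fst_components,
    hudson_fst_windows,
    nucleotide_diversity,
    tajimas_d,
    tajimas_d_from_counts,
)

from conftest import make_gm


def af_from_freqs(p1, p2, a1=16, a2=16, positions=None):
    n = len(p1)
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions if positions is not None else np.arange(1, n + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    alt = np.round(np.stack([p1 * a1, p2 * a2])).astype(int)
    tot = np.stack([np.full(n, a1), np.full(n, a2)])
    return AlleleFreqTable(["S", "N"], sites, alt, tot)


class TestHudsonFst:
    def test_equal_frequencies_give_near_zero(self):
        p = np.linspace(0.1, 0.9, 20)
        af = af_from_freqs(p, p)
        w = hudson_fst_windows(af, ("S", "N"), window_size=1000, min_snps=10)
        assert abs(w["fst"].iloc[0]) < 0.08  # unbiased estimator, noisy zero

    def test_fixed_differences_give_one(self):
        af = af_from_freqs([1.0] * 12, [0.0] * 12)
        w = hudson_fst_windows(af, ("S", "N"))
        assert w["fst"].iloc[0] == pytest.approx(1.0)

    def test_single_snp_hand_value(self):
        # p1=0.5, p2=0.25, a=16: N = 0.0625 - 0.25/15 - 0.1875/15 = 0.03333
        # D = 0.5*0.75 + 0.25*0.5 = 0.5 -> ratio 0.0667
        num, den = hudson_fst_components([0.5], [0.25], [16], [16])
        assert num[0] / den[0] == pytest.approx(0.0333333 / 0.5, rel=1e-4)

    def test_ratio_of_averages_equals_bruteforce(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0.05, 0.95, 40), rng.uniform(0.05, 0.95, 40)
        af = af_from_freqs(p1, p2, positions=rng.choice(900, 40, replace=False) + 1)
        w = hudson_fst_windows(af, ("S", "N"))
        num, den = hudson_fst_components(af.freq[0], af.freq[1], 16, 16)
        assert w["fst"].iloc[0] == pytest.approx(num.sum() / den.sum())

    def test_symmetry_and_allele_label_invariance(self):
        rng = np.random.default_rng(2)
        p1, p2 = rng.uniform(0.1, 0.9, 20), rng.uniform(0.1, 0.9, 20)
        af = af_from_freqs(p1, p2)
        base = hudson_fst_windows(af, ("S", "N"))["fst"].iloc[0]
        assert hudson_fst_windows(af, ("N", "S"))["fst"].iloc[0] == pytest.approx(base)
        flipped = af_from_freqs(1 - p1, 1 - p2)
        assert hudson_fst_windows(flipped, ("S", "N"))["fst"].iloc[0] == pytest.approx(base)

    def test_window_below_min_snps_undefined(self):
        af = af_from_freqs([0.5] * 5, [0.2] * 5)
        w = hudson_fst_windows(af, ("S", "N"), min_snps=10)
        assert np.isnan(w["fst"].iloc[0]) and w["n_snps"].iloc[0] == 5

    def test_monomorphic_input_no_windows_with_fst(self):
        af = af_from_freqs([0.0] * 15, [0.0] * 15)
        w = hudson_fst_windows(af, ("S", "N"))
        assert np.isnan(w["fst"]).all()


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        gm = make_gm(np.zeros((8, 10)), ["P1"] * 8)
        assert nucleotide_diversity(gm, "P1") == 0.0

    def test_single_site_direct_formula(self):
        # 6 individuals, 24 copies, 12 alt -> 2*12*12/(24*23)
        gm = make_gm([[2]] * 6, ["P1"] * 6)
        assert nucleotide_diversity(gm, "P1") == pytest.approx(2 * 12 * 12 / (24 * 23))

    def test_seed_invariance_without_missingness(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 5, (8, 50)), ["P1"] * 8)
        assert nucleotide_diversity(gm, "P1", seed=1) == nucleotide_diversity(
            gm, "P1", seed=99
        )

    def test_site_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 5, (8, 30))
        gm = make_gm(dos, ["P1"] * 8)
        perm = rng.permutation(30)
        gm2 = make_gm(dos[:, perm], ["P1"] * 8)
        assert nucleotide_diversity(gm, "P1") == pytest.approx(
            nucleotide_diversity(gm2, "P1")
        )

    def test_low_coverage_sites_excluded(self):
        dos = np.full((8, 2), 2)
        dos[0:4, 1] = MISSING  # 4 non-missing < 6 -> excluded
        gm = make_gm(dos, ["P1"] * 8)
        expected = 2 * 16 * 16 / (32 * 31)
        assert nucleotide_diversity(gm, "P1") == pytest.approx(expected)


class TestTajimasD:
    def test_all_singletons_negative(self):
        dos = np.zeros((6, 20), dtype=int)
        dos[0, :] = 1  # every segregating site is a singleton
        gm = make_gm(dos, ["P1"] * 6)
        assert tajimas_d(gm, "P1") < 0

    def test_no_segregating_sites_sentinel(self):
        gm = make_gm(np.zeros((6, 10)), ["P1"] * 6)
        assert np.isnan(tajimas_d(gm, "P1"))

    def test_textbook_formula_oracle_small_sample(self):
        # a = 4 copies, 3 segregating sites with alt counts 1, 2, 1
        alt = np.array([1, 2, 1])
        n = 4
        # independent textbook computation
        S = 3
        pi_tot = sum(2 * k * (n - k) / (n * (n - 1)) for k in alt)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi_tot - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d_from_counts(alt, 4) == pytest.approx(expected)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 5, (8, 40))
        gm = make_gm(dos, ["P1"] * 8)
        perm = rng.permutation(40)
        gm2 = make_gm(dos[:, perm], ["P1"] * 8)
        assert tajimas_d(gm, "P1", seed=0) == pytest.approx(
            tajimas_d(gm2, "P1", seed=0), rel=0.15
        )


# --- fourfold-degenerate sites -------------------------------------------

GFF_TEMPLATE = """##gff-version 3
chr1\tsrc\tgene\t{g1s}\t{g1e}\t.\t+\t.\tID=gene1
chr1\tsrc\tmRNA\t{g1s}\t{g1e}\t.\t+\t.\tID=t1;Parent=gene1
chr1\tsrc\tCDS\t{g1s}\t{g1e}\t.\t+\t0\tID=c1;Parent=t1
chr1\tsrc\tgene\t{g2s}\t{g2e}\t.\t-\t.\tID=gene2
chr1\tsrc\tmRNA\t{g2s}\t{g2e}\t.\t-\t.\tID=t2;Parent=gene2
chr1\tsrc\tCDS\t{g2s}\t{g2e}\t.\t-\t0\tID=c2;Parent=t2
"""


def _fourfold_codons():
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    out = set()
    for b1, b2 in itertools.product("ACGT", repeat=2):
        codons = [b1 + b2 + b3 for b3 in "ACGT"]
        if any(c in standard_dna_table.stop_codons for c in codons):
            continue
        if len({table[c] for c in codons}) == 1:
            out.add(b1 + b2)
    return out


COMP = str.maketrans("ACGT", "TGCA")


def test_fourfold_mask_matches_exhaustive_codon_enumeration(tmp_path):
    """Toy two-gene reference (one minus-strand): every codon of the
    standard table appears; mask equals brute-force enumeration."""
    rng = np.random.default_rng(11)
    codons1 = ["".join(c) for c in itertools.product("ACGT", repeat=3)][:32]
    codons2 = ["".join(c) for c in itertools.product("ACGT", repeat=3)][32:]
    gene1 = "ATG" + "".join(codons1) + "TAA"
    gene2_mrna = "ATG" + "".join(codons2) + "TGA"
    gene2_genomic = gene2_mrna.translate(COMP)[::-1]
    spacer1 = "".join(rng.choice(list("ACGT"), 10))
    spacer2 = "".join(rng.choice(list("ACGT"), 7))
    seq = spacer1 + gene1 + spacer2 + gene2_genomic + "AACC"
    g1s, g1e = len(spacer1) + 1, len(spacer1) + len(gene1)
    g2s = g1e + len(spacer2) + 1
    g2e = g2s + len(gene2_genomic) - 1
    fa = tmp_path / "ref.fa"
    fa.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / "ann.gff3"
    gff.write_text(GFF_TEMPLATE.format(g1s=g1s, g1e=g1e, g2s=g2s, g2e=g2e))

    mask = fourfold_degenerate_sites(str(fa), str(gff))

    ff = _fourfold_codons()
    expected = set()
    for i in range(0, len(gene1), 3):  # + strand: third position = offset+2
        if gene1[i : i + 2] in ff:
            expected.add(("chr1", g1s + i + 2))
    for i in range(0, len(gene2_mrna), 3):  # - strand: walk from the end
        if gene2_mrna[i : i + 2] in ff:
            expected.add(("chr1", g2e - (i + 2)))
    assert mask == expected


def test_fourfold_examples_gly_and_met(tmp_path):
    # single + strand gene ATG GGA TAA: GGA is 4-fold at its third base
    seq = "ATGGGATAA"
    fa = tmp_path / "r.fa"
    fa.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g\n"
        "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c;Parent=g\n"
    )
    mask = fourfold_degenerate_sites(str(fa), str(gff))
    assert mask == {("chr1", 6)}  # GGA third base; ATG and TAA contribute none


def test_cds_not_multiple_of_three_skipped(tmp_path):
    fa = tmp_path / "r.fa"
    fa.write_text(">chr1\nATGGGAT\n")
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t7\t.\t+\t.\tID=g\n"
        "chr1\tsrc\tCDS\t1\t7\t.\t+\t0\tID=c;Parent=g\n"
    )
    assert fourfold_degenerate_sites(str(fa), str(gff)) == set()
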