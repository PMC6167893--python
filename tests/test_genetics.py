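"""Additive coding, Hardy–Weinberg tests, relative pruning, VCF ingestion."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from cohortpath.genetics import (
    GenotypeCounts,
    additive_code,
    genotype_counts_from_dosage,
    hwe_test,
    prune_relatives,
    read_variant_vcf,
)


@pytest.mark.parametrize(
    "genotype, expected",
    [
        ("CC", 0.0),
        ("CT", 1.0),
        ("TC", 1.0),  # permutation invariant
        ("TT", 2.0),
        (("T", "C"), 1.0),
        (("C", "T"), 1.0),
    ],
)
def test_additive_code(genotype, expected):
    assert additive_code(genotype, "T") == expected


def test_additive_code_missing_propagates():
    assert np.isnan(additive_code(None, "T"))
    assert np.isnan(additive_code("./.", "T"))
    assert np.isnan(additive_code(float("nan"), "T"))


def test_additive_code_rejects_foreign_allele():
    with pytest.raises(ValueError, match="neither"):
        additive_code(("A", "T"), "T", ref_allele="C")


def test_hwe_chi2_published_genotype_counts():
    # 5040 / 3373 / 618 -> chi2 ~ 2.75, p ~ 0.10
    chi2, p = hwe_test(GenotypeCounts(5040, 3373, 618))
    assert chi2 == pytest.approx(2.7488, abs=1e-3)
    assert round(p, 2) == 0.10


def test_hwe_chi2_equals_independent_goodness_of_fit():
    counts = GenotypeCounts(5040, 3373, 618)
    chi2, p = hwe_test(counts)
    n = counts.n_total
    q = counts.risk_allele_freq
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    ref = stats.chisquare([5040, 3373, 618], expected, ddof=1)
    assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_hwe_perfect_equilibrium():
    chi2, p = hwe_test(GenotypeCounts(2500, 5000, 2500))
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_hwe_extreme_departure():
    chi2, p = hwe_test(GenotypeCounts(10, 0, 10))
    assert chi2 > 15 and p < 1e-4


def test_hwe_monomorphic_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        hwe_test(GenotypeCounts(50, 0, 0))


def test_hwe_exact_matches_rational_enumeration():
    """Exact-test p-value equals a from-scratch enumeration of the
    Levene/Haldane distribution with exact rational arithmetic."""
    counts = GenotypeCounts(21, 10, 4)  # N=35, 18 rare alleles
    obs_het, p = hwe_test(counts, method="exact")
    assert obs_het == 10
    N, n_rare = 35, 18

    def prob(h: int) -> Fraction:
        ra = (n_rare - h) // 2
        ca = N - h - ra
        if ra < 0 or ca < 0:
            return Fraction(0)
        # multinomial count of genotype configurations x 2^h, normalized below
        return Fraction(
            Fraction(comb(N, h)) * comb(N - h, ra) * 2**h
        )

    hs = range(n_rare % 2, min(n_rare, N) + 1, 2)
    weights = {h: prob(h) for h in hs}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_ref = float(sum(q for q in probs.values() if q <= probs[10]))
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_hwe_pvalues_uniform_under_null():
    """Chi-square p-values over multinomial draws from exact HWE proportions
    are uniform (KS not rejected at alpha = 0.01)."""
    rng = np.random.default_rng(2024)
    q, n = 0.3, 500
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    pvals = []
    for _ in range(1000):
        c = rng.multinomial(n, probs)
        if c[1] + 2 * min(c[0], c[2]) == 0:
            continue
        pvals.append(hwe_test(GenotypeCounts(*c))[1])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# --- relative pruning --------------------------------------------------------

def test_prune_drops_member_with_fewer_weights():
    keep = prune_relatives([("A", "B", 0.5)], {"A": 4, "B": 2})
    assert keep == {"A"}


def test_prune_ignores_duplicate_range():
    keep = prune_relatives([("A", "B", 0.99)], {"A": 4, "B": 2})
    assert keep == {"A", "B"}  # pi-hat >= 0.98 is duplicate-QC domain


def test_prune_tie_drops_lexicographically_larger():
    keep = prune_relatives([("A", "B", 0.5)], {"A": 3, "B": 3})
    assert keep == {"A"}


def test_prune_unknown_id_errors():
    with pytest.raises(ValueError, match="absent"):
        prune_relatives([("A", "Z", 0.5)], {"A": 1, "B": 1})


def _flagged(pairs):
    return [(a, b) for a, b, pi in pairs if 0.35 < pi < 0.98]


def test_prune_triangle_equal_counts_matches_minimal_removal():
    pairs = [("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.5)]
    nw = {"A": 2, "B": 2, "C": 2}
    keep = prune_relatives(pairs, nw)
    # no flagged pair remains
    assert not any(a in keep and b in keep for a, b in _flagged(pairs))
    # exhaustive search: largest conflict-free subset of a triangle has size 1
    best = max(
        (s for r in range(4) for s in itertools.combinations("ABC", r)
         if not any(a in s and b in s for a, b in _flagged(pairs))),
        key=len,
    )
    assert len(keep) == len(best) == 1


def test_prune_random_graphs_no_flagged_pair_and_maximal():
    """On random relatedness graphs up to 50 nodes the kept set never
    contains a flagged pair, and it is maximal: every dropped individual
    conflicts with someone kept (checked exhaustively)."""
    rng = np.random.default_rng(7)
    for trial in range(40):
        n = int(rng.integers(2, 51))
        ids = [f"N{i}" for i in range(n)]
        nw = {i: int(rng.integers(0, 6)) for i in ids}
        pairs = []
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.08:
                pairs.append((a, b, float(rng.uniform(0.2, 1.0))))
        keep = prune_relatives(pairs, nw)
        flagged = _flagged(pairs)
        assert not any(a in keep and b in keep for a, b in flagged)
        dropped = set(ids) - keep
        for d in dropped:
            assert any(
                (a == d and b in keep) or (b == d and a in keep) for a, b in flagged
            )


# --- VCF ---------------------------------------------------------------------

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=10,length=135534747>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
10\t114758349\trs7903146\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
10\t114758350\trs_multi\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
"""


@pytest.fixture()
def vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    return p


def test_read_variant_vcf_counts(vcf_path):
    geno = read_variant_vcf(vcf_path, "rs7903146")
    assert geno["S1"] == ("C", "C")
    assert geno["S2"] == ("C", "T")
    assert geno["S3"] == ("T", "T")
    assert geno["S4"] is None
    dosages = [additive_code(g, "T") if g else float("nan") for g in geno.values()]
    counts = genotype_counts_from_dosage(dosages)
    assert (counts.n_ref_hom, counts.n_het, counts.n_risk_hom) == (1, 1, 1)


def test_read_variant_vcf_errors(vcf_path):
    with pytest.raises(ValueError, match="not found"):
        read_variant_vcf(vcf_path, "rs_nonexistent")
    with pytest.raises(ValueError, match="biallelic"):
        read_variant_vcf(vcf_path, "rs_multi")
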