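"""Mendelian-error mask, HWE exact test, and the QC driver."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

import trioknock as tk
from conftest import manual_cohort
from trioknock.qc import QCError


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _mendel_possible_oracle(gf: int, gm: int, gc: int) -> bool:
    """Brute force: enumerate one transmitted allele from each parent."""
    def alleles(g):
        return {(0, 0): [0], (1, 1): [0, 1], (2, 2): [1]}[(g, g)]
    kids = {a + b for a in alleles(gf) for b in alleles(gm)}
    return gc in kids


def _trio_cohort(gf, gm, gc):
    def pair(g):
        a = [0, 0] if g == 0 else ([0, 1] if g == 1 else [1, 1])
        return ((a[0],), (a[1],))
    return manual_cohort([pair(gf)], [pair(gm)], [pair(gc)])


@pytest.mark.parametrize("gf", [0, 1, 2])
@pytest.mark.parametrize("gm", [0, 1, 2])
@pytest.mark.parametrize("gc", [0, 1, 2])
def test_mendel_mask_matches_enumeration(gf, gm, gc):
    """All 27 genotype triples agree with the transmission enumeration."""
    cohort = _trio_cohort(gf, gm, gc)
    mask, counts = tk.mendelian_error_mask(cohort)
    assert bool(mask[0, 0]) == (not _mendel_possible_oracle(gf, gm, gc))


def test_mendel_mask_examples_and_missing():
    # AA x AA -> Aa is impossible; AA x aa -> Aa is required
    assert tk.mendelian_error_mask(_trio_cohort(0, 0, 1))[0][0, 0]
    assert not tk.mendelian_error_mask(_trio_cohort(0, 2, 1))[0][0, 0]
    cohort = _trio_cohort(0, 0, 1)
    cohort.H[0:2, 0] = -1  # father missing: duo check vs mother AA, child Aa
    mask, _ = tk.mendelian_error_mask(cohort)
    assert not mask[0, 0]
    cohort.H[2:4, 0] = -1  # both parents missing: never flagged
    assert not tk.mendelian_error_mask(cohort)[0][0, 0]


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_oracle(n_aa, n_ab, n_bb) -> float:
    """Exact-fraction enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    probs = {}
    for het in range(min(na, nb) % 2, min(na, nb) + 1, 2):
        hom_a = (na - het) // 2
        hom_b = (nb - het) // 2
        if hom_a < 0 or hom_b < 0:
            continue
        num = (
            Fraction(comb(n, hom_a))
            * comb(n - hom_a, het)
            * Fraction(2) ** het
        )
        probs[het] = num
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


def test_hwe_monomorphic_is_one():
    assert tk.hwe_exact_test(25, 0, 0) == 1.0
    assert tk.hwe_exact_test(0, 0, 9) == 1.0


def test_hwe_small_example_matches_enumeration():
    assert tk.hwe_exact_test(2, 2, 2) == pytest.approx(_hwe_oracle(2, 2, 2), abs=1e-12)


def test_hwe_matches_enumeration_up_to_30_alleles():
    """Full equality with the exact-fraction oracle for all count
    configurations with at most 30 alleles."""
    for n_tot in range(1, 16):  # 2*n_tot alleles <= 30
        for n_aa in range(n_tot + 1):
            for n_ab in range(n_tot - n_aa + 1):
                n_bb = n_tot - n_aa - n_ab
                got = tk.hwe_exact_test(n_aa, n_ab, n_bb)
                want = _hwe_oracle(n_aa, n_ab, n_bb)
                assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)


def test_hwe_null_pvalues_super_uniform():
    """p-values of HWE-null draws lie on/under the uniform (DKW band)."""
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(1000):
        p = rng.uniform(0.1, 0.9)
        g = rng.binomial(1, p, size=(200, 2)).sum(axis=1)
        ps.append(tk.hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                                    int((g == 2).sum())))
    ps = np.sort(ps)
    ecdf = np.arange(1, 1001) / 1000
    dkw = np.sqrt(np.log(2 / 0.01) / (2 * 1000))
    assert np.all(ecdf - ps <= dkw + 1e-9)


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------

def test_apply_qc_maf_filter(small_cohort):
    cohort, _ = small_cohort
    # plant a rare variant: 1 alt haplotype among founders only
    work = tk.PhasedCohort(
        variants=cohort.variants, H=cohort.H.copy(),
        individuals=cohort.individuals, trios=cohort.trios,
    )
    j = 0
    work.H[:, j] = 0
    work.H[0, j] = 1  # a single founder haplotype carries the alt allele
    filtered, report = tk.apply_qc(work, tk.QCThresholds(maf_min=0.01))
    row = report.per_variant.iloc[j]
    assert not row["passed"] and row["reason"] in ("maf", "mendel")
    assert filtered.n_variants == report.n_pass_variants


def test_apply_qc_extreme_thresholds_identity(small_cohort):
    cohort, _ = small_cohort
    thr = tk.QCThresholds(hwe_p_min=0.0, maf_min=0.0, max_missing_rate=1.0)
    filtered, report = tk.apply_qc(cohort, thr)
    assert filtered.n_variants == cohort.n_variants
    assert np.array_equal(filtered.H, cohort.H)


def test_apply_qc_missingness_filter(small_pool):
    cohort, _ = tk.simulate_trios(small_pool, 15, 0, seed=31)
    work = tk.PhasedCohort(
        variants=cohort.variants, H=cohort.H.copy(),
        individuals=cohort.individuals, trios=cohort.trios,
    )
    rng = np.random.default_rng(0)
    victims = rng.choice(cohort.n_individuals, size=3, replace=False)
    for i in victims:  # 3/45 individuals missing at variant 7 => rate ~6.7%
        work.H[2 * i : 2 * i + 2, 7] = -1
    direct_rate = (work.genotypes() == -1)[:, 7].mean()
    assert direct_rate > 0.01
    filtered, report = tk.apply_qc(work, tk.QCThresholds(max_missing_rate=0.01))
    row = report.per_variant.iloc[7]
    assert not row["passed"] and row["reason"] == "missing_rate"
    assert row["missing_rate"] == pytest.approx(direct_rate)


def test_apply_qc_idempotent(small_pool):
    cohort, _ = tk.simulate_trios(small_pool, 15, 5, seed=33, missing_rate=0.005)
    once, r1 = tk.apply_qc(cohort)
    twice, r2 = tk.apply_qc(once)
    assert np.array_equal(once.H, twice.H)
    assert r2.n_pass_variants == r1.n_pass_variants
    assert r2.n_pass_trios == r1.n_pass_trios


def test_apply_qc_all_removed_raises(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(QCError):
        tk.apply_qc(cohort, tk.QCThresholds(maf_min=0.9999))


def test_mendel_zero_out_policy_blanks_trio(small_cohort):
    cohort, _ = small_cohort
    work = tk.PhasedCohort(
        variants=cohort.variants, H=cohort.H.copy(),
        individuals=cohort.individuals, trios=cohort.trios,
    )
    trio = work.trios.iloc[0]
    # force an impossible triple at variant 3: parents hom-ref, child hom-alt
    for who in ("father", "mother"):
        r0, r1 = work.hap_rows(trio[who])
        work.H[[r0, r1], 3] = 0
    c0, c1 = work.hap_rows(trio["child"])
    work.H[[c0, c1], 3] = 1
    filtered, report = tk.apply_qc(work, tk.QCThresholds(max_missing_rate=0.05))
    assert report.per_variant.iloc[3]["mendel_errors"] >= 1
    # blanked (one trio missing stays under the missingness cap), not dropped
    assert report.per_variant.iloc[3]["passed"]
    j_new = filtered.variants.index[filtered.variants["id"] == work.variants.iloc[3]["id"]][0]
    assert (filtered.haplotypes_of(trio["child"])[:, j_new] == -1).all()
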