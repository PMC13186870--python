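"""Synthetic-cohort generator: pool structure, ascertainment, ground truth."""

import math

import numpy as np
import pytest
from scipy import stats

import trioknock as tk
from trioknock.ld import ld_r2_matrix
from trioknock.power import tdt_counts, tdt_counts_all
from trioknock.simulate import ConfigurationError


def test_two_ancestral_no_recombination_gives_perfect_ld():
    """With 2 ancestral haplotypes and no recombination every founder equals
    one ancestral, so every polymorphic variant pair has r^2 = 1."""
    cfg = tk.PoolConfig(
        n_founders=50, n_variants=60, region_start=1, region_end=100_000,
        maf_min=0.2, maf_max=0.5, n_ancestral=2,
        recomb_prob_per_interval=0.0, rare_thinning=False,
    )
    pool = tk.build_haplotype_pool(cfg, seed=5)
    # at most 2 distinct haplotype rows
    assert len(np.unique(pool.H, axis=0)) <= 2
    r2 = ld_r2_matrix(pool.H.astype(float))
    assert np.nanmin(r2) == pytest.approx(1.0, abs=1e-9)


def test_realized_maf_within_bounds_by_direct_count():
    cfg = tk.PoolConfig(
        n_founders=1000, n_variants=100, region_start=1, region_end=200_000,
        maf_min=0.05, maf_max=0.5,
    )
    pool = tk.build_haplotype_pool(cfg, seed=2)
    freq = pool.H.mean(axis=0)  # direct count oracle
    maf = np.minimum(freq, 1 - freq)
    assert np.all(maf >= 0.05 - 1e-12) and np.all(maf <= 0.5 + 1e-12)
    assert np.all(np.diff(pool.positions) > 0)
    assert set(np.unique(pool.H)) <= {0, 1}


def test_infeasible_maf_bounds_raise():
    with pytest.raises(ConfigurationError):
        tk.PoolConfig(maf_min=0.6).validate()
    with pytest.raises(ConfigurationError):
        tk.PoolConfig(n_founders=2).validate()


def test_pool_seed_determinism(small_pool):
    again = tk.build_haplotype_pool(small_pool.config, seed=7)
    assert np.array_equal(small_pool.H, again.H)
    assert np.array_equal(small_pool.positions, again.positions)


def test_study_sized_cohort_structure(study_null_cohort):
    cohort, truth = study_null_cohort
    assert len(cohort.trios) == 157
    assert (cohort.trios["trio_type"] == 1).sum() == 97
    assert (cohort.trios["trio_type"] == 2).sum() == 60
    assert cohort.n_individuals == 471
    # probands affected by ascertainment
    for _, trio in cohort.trios.iterrows():
        assert cohort.phenotype_of(trio["proband"]) == 1.0
    # type-1 proband is the child, type-2 proband a parent
    t1 = cohort.trios[cohort.trios["trio_type"] == 1]
    assert (t1["proband"] == t1["child"]).all()
    t2 = cohort.trios[cohort.trios["trio_type"] == 2]
    assert ((t2["proband"] == t2["father"]) | (t2["proband"] == t2["mother"])).all()


def test_no_mendelian_errors_and_truth_replay(small_pool, small_cohort):
    cohort, truth = small_cohort
    mask, _ = tk.mendelian_error_mask(cohort)
    assert mask.sum() == 0
    # replay: offspring haplotype j equals the recorded transmitted parental
    # pool haplotype at every variant
    for t, trio in cohort.trios.iterrows():
        off = cohort.haplotypes_of(trio["child"])
        for p in range(2):
            rows = truth.parent_rows[t, p]
            tr = truth.transmitted[t, p]
            expect = small_pool.H[rows[0]].copy()
            expect[tr == 1] = small_pool.H[rows[1]][tr == 1]
            assert np.array_equal(off[p], expect)


def test_cohort_seed_determinism(small_pool):
    a, _ = tk.simulate_trios(small_pool, 8, 4, seed=9)
    b, _ = tk.simulate_trios(small_pool, 8, 4, seed=9)
    assert np.array_equal(a.H, b.H)
    assert a.individuals["phenotype"].equals(b.individuals["phenotype"])


def test_null_transmission_rate_is_half(study_null_cohort):
    """Under the global null, het-parent transmissions are fair coin flips."""
    cohort, _ = study_null_cohort
    bs, cs = tdt_counts_all(cohort)
    b, c = bs[::25].sum(), cs[::25].sum()
    n = b + c
    rate = b / n
    assert abs(rate - 0.5) < 3 * math.sqrt(0.25 / n)
    # the scalar counting rule agrees with the vectorised one
    for j in (0, 100, 250):
        assert tdt_counts(cohort, j) == (bs[j], cs[j])


def test_causal_transmission_rate_matches_odds_ratio():
    """Per-allele OR 3 at a common SNP: het parents of affected offspring
    transmit the risk allele with probability OR/(1+OR) = 0.75."""
    cfg = tk.PoolConfig(
        n_founders=400, n_variants=30, region_start=1, region_end=40_000,
        maf_min=0.1, maf_max=0.4,
    )
    pool = tk.build_haplotype_pool(cfg, seed=21)
    causal = int(np.argmin(np.abs(pool.maf() - 0.2)))
    model = tk.DiseaseModel(causal_effects={causal: math.log(3.0)})
    cohort, _ = tk.simulate_trios(pool, 500, 0, model, seed=22)
    b, c = tdt_counts(cohort, causal)
    rate = b / (b + c)
    assert abs(rate - 0.75) < 3 * math.sqrt(0.75 * 0.25 / (b + c))


def test_null_tdt_statistics_chi_square_calibrated():
    """Per-SNP TDT statistics on null data follow chi-square(1): KS over
    >= 500 well-informed unlinked SNPs (free recombination, so the SNPs are
    independent and the KS p-value is valid)."""
    cfg = tk.PoolConfig(
        n_founders=300, n_variants=800, region_start=1,
        region_end=800 * 656, maf_min=0.05,
        recomb_prob_per_interval=0.5, boundary_hotspot_factor=1.0,
    )
    pool = tk.build_haplotype_pool(cfg, seed=61)
    cohort, _ = tk.study_cohort(pool, seed=62)
    b, c = tdt_counts_all(cohort)
    n = b + c
    keep = n >= 30
    assert keep.sum() >= 500
    stats_ = (b[keep] - c[keep]) ** 2 / n[keep]
    ks = stats.kstest(stats_, stats.chi2(1).cdf)
    assert ks.pvalue > 0.01


def test_ascertainment_cap_raises():
    cfg = tk.PoolConfig(
        n_founders=30, n_variants=5, region_start=1, region_end=10_000,
        maf_min=0.2,
    )
    pool = tk.build_haplotype_pool(cfg, seed=1)
    impossible = tk.DiseaseModel(intercept_log_odds=-30.0)
    with pytest.raises(tk.simulate.SimulationError):
        tk.simulate_trios(pool, 2, 0, impossible, seed=1, max_attempts=200)


def test_single_parent_fraction_and_missingness(small_pool):
    cohort, _ = tk.simulate_trios(
        small_pool, 30, 0, seed=17, single_parent_fraction=0.5,
        missing_rate=0.05,
    )
    duos = ((cohort.trios["father"] == "0") | (cohort.trios["mother"] == "0")).sum()
    assert 5 <= duos <= 25
    miss = (cohort.H == -1).mean()
    assert 0.02 < miss < 0.10
    # duo parents removed from the individual table
    assert cohort.n_individuals == 3 * 30 - duos
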