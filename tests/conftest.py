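"""Shared fixtures: small pools/cohorts plus the study-sized null scan.

The expensive study-shaped objects (500-SNP null cohort and its full
knockoff scan) are session-scoped and shared between the calibration
property tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import trioknock as tk


@pytest.fixture(scope="session")
def small_pool() -> tk.HaplotypePool:
    cfg = tk.PoolConfig(
        n_founders=60,
        n_variants=120,
        region_start=1_000_000,
        region_end=1_080_000,
        maf_min=0.05,
    )
    return tk.build_haplotype_pool(cfg, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_pool):
    cohort, truth = tk.simulate_trios(small_pool, 20, 10, seed=3)
    return cohort, truth


@pytest.fixture(scope="session")
def study_null_pool() -> tk.HaplotypePool:
    """500-SNP pool at the design marker density (~656 bp spacing)."""
    cfg = tk.PoolConfig(
        n_founders=300,
        n_variants=500,
        region_start=30_820_506,
        region_end=30_820_506 + 500 * 656,
        maf_min=0.01,
    )
    return tk.build_haplotype_pool(cfg, seed=11)


@pytest.fixture(scope="session")
def study_null_cohort(study_null_pool):
    """Study design (97 type-1 + 60 type-2 trios) under the global null."""
    cohort, truth = tk.study_cohort(study_null_pool, seed=12)
    return cohort, truth


@pytest.fixture(scope="session")
def study_null_scan(study_null_cohort) -> pd.DataFrame:
    """Full knockoff scan (M = 10) of the null study cohort."""
    cohort, _ = study_null_cohort
    return tk.scan_region(
        cohort, sizes=(1000, 2000, 5000), M=10, q_target=0.10, seed=13
    )


def manual_cohort(
    father_haps: list[tuple[tuple[int, int], ...]],
    mother_haps: list[tuple[tuple[int, int], ...]],
    child_haps: list[tuple[tuple[int, int], ...]],
    child_pheno: list[float] | None = None,
    positions: list[int] | None = None,
) -> tk.PhasedCohort:
    """Hand-built trio cohort; haplotypes given per individual as
    ((hap0_alleles...), (hap1_alleles...)) over the variants."""
    n_trios = len(father_haps)
    n_var = len(father_haps[0][0])
    pos = positions or [1000 * (j + 1) for j in range(n_var)]
    variants = pd.DataFrame(
        dict(
            chrom="1",
            pos=pos,
            id=[f"v{j}" for j in range(n_var)],
            ref="A",
            alt="G",
        )
    )
    rows, recs, trios = [], [], []
    pheno = child_pheno or [1.0] * n_trios
    for t in range(n_trios):
        tid = f"trio{t:04d}"
        fa, mo, ch = f"{tid}_F", f"{tid}_M", f"{tid}_C"
        for iid, haps, (sex, father, mother, y) in (
            (fa, father_haps[t], (1, "0", "0", np.nan)),
            (mo, mother_haps[t], (2, "0", "0", np.nan)),
            (ch, child_haps[t], (1, fa, mo, pheno[t])),
        ):
            recs.append(
                dict(iid=iid, fid=tid, father=father, mother=mother,
                     sex=sex, phenotype=y)
            )
            rows += [list(haps[0]), list(haps[1])]
        trios.append(
            dict(trio_id=tid, trio_type=1, father=fa, mother=mo,
                 child=ch, proband=ch)
        )
    return tk.PhasedCohort(
        variants=variants,
        H=np.asarray(rows, dtype=np.int8),
        individuals=pd.DataFrame(recs),
        trios=pd.DataFrame(trios),
    )
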