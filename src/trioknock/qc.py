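"""Post-imputation quality control: Mendelian errors, HWE, MAF, missingness.

Filters follow standard post-imputation practice for trio data: variants are
dropped when the founder minor allele frequency falls below ``maf_min``, the
founder Hardy-Weinberg exact-test p-value falls below ``hwe_p_min``, or the
genotype missing rate exceeds ``max_missing_rate``; Mendelian-inconsistent
trio genotypes are either blanked (default) or cause the variant to be
dropped. Allele frequency and HWE are computed on founders only, avoiding
the dependence induced by transmitted chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import MISSING, PhasedCohort

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "mendelian_error_mask",
    "apply_qc",
]


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    max_missing_rate: float = 0.01
    mendel_policy: str = "zero_out_trio_genotype"  # or "drop_variant"

    def validate(self) -> None:
        for name in ("hwe_p_min", "maf_min", "max_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise QCError(f"{name}={v} outside [0, 1]")
        if self.mendel_policy not in ("zero_out_trio_genotype", "drop_variant"):
            raise QCError(f"unknown mendel_policy {self.mendel_policy!r}")


@dataclass
class QCReport:
    per_variant: pd.DataFrame  # id, maf, hwe_p, missing_rate, mendel_errors, pass, reason
    n_input_variants: int
    n_pass_variants: int
    n_input_trios: int
    n_pass_trios: int

    def write_tsv(self, path: str) -> None:
        self.per_variant.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional HWE test p-value.

    Conditions on the observed allele counts; the p-value sums the
    hypergeometric-type null probabilities of every heterozygote count with
    the same parity whose probability does not exceed that of the observed
    count. Monomorphic input returns 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise QCError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise QCError("all genotype counts zero")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # P(het | allele counts) ∝ n! 2^het / (hom_maj! het! hom_min!)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_maj + 1)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _mendel_table() -> np.ndarray:
    """err[gf, gm, gc] over codes 0..2 plus 3 = missing (never an error)."""
    err = np.zeros((4, 4, 4), dtype=bool)
    for gf in range(3):
        for gm in range(3):
            fa = {0: {0}, 1: {0, 1}, 2: {1}}[gf]
            mo = {0: {0}, 1: {0, 1}, 2: {1}}[gm]
            poss = {a + b for a in fa for b in mo}
            for gc in range(3):
                err[gf, gm, gc] = gc not in poss
    # duo checks: one parent coded missing (3)
    for gp in range(3):
        trans = {0: {0}, 1: {0, 1}, 2: {1}}[gp]
        for gc in range(3):
            ok = any(gc - a in (0, 1) for a in trans)
            err[gp, 3, gc] = not ok
            err[3, gp, gc] = not ok
    return err


_MENDEL_ERR = _mendel_table()


def mendelian_error_mask(cohort: PhasedCohort) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-(trio, variant) boolean mask of Mendelian-impossible genotypes.

    The check is at the unphased genotype level; duos are checked against
    the single present parent; missing genotypes are never flagged.
    Returns the mask (n_trios, n_variants) and a per-variant count frame.
    """
    G = cohort.genotypes()
    n_trios = len(cohort.trios)
    mask = np.zeros((n_trios, cohort.n_variants), dtype=bool)
    for t, trio in cohort.trios.iterrows():
        gc = G[cohort.index_of(trio["child"])]
        gf = (
            G[cohort.index_of(trio["father"])]
            if trio["father"] != "0"
            else np.full_like(gc, MISSING)
        )
        gm = (
            G[cohort.index_of(trio["mother"])]
            if trio["mother"] != "0"
            else np.full_like(gc, MISSING)
        )
        code = lambda g: np.where(g == MISSING, 3, g)
        mask[t] = _MENDEL_ERR[code(gf), code(gm), code(gc)]
    counts = pd.DataFrame(
        dict(id=cohort.variants["id"], mendel_errors=mask.sum(axis=0))
    )
    return mask, counts


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------

def _founder_genotype_counts(cohort: PhasedCohort) -> np.ndarray:
    """(n_variants, 3) counts of ref-hom / het / alt-hom among founders."""
    G = cohort.genotypes()[cohort.founder_mask()]
    out = np.zeros((cohort.n_variants, 3), dtype=np.int64)
    for g in range(3):
        out[:, g] = (G == g).sum(axis=0)
    return out


def apply_qc(
    cohort: PhasedCohort, thresholds: QCThresholds | None = None
) -> tuple[PhasedCohort, QCReport]:
    """Apply the variant filters and the Mendelian-error policy.

    Order: Mendelian policy first (blanking introduces missingness that the
    missing-rate filter must see), then missing rate, founder MAF, founder
    HWE. Trios whose proband genotype is entirely missing are removed along
    with their members. Raises :class:`QCError` if no variant survives.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    thr.validate()
    n_in_var, n_in_trio = cohort.n_variants, len(cohort.trios)

    mask, mendel_counts = mendelian_error_mask(cohort)
    H = cohort.H.copy()
    if thr.mendel_policy == "zero_out_trio_genotype":
        for t, trio in cohort.trios.iterrows():
            bad = np.flatnonzero(mask[t])
            if bad.size == 0:
                continue
            for col in ("father", "mother", "child"):
                if trio[col] != "0":
                    r0, r1 = cohort.hap_rows(trio[col])
                    H[r0, bad] = MISSING
                    H[r1, bad] = MISSING
    work = PhasedCohort(
        variants=cohort.variants,
        H=H,
        individuals=cohort.individuals,
        trios=cohort.trios,
    )

    G = work.genotypes()
    missing_rate = (G == MISSING).mean(axis=0)
    counts = _founder_genotype_counts(work)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_f = (2 * counts[:, 2] + counts[:, 1]) / (2 * total)
    maf = np.minimum(alt_f, 1 - alt_f)
    hwe_p = np.array(
        [
            hwe_exact_test(int(c[0]), int(c[1]), int(c[2])) if c.sum() else 1.0
            for c in counts
        ]
    )

    reason = np.full(work.n_variants, "", dtype=object)
    if thr.mendel_policy == "drop_variant":
        reason[mendel_counts["mendel_errors"].to_numpy() > 0] = "mendel"
    drop_missing = (missing_rate > thr.max_missing_rate) & (reason == "")
    reason[drop_missing] = "missing_rate"
    drop_maf = (np.nan_to_num(maf, nan=0.0) < thr.maf_min) & (reason == "")
    reason[drop_maf] = "maf"
    drop_hwe = (hwe_p < thr.hwe_p_min) & (reason == "")
    reason[drop_hwe] = "hwe"
    ok = reason == ""

    per_variant = pd.DataFrame(
        dict(
            id=work.variants["id"],
            maf=maf,
            hwe_p=hwe_p,
            missing_rate=missing_rate,
            mendel_errors=mendel_counts["mendel_errors"],
            passed=ok,
            reason=reason,
        )
    )
    if not ok.any():
        raise QCError("all variants removed by QC")
    filtered = work.subset_variants(np.flatnonzero(ok))

    # drop trios whose proband genotype is fully missing
    Gf = filtered.genotypes()
    keep_trio = np.ones(len(filtered.trios), dtype=bool)
    for t, trio in filtered.trios.iterrows():
        gp = Gf[filtered.index_of(trio["proband"])]
        if np.all(gp == MISSING):
            keep_trio[t] = False
    if not keep_trio.all():
        dead = filtered.trios[~keep_trio]
        member_cols = dead[["father", "mother", "child"]].to_numpy().ravel()
        drop_iids = {m for m in member_cols if m != "0"}
        keep_iids = set(filtered.individuals["iid"]) - drop_iids
        filtered = filtered.subset_individuals(keep_iids)

    report = QCReport(
        per_variant=per_variant,
        n_input_variants=n_in_var,
        n_pass_variants=filtered.n_variants,
        n_input_trios=n_in_trio,
        n_pass_trios=len(filtered.trios),
    )
    return filtered, report
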