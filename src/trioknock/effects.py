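"""Per-SNP odds ratios from case/pseudo-control conditional logistic models.

For each variant, trios with at least one heterozygous parent and an
affected offspring form 1:3 matched sets: the affected offspring's additive
genotype is the case, and the three alternative genotypes constructible
from the parents' alleles are its pseudo-controls. Maximising the
conditional likelihood gives the per-allele log odds ratio; affected
parents are permissible because the likelihood conditions on parental
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, PhasedCohort

__all__ = ["EffectEstimate", "select_informative_trios", "pseudo_control_logistic"]


@dataclass
class EffectEstimate:
    variant_id: str
    allele: str
    n_informative_trios: int
    log_or: float
    or_: float
    ci95: tuple[float, float]
    p: float
    status: str  # "ok" | "separated" | "no_informative_trios"

    def to_dict(self) -> dict:
        return dict(
            variant=self.variant_id,
            allele=self.allele,
            n_informative=self.n_informative_trios,
            OR=self.or_,
            ci_low=self.ci95[0],
            ci_high=self.ci95[1],
            p=self.p,
            status=self.status,
        )


def select_informative_trios(variant_index: int, cohort: PhasedCohort) -> pd.DataFrame:
    """Complete trios where the father or the mother is heterozygous."""
    G = cohort.genotypes()
    keep = []
    for t, trio in cohort.complete_trios().iterrows():
        gf = G[cohort.index_of(trio["father"]), variant_index]
        gm = G[cohort.index_of(trio["mother"]), variant_index]
        if gf == 1 or gm == 1:
            keep.append(trio)
    return pd.DataFrame(keep).reset_index(drop=True)


def _matched_sets(
    variant_index: int, cohort: PhasedCohort, trios: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Case/pseudo-control dosages; also transmitted/untransmitted alt counts."""
    xs, ys, groups = [], [], []
    b = c = 0  # alt / ref transmissions from heterozygous parents
    g = 0
    for _, trio in trios.iterrows():
        if cohort.phenotype_of(trio["child"]) != 1.0:
            continue  # the conditional likelihood needs an affected offspring
        fh = cohort.haplotypes_of(trio["father"])
        mh = cohort.haplotypes_of(trio["mother"])
        ch = cohort.haplotypes_of(trio["child"])
        fa = fh[:, variant_index]
        mo = mh[:, variant_index]
        kid = ch[:, variant_index]
        if MISSING in (*fa, *mo, *kid):
            continue
        case = int(kid.sum())
        combos = [int(a + m) for a in fa for m in mo]
        # the case corresponds to one transmitted combination; remove one
        # matching instance and keep the other three as pseudo-controls
        combos.remove(case)
        xs += [case] + combos
        ys += [1, 0, 0, 0]
        groups += [g] * 4
        g += 1
        # transmitted/untransmitted counts from het parents (TDT counting
        # rule on unphased genotypes; double-het with het child is ambiguous)
        if fa[0] != fa[1]:
            tf = _transmitted_allele(fa, mo, kid)
            if tf is not None:
                b += tf
                c += 1 - tf
        if mo[0] != mo[1]:
            tm = _transmitted_allele(mo, fa, kid)
            if tm is not None:
                b += tm
                c += 1 - tm
    return (
        np.asarray(xs, dtype=float),
        np.asarray(ys),
        np.asarray(groups),
        b,
        c,
    )


def _transmitted_allele(het_parent, other_parent, kid) -> int | None:
    """Allele transmitted by a heterozygous parent, from unphased genotypes.

    Determined whenever the child genotype resolves it (the classic TDT
    counting rule); ambiguous double-het configurations where both
    transmissions are consistent return half-informative None.
    """
    gc = int(kid.sum())
    go = int(other_parent.sum())
    if go == 0:
        return 1 if gc >= 1 else 0
    if go == 2:
        return 1 if gc == 2 else 0
    # other parent het too: child hom resolves both, child het is ambiguous
    if gc == 0:
        return 0
    if gc == 2:
        return 1
    return None


def pseudo_control_logistic(
    variant_index: int, cohort: PhasedCohort
) -> EffectEstimate:
    """Estimate the per-allele OR for one variant.

    Complete separation (all informative transmissions one-sided) is
    reported as an infinite (or zero) OR with status ``"separated"``
    rather than an optimiser failure.
    """
    vid = str(cohort.variants["id"].iloc[variant_index])
    trios = select_informative_trios(variant_index, cohort)
    if len(trios) == 0:
        return EffectEstimate(
            vid, "alt", 0, np.nan, np.nan, (np.nan, np.nan), np.nan,
            "no_informative_trios",
        )
    x, y, groups, b, c = _matched_sets(variant_index, cohort, trios)
    n_sets = len(np.unique(groups)) if len(groups) else 0
    if n_sets == 0:
        return EffectEstimate(
            vid, "alt", len(trios), np.nan, np.nan, (np.nan, np.nan), np.nan,
            "no_informative_trios",
        )
    if b == 0 or c == 0:
        est = np.inf if c == 0 else 0.0
        return EffectEstimate(
            vid, "alt", len(trios), np.log(est) if est else -np.inf, est,
            (np.nan, np.nan), np.nan, "separated",
        )
    from statsmodels.discrete.conditional_models import ConditionalLogit

    model = ConditionalLogit(y, x[:, None], groups=groups)
    fit = model.fit(disp=False, method="newton")
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    ci = (np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se))
    return EffectEstimate(
        vid, "alt", len(trios), beta, float(np.exp(beta)), ci,
        float(fit.pvalues[0]), "ok",
    )


def estimate_effects(
    cohort: PhasedCohort, variant_ids: list[str]
) -> pd.DataFrame:
    """Per-variant conditional-logistic estimates as a tidy frame."""
    idx = {v: j for j, v in enumerate(cohort.variants["id"])}
    rows = []
    for vid in variant_ids:
        if vid not in idx:
            raise KeyError(f"unknown variant id {vid!r}")
        rows.append(pseudo_control_logistic(idx[vid], cohort).to_dict())
    return pd.DataFrame(rows)
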