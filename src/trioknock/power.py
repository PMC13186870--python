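"""Analytic TDT power over a MAF x OR grid, with a simulation cross-check.

The transmission disequilibrium test (TDT) counts transmissions of the risk
allele from heterozygous parents to affected offspring and rejects when
(b - c)^2 / (b + c) exceeds the chi-square(1) critical value. Power is
computed from the joint distribution of parental mating types and
transmissions conditional on an affected offspring: parental genotypes in
Hardy-Weinberg proportions, genotype risks in the rare-disease
approximation, and — under the additive model — genotype relative risks
1 : OR : 2*OR - 1 (the convention of standard trio power calculators;
``model="multiplicative"`` gives 1 : OR : OR^2).

``method="exact"`` convolves the per-trio transmission distribution to the
exact rejection probability of the discrete statistic;
``method="ncx2"`` uses the classical noncentral-chi-square approximation
with ncp = 2 n h (2 tau - 1)^2, where h is the probability a parent of an
affected offspring is heterozygous and tau the risk-allele transmission
probability from such a parent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionalMatingDistribution",
    "conditional_mating_distribution",
    "tdt_power",
    "tdt_power_simulated",
    "power_grid",
    "tdt_counts",
    "tdt_counts_all",
]

_TRANSMIT = {0: ((0, 1.0),), 1: ((0, 0.5), (1, 0.5)), 2: ((1, 1.0),)}


def _genotype_relative_risk(or_: float, model: str) -> dict[int, float]:
    if model == "additive":
        return {g: 1.0 + (or_ - 1.0) * g for g in range(3)}
    if model == "multiplicative":
        return {g: or_**g for g in range(3)}
    raise ValueError(f"unknown model {model!r}")


@dataclass
class ConditionalMatingDistribution:
    """Joint law of (parent genotypes, transmissions) given an affected child."""

    joint: pd.DataFrame  # gf, gm, tf, tm, prob
    het_parent_prob: float  # h: P(a given parent is heterozygous)
    transmission_prob: float  # tau: P(het parent transmits the risk allele)
    per_trio_bc: dict[tuple[int, int], float]  # informative (b, c) per trio

    def total(self) -> float:
        return float(self.joint["prob"].sum())


def conditional_mating_distribution(
    maf: float, per_allele_or: float, model: str = "additive"
) -> ConditionalMatingDistribution:
    """Distribution of parental genotypes and transmissions given affection.

    Parental genotypes follow Hardy-Weinberg proportions at risk-allele
    frequency ``maf``; the offspring genotype (the two transmitted alleles)
    carries relative risk per :func:`_genotype_relative_risk`; Bayes
    inversion conditions on the offspring being affected (the baseline risk
    cancels under the rare-disease approximation).
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if per_allele_or <= 0:
        raise ValueError("per-allele OR must be positive")
    p = maf
    gt_freq = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
    grr = _genotype_relative_risk(per_allele_or, model)
    rows = []
    bc: dict[tuple[int, int], float] = {}
    for gf, gm in itertools.product(range(3), repeat=2):
        for (tf, pf), (tm, pm) in itertools.product(_TRANSMIT[gf], _TRANSMIT[gm]):
            w = gt_freq[gf] * gt_freq[gm] * pf * pm * grr[tf + tm]
            rows.append(dict(gf=gf, gm=gm, tf=tf, tm=tm, prob=w))
    joint = pd.DataFrame(rows)
    joint["prob"] /= joint["prob"].sum()
    joint = joint.groupby(["gf", "gm", "tf", "tm"], as_index=False)["prob"].sum()
    for _, r in joint.iterrows():
        b = int(r.gf == 1 and r.tf == 1) + int(r.gm == 1 and r.tm == 1)
        c = int(r.gf == 1 and r.tf == 0) + int(r.gm == 1 and r.tm == 0)
        bc[(b, c)] = bc.get((b, c), 0.0) + float(r.prob)
    h = float(joint.loc[joint.gf == 1, "prob"].sum())
    tau = float(joint.loc[(joint.gf == 1) & (joint.tf == 1), "prob"].sum()) / h
    return ConditionalMatingDistribution(joint, h, tau, bc)


def _exact_power(n: int, bc: dict[tuple[int, int], float], alpha: float) -> float:
    """Exact rejection probability by 2-D convolution over (b, c) totals."""
    S = 2 * n + 1
    P = np.zeros((S, S))
    P[0, 0] = 1.0
    for _ in range(n):
        Q = np.zeros_like(P)
        for (b, c), w in bc.items():
            if b == 0 and c == 0:
                Q += w * P
            else:
                Q[b:, c:] += w * P[: S - b, : S - c]
        P = Q
    B, C = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
    T = B + C
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(T > 0, (B - C) ** 2 / np.maximum(T, 1), 0.0)
    crit = stats.chi2.ppf(1 - alpha, 1)
    return float(P[stat > crit].sum())


def tdt_power(
    n_trios: int,
    maf: float,
    per_allele_or: float,
    alpha: float = 0.05,
    model: str = "additive",
    method: str = "exact",
) -> float:
    """Power of the allelic TDT for ``n_trios`` ascertained trios."""
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    dist = conditional_mating_distribution(maf, per_allele_or, model)
    if method == "exact":
        return _exact_power(n_trios, dist.per_trio_bc, alpha)
    if method == "ncx2":
        h, tau = dist.het_parent_prob, dist.transmission_prob
        ncp = 2 * n_trios * h * (2 * tau - 1) ** 2
        crit = stats.chi2.ppf(1 - alpha, 1)
        return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)
    raise ValueError(f"unknown method {method!r}")


def tdt_power_simulated(
    n_trios: int,
    maf: float,
    per_allele_or: float,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
    model: str = "additive",
    base_risk: float = 0.05,
) -> tuple[float, float]:
    """Monte-Carlo TDT power from rejection-sampled ascertained trios.

    Each replicate draws ``n_trios`` trios: parental alleles Bernoulli(maf)
    under random mating, fair Mendelian transmission, affection with
    probability base_risk * relative-risk(genotype), redrawn until the
    offspring is affected. Under the relative-risk model the accepted-trio
    distribution is invariant to ``base_risk`` (it cancels in the
    conditioning), which only sets the rejection rate. Returns the
    rejection fraction and its binomial Monte-Carlo standard error.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    grr_map = _genotype_relative_risk(per_allele_or, model)
    grr = np.array([grr_map[g] for g in range(3)])
    risk = np.clip(base_risk * grr, 0.0, 1.0)
    if risk[2] >= 1.0:
        raise ValueError("base_risk too large for this OR")
    rng = np.random.default_rng(seed)
    total = n_reps * n_trios
    b_tot = np.zeros(total, dtype=np.int64)
    c_tot = np.zeros(total, dtype=np.int64)
    active = np.arange(total)
    while active.size:
        n = active.size
        fa = (rng.random((n, 2)) < maf).astype(np.int8)
        mo = (rng.random((n, 2)) < maf).astype(np.int8)
        tf = rng.integers(0, 2, size=n)
        tm = rng.integers(0, 2, size=n)
        af = fa[np.arange(n), tf]
        am = mo[np.arange(n), tm]
        g = af + am
        y = rng.random(n) < risk[g]
        acc = np.flatnonzero(y)
        idx = active[acc]
        fhet = fa[acc, 0] != fa[acc, 1]
        mhet = mo[acc, 0] != mo[acc, 1]
        b_tot[idx] = fhet * af[acc] + mhet * am[acc]
        c_tot[idx] = fhet * (1 - af[acc]) + mhet * (1 - am[acc])
        active = active[~y]
    B = b_tot.reshape(n_reps, n_trios).sum(axis=1)
    C = c_tot.reshape(n_reps, n_trios).sum(axis=1)
    T = B + C
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(T > 0, (B - C) ** 2 / np.maximum(T, 1), 0.0)
    crit = stats.chi2.ppf(1 - alpha, 1)
    power = float(np.mean(stat > crit))
    se = float(np.sqrt(power * (1 - power) / n_reps))
    return power, se


def power_grid(
    n_trios: int = 142,
    alpha: float = 0.05,
    mafs: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3),
    ors: tuple[float, ...] = (1.2, 1.9, 3.0),
    model: str = "additive",
    method: str = "exact",
) -> pd.DataFrame:
    """Analytic power grid for the default design (rows = MAF, columns = OR)."""
    grid = pd.DataFrame(
        {
            f"OR={o}": [
                tdt_power(n_trios, m, o, alpha, model, method) for m in mafs
            ]
            for o in ors
        },
        index=pd.Index(mafs, name="MAF"),
    )
    return grid


def tdt_counts_all(cohort) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allelic TDT counts (b, c) for every variant.

    Complete trios with an affected offspring and no missing genotypes at
    the variant contribute; double-het matings with a het child add one
    transmission of each allele.
    """
    rows_f, rows_m, rows_c = [], [], []
    for _, trio in cohort.complete_trios().iterrows():
        if cohort.phenotype_of(trio["child"]) != 1.0:
            continue
        rows_f.append(cohort.index_of(trio["father"]))
        rows_m.append(cohort.index_of(trio["mother"]))
        rows_c.append(cohort.index_of(trio["child"]))
    G = cohort.genotypes()
    gf = G[rows_f].astype(np.int64)
    gm = G[rows_m].astype(np.int64)
    gc = G[rows_c].astype(np.int64)
    ok = (gf >= 0) & (gm >= 0) & (gc >= 0)
    fhet = (gf == 1) & ok
    mhet = (gm == 1) & ok
    b = np.zeros(G.shape[1], dtype=np.int64)
    c = np.zeros(G.shape[1], dtype=np.int64)
    one_f = fhet & ~mhet
    t_f = gc - gm // 2
    b += (one_f & (t_f == 1)).sum(axis=0)
    c += (one_f & (t_f == 0)).sum(axis=0)
    one_m = mhet & ~fhet
    t_m = gc - gf // 2
    b += (one_m & (t_m == 1)).sum(axis=0)
    c += (one_m & (t_m == 0)).sum(axis=0)
    both = fhet & mhet
    b += 2 * (both & (gc == 2)).sum(axis=0) + (both & (gc == 1)).sum(axis=0)
    c += 2 * (both & (gc == 0)).sum(axis=0) + (both & (gc == 1)).sum(axis=0)
    return b, c


def tdt_counts(cohort, variant_index: int) -> tuple[int, int]:
    """Allelic TDT transmitted/untransmitted alt counts for one variant.

    Uses the classic unphased counting rule over complete trios with an
    affected offspring; double-het matings with a het child contribute one
    transmission of each allele.
    """
    from .effects import _transmitted_allele

    b = c = 0
    for _, trio in cohort.complete_trios().iterrows():
        if cohort.phenotype_of(trio["child"]) != 1.0:
            continue
        fa = cohort.haplotypes_of(trio["father"])[:, variant_index]
        mo = cohort.haplotypes_of(trio["mother"])[:, variant_index]
        kid = cohort.haplotypes_of(trio["child"])[:, variant_index]
        if min(*fa, *mo, *kid) < 0:
            continue
        fhet, mhet = fa[0] != fa[1], mo[0] != mo[1]
        gc = int(kid.sum())
        if fhet and mhet and gc == 1:
            b += 1
            c += 1
            continue
        for par, other in ((fa, mo), (mo, fa)):
            if par[0] != par[1]:
                t = _transmitted_allele(par, other, kid)
                if t is not None:
                    b += t
                    c += 1 - t
    return b, c
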