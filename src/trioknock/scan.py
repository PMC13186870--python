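"""Multi-resolution LASSO-weighted burden FBAT scan with knockoff FDR filter.

The region is tiled with half-overlapping windows at several sizes (500 bp
to 20 kb by default). Each window gets burden weights from an L1-penalised
regression of offspring phenotype on offspring dosages, a family-based
score statistic Z comparing observed transmissions with their Mendelian
expectation conditional on phased parental haplotypes, the same statistic
Z* on each of the M knockoff copies, the ratio statistic
W = |Z| / median|Z*|, and a two-sided normal p-value for Z. Selection uses
the multiple-knockoff kappa/tau filter at a target FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .cohort import MISSING, PhasedCohort
from .knockoffs import KnockoffSet, generate_knockoff_cohorts
from .ld import LDBlockPartition, ld_r2_matrix, partition_blocks, scaffold_partition
from .transmission import infer_transmission

__all__ = [
    "DEFAULT_WINDOW_SIZES",
    "ScanWindow",
    "BurdenWeights",
    "make_windows",
    "fit_burden_weights",
    "FbatEngine",
    "z_to_p",
    "window_statistic",
    "knockoff_fdr_select",
    "scan_region",
]

DEFAULT_WINDOW_SIZES = (500, 1000, 2000, 5000, 10_000, 15_000, 20_000)


@dataclass
class ScanWindow:
    """1-based inclusive window [start_bp, end_bp] with its member variants."""

    chrom: str
    start_bp: int
    end_bp: int
    size: int
    members: np.ndarray  # variant indices
    clipped: bool = False


@dataclass
class BurdenWeights:
    b: np.ndarray
    lam: float | None
    fallback: bool


def make_windows(
    region: tuple[int, int],
    sizes: tuple[int, ...],
    positions: np.ndarray,
    chrom: str = ".",
) -> list[ScanWindow]:
    """Half-overlapping windows of each size covering the region.

    Windows of size s start at region_start + k*(s // 2) while they fit in
    the region; windows containing no variants are dropped. A region
    shorter than a requested size yields a single clipped window flagged as
    such.
    """
    start0, end0 = region
    if start0 > end0:
        raise ValueError("region start after end")
    pos = np.asarray(positions)
    out: list[ScanWindow] = []
    for s in sizes:
        if end0 - start0 + 1 < s:
            members = np.arange(
                np.searchsorted(pos, start0), np.searchsorted(pos, end0, "right")
            )
            if members.size:
                out.append(ScanWindow(chrom, start0, end0, s, members, clipped=True))
            continue
        step = s // 2
        w_start = start0
        while w_start + s - 1 <= end0:
            w_end = w_start + s - 1
            members = np.arange(
                np.searchsorted(pos, w_start), np.searchsorted(pos, w_end, "right")
            )
            if members.size:
                out.append(ScanWindow(chrom, w_start, w_end, s, members))
            w_start += step
    return out


def fit_burden_weights(
    X: np.ndarray,
    y: np.ndarray,
    lambda_policy: str = "cv_min",
    lam: float | None = None,
    fold_seed: int = 13,
) -> BurdenWeights:
    """LASSO burden weights for one window.

    Minimises 0.5 ||y - Xb||^2 + lam ||b||_1 on offspring additive dosages
    against phenotype; ``lambda_policy="cv_min"`` picks lam by 5-fold
    cross-validation (fixed fold seed), ``"fixed"`` uses ``lam``. If every
    coefficient shrinks to zero (or the phenotype is constant), weights
    fall back to equal 1/sqrt(p) with the fallback flag set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    equal = np.full(p, 1.0 / np.sqrt(p))
    if np.ptp(y) == 0 or np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("constant phenotype or genotypes; equal burden weights used")
        return BurdenWeights(equal, None, True)
    if len(y) < 10:
        raise ValueError("need at least 10 phenotyped offspring")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if lambda_policy == "cv_min":
            cv = KFold(n_splits=5, shuffle=True, random_state=fold_seed)
            model = LassoCV(alphas=30, cv=cv, max_iter=2000).fit(X, y)
            lam_used = float(model.alpha_) * len(y)  # sklearn scales by 1/n
        elif lambda_policy == "fixed":
            if lam is None:
                raise ValueError("lambda_policy='fixed' requires lam")
            model = Lasso(alpha=lam / len(y), max_iter=2000).fit(X, y)
            lam_used = lam
        else:
            raise ValueError(f"unknown lambda_policy {lambda_policy!r}")
    b = model.coef_.copy()
    if np.all(b == 0):
        return BurdenWeights(equal, lam_used, True)
    return BurdenWeights(b, lam_used, False)


class FbatEngine:
    """Weighted burden FBAT scores on a trio cohort (original or knockoff).

    Per complete trio i with offspring phenotype y_i the burden is
    B_i = sum_j b_j x_ij over offspring dosages; its expectation and
    variance conditional on the phased parents assume each parent transmits
    either window haplotype with probability 1/2, independently. The score
    is Z = U / sqrt(V) with U = sum_i (y_i - mu)(B_i - E B_i) and
    V = sum_i (y_i - mu)^2 Var B_i; mu defaults to the offspring
    prevalence in the cohort. Trio-variant entries with any missing member
    genotype contribute nothing.
    """

    def __init__(self, cohort: PhasedCohort, offset_mu: float | None = None):
        rows = {k: [] for k in ("f0", "f1", "m0", "m1", "c0", "c1")}
        y = []
        for _, trio in cohort.trios.iterrows():
            if trio["father"] == "0" or trio["mother"] == "0":
                continue  # duos: conditional expectation needs both parents
            yo = cohort.phenotype_of(trio["child"])
            if np.isnan(yo):
                continue
            f = cohort.hap_rows(trio["father"])
            m = cohort.hap_rows(trio["mother"])
            c = cohort.hap_rows(trio["child"])
            for k, r in zip(("f0", "f1", "m0", "m1", "c0", "c1"), (*f, *m, *c)):
                rows[k].append(r)
            y.append(yo)
        self.rows = {k: np.asarray(v, dtype=np.int64) for k, v in rows.items()}
        self.y = np.asarray(y)
        self.n_trios = len(y)
        self.mu = float(np.mean(self.y)) if offset_mu is None else float(offset_mu)
        self.w = self.y - self.mu

    def _gather(self, H: np.ndarray, cols: np.ndarray):
        g = {k: H[r][:, cols].astype(np.float64) for k, r in self.rows.items()}
        miss = np.zeros_like(g["f0"], dtype=bool)
        for k in g:
            miss |= g[k] == MISSING
        x = g["c0"] + g["c1"]
        ex = (g["f0"] + g["f1"] + g["m0"] + g["m1"]) / 2.0
        df = (g["f0"] - g["f1"]) / 2.0
        dm = (g["m0"] - g["m1"]) / 2.0
        for arr in (x, ex, df, dm):
            arr[miss] = 0.0
        x[miss] = 0.0
        ex[miss] = 0.0
        return x, ex, df, dm

    def offspring_dosage(self, H: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Offspring dosages with missing entries mean-imputed (for LASSO)."""
        c0 = H[self.rows["c0"]][:, cols].astype(float)
        c1 = H[self.rows["c1"]][:, cols].astype(float)
        x = c0 + c1
        x[(c0 == MISSING) | (c1 == MISSING)] = np.nan
        return _mean_impute(x)

    def parental_expected_dosage(self, H: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """E[offspring dosage | parents] = mean parental dosage, per trio.

        The between-family component of the genotype: a function of the
        parents only, hence independent of the Mendelian transmissions that
        the FBAT scores. Burden weights fitted on it leave the
        within-family test (and the original/knockoff comparison) free of
        selection-induced inflation.
        """
        g = {
            k: H[self.rows[k]][:, cols].astype(float)
            for k in ("f0", "f1", "m0", "m1")
        }
        miss = np.zeros_like(g["f0"], dtype=bool)
        for k in g:
            miss |= g[k] == MISSING
        ex = (g["f0"] + g["f1"] + g["m0"] + g["m1"]) / 2.0
        ex[miss] = np.nan
        return _mean_impute(ex)

    def zstat(self, H: np.ndarray, cols: np.ndarray, b: np.ndarray) -> float:
        """Z for one window; NaN when no trio is informative (V = 0)."""
        x, ex, df, dm = self._gather(H, cols)
        resid = (x - ex) @ b
        var = (df @ b) ** 2 + (dm @ b) ** 2
        U = self.w @ resid
        V = (self.w**2) @ var
        if V <= 0:
            return float("nan")
        return float(U / np.sqrt(V))


def _mean_impute(x: np.ndarray) -> np.ndarray:
    mu = np.nan_to_num(np.nanmean(x, axis=0))
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    return x


def z_to_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal tail probability 2(1 - Phi(|Z|))."""
    return special.erfc(np.abs(z) / np.sqrt(2.0))


def window_statistic(z: float, zstar: np.ndarray) -> tuple[float, float]:
    """(W, p_burden): W = |Z| / median_m |Z*_m|, NaN copies dropped.

    W is NaN when Z is undefined, every knockoff score is undefined, or the
    median knockoff score is 0.
    """
    zstar = np.asarray(zstar, dtype=float)
    if np.isnan(zstar).any():
        warnings.warn("undefined knockoff scores dropped from the W median")
    med = np.nanmedian(np.abs(zstar)) if not np.all(np.isnan(zstar)) else np.nan
    if np.isnan(z) or np.isnan(med) or med == 0:
        w = float("nan")
    else:
        w = float(np.abs(z) / med)
    p = float(z_to_p(z)) if not np.isnan(z) else float("nan")
    return w, p


def _kappa_tau(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per row of |scores| (original first): winner index and margin.

    kappa is the index of the largest absolute score (0 = original wins,
    ties favour the original); tau is that maximum minus the median of the
    remaining scores.
    """
    a = np.abs(scores)
    kappa = np.nanargmax(a, axis=1)
    amax = np.nanmax(a, axis=1)
    rest = a.copy()
    rest[np.arange(len(a)), kappa] = np.nan
    tau = amax - np.nanmedian(rest, axis=1)
    return kappa, tau


def knockoff_fdr_select(
    results: pd.DataFrame, q_target: float = 0.05, M: int | None = None
) -> pd.DataFrame:
    """Multiple-knockoff kappa/tau selection with per-window q.

    For each window the winner among (|Z|, |Z*_1|, ..., |Z*_M|) and the
    margin tau = winner - median(losers) are computed; a window is
    selectable only when the original wins (kappa = 0). The tau threshold
    is the smallest value at which the estimated FDR
    (1 + #knockoff wins above threshold) / M / #original wins above it
    drops to ``q_target``; the per-window ``q`` is the smallest target at
    which that window would be selected. Returns a copy of ``results``
    with ``q`` and ``selected`` columns filled.
    """
    out = results.copy()
    zcols = [c for c in results.columns if c.startswith("Zstar_")]
    if M is None:
        M = len(zcols)
    scores = results[["Z", *zcols]].to_numpy(dtype=float)
    valid = ~np.isnan(scores[:, 0]) & ~np.all(np.isnan(scores[:, 1:]), axis=1)
    out["q"] = np.nan
    out["selected"] = False
    if valid.sum() == 0:
        return out
    kappa, tau = _kappa_tau(scores[valid])

    cand = np.unique(tau)
    # counts of wins with tau >= t via reverse cumulative sums
    order = np.argsort(tau)
    tau_sorted = tau[order]
    orig_sorted = (kappa[order] == 0).astype(int)

    def counts_at(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(tau_sorted, ts, side="left")
        tot_orig = np.cumsum(orig_sorted[::-1])[::-1]
        tot_any = np.arange(len(tau_sorted), 0, -1)
        n_orig = np.where(idx < len(tau_sorted), tot_orig[np.minimum(idx, len(tau_sorted) - 1)], 0)
        n_any = np.where(idx < len(tau_sorted), tot_any[np.minimum(idx, len(tau_sorted) - 1)], 0)
        return n_orig, n_any - n_orig

    n_orig, n_ko = counts_at(cand)
    with np.errstate(divide="ignore"):
        fdr_est = (1.0 + n_ko) / M / np.maximum(n_orig, 1)
    fdr_est[n_orig == 0] = np.inf
    # smallest q at which a window with margin tau_w is selected:
    # min over candidate thresholds t <= tau_w of fdr_est(t)
    # smallest achievable estimate over thresholds <= tau_w: cumulative min
    cum_min = np.minimum.accumulate(fdr_est)
    pos = np.searchsorted(cand, tau, side="right") - 1
    qvals = np.where((kappa == 0) & (pos >= 0), cum_min[np.maximum(pos, 0)], np.nan)
    sel = (kappa == 0) & ~np.isnan(qvals) & (qvals <= q_target)
    out.loc[np.flatnonzero(valid), "q"] = qvals
    out.loc[np.flatnonzero(valid), "selected"] = sel
    return out


def scan_region(
    cohort: PhasedCohort,
    sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    M: int = 10,
    q_target: float = 0.05,
    seed: int = 0,
    *,
    region: tuple[int, int] | None = None,
    blocks: LDBlockPartition | None = None,
    knockoffs: KnockoffSet | None = None,
    r2_threshold: float = 0.5,
    max_block_span_bp: int = 100_000,
    min_stratum_size: int = 10,
    context_blocks: int = 1,
    lambda_policy: str = "cv_min",
    offset_mu: float | None = None,
    weight_source: str = "parental_expectation",
    weight_policy: str = "shared",
) -> pd.DataFrame:
    """Run the full knockoff-calibrated burden FBAT scan.

    Returns one row per window: chrom, start, end, size, n (members with
    nonzero weight), Dir, W, Z, Zstar_1..M, p_burden, q, selected.
    ``weight_policy="shared"`` applies the weights fitted on the original
    offspring dosages to every knockoff copy (a pure genotype swap);
    ``"symmetric"`` refits them per copy by the identical procedure.
    """
    pos = cohort.variants["pos"].to_numpy()
    chrom = str(cohort.variants["chrom"].iloc[0])
    if region is None:
        region = (int(pos[0]), int(pos[-1]))
    if blocks is None:
        founders = np.repeat(cohort.founder_mask(), 2)
        Hf = cohort.H[founders]
        ok = (Hf >= 0).all(axis=0)
        Hf = np.where(ok, Hf, 0)  # blanking rare missing founders for LD only
        blocks = scaffold_partition(Hf, pos, r2_threshold, max_block_span_bp)
    tmap = infer_transmission(cohort, blocks)
    if knockoffs is None:
        knockoffs = generate_knockoff_cohorts(
            cohort, blocks, tmap, M=M, min_stratum_size=min_stratum_size,
            seed=seed, context_blocks=context_blocks,
        )
    M = knockoffs.M
    engine = FbatEngine(cohort, offset_mu=offset_mu)
    windows = make_windows(region, sizes, pos, chrom)
    rows = []
    if weight_source == "parental_expectation":
        design = engine.parental_expected_dosage
    elif weight_source == "offspring":
        design = engine.offspring_dosage
    else:
        raise ValueError(f"unknown weight_source {weight_source!r}")
    for w in windows:
        X = design(cohort.H, w.members)
        bw = fit_burden_weights(X, engine.y, lambda_policy=lambda_policy)
        z = engine.zstat(cohort.H, w.members, bw.b)
        zstar = np.empty(M)
        for m in range(M):
            if weight_policy == "shared":
                bm = bw.b
            elif weight_policy == "symmetric":
                Xm = design(knockoffs.matrices[m], w.members)
                bm = fit_burden_weights(Xm, engine.y, lambda_policy=lambda_policy).b
            else:
                raise ValueError(f"unknown weight_policy {weight_policy!r}")
            zstar[m] = engine.zstat(knockoffs.matrices[m], w.members, bm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W, p_burden = window_statistic(z, zstar)
        rows.append(
            dict(
                chrom=w.chrom,
                start=w.start_bp,
                end=w.end_bp,
                size=w.size,
                n=int(np.count_nonzero(bw.b)),
                Dir=int(np.sign(z)) if not np.isnan(z) else 0,
                W=W,
                Z=z,
                **{f"Zstar_{m + 1}": zstar[m] for m in range(M)},
                p_burden=p_burden,
                fallback_weights=bw.fallback,
            )
        )
    results = pd.DataFrame(rows)
    return knockoff_fdr_select(results, q_target=q_target, M=M)
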