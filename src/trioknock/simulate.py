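"""Synthetic phased trio cohorts with blockwise LD and ascertainment.

The generator emulates a genotyped-and-imputed candidate region in a
genetic isolate: a founder haplotype pool built as mosaics of a small
ancestral panel (giving strong within-block LD that decays across block
boundaries), parent-offspring trios drawn from that pool with Mendelian
transmission and per-interval recombination, an additive disease model on
the logistic or relative-risk scale, and rejection-sampling ascertainment
of an affected proband (the offspring in a type-1 trio, one parent in a
type-2 trio).

Every stochastic choice flows from a single :class:`numpy.random.Generator`
seeded by the caller, and the full ground truth (founder rows, transmitted
haplotype per variant, causal effects) is returned so downstream stages can
be tested against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, PhasedCohort

__all__ = [
    "PoolConfig",
    "HaplotypePool",
    "DiseaseModel",
    "TruthRecord",
    "build_haplotype_pool",
    "simulate_trios",
    "study_cohort",
]


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Founder haplotype pool
# ---------------------------------------------------------------------------

@dataclass
class PoolConfig:
    """Parameters of the founder haplotype pool.

    Defaults emulate the target region: 2,534 SNPs on chr17 between
    30,820,506 and 32,483,270 bp with minor allele frequencies spread
    log-uniformly down to 0.01.

    ``n_ancestral`` ancestral haplotypes are partitioned, per ancestral
    block, into at most ``block_diversity`` groups carrying distinct block
    haplotypes; founder haplotypes follow a Markov mosaic over ancestrals
    with switch probability ``recomb_prob_per_interval`` per adjacent-variant
    interval. Targets rarer than half the smallest panel frequency are
    realised by thinning carriers at the founder level (set
    ``rare_thinning=False`` to keep every variant an exact function of the
    ancestral state, e.g. when exercising the zero-recombination limit).
    """

    n_founders: int = 300
    n_variants: int = 2534
    chrom: str = "17"
    region_start: int = 30_820_506
    region_end: int = 32_483_270
    maf_min: float = 0.01
    maf_max: float = 0.5
    n_ancestral: int = 12
    block_diversity: int = 4
    mean_block_variants: int = 20
    anchors_per_block: int = 3
    anchor_prob: float = 0.8
    recomb_prob_per_interval: float = 0.002
    boundary_hotspot_factor: float = 250.0
    rare_thinning: bool = True
    positions: np.ndarray | None = None
    max_resample: int = 100

    def validate(self) -> None:
        if self.n_founders < 4:
            raise ConfigurationError("need at least 4 founders")
        if self.n_variants < 1:
            raise ConfigurationError("need at least 1 variant")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            raise ConfigurationError(
                f"infeasible MAF bounds [{self.maf_min}, {self.maf_max}]"
            )
        if self.n_ancestral < 2:
            raise ConfigurationError("need at least 2 ancestral haplotypes")
        if not 0 <= self.recomb_prob_per_interval <= 1:
            raise ConfigurationError("recomb_prob_per_interval must be in [0,1]")


@dataclass
class HaplotypePool:
    """Founder haplotypes (rows = 2 * n_founders) over a variant table."""

    config: PoolConfig
    variants: pd.DataFrame
    H: np.ndarray  # uint8 (n_haplotypes, n_variants)
    ancestral_blocks: list[tuple[int, int]]  # half-open index ranges
    seed: int

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_variants(self) -> int:
        return self.H.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def alt_freq(self) -> np.ndarray:
        return self.H.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)


def _draw_positions(rng: np.random.Generator, cfg: PoolConfig) -> np.ndarray:
    if cfg.positions is not None:
        pos = np.asarray(cfg.positions, dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ConfigurationError("supplied positions must be strictly increasing")
        return pos
    span = cfg.region_end - cfg.region_start + 1
    if span < cfg.n_variants:
        raise ConfigurationError("region too short for requested variant count")
    offs = rng.choice(span, size=cfg.n_variants, replace=False)
    offs.sort()
    return cfg.region_start + offs


def build_haplotype_pool(config: PoolConfig, seed: int = 0) -> HaplotypePool:
    """Generate the founder haplotype pool.

    Realised minor allele frequencies are guaranteed to lie within
    ``[maf_min, maf_max]``: variants falling outside after generation are
    re-assigned (fresh target frequency and carrier draw) up to
    ``max_resample`` times.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(seed)
    V = cfg.n_variants
    K = cfg.n_ancestral
    R = 2 * cfg.n_founders
    pos = _draw_positions(rng, cfg)

    # ancestral blocks: contiguous runs of variants with geometric lengths
    blocks: list[tuple[int, int]] = []
    start = 0
    while start < V:
        ln = int(rng.geometric(1.0 / cfg.mean_block_variants))
        blocks.append((start, min(start + ln, V)))
        start += ln

    # per block: partition ancestrals into <= block_diversity groups (>= 2
    # nonempty) and fix a random "background age" order of the groups;
    # carrier sets within the block are prefixes of that order, so variant
    # pairs in a block sit on nested ancestral backgrounds (D' = 1), the way
    # alleles share haplotype backgrounds in real blocks
    group_of = np.empty((len(blocks), K), dtype=np.int64)
    block_group_order: list[np.ndarray] = []
    block_group_counts: list[np.ndarray] = []
    for b in range(len(blocks)):
        d = min(cfg.block_diversity, K)
        while True:
            g = rng.integers(0, d, size=K)
            if len(np.unique(g)) >= 2:
                group_of[b] = g
                break
        gids, counts = np.unique(g, return_counts=True)
        order = rng.permutation(len(gids))
        block_group_order.append(gids[order])
        block_group_counts.append(counts[order])

    def draw_target() -> float:
        return math.exp(rng.uniform(math.log(cfg.maf_min), math.log(cfg.maf_max)))

    # per-block anchor frequencies: common variants inside a block cluster on
    # a few shared frequencies (hence shared carrier prefixes), reproducing
    # the tight runs of near-identical columns seen in real LD blocks
    block_anchors = [
        [draw_target() for _ in range(max(1, cfg.anchors_per_block))]
        for _ in range(len(blocks))
    ]

    # founder mosaic states over ancestrals; hotspot intervals sit at
    # ancestral block boundaries
    if cfg.recomb_prob_per_interval > 0 and V > 1:
        p_int = np.full(V - 1, cfg.recomb_prob_per_interval)
        for lo, _ in blocks[1:]:
            p_int[lo - 1] = min(
                1.0, cfg.recomb_prob_per_interval * cfg.boundary_hotspot_factor
            )
        switches = rng.random((R, V - 1)) < p_int
        seg = np.concatenate(
            [np.zeros((R, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
        )
    else:
        seg = np.zeros((R, V), dtype=np.int64)
    n_seg = int(seg.max()) + 1
    pick = rng.integers(0, K, size=(R, n_seg))
    states = np.take_along_axis(pick, seg, axis=1)  # (R, V) ancestral index

    block_of_variant = np.empty(V, dtype=np.int64)
    for b, (lo, hi) in enumerate(blocks):
        block_of_variant[lo:hi] = b

    H = np.zeros((R, V), dtype=np.uint8)
    min_maf, max_maf = cfg.maf_min, cfg.maf_max

    def assign_column(j: int) -> None:
        b = block_of_variant[j]
        g = group_of[b]
        gids = block_group_order[b]
        counts = block_group_counts[b]
        if rng.random() < cfg.anchor_prob:
            target = block_anchors[b][int(rng.integers(len(block_anchors[b])))]
        else:
            target = draw_target()
        # carrier set = shortest proper prefix of the block's group order
        # whose cumulative panel frequency is nearest the target
        cum = np.cumsum(counts)[:-1] / K  # proper prefixes only
        ell = int(np.argmin(np.abs(cum - target))) + 1
        thin_keep = None
        best = cum[ell - 1]
        if cfg.rare_thinning and (
            target < 0.5 * best or best > max_maf + 1e-12 or best < min_maf - 1e-12
        ):
            # thin down from the smallest prefix that can reach the target
            reach = np.flatnonzero(cum >= target)
            if reach.size:
                ell = int(reach[0]) + 1
                thin_keep = target / cum[ell - 1]
        carrier_groups = gids[:ell]
        carr_anc = np.isin(g, carrier_groups)
        col = carr_anc[states[:, j]]
        if thin_keep is not None:
            col = col & (rng.random(R) < thin_keep)
        H[:, j] = col

    for j in range(V):
        assign_column(j)

    freq = H.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    bad = np.flatnonzero((maf < min_maf - 1e-12) | (maf > max_maf + 1e-12))
    for j in bad:
        for _ in range(cfg.max_resample):
            assign_column(j)
            f = H[:, j].mean()
            if min_maf - 1e-12 <= min(f, 1 - f) <= max_maf + 1e-12:
                break
        else:
            raise ConfigurationError(
                f"could not realise MAF in [{min_maf}, {max_maf}] at variant {j}"
            )

    variants = pd.DataFrame(
        dict(
            chrom=cfg.chrom,
            pos=pos,
            id=[f"var{j:05d}" for j in range(V)],
            ref="A",
            alt="G",
        )
    )
    return HaplotypePool(
        config=cfg, variants=variants, H=H, ancestral_blocks=blocks, seed=seed
    )


# ---------------------------------------------------------------------------
# Disease model
# ---------------------------------------------------------------------------

# multiple-sclerosis prevalence in high-risk genetic isolates (~330/100,000)
_ISOLATE_MS_PREVALENCE = 0.0033


@dataclass
class DiseaseModel:
    """Additive disease model on the logistic or relative-risk scale.

    ``causal_effects`` maps variant index to the per-allele log odds ratio.
    ``mode="logit_additive"`` gives logit P(aff) = intercept + sum(beta * g);
    ``mode="risk_additive"`` gives genotype relative risks additive in the
    allele count, 1 + sum((OR - 1) * g), on the baseline risk implied by the
    intercept (the convention under which TDT power tables are computed).
    Empty ``causal_effects`` is the global null.
    """

    intercept_log_odds: float = math.log(
        _ISOLATE_MS_PREVALENCE / (1 - _ISOLATE_MS_PREVALENCE)
    )
    causal_effects: dict[int, float] = field(default_factory=dict)
    mode: str = "logit_additive"

    def __post_init__(self) -> None:
        if self.mode not in ("logit_additive", "risk_additive"):
            raise ConfigurationError(f"unknown disease-model mode {self.mode!r}")

    @property
    def causal_indices(self) -> np.ndarray:
        return np.asarray(sorted(self.causal_effects), dtype=np.int64)

    @property
    def betas(self) -> np.ndarray:
        return np.asarray(
            [self.causal_effects[j] for j in sorted(self.causal_effects)]
        )

    def risk(self, dosages: np.ndarray) -> np.ndarray:
        """P(affected) for dosage rows aligned with ``causal_indices``."""
        dosages = np.asarray(dosages, dtype=float)
        base = 1.0 / (1.0 + math.exp(-self.intercept_log_odds))
        if len(self.causal_effects) == 0:
            return np.full(dosages.shape[:-1] or (1,), base)
        if self.mode == "logit_additive":
            eta = self.intercept_log_odds + dosages @ self.betas
            return 1.0 / (1.0 + np.exp(-eta))
        rr = 1.0 + dosages @ (np.exp(self.betas) - 1.0)
        return np.clip(base * rr, 0.0, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Trio simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort; replaying the seed reproduces it.

    ``parent_rows[t, p]`` holds the two pool haplotype rows of parent ``p``
    (0 = father, 1 = mother) of trio ``t``; ``transmitted[t, p, j]`` is which
    of the two (0 or 1) was transmitted to the offspring at variant ``j``.
    """

    parent_rows: np.ndarray  # (n_trios, 2, 2) int64
    transmitted: np.ndarray  # (n_trios, 2, n_variants) uint8
    trio_types: np.ndarray  # (n_trios,) int
    causal_indices: np.ndarray
    causal_betas: np.ndarray
    model_mode: str
    seed: int
    attempts: np.ndarray  # rejection-sampling attempts per trio

    def to_frame(self) -> pd.DataFrame:
        """Compact sidecar: per trio/parent, run-length transmitted segments."""
        rows = []
        for t in range(self.transmitted.shape[0]):
            for p, role in enumerate(("father", "mother")):
                tr = self.transmitted[t, p]
                breaks = np.flatnonzero(np.diff(tr)) + 1
                segs = ";".join(
                    f"{s}-{e}:{tr[s] + 1}"
                    for s, e in zip(
                        np.r_[0, breaks], np.r_[breaks, len(tr)]
                    )
                )
                rows.append(
                    dict(
                        trio=t,
                        parent=role,
                        trio_type=int(self.trio_types[t]),
                        pool_rows=f"{self.parent_rows[t, p, 0]},{self.parent_rows[t, p, 1]}",
                        transmitted_segments=segs,
                        attempts=int(self.attempts[t]),
                    )
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _meiosis_states(
    rng: np.random.Generator, n: int, n_variants: int, rho: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sample ``n`` meiosis paths: start haplotype + sparse switch positions."""
    s0 = rng.integers(0, 2, size=n).astype(np.int8)
    if rho <= 0 or n_variants < 2:
        return s0, [np.empty(0, dtype=np.int64)] * n
    counts = rng.binomial(n_variants - 1, rho, size=n)
    switches = []
    for c in counts:
        if c == 0:
            switches.append(np.empty(0, dtype=np.int64))
        else:
            # a switch at interval i flips the source from variant i+1 on
            p = rng.choice(n_variants - 1, size=c, replace=False) + 1
            p.sort()
            switches.append(p)
    return s0, switches


def _states_at(
    s0: np.int8, switches: np.ndarray, sites: np.ndarray
) -> np.ndarray:
    if len(switches) == 0:
        return np.full(len(sites), s0, dtype=np.int8)
    parity = np.searchsorted(switches, sites, side="right") % 2
    return (s0 ^ parity).astype(np.int8)


def _full_states(s0: np.int8, switches: np.ndarray, n_variants: int) -> np.ndarray:
    flips = np.zeros(n_variants, dtype=np.int8)
    if len(switches):
        flips[switches] = 1
    return (np.cumsum(flips) % 2 ^ s0).astype(np.uint8)


def simulate_trios(
    pool: HaplotypePool,
    n_type1: int,
    n_type2: int,
    disease_model: DiseaseModel | None = None,
    seed: int = 0,
    *,
    ascertained: bool = True,
    single_parent_fraction: float = 0.0,
    missing_rate: float = 0.0,
    meiosis_recomb_prob: float | None = None,
    max_attempts: int = 10_000,
) -> tuple[PhasedCohort, TruthRecord]:
    """Draw an ascertained trio cohort from the founder pool.

    Parents are random founder haplotype pairs; offspring haplotypes follow
    Mendelian transmission with per-interval recombination probability
    ``meiosis_recomb_prob`` (default: the pool's mosaic switch probability).
    Under ascertainment a whole trio is redrawn until its proband — the
    offspring for type 1, a randomly chosen parent for type 2 — is affected;
    exceeding ``max_attempts`` redraws for any trio raises
    :class:`SimulationError` with a diagnostic.
    """
    if n_type1 + n_type2 < 1:
        raise ConfigurationError("need at least one trio")
    model = disease_model if disease_model is not None else DiseaseModel()
    bad = [j for j in model.causal_effects if not 0 <= j < pool.n_variants]
    if bad:
        raise ConfigurationError(f"causal variant indices out of range: {bad}")
    rng = np.random.default_rng(seed)
    V = pool.n_variants
    R = pool.n_haplotypes
    rho = (
        pool.config.recomb_prob_per_interval
        if meiosis_recomb_prob is None
        else meiosis_recomb_prob
    )
    causal = model.causal_indices
    n_trios = n_type1 + n_type2
    trio_types = np.r_[np.ones(n_type1, int), np.full(n_type2, 2)]
    # proband member: 2 = child (type 1); 0/1 = father/mother (type 2)
    proband_member = np.where(
        trio_types == 1, 2, rng.integers(0, 2, size=n_trios)
    )

    parent_rows = np.zeros((n_trios, 2, 2), dtype=np.int64)
    s0_acc = np.zeros((n_trios, 2), dtype=np.int8)
    sw_acc: list[list[np.ndarray]] = [[None, None] for _ in range(n_trios)]
    attempts = np.zeros(n_trios, dtype=np.int64)
    BATCH = 64

    for t in range(n_trios):
        accepted = False
        while not accepted:
            if attempts[t] >= max_attempts:
                raise SimulationError(
                    f"trio {t} (type {trio_types[t]}): proband not affected "
                    f"after {max_attempts} redraws; the disease model makes "
                    "affection too rare for ascertainment"
                )
            nb = min(BATCH, max_attempts - attempts[t])
            rows = rng.integers(0, R, size=(nb, 2, 2))  # (attempt, parent, hap)
            s0_f, sw_f = _meiosis_states(rng, nb, V, rho)
            s0_m, sw_m = _meiosis_states(rng, nb, V, rho)
            if len(causal):
                if proband_member[t] == 2:
                    alle_f = np.empty((nb, len(causal)), dtype=np.int64)
                    alle_m = np.empty((nb, len(causal)), dtype=np.int64)
                    for a in range(nb):
                        st_f = _states_at(s0_f[a], sw_f[a], causal)
                        st_m = _states_at(s0_m[a], sw_m[a], causal)
                        alle_f[a] = pool.H[rows[a, 0, st_f], causal]
                        alle_m[a] = pool.H[rows[a, 1, st_m], causal]
                    dos = alle_f + alle_m
                else:
                    p = proband_member[t]
                    dos = (
                        pool.H[rows[:, p, 0]][:, causal].astype(np.int64)
                        + pool.H[rows[:, p, 1]][:, causal]
                    )
                prob = model.risk(dos)
            else:
                prob = np.full(nb, model.risk(np.zeros((1, 0)))[0])
            y = rng.random(nb) < prob
            if not ascertained:
                y[:] = True
            hit = np.flatnonzero(y)
            if hit.size:
                a = int(hit[0])
                attempts[t] += a + 1
                parent_rows[t, 0] = rows[a, 0]
                parent_rows[t, 1] = rows[a, 1]
                s0_acc[t] = (s0_f[a], s0_m[a])
                sw_acc[t] = [sw_f[a], sw_m[a]]
                accepted = True
            else:
                attempts[t] += nb

    # materialise haplotypes and phenotypes
    transmitted = np.zeros((n_trios, 2, V), dtype=np.uint8)
    H = np.zeros((2 * 3 * n_trios, V), dtype=np.int8)
    recs = []
    trio_rows = []
    pheno_all = np.zeros((n_trios, 3))
    for t in range(n_trios):
        tid = f"trio{t:04d}"
        hap_members = []
        for p in range(2):  # parents
            hp = pool.H[parent_rows[t, p]]  # (2, V)
            hap_members.append(hp)
        off = np.zeros((2, V), dtype=np.uint8)
        for p in range(2):
            st = _full_states(s0_acc[t][p], sw_acc[t][p], V)
            transmitted[t, p] = st
            off[p] = np.where(st == 0, hap_members[p][0], hap_members[p][1])
        hap_members.append(off)
        # phenotypes: proband affected by construction, others from the model
        if len(causal):
            doses = [
                hm[0][causal].astype(np.int64) + hm[1][causal]
                for hm in hap_members
            ]
            probs = model.risk(np.asarray(doses))
        else:
            probs = np.full(3, model.risk(np.zeros((1, 0)))[0])
        for m in range(3):
            if m == proband_member[t]:
                pheno_all[t, m] = 1.0
            else:
                pheno_all[t, m] = float(rng.random() < probs[m])
        base = 6 * t
        for m in range(3):
            H[base + 2 * m : base + 2 * m + 2] = hap_members[m]
        fa, mo, ch = f"{tid}_F", f"{tid}_M", f"{tid}_C"
        child_sex = int(rng.integers(1, 3))
        recs += [
            dict(iid=fa, fid=tid, father="0", mother="0", sex=1,
                 phenotype=pheno_all[t, 0]),
            dict(iid=mo, fid=tid, father="0", mother="0", sex=2,
                 phenotype=pheno_all[t, 1]),
            dict(iid=ch, fid=tid, father=fa, mother=mo, sex=child_sex,
                 phenotype=pheno_all[t, 2]),
        ]
        proband_id = (fa, mo, ch)[proband_member[t]]
        trio_rows.append(
            dict(trio_id=tid, trio_type=int(trio_types[t]), father=fa,
                 mother=mo, child=ch, proband=proband_id)
        )

    individuals = pd.DataFrame(recs)
    trios = pd.DataFrame(trio_rows)

    # optional single-parent (duo) type-1 trios
    if single_parent_fraction > 0:
        drop_iids = []
        for t in range(n_trios):
            if trio_types[t] == 1 and rng.random() < single_parent_fraction:
                side = int(rng.integers(0, 2))
                col = "father" if side == 0 else "mother"
                drop_iids.append(trios.at[t, col])
                trios.at[t, col] = "0"
        if drop_iids:
            keep = ~individuals["iid"].isin(drop_iids).to_numpy()
            H = H[np.repeat(keep, 2)]
            individuals = individuals[keep].reset_index(drop=True)

    cohort = PhasedCohort(
        variants=pool.variants.copy(), H=H, individuals=individuals, trios=trios
    )

    if missing_rate > 0:
        miss = rng.random((cohort.n_individuals, V)) < missing_rate
        rows_mask = np.repeat(miss, 2, axis=0)
        cohort.H[rows_mask] = MISSING

    truth = TruthRecord(
        parent_rows=parent_rows,
        transmitted=transmitted,
        trio_types=trio_types,
        causal_indices=causal,
        causal_betas=model.betas,
        model_mode=model.mode,
        seed=seed,
        attempts=attempts,
    )
    return cohort, truth


def study_cohort(
    pool: HaplotypePool,
    disease_model: DiseaseModel | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[PhasedCohort, TruthRecord]:
    """The study-sized design: 97 type-1 + 60 type-2 ascertained trios."""
    return simulate_trios(pool, 97, 60, disease_model, seed, **kwargs)
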