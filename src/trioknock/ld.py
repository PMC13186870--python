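"""Haplotype r² linkage-disequilibrium matrix and greedy block partition.

r² between two variants is the squared Pearson correlation of their binary
haplotype columns, equivalently (p_AB - p_A p_B)² / (p_A(1-p_A) p_B(1-p_B))
on haplotype frequencies. Monomorphic columns have undefined r² (reported
as NaN, never 0). Blocks are contiguous, non-overlapping runs of variants
built by a deterministic greedy scan; they parameterise the permutation
strata of knockoff generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDBlockPartition", "ld_r2_matrix", "partition_blocks", "scaffold_partition"]


@dataclass
class LDBlockPartition:
    """Ordered contiguous blocks of variant indices (half-open ranges)."""

    blocks: list[tuple[int, int]]
    r2_threshold: float
    max_block_span_bp: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, n_variants: int) -> np.ndarray:
        out = np.empty(n_variants, dtype=np.int64)
        for b, (lo, hi) in enumerate(self.blocks):
            out[lo:hi] = b
        return out

    def sizes(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.blocks])

    def to_bed(self, variants: pd.DataFrame) -> pd.DataFrame:
        """0-based half-open genomic intervals spanning each block."""
        rows = []
        for lo, hi in self.blocks:
            rows.append(
                dict(
                    chrom=variants["chrom"].iloc[lo],
                    start=int(variants["pos"].iloc[lo]) - 1,
                    end=int(variants["pos"].iloc[hi - 1]),
                    first_index=lo,
                    last_index=hi - 1,
                )
            )
        return pd.DataFrame(rows)


def ld_r2_matrix(
    haplotypes: np.ndarray,
    positions: np.ndarray | None = None,
    window_limit_bp: int | None = None,
) -> np.ndarray:
    """Pairwise haplotype r²; NaN for monomorphic columns and omitted pairs.

    ``haplotypes`` is a binary (rows = haplotypes, columns = variants)
    matrix; entries involving a monomorphic column are NaN, as are pairs
    farther apart than ``window_limit_bp`` when a limit and positions are
    given.
    """
    X = np.asarray(haplotypes, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    if not np.isin(np.unique(X), (0.0, 1.0)).all():
        raise ValueError("haplotype matrix must be binary")
    p = X.mean(axis=0)
    sd = np.sqrt(p * (1 - p))
    mono = sd == 0
    Xc = X - p
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Xc.T @ Xc / X.shape[0]
        r2 = (cov / np.outer(sd, sd)) ** 2
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    if window_limit_bp is not None:
        if positions is None:
            raise ValueError("window_limit_bp requires positions")
        pos = np.asarray(positions)
        far = np.abs(pos[:, None] - pos[None, :]) > window_limit_bp
        r2[far] = np.nan
    return r2


def partition_blocks(
    r2: np.ndarray,
    positions: np.ndarray,
    r2_threshold: float = 0.5,
    max_block_span_bp: int = 100_000,
) -> LDBlockPartition:
    """Greedy left-to-right LD blocks.

    The current block absorbs the next variant while its r² with ANY variant
    already in the block reaches ``r2_threshold`` and the genomic span stays
    within ``max_block_span_bp``; otherwise a new block starts. NaN r²
    (monomorphic, out-of-window) never joins, so monomorphic variants end up
    in singleton blocks.
    """
    pos = np.asarray(positions)
    n = len(pos)
    if r2.shape != (n, n):
        raise ValueError("r2 matrix does not match positions")
    blocks: list[tuple[int, int]] = []
    if n == 0:
        return LDBlockPartition([], r2_threshold, max_block_span_bp)
    lo = 0
    for j in range(1, n):
        linked = np.any(r2[j, lo:j] >= r2_threshold)
        within_span = pos[j] - pos[lo] <= max_block_span_bp
        if linked and within_span:
            continue
        blocks.append((lo, j))
        lo = j
    blocks.append((lo, n))
    return LDBlockPartition(blocks, r2_threshold, max_block_span_bp)


def scaffold_partition(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    r2_threshold: float = 0.5,
    max_block_span_bp: int = 100_000,
    scaffold_maf_min: float = 0.05,
) -> LDBlockPartition:
    """LD blocks from a common-variant scaffold.

    Pairwise-r² chains are uninformative through rare variants, so (as PLINK
    block detection does with its default MAF filter) the greedy partition is
    computed on variants with MAF >= ``scaffold_maf_min`` only; every other
    variant then joins the scaffold block whose span covers it, or the
    nearer adjacent block in base pairs (ties to the left).
    """
    X = np.asarray(haplotypes, dtype=float)
    pos = np.asarray(positions)
    n = len(pos)
    p = X.mean(axis=0)
    maf = np.minimum(p, 1 - p)
    common = np.flatnonzero(maf >= scaffold_maf_min)
    if common.size == 0:
        return partition_blocks(
            ld_r2_matrix(X, pos, max_block_span_bp), pos,
            r2_threshold, max_block_span_bp,
        )
    r2c = ld_r2_matrix(X[:, common], pos[common], max_block_span_bp)
    part_c = partition_blocks(r2c, pos[common], r2_threshold, max_block_span_bp)
    # boundaries between consecutive scaffold blocks: midpoint in bp between
    # the last variant of one block and the first of the next
    cuts = []
    for (lo_a, hi_a), (lo_b, hi_b) in zip(part_c.blocks[:-1], part_c.blocks[1:]):
        left_bp = pos[common[hi_a - 1]]
        right_bp = pos[common[lo_b]]
        mid = (left_bp + right_bp) / 2.0
        cuts.append(int(np.searchsorted(pos, mid, side="right")))
    edges = [0, *cuts, n]
    blocks = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    return LDBlockPartition(blocks, r2_threshold, max_block_span_bp)
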