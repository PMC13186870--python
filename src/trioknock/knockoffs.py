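"""Trio-aware knockoff genotypes by sequential blockwise permutation.

Knockoff parental haplotypes are built per LD block, left to right: the
haplotype rows are stratified by their local context — the block to the
left as already realised in the knockoff, the block to the right as in the
original — and the block haplotypes are randomly permuted among rows within
each stratum. This conserves per-block allele counts exactly, preserves
within-block LD, and breaks the phenotype link. Knockoff offspring are then
derived, never permuted: each copies, per block, the same parental
haplotype index that was originally transmitted, read from the knockoff
parent, so knockoff trios are Mendelian-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PhasedCohort
from .ld import LDBlockPartition
from .transmission import TransmissionMap

__all__ = ["KnockoffSet", "generate_parental_knockoffs", "derive_knockoff_offspring",
           "generate_knockoff_cohorts"]

DEFAULT_M = 10


class KnockoffError(ValueError):
    pass


@dataclass
class KnockoffSet:
    """M knockoff copies of the cohort haplotype matrix.

    ``matrices[m]`` is aligned row-for-row with the original ``cohort.H``:
    parental rows of complete trios carry permuted block haplotypes,
    offspring rows carry the derived knockoff transmissions, and any other
    row (duo parents, unrelated individuals) is an untouched copy.
    """

    M: int
    matrices: list[np.ndarray]
    parent_row_indices: np.ndarray
    seed: int


def _block_labels(mat: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Integer label of each row's haplotype within a block."""
    _, inv = np.unique(mat[:, lo:hi], axis=0, return_inverse=True)
    return inv


def _context_labels(
    mat: np.ndarray, blocks: list[tuple[int, int]], ids: list[int]
) -> np.ndarray | None:
    """Joint haplotype label over a run of context blocks (None if empty)."""
    if not ids:
        return None
    lo = blocks[ids[0]][0]
    hi = blocks[ids[-1]][1]
    return _block_labels(mat, lo, hi)


def _strata_from_context(
    left: np.ndarray | None, right: np.ndarray | None, n_rows: int,
    min_stratum_size: int,
) -> list[np.ndarray]:
    """Group rows by (left, right) context labels, merging small strata.

    Undersized strata are repeatedly merged with the stratum nearest in
    context frequency (deterministic tie-break by label order).
    """
    if left is None and right is None:
        return [np.arange(n_rows)]
    key = np.zeros(n_rows, dtype=np.int64)
    if left is not None:
        key = key * (left.max() + 1) + left
    if right is not None:
        key = key * (right.max() + 1) + right
    order = np.argsort(key, kind="stable")
    uniq, starts = np.unique(key[order], return_index=True)
    strata = [order[s:e] for s, e in zip(starts, np.r_[starts[1:], n_rows])]
    while len(strata) > 1:
        sizes = np.array([len(s) for s in strata])
        small = int(np.argmin(sizes))
        if sizes[small] >= min_stratum_size:
            break
        others = [i for i in range(len(strata)) if i != small]
        nearest = min(others, key=lambda i: (abs(sizes[i] - sizes[small]), i))
        merged = np.sort(np.concatenate([strata[small], strata[nearest]]))
        strata = [s for i, s in enumerate(strata) if i not in (small, nearest)]
        strata.append(merged)
        strata.sort(key=lambda s: s[0])
    return strata


def generate_parental_knockoffs(
    parent_haplotypes: np.ndarray,
    blocks: LDBlockPartition,
    M: int = DEFAULT_M,
    min_stratum_size: int = 10,
    seed: int = 0,
    context_blocks: int = 1,
) -> list[np.ndarray]:
    """M knockoff copies of a parental haplotype matrix.

    Block k strata condition on the pair (blocks k-1..k-context haplotype
    in the knockoff being built, blocks k+1..k+context haplotype in the
    original); boundary blocks condition on the neighbours that exist. Each
    copy draws from an independent stream spawned from ``seed``.
    """
    if M < 1:
        raise KnockoffError("M must be >= 1")
    if parent_haplotypes.shape[0] < 2:
        raise KnockoffError("need at least 2 parental haplotype rows")
    H = parent_haplotypes
    n_rows = H.shape[0]
    n_blocks = blocks.n_blocks
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(seed).spawn(M)]
    out = []
    for m in range(M):
        rng = streams[m]
        ko = H.copy()
        for b, (lo, hi) in enumerate(blocks.blocks):
            left = _context_labels(
                ko, blocks.blocks, list(range(max(0, b - context_blocks), b))
            )
            right = _context_labels(
                H, blocks.blocks,
                list(range(b + 1, min(n_blocks, b + 1 + context_blocks))),
            )
            for rows in _strata_from_context(left, right, n_rows, min_stratum_size):
                perm = rng.permutation(len(rows))
                ko[rows[:, None], np.arange(lo, hi)[None, :]] = H[
                    rows[perm][:, None], np.arange(lo, hi)[None, :]
                ]
        out.append(ko)
    return out


def derive_knockoff_offspring(
    knockoff_parents: dict[tuple[int, int], np.ndarray],
    tmap: TransmissionMap,
    n_variants: int,
) -> dict[tuple[int, int], np.ndarray]:
    """Knockoff offspring haplotypes from knockoff parents + transmissions.

    ``knockoff_parents[(t, p)]`` is the (2, n_variants) knockoff haplotype
    pair of parent p of trio t. Returns, per (trio, parent), the offspring
    haplotype attributed to that parent, copying block k of the originally
    transmitted haplotype index from the knockoff parent.
    """
    out: dict[tuple[int, int], np.ndarray] = {}
    for (t, p), kp in knockoff_parents.items():
        hap = np.empty(n_variants, dtype=kp.dtype)
        for b, (lo, hi) in enumerate(tmap.blocks.blocks):
            tr = int(tmap.transmitted[t, p, b])
            if tr == 0:
                raise KnockoffError(
                    f"missing transmission entry for trio {t}, parent {p}, block {b}"
                )
            hap[lo:hi] = kp[tr - 1, lo:hi]
        out[(t, p)] = hap
    return out


def generate_knockoff_cohorts(
    cohort: PhasedCohort,
    blocks: LDBlockPartition,
    tmap: TransmissionMap,
    M: int = DEFAULT_M,
    min_stratum_size: int = 10,
    seed: int = 0,
    context_blocks: int = 1,
) -> KnockoffSet:
    """Full-cohort knockoff set: permuted parents + derived offspring.

    Only parents of complete trios enter the permutation pool (the
    conditional FBAT uses complete trios only); all other rows are copied
    unchanged.
    """
    trios = cohort.trios
    complete = [
        t for t, tr in trios.iterrows() if tr["father"] != "0" and tr["mother"] != "0"
    ]
    parent_rows = []
    row_span: dict[tuple[int, int], slice] = {}
    for t in complete:
        for p, col in enumerate(("father", "mother")):
            r0, r1 = cohort.hap_rows(trios.at[t, col])
            row_span[(t, p)] = slice(len(parent_rows), len(parent_rows) + 2)
            parent_rows += [r0, r1]
    parent_rows = np.asarray(parent_rows, dtype=np.int64)
    kos = generate_parental_knockoffs(
        cohort.H[parent_rows], blocks, M=M,
        min_stratum_size=min_stratum_size, seed=seed,
        context_blocks=context_blocks,
    )
    matrices = []
    for m in range(M):
        full = cohort.H.copy()
        full[parent_rows] = kos[m]
        kp = {key: kos[m][span] for key, span in row_span.items()}
        off = derive_knockoff_offspring(kp, tmap, cohort.n_variants)
        for t in complete:
            child = trios.at[t, "child"]
            c0, _ = cohort.hap_rows(child)
            for p in range(2):
                orow = int(tmap.child_row_of_parent[t, p])
                if orow >= 0:
                    full[c0 + orow] = off[(t, p)]
        matrices.append(full)
    return KnockoffSet(
        M=M, matrices=matrices, parent_row_indices=parent_rows, seed=seed
    )
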