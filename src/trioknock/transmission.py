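"""Per-trio, per-parent, per-LD-block transmitted-haplotype inference.

For each complete trio the two offspring haplotypes are attributed to the
two parents by the whole-trio assignment that minimises total block
mismatches; within each (parent, block) the transmitted parental haplotype
is the one matching the attributed offspring block haplotype more closely.
Working at block rather than whole-chromosome level keeps recombinant
offspring consistent with the blockwise knockoff construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .ld import LDBlockPartition

__all__ = ["TransmissionMap", "infer_transmission"]


@dataclass
class TransmissionMap:
    """transmitted[t, p, b] ∈ {1, 2}; 0 marks an absent parent (duo).

    ``ambiguous`` flags ties (equal mismatch counts for both parental
    haplotypes — on clean data exactly the homozygous-block case) where the
    tie-break "transmitted = 1" was applied; ``mismatches`` counts residual
    disagreements of the chosen haplotype, 0 on error-free phased data.
    ``child_row_of_parent[t, p]`` records which offspring haplotype row
    (0 or 1) was attributed to parent p (0 = father, 1 = mother).
    """

    transmitted: np.ndarray  # (n_trios, 2, n_blocks) uint8
    ambiguous: np.ndarray  # same shape, bool
    mismatches: np.ndarray  # same shape, int64
    child_row_of_parent: np.ndarray  # (n_trios, 2) int8
    blocks: LDBlockPartition
    trio_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, tid in enumerate(self.trio_ids):
            for p, role in enumerate(("father", "mother")):
                for b in range(self.transmitted.shape[2]):
                    if self.transmitted[t, p, b] == 0:
                        continue
                    rows.append(
                        dict(
                            trio=tid,
                            parent=role,
                            block=b,
                            transmitted=int(self.transmitted[t, p, b]),
                            ambiguous=bool(self.ambiguous[t, p, b]),
                            mismatches=int(self.mismatches[t, p, b]),
                        )
                    )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _block_mismatches(
    diff: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Sum a per-variant disagreement vector within each block."""
    return np.add.reduceat(diff, starts)


def infer_transmission(
    cohort: PhasedCohort, blocks: LDBlockPartition
) -> TransmissionMap:
    """Infer the transmitted parental haplotype for every parent and block.

    Missing alleles never count as mismatches. Trios without a genotyped
    child are skipped with a warning; duos are inferred for the present
    parent only.
    """
    n_blocks = blocks.n_blocks
    starts = np.array([lo for lo, _ in blocks.blocks], dtype=np.int64)
    trios = cohort.trios
    n_trios = len(trios)
    transmitted = np.zeros((n_trios, 2, n_blocks), dtype=np.uint8)
    ambiguous = np.zeros((n_trios, 2, n_blocks), dtype=bool)
    mismatches = np.zeros((n_trios, 2, n_blocks), dtype=np.int64)
    child_row = np.full((n_trios, 2), -1, dtype=np.int8)

    H = cohort.H
    for t, trio in trios.iterrows():
        if trio["child"] == "0" or trio["child"] not in cohort.individuals["iid"].values:
            warnings.warn(f"trio {trio['trio_id']} has no offspring; skipped")
            continue
        off = cohort.haplotypes_of(trio["child"])
        parents = []
        for col in ("father", "mother"):
            parents.append(
                cohort.haplotypes_of(trio[col]) if trio[col] != "0" else None
            )

        # per (parent, parent-hap, offspring-row): blockwise mismatch counts
        # missing alleles (negative) never mismatch
        mm = np.full((2, 2, 2, n_blocks), 0, dtype=np.int64)
        for p, par in enumerate(parents):
            if par is None:
                continue
            for ph in range(2):
                for orow in range(2):
                    a, b = par[ph], off[orow]
                    diff = (a != b) & (a >= 0) & (b >= 0)
                    mm[p, ph, orow] = _block_mismatches(diff, starts)
        best = mm.min(axis=1)  # (parent, offspring-row, blocks)

        if parents[0] is not None and parents[1] is not None:
            # assignment A: off row0 -> father, row1 -> mother; B: swapped
            cost_a = best[0, 0].sum() + best[1, 1].sum()
            cost_b = best[0, 1].sum() + best[1, 0].sum()
            rows = (0, 1) if cost_a <= cost_b else (1, 0)
        else:
            p = 0 if parents[0] is not None else 1
            rows_p = 0 if best[p, 0].sum() <= best[p, 1].sum() else 1
            rows = (rows_p, 1 - rows_p) if p == 0 else (1 - rows_p, rows_p)

        for p, par in enumerate(parents):
            if par is None:
                continue
            orow = rows[p]
            child_row[t, p] = orow
            m1, m2 = mm[p, 0, orow], mm[p, 1, orow]
            take2 = m2 < m1
            transmitted[t, p] = np.where(take2, 2, 1)
            ambiguous[t, p] = m1 == m2
            mismatches[t, p] = np.where(take2, m2, m1)
    return TransmissionMap(
        transmitted=transmitted,
        ambiguous=ambiguous,
        mismatches=mismatches,
        child_row_of_parent=child_row,
        blocks=blocks,
        trio_ids=list(trios["trio_id"]),
    )
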