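"""Phased cohort container plus VCF/PED input and output.

The in-memory substrate for every analysis stage is :class:`PhasedCohort`:
a phased haplotype matrix (two ``int8`` rows per individual, ``1`` = alt
allele, ``-1`` = missing), a variant table, an individual table carrying
pedigree links and affection status, and a resolved trio table.

Phenotype coding is ``1.0`` affected, ``0.0`` unaffected, ``NaN`` missing
(PED files use the conventional 2/1/0-or-(-9) coding on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PhasedCohort",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_ped",
    "write_ped",
    "attach_pedigree",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
MISSING = -1


class CohortError(ValueError):
    """Malformed cohort input (unphased genotypes, broken pedigree links...)."""


@dataclass
class PhasedCohort:
    """Phased haplotypes + variant metadata + pedigree/phenotypes.

    Attributes
    ----------
    variants : DataFrame with columns chrom, pos, id, ref, alt (pos 1-based).
    H : int8 array of shape (2 * n_individuals, n_variants); rows ``2i`` and
        ``2i + 1`` are the two haplotypes of individual ``i`` in the order of
        ``individuals``. For simulated offspring row ``2i`` is the paternal
        haplotype; for data read from disk the order is as phased.
    individuals : DataFrame with columns iid, fid, father, mother, sex,
        phenotype ('0' marks an absent parent link).
    trios : DataFrame with columns trio_id, trio_type (1 | 2 | 0 unknown),
        father, mother, child, proband; parent ids may be '0' for duos.
    """

    variants: pd.DataFrame
    H: np.ndarray
    individuals: pd.DataFrame
    trios: pd.DataFrame = field(default_factory=lambda: _empty_trios())

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.trios = self.trios.reset_index(drop=True)
        if self.H.shape != (2 * len(self.individuals), len(self.variants)):
            raise CohortError(
                f"haplotype matrix {self.H.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        pos = self.variants["pos"].to_numpy()
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise CohortError(f"positions not strictly increasing on {chrom}")
        del pos
        self._row_of = {iid: i for i, iid in enumerate(self.individuals["iid"])}
        for col in ("father", "mother", "child"):
            for iid in self.trios[col]:
                if iid != "0" and iid not in self._row_of:
                    raise CohortError(f"trio member {iid!r} not among individuals")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, iid: str) -> int:
        return self._row_of[iid]

    def hap_rows(self, iid: str) -> tuple[int, int]:
        i = self._row_of[iid]
        return 2 * i, 2 * i + 1

    def haplotypes_of(self, iid: str) -> np.ndarray:
        """(2, n_variants) view of one individual's haplotypes."""
        i = self._row_of[iid]
        return self.H[2 * i : 2 * i + 2]

    def genotypes(self) -> np.ndarray:
        """Additive dosage matrix (n_individuals, n_variants), ``-1`` missing."""
        g = self.H[0::2].astype(np.int16) + self.H[1::2]
        g[(self.H[0::2] == MISSING) | (self.H[1::2] == MISSING)] = MISSING
        return g.astype(np.int8)

    def founder_mask(self) -> np.ndarray:
        """Boolean per individual: not the child of any trio."""
        children = set(self.trios["child"])
        return ~self.individuals["iid"].isin(children).to_numpy()

    def phenotype_of(self, iid: str) -> float:
        return float(self.individuals.loc[self._row_of[iid], "phenotype"])

    def complete_trios(self) -> pd.DataFrame:
        """Trios with both parents and the child present in the cohort."""
        t = self.trios
        ok = (t["father"] != "0") & (t["mother"] != "0")
        return t[ok].reset_index(drop=True)

    # -- subsetting -------------------------------------------------------
    def subset_variants(self, keep: np.ndarray) -> "PhasedCohort":
        keep = np.asarray(keep)
        return replace(
            self,
            variants=self.variants.iloc[keep].reset_index(drop=True),
            H=np.ascontiguousarray(self.H[:, keep]),
        )

    def subset_individuals(self, keep_iids: set[str]) -> "PhasedCohort":
        mask = self.individuals["iid"].isin(keep_iids).to_numpy()
        rows = np.repeat(mask, 2)
        trios = self.trios[
            self.trios["child"].isin(keep_iids)
        ].reset_index(drop=True)
        return PhasedCohort(
            variants=self.variants,
            H=np.ascontiguousarray(self.H[rows]),
            individuals=self.individuals[mask],
            trios=trios,
        )


def _empty_trios() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["trio_id", "trio_type", "father", "mother", "child", "proband"]
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_phased_vcf(cohort: PhasedCohort, path: str) -> None:
    """Write a minimal phased VCF v4.2 (GT only, '|' separated)."""
    iids = list(cohort.individuals["iid"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in cohort.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(iids) + "\n")
        allele = {MISSING: ".", 0: "0", 1: "1"}
        h0, h1 = cohort.H[0::2], cohort.H[1::2]
        for j, row in cohort.variants.iterrows():
            gts = "\t".join(
                f"{allele[int(a)]}|{allele[int(b)]}"
                for a, b in zip(h0[:, j], h1[:, j])
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str) -> PhasedCohort:
    """Read a phased VCF into a pedigree-less :class:`PhasedCohort`.

    Raises :class:`CohortError` on unphased ('/') genotypes or multi-allelic
    records; a fully missing genotype ('.|.' or './.') is accepted.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[dict] = []
    haps: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise CohortError(
                f"multi-allelic record at {v.CHROM}:{v.POS} is not supported"
            )
        gt = np.asarray(v.genotype.array(), dtype=np.int16)
        alleles = gt[:, :2]
        phased = gt[:, 2].astype(bool)
        missing = (alleles < 0).any(axis=1)
        if np.any(~phased & ~missing):
            bad = samples[int(np.flatnonzero(~phased & ~missing)[0])]
            raise CohortError(
                f"unphased genotype for sample {bad} at {v.CHROM}:{v.POS}"
            )
        col = alleles.astype(np.int8)
        col[missing] = MISSING
        haps.append(col)
        rows.append(
            dict(chrom=v.CHROM, pos=v.POS, id=v.ID or ".", ref=v.REF, alt=v.ALT[0])
        )
    vcf.close()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    n_ind = len(samples)
    H = np.full((2 * n_ind, len(rows)), MISSING, dtype=np.int8)
    for j, col in enumerate(haps):
        H[0::2, j] = col[:, 0]
        H[1::2, j] = col[:, 1]
    individuals = pd.DataFrame(
        dict(
            iid=samples,
            fid=samples,
            father="0",
            mother="0",
            sex=0,
            phenotype=np.nan,
        )
    )
    return PhasedCohort(variants=variants, H=H, individuals=individuals)


# ---------------------------------------------------------------------------
# PED / FAM
# ---------------------------------------------------------------------------

def write_ped(cohort: PhasedCohort, path: str) -> None:
    """6-column PED: fid iid father mother sex phenotype (2/1, 0 missing)."""
    df = cohort.individuals.copy()
    pheno = df["phenotype"].map(lambda y: 0 if pd.isna(y) else int(y) + 1)
    out = pd.DataFrame(
        dict(
            fid=df["fid"],
            iid=df["iid"],
            father=df["father"],
            mother=df["mother"],
            sex=df["sex"],
            phenotype=pheno,
        )
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: str) -> pd.DataFrame:
    """Read a 6-column PED/FAM into the internal individual-table layout."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    df["phenotype"] = df["phenotype"].map(
        lambda v: np.nan if v in (0, -9) else float(v) - 1.0
    )
    return df


def build_trios(individuals: pd.DataFrame) -> pd.DataFrame:
    """Resolve trio records from pedigree links.

    Every individual with at least one parent link becomes the child of a
    trio. The trio type is inferred from affection: an affected child gives
    type 1 (child proband); an unaffected/unknown child with an affected
    parent gives type 2 (that parent is the proband); otherwise the type is
    recorded as 0 (unknown) with the child as nominal proband.
    """
    present = set(individuals["iid"])
    pheno = dict(zip(individuals["iid"], individuals["phenotype"]))
    recs = []
    k = 0
    for _, row in individuals.iterrows():
        fa = row["father"] if row["father"] in present else "0"
        mo = row["mother"] if row["mother"] in present else "0"
        if fa == "0" and mo == "0":
            continue
        child = row["iid"]
        if pheno.get(child) == 1.0:
            ttype, proband = 1, child
        elif fa != "0" and pheno.get(fa) == 1.0:
            ttype, proband = 2, fa
        elif mo != "0" and pheno.get(mo) == 1.0:
            ttype, proband = 2, mo
        else:
            ttype, proband = 0, child
        recs.append(
            dict(
                trio_id=f"trio{k:04d}",
                trio_type=ttype,
                father=fa,
                mother=mo,
                child=child,
                proband=proband,
            )
        )
        k += 1
    return pd.DataFrame(recs, columns=_empty_trios().columns)


def attach_pedigree(cohort: PhasedCohort, ped: pd.DataFrame) -> PhasedCohort:
    """Merge a PED table into a VCF-derived cohort and resolve trios."""
    ped = ped.set_index("iid")
    missing = [s for s in cohort.individuals["iid"] if s not in ped.index]
    if missing:
        raise CohortError(f"samples missing from pedigree: {missing[:5]}")
    ind = cohort.individuals.copy()
    for col in ("fid", "father", "mother", "sex", "phenotype"):
        ind[col] = [ped.at[s, col] for s in ind["iid"]]
    return PhasedCohort(
        variants=cohort.variants,
        H=cohort.H,
        individuals=ind,
        trios=build_trios(ind),
    )
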