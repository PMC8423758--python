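"""Read/filter phased VCFs and panel files into matrices; write tabular outputs.

Loci are kept when they (1) sit on an autosome, (2) are biallelic SNVs among
the subjects, and (3) are called in more than 90% of subjects.  Allele codes
are re-oriented so that 0 is the cohort-major allele (REF/ALT roles swap when
ALT is the majority allele; an exact 50/50 tie keeps REF as major).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # cyvcf2 is the standard reader; import lazily tolerant for docs builds
    from cyvcf2 import VCF as _VCF
except ImportError:  # pragma: no cover
    _VCF = None

__all__ = [
    "AUTOSOMES",
    "PhasedGenotypeMatrix",
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "collapse_genotypes",
    "read_panel",
    "write_tracts",
    "write_projections",
    "write_loadings",
]

AUTOSOMES = tuple(str(i) for i in range(1, 23))

MISSING = -1


@dataclass
class PhasedGenotypeMatrix:
    """Per-locus, per-subject ordered haplotype allele pairs in {0,1}.

    ``alleles`` has shape (n_loci, n_subjects, 2) with -1 for a missing call;
    0 denotes the cohort-major allele and 1 the minor allele.  ``loci`` is a
    table with columns chrom, pos, major, minor, call_rate.
    """

    alleles: np.ndarray
    loci: pd.DataFrame
    subjects: list[str]
    panel: pd.Series | None = None
    all_phased: bool = True
    n_skipped_multiallelic: int = 0

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.alleles.shape[1]

    def haplotype_matrix(self) -> np.ndarray:
        """(n_loci, 2*n_subjects) view with haplotypes interleaved per subject."""
        return self.alleles.reshape(self.n_loci, -1)


@dataclass
class GenotypeMatrix:
    """Minor-allele count matrix X (loci x subjects).

    ``values`` holds the analysis matrix: allele sums in {0,1,2} where both
    haplotypes are called, and the locus mean among called subjects where not
    (mean imputation; equivalently such entries contribute 0 after
    centering).  ``called`` marks fully-called entries.
    """

    values: np.ndarray
    called: np.ndarray
    loci: pd.DataFrame
    subjects: list[str]

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


class VCFParseError(ValueError):
    pass


def _is_snv(ref: str, alts: list[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1


def read_vcf(path, max_missing: float = 0.10,
             autosomes: tuple[str, ...] = AUTOSOMES) -> PhasedGenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a PhasedGenotypeMatrix.

    Applies the three locus filters (autosome, biallelic SNV, call rate
    > 1 - max_missing) and re-orients alleles so 0 is the cohort-major
    allele.  Multiallelic records are skipped and counted; unphased GT
    entries are accepted but flagged (``all_phased=False``).
    """
    if _VCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    allow = {a for a in autosomes} | {f"chr{a}" for a in autosomes}
    vcf = _VCF(str(path), gts012=False)
    subjects = list(vcf.samples)
    m = len(subjects)
    rows, records, n_multi, all_phased = [], [], 0, True
    for v in vcf:
        if v.CHROM not in allow:
            continue
        alts = v.ALT
        if len(alts) != 1:
            n_multi += 1
            continue
        if not _is_snv(v.REF, alts):
            continue
        gts = np.asarray(v.genotype.array())  # (m, 3): a0, a1, phased flag
        a = gts[:, :2].astype(np.int8)
        a[a < 0] = MISSING
        called = a >= 0
        call_rate = called.all(axis=1).mean()
        if call_rate <= 1.0 - max_missing:
            continue
        if not np.all(gts[called.all(axis=1), 2] == 1):
            all_phased = False
        n1 = int(a[called].sum())
        n_called = int(called.sum())
        if 2 * n1 > n_called:  # ALT is the majority allele: swap orientation
            a[called] = 1 - a[called]
            major, minor = alts[0], v.REF
        else:
            major, minor = v.REF, alts[0]
        rows.append(a)
        records.append((v.CHROM, v.POS, major, minor, float(call_rate)))
    loci = pd.DataFrame(records, columns=["chrom", "pos", "major", "minor", "call_rate"])
    alleles = (np.stack(rows) if rows else np.empty((0, m, 2), dtype=np.int8))
    return PhasedGenotypeMatrix(alleles=alleles, loci=loci, subjects=subjects,
                                all_phased=all_phased,
                                n_skipped_multiallelic=n_multi)


def write_vcf(pgm: PhasedGenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with phased GT fields.

    REF/ALT are the stored major/minor alleles, so a round trip preserves
    allele orientation.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(pgm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pgm.subjects) + "\n")
        sep = "|" if pgm.all_phased else "/"
        for j, row in enumerate(pgm.loci.itertuples(index=False)):
            a = pgm.alleles[j]
            gts = "\t".join(
                "./." if a[i, 0] < 0 or a[i, 1] < 0 else f"{a[i, 0]}{sep}{a[i, 1]}"
                for i in range(pgm.n_subjects)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.major}\t{row.minor}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def collapse_genotypes(pgm: PhasedGenotypeMatrix) -> GenotypeMatrix:
    """Collapse phased haplotype pairs into minor-allele counts {0,1,2}.

    Entries with a missing haplotype call are imputed to the locus mean over
    fully-called subjects (0 when no subject is called).
    """
    if pgm.n_loci == 0 or pgm.n_subjects == 0:
        raise ValueError("cannot collapse an empty phased matrix")
    a = pgm.alleles
    called = (a >= 0).all(axis=2)
    x = a.sum(axis=2, dtype=np.float64)
    x[~called] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
        means = np.nanmean(x, axis=1)
    means = np.nan_to_num(means)
    idx = np.where(called, 0, 1)
    x = np.where(called, np.nan_to_num(x), means[:, None])
    del idx
    return GenotypeMatrix(values=x, called=called, loci=pgm.loci,
                          subjects=list(pgm.subjects))


def read_panel(path, groups: dict[str, list[str]] | None = None,
               subjects: list[str] | None = None) -> pd.Series:
    """Read a subject->population panel TSV (columns subject_id, population).

    ``groups`` maps super-group names to member population lists (e.g.
    ``{"NEU": ["GBR", "CEU"]}``); member labels are replaced by the group
    label.  With ``subjects`` given, every subject must appear in the panel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    sub_col, pop_col = df.columns[0], df.columns[1]
    dup = df.duplicated(subset=[sub_col], keep=False)
    if dup.any():
        conflicting = df[dup].groupby(sub_col)[pop_col].nunique()
        bad = conflicting[conflicting > 1]
        if len(bad):
            raise ValueError(f"conflicting panel labels for subjects: {list(bad.index)}")
        warnings.warn("panel contains duplicate subject rows with identical labels")
        df = df.drop_duplicates(subset=[sub_col])
    panel = pd.Series(df[pop_col].to_numpy(), index=df[sub_col].to_numpy(),
                      name="population")
    if groups:
        mapping = {pop: g for g, pops in groups.items() for pop in pops}
        panel = panel.map(lambda p: mapping.get(p, p))
    if subjects is not None:
        missing = [s for s in subjects if s not in panel.index]
        if missing:
            raise ValueError(f"subjects missing from panel: {missing}")
        panel = panel.loc[subjects]
    return panel


def write_panel(panel: pd.Series, path) -> None:
    panel.rename_axis("subject_id").to_frame().to_csv(path, sep="\t")


def write_projections(P: np.ndarray, subjects: list[str], path) -> None:
    cols = [f"PC{k + 1}" for k in range(P.shape[1])]
    pd.DataFrame(P, index=pd.Index(subjects, name="subject"),
                 columns=cols).to_csv(path, sep="\t")


def write_loadings(loadings: np.ndarray, loci: pd.DataFrame, path) -> None:
    df = loci[["chrom", "pos"]].copy()
    for k in range(loadings.shape[1]):
        df[f"PC{k + 1}"] = loadings[:, k]
    df.to_csv(path, sep="\t", index=False)


def write_tracts(tracts: pd.DataFrame, path) -> None:
    """BED-like tract TSV: chrom, start, end (0-based half-open bp), then
    subject/haplotype/label columns."""
    tracts.to_csv(path, sep="\t", index=False)
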