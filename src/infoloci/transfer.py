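"""Transfer of reference-derived SVD loadings to an external cohort.

The two cohorts are harmonized to the loci shared on (chromosome, position)
with concordant major/minor allele definitions; the joint genotype matrix is
centered with joint row means, and each subject's projection on PC k is
approximated by the partial projection over the reference cohort's
informative loci using loadings recomputed on the reference cohort restricted
to the harmonized loci.  Approximate projections are compared with a joint
PCA by greedy |r|-matching of PC pairs (nearly degenerate eigenvalues can
swap PCs between the two analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .informative import InformativeLociSet
from .pca import (LoadingsMatrix, center_matrix, compute_loadings,
                  eigen_decompose, project)

__all__ = [
    "HarmonizedJoint",
    "TransferProjection",
    "harmonize_loci",
    "transfer_projection",
    "match_pcs",
]


@dataclass
class HarmonizedJoint:
    """Locus-intersected joint matrix over reference + external subjects."""

    loci: pd.DataFrame
    ref_rows: np.ndarray  # harmonized locus rows in the reference table
    ext_rows: np.ndarray  # harmonized locus rows in the external table
    joint: np.ndarray  # (n_shared, m_ref + m_ext) genotype values
    n_ref_subjects: int
    n_discordant: int  # shared positions dropped for allele-definition mismatch


def harmonize_loci(ref_loci: pd.DataFrame, ref_values: np.ndarray,
                   ext_loci: pd.DataFrame, ext_values: np.ndarray) -> HarmonizedJoint:
    """Intersect two cohorts on (chrom, pos) and concordant major/minor
    alleles; discordant definitions are dropped and counted."""
    key = ["chrom", "pos"]
    merged = ref_loci.reset_index().merge(
        ext_loci.reset_index(), on=key, suffixes=("_ref", "_ext"))
    concordant = ((merged["major_ref"] == merged["major_ext"])
                  & (merged["minor_ref"] == merged["minor_ext"]))
    n_discordant = int((~concordant).sum())
    merged = merged[concordant]
    if merged.empty:
        raise ValueError("no concordant shared loci between the cohorts")
    ref_rows = merged["index_ref"].to_numpy()
    ext_rows = merged["index_ext"].to_numpy()
    joint = np.concatenate([ref_values[ref_rows], ext_values[ext_rows]], axis=1)
    loci = merged[["chrom", "pos"]].assign(major=merged["major_ref"],
                                           minor=merged["minor_ref"])
    return HarmonizedJoint(loci.reset_index(drop=True), ref_rows, ext_rows,
                           joint, ref_values.shape[1], n_discordant)


@dataclass
class TransferProjection:
    """Approximate (transfer) and joint-PCA projections with per-PC
    correlations split by subject group."""

    approx: np.ndarray  # (m_ref + m_ext, k) partial projections, Eq.-style
    joint_pca: np.ndarray  # (m_ref + m_ext, r) full joint projections
    n_ref_subjects: int
    loadings: LoadingsMatrix  # reference loadings on harmonized loci
    report: pd.DataFrame | None = None


def transfer_projection(harmonized: HarmonizedJoint,
                        informative: dict[int, InformativeLociSet] | None = None,
                        k_max: int = 7,
                        centering: str = "joint") -> TransferProjection:
    """Approximate joint projections from reference-derived loadings.

    Loadings are recomputed on the reference cohort restricted to the
    harmonized loci; the approximation on PC k sums loadings times the
    centered joint genotypes over that PC's informative loci (all harmonized
    loci when ``informative`` is None).  ``centering`` selects joint row
    means (default) or reference-only row means for the joint matrix.
    """
    m_ref = harmonized.n_ref_subjects
    ref_cgm = center_matrix(harmonized.joint[:, :m_ref])
    eig = eigen_decompose(ref_cgm)
    loadings = compute_loadings(ref_cgm, eig)
    k_max = min(k_max, loadings.values.shape[1])
    if centering == "joint":
        means = harmonized.joint.mean(axis=1)
    elif centering == "reference":
        means = ref_cgm.row_means
    else:
        raise ValueError("centering must be 'joint' or 'reference'")
    xj = harmonized.joint - means[:, None]
    approx = np.zeros((xj.shape[1], k_max))
    for k in range(k_max):
        if informative is None:
            rows = np.arange(xj.shape[0])
        else:
            ils = informative.get(k)
            rows = _map_rows(ils, harmonized) if ils is not None else np.array([], int)
            if rows.size == 0:
                import warnings
                warnings.warn(f"no informative loci survive harmonization on PC {k + 1}")
                continue
        approx[:, k] = xj[rows].T @ loadings.values[rows, k]
    joint_cgm = center_matrix(harmonized.joint)
    joint_eig = eigen_decompose(joint_cgm)
    joint_p = project(joint_cgm, joint_eig, route="eigen")
    return TransferProjection(approx, joint_p, m_ref, loadings)


def _map_rows(ils: InformativeLociSet, harmonized: HarmonizedJoint) -> np.ndarray:
    """Informative-set rows (indices in the original reference table) mapped
    to harmonized row positions."""
    lookup = {r: i for i, r in enumerate(harmonized.ref_rows)}
    return np.array([lookup[r] for r in ils.indices if r in lookup], dtype=np.intp)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_pcs(tp: TransferProjection, k_max: int | None = None,
              min_abs_r: float = 0.2) -> pd.DataFrame:
    """Greedy matching of joint-PCA PCs to approximate-projection PCs by
    descending |r| over all subjects; signed r reported separately for the
    reference and external subject groups.  Pairs below ``min_abs_r`` are
    flagged unmatched."""
    k = k_max or tp.approx.shape[1]
    k = min(k, tp.approx.shape[1], tp.joint_pca.shape[1])
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = _safe_corr(tp.joint_pca[:, i], tp.approx[:, j])
    pairs = sorted(((abs(corr[i, j]), i, j) for i in range(k) for j in range(k)),
                   reverse=True)
    used_i, used_j, rows = set(), set(), []
    m = tp.n_ref_subjects
    for a, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        rows.append({
            "pc_joint": i + 1,
            "pc_proxy": j + 1,
            "r_all": corr[i, j],
            "r_reference_subjects": _safe_corr(tp.joint_pca[:m, i], tp.approx[:m, j]),
            "r_external_subjects": _safe_corr(tp.joint_pca[m:, i], tp.approx[m:, j]),
            "matched": a >= min_abs_r,
        })
    return pd.DataFrame(rows).sort_values("pc_joint").reset_index(drop=True)
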