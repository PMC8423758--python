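"""Selection of necessary informative loci per principal component.

A locus is necessary-informative for a PC when it is among the top/bottom
loading-ranked loci whose removal keeps the truncated partial projections
correlated with the full projections above a threshold, or when its
per-population genotype-frequency profile separates the PC's reference
populations monotonically (with non-overlapping one-SD intervals when only
two populations are compared).  The same genotype moments yield
allele-frequency proxy weights that approximate projections as weighted
allele sums, homozygote-fraction summaries, and max-|loading| gene scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import CenteredGenotypeMatrix, LoadingsMatrix
from .vcfio import GenotypeMatrix

__all__ = [
    "InformativeLociSet",
    "genotype_moments",
    "population_genotype_frequencies",
    "frequency_criterion",
    "rank_loci",
    "truncation_curve",
    "accretion_curve",
    "select_necessary",
    "proxy_weights",
    "proxy_projection",
    "homozygote_fractions",
    "score_genes",
    "all_informative",
    "read_gene_intervals",
]


@dataclass
class InformativeLociSet:
    """Selected loci for one PC with loadings, sign groups, and provenance."""

    pc: int  # 0-based PC index
    indices: np.ndarray  # locus row indices, loading-rank order (descending)
    loadings: np.ndarray
    sign_group: np.ndarray  # +1 top-ranking, -1 bottom-ranking, 0 null loading
    provenance: np.ndarray  # "truncation" | "frequency-criterion"
    achieved_correlation: float
    threshold: float
    threshold_unreachable: bool = False

    def __len__(self) -> int:
        return self.indices.size


def genotype_moments(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the genotype value under frequencies f = (f0, f1, f2).

    mu = sum_g f_g * g, sigma = sqrt(sum_g f_g * g^2 - mu^2); broadcast over
    leading axes.
    """
    f = np.asarray(f, dtype=np.float64)
    mu = f[..., 1] + 2.0 * f[..., 2]
    var = f[..., 1] + 4.0 * f[..., 2] - mu**2
    if np.any(var < -1e-12):
        raise ValueError("negative genotype variance beyond tolerance")
    return mu, np.sqrt(np.clip(var, 0.0, None))


def population_genotype_frequencies(gm: GenotypeMatrix, panel: pd.Series,
                                    populations: list[str]) -> np.ndarray:
    """Per-locus genotype-class frequencies f (n_loci, L, 3) over called
    subjects of each listed population."""
    panel = panel.loc[gm.subjects]
    out = np.zeros((gm.n_loci, len(populations), 3))
    for l, pop in enumerate(populations):
        cols = np.flatnonzero(panel.to_numpy() == pop)
        if cols.size == 0:
            raise ValueError(f"population {pop!r} has no subjects")
        vals = gm.values[:, cols]
        called = gm.called[:, cols]
        for g in (0, 1, 2):
            out[:, l, g] = ((vals == g) & called).sum(axis=1)
    totals = out.sum(axis=2, keepdims=True)
    totals[totals == 0] = 1.0
    return out / totals


def frequency_criterion(f: np.ndarray) -> np.ndarray:
    """Allele-frequency separation test per locus.

    f has shape (n_loci, L, 3) with populations already ordered by their
    projections along the PC.  True when the genotype means are monotone
    (non-strict) across populations and, for L = 2, the one-SD intervals
    (mu - sigma, mu + sigma) of the two populations do not overlap.
    """
    f = np.atleast_3d(np.asarray(f, dtype=np.float64))
    if f.shape[1] < 2:
        raise ValueError("need at least two reference populations")
    mu, sigma = genotype_moments(f)
    diffs = np.diff(mu, axis=1)
    monotone = np.all(diffs >= 0, axis=1) | np.all(diffs <= 0, axis=1)
    if f.shape[1] == 2:
        disjoint = np.abs(mu[:, 1] - mu[:, 0]) >= sigma[:, 0] + sigma[:, 1]
        return monotone & disjoint
    return monotone


def rank_loci(loadings: LoadingsMatrix, k: int,
              loci: pd.DataFrame | None = None) -> np.ndarray:
    """Locus indices sorted by loading on PC k, descending; ties broken by
    (chrom, pos) ascending when a locus table is supplied."""
    g = loadings.values[:, k]
    if loci is not None:
        chrom = pd.factorize(loci["chrom"], sort=True)[0]
        pos = loci["pos"].to_numpy()
        return np.lexsort((pos, chrom, -g))
    return np.argsort(-g, kind="stable")


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson r with the empty/constant convention: r = 0 with a flag."""
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def _default_step(n: int) -> int:
    return max(1, n // 1000)


def _removal_stages(cgm: CenteredGenotypeMatrix, loadings: LoadingsMatrix,
                    k: int, step: int, loci: pd.DataFrame | None):
    """Yield (n_removed, removed_sum) over truncation stages; stage 0 removes
    nothing.  Each stage removes `step` loci from the top AND `step` from the
    bottom of the loading ranking until the ranking is exhausted."""
    order = rank_loci(loadings, k, loci)
    n = order.size
    gamma = loadings.values[:, k]
    removed = np.zeros(cgm.n_subjects)
    yield 0, removed.copy(), 0
    lo, hi, stage = 0, n, 0
    while lo < hi:
        stage += 1
        take = order[lo:min(lo + step, hi)]
        lo += take.size
        take2 = order[max(hi - step, lo):hi]
        hi -= take2.size
        idx = np.concatenate([take, take2])
        removed += cgm.values[idx].T @ gamma[idx]
        yield n - (hi - lo), removed.copy(), stage


def truncation_curve(cgm: CenteredGenotypeMatrix, loadings: LoadingsMatrix,
                     k: int, step: int | None = None,
                     loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correlation between full and truncated projections as top/bottom
    ranking loci are incrementally removed.  Starts at r = 1; a fully
    truncated (constant-zero) projection is reported as r = 0 with
    ``degenerate=True``."""
    if step is not None and step < 1:
        raise ValueError("step must be >= 1")
    step = step or _default_step(cgm.n_loci)
    full = cgm.values.T @ loadings.values[:, k]
    rows = []
    for n_removed, removed, stage in _removal_stages(cgm, loadings, k, step, loci):
        if n_removed == 0:
            rows.append((stage, 0, 1.0, False))
            continue
        if n_removed == cgm.n_loci:  # empty sum: correlation undefined
            rows.append((stage, n_removed, 0.0, True))
            continue
        r, flag = _pearson(full, full - removed)
        rows.append((stage, n_removed, r, flag))
    return pd.DataFrame(rows, columns=["stage", "n_removed", "r", "degenerate"])


def accretion_curve(cgm: CenteredGenotypeMatrix, loadings: LoadingsMatrix,
                    k: int, step: int | None = None,
                    loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correlation between full and accrued projections as top/bottom ranking
    loci are incrementally added, starting from the empty set (r = 0,
    flagged)."""
    if step is not None and step < 1:
        raise ValueError("step must be >= 1")
    step = step or _default_step(cgm.n_loci)
    full = cgm.values.T @ loadings.values[:, k]
    rows = []
    for n_added, accrued, stage in _removal_stages(cgm, loadings, k, step, loci):
        r, flag = _pearson(full, accrued)
        rows.append((stage, n_added, r, flag))
    return pd.DataFrame(rows, columns=["stage", "n_added", "r", "degenerate"])


def select_necessary(cgm: CenteredGenotypeMatrix, loadings: LoadingsMatrix,
                     k: int, threshold: float = 0.9, step: int | None = None,
                     loci: pd.DataFrame | None = None,
                     freqs: np.ndarray | None = None) -> InformativeLociSet:
    """Necessary informative loci of PC k.

    Truncation component: all top/bottom loci removed up to the last stage
    (scanning from no removal) whose truncated-vs-full correlation stays at
    or above ``threshold``.  Union with all loci passing the allele-frequency
    criterion when per-population frequencies ``freqs`` (already in the PC's
    projection order) are given.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    step = step or _default_step(cgm.n_loci)
    curve = truncation_curve(cgm, loadings, k, step, loci)
    order = rank_loci(loadings, k, loci)
    n = order.size
    # degenerate stages (constant truncated projection) carry no correlation
    # evidence and do not stop the scan
    below = curve.index[(curve["r"] < threshold) & ~curve["degenerate"]]
    unreachable = len(below) == 0
    if unreachable:
        warnings.warn(f"truncation correlation never drops below {threshold}; "
                      "selecting all loci")
        last = curve.index[-1]
    else:
        last = below[0] - 1
    n_removed = int(curve.loc[last, "n_removed"])
    achieved = float(curve.loc[last, "r"])
    per_side = min(step * int(curve.loc[last, "stage"]), n)
    top = order[:per_side]
    bottom = order[max(n - per_side, per_side):]
    trunc_idx = np.concatenate([top, bottom])
    assert trunc_idx.size == n_removed
    in_trunc = np.zeros(n, dtype=bool)
    in_trunc[trunc_idx] = True
    if freqs is not None:
        freq_mask = frequency_criterion(freqs)
    else:
        freq_mask = np.zeros(n, dtype=bool)
    selected_mask = in_trunc | freq_mask
    sel = order[selected_mask[order]]  # loading-rank order
    provenance = np.where(in_trunc[sel], "truncation", "frequency-criterion")
    g = loadings.values[sel, k]
    return InformativeLociSet(
        pc=k, indices=sel, loadings=g, sign_group=np.sign(g).astype(np.int8),
        provenance=provenance, achieved_correlation=achieved,
        threshold=threshold, threshold_unreachable=unreachable,
    )


def proxy_weights(freqs: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Allele-frequency margin weights.

    With populations ordered by their projections along the PC, the weight is
    sign(gamma) times the minimal margin between consecutive population
    genotype means, and 0 when the means are not monotone.
    """
    freqs = np.atleast_3d(np.asarray(freqs, dtype=np.float64))
    if freqs.shape[1] < 2:
        raise ValueError("need at least two reference populations")
    mu, _ = genotype_moments(freqs)
    diffs = np.diff(mu, axis=1)
    monotone = np.all(diffs >= 0, axis=1) | np.all(diffs <= 0, axis=1)
    margin = np.min(np.abs(diffs), axis=1)
    sign = np.sign(np.asarray(gamma, dtype=np.float64))
    return np.where(monotone, sign * margin, 0.0)


def proxy_projection(cgm: CenteredGenotypeMatrix, weights: np.ndarray,
                     locus_subset) -> np.ndarray:
    """Weighted allele sums over informative loci: per-subject proxy
    projections sum_{j in I_k} w_jk X̃_ji."""
    s = np.asarray(locus_subset, dtype=np.intp)
    if s.size == 0:
        return np.zeros(cgm.n_subjects)
    return cgm.values[s].T @ np.asarray(weights)[s]


def homozygote_fractions(gm: GenotypeMatrix, ils: InformativeLociSet,
                         K: int, sign: int) -> pd.DataFrame:
    """Per-subject fractions of homozygote major (genotype 0) and minor
    (genotype 2) alleles among the K largest-|loading| loci of one sign group
    of an informative-loci set."""
    group = ils.indices[ils.sign_group == sign]
    g_abs = np.abs(ils.loadings[ils.sign_group == sign])
    if K > group.size:
        warnings.warn(f"K={K} exceeds sign-group size {group.size}; clamping")
        K = group.size
    top = group[np.argsort(-g_abs, kind="stable")[:K]]
    vals = gm.values[top]
    called = gm.called[top]
    denom = np.maximum(called.sum(axis=0), 1)
    frac0 = ((vals == 0) & called).sum(axis=0) / denom
    frac2 = ((vals == 2) & called).sum(axis=0) / denom
    return pd.DataFrame({"frac_hom_major": frac0, "frac_hom_minor": frac2},
                        index=pd.Index(gm.subjects, name="subject"))


def score_genes(loadings: LoadingsMatrix, loci: pd.DataFrame,
                genes: pd.DataFrame, k: int) -> pd.Series:
    """Gene score on PC k: max |loading| over the loci inside the gene's
    interval (BED convention, 0-based half-open); genes containing no locus
    are absent from the result."""
    g = np.abs(loadings.values[:, k])
    pos0 = loci["pos"].to_numpy() - 1  # 0-based locus coordinates
    chrom = loci["chrom"].to_numpy()
    scores = {}
    for row in genes.itertuples(index=False):
        mask = (chrom == row.chrom) & (pos0 >= row.start) & (pos0 < row.end)
        if mask.any():
            scores[row.name] = float(g[mask].max())
    return pd.Series(scores, name=f"PC{k + 1}", dtype=float)


def all_informative(scores: pd.DataFrame, top_fraction: float = 0.25) -> list[str]:
    """Genes whose score is in the top fraction of the ranked gene list on
    every PC (column) simultaneously."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n_top = int(np.ceil(top_fraction * len(scores)))
    keep = None
    for col in scores.columns:
        top = set(scores[col].sort_values(ascending=False, kind="stable")
                  .index[:n_top])
        keep = top if keep is None else keep & top
    return sorted(keep or [])


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene intervals from BED (chrom, start, end, name) or GFF3 (``gene``
    features; Name= or ID= attribute), as 0-based half-open intervals."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}"))
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    return df
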