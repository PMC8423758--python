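"""Local-ancestry tract deconvolution from partial projections.

Training subdivides each chromosome into minimal tracts: the shortest runs
of consecutive informative loci whose reference-panel haplotype partial
projections separate every pair of reference groups by at least ``alpha``
pooled within-group standard deviations.  A test haplotype's tract is
labeled by the nearest reference centroid of its partial projection, scored
by the margin to the second-nearest centroid in pooled-SD units.  Per-PC
labels are combined root-to-leaf through a configurable ancestry hierarchy,
either by maximal score (relaxed criterion) or by unanimity across the
decision's PCs (stringent criterion, disagreements left unassigned).

Haplotype alleles in {0,1} are doubled and centered with the training row
means so that haploid partial projections live on the diploid genotype
scale (a haploid copy of a homozygote projects like its diploid source).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .informative import InformativeLociSet, select_necessary
from .pca import center_matrix, compute_loadings, eigen_decompose
from .vcfio import PhasedGenotypeMatrix, collapse_genotypes

__all__ = [
    "Decision",
    "AncestryHierarchy",
    "PartitionTract",
    "TractPartition",
    "partition_tracts",
    "classify_tracts",
    "aggregate_hierarchy",
    "summarize_proportions",
    "ReferenceModel",
    "train_reference",
    "infer_tracts",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Decision:
    """One hierarchy node: which PCs separate which reference groups.

    ``groups`` maps group labels to reference population lists; ``parent`` is
    the group label of the parent decision this refines (None at the root).
    PC indices are 0-based.
    """

    name: str
    pcs: tuple[int, ...]
    groups: dict[str, tuple[str, ...]]
    parent: str | None = None

    def __post_init__(self):
        if len(self.groups) < 2 or len(self.pcs) < 1:
            raise ValueError("a decision needs >= 2 groups and >= 1 PC")


@dataclass
class AncestryHierarchy:
    """Tree of decisions; exactly one root (parent None)."""

    decisions: list[Decision]

    def __post_init__(self):
        roots = [d for d in self.decisions if d.parent is None]
        if len(roots) != 1:
            raise ValueError("hierarchy needs exactly one root decision")

    @property
    def root(self) -> Decision:
        return next(d for d in self.decisions if d.parent is None)

    def children_of(self, label: str) -> list[Decision]:
        return [d for d in self.decisions if d.parent == label]


@dataclass
class PartitionTract:
    """One minimal tract of a reference partition on one chromosome."""

    start: int  # index into the chromosome's informative-loci array
    end: int  # half-open
    start_bp: int
    end_bp: int
    centroids: np.ndarray  # one partial-projection centroid per group
    pooled_sd: float
    ok: bool  # separation criterion achieved


@dataclass
class TractPartition:
    """Per-PC reference partition: minimal tracts per chromosome, plus
    everything needed to project test haplotypes onto them."""

    pc: int
    group_labels: list[str]
    alpha: float
    loci_by_chrom: dict[str, np.ndarray]  # global locus rows, position order
    tracts_by_chrom: dict[str, list[PartitionTract]]
    gamma: np.ndarray  # full-length loadings column
    row_means: np.ndarray  # full-length training row means
    chrom_lengths: dict[str, int]


def _hap_contributions(alleles: np.ndarray, idx: np.ndarray, gamma: np.ndarray,
                       row_means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus per-haplotype loading contributions on the diploid scale.

    Missing alleles contribute 0 (mean imputation after centering); returns
    (contributions, missing mask), both (n_idx, n_haplotypes).
    """
    a = alleles[idx].reshape(idx.size, -1).astype(np.float64)  # haps interleaved
    missing = a < 0
    centered = 2.0 * a - row_means[idx][:, None]
    centered[missing] = 0.0
    return gamma[idx][:, None] * centered, missing


def _separated(means: np.ndarray, pooled_sd: float, alpha: float) -> bool:
    gaps = np.abs(means[:, None] - means[None, :])
    min_gap = gaps[np.triu_indices_from(gaps, k=1)].min()
    if pooled_sd == 0.0:
        return bool(min_gap > 0.0)
    return bool(min_gap >= alpha * pooled_sd)


def partition_tracts(reference: PhasedGenotypeMatrix, ils: InformativeLociSet,
                     gamma: np.ndarray, row_means: np.ndarray,
                     group_of_hap: np.ndarray, group_labels: list[str],
                     alpha: float = 3.0, min_loci: int = 1,
                     chrom_lengths: dict[str, int] | None = None) -> TractPartition:
    """Greedy left-to-right minimal-tract partition of each chromosome.

    The current window of consecutive informative loci grows until every pair
    of reference-group centroids differs by >= alpha pooled within-group SDs
    of the haplotype partial projections, then the tract closes.  A trailing
    window failing the test merges into the previous tract; a chromosome that
    never reaches separation becomes a single tract flagged low-confidence.

    Tract bp boundaries are midpoints between flanking informative loci;
    chromosome ends extend to 0 and the chromosome length.
    """
    n_groups = len(group_labels)
    counts = np.bincount(group_of_hap, minlength=n_groups).astype(np.float64)
    if np.any(counts < 4):
        raise ValueError("every reference group needs >= 2 subjects")
    chroms = reference.loci["chrom"].to_numpy()
    pos = reference.loci["pos"].to_numpy()
    order = ils.indices[np.lexsort((pos[ils.indices],
                                    pd.factorize(chroms[ils.indices], sort=True)[0]))]
    loci_by_chrom: dict[str, np.ndarray] = {}
    tracts_by_chrom: dict[str, list[PartitionTract]] = {}
    lengths = dict(chrom_lengths or {})
    for c in pd.unique(chroms):
        idx = order[chroms[order] == c]
        loci_by_chrom[c] = idx
        lengths.setdefault(c, int(pos[chroms == c].max()))
        if idx.size == 0:
            tracts_by_chrom[c] = []
            continue
        contrib, _ = _hap_contributions(reference.alleles, idx, gamma, row_means)
        onehot = np.zeros((contrib.shape[1], n_groups))
        onehot[np.arange(contrib.shape[1]), group_of_hap] = 1.0
        csum = np.vstack([np.zeros(contrib.shape[1]),
                          np.cumsum(contrib, axis=0)])
        dof = max(counts.sum() - n_groups, 1.0)

        def window_stats(a: int, b: int) -> tuple[np.ndarray, float]:
            w = csum[b] - csum[a]  # per-haplotype partial projections
            means = (w @ onehot) / counts
            within = float(np.sum(w**2 @ onehot - counts * means**2))
            return means, float(np.sqrt(max(within, 0.0) / dof))

        tracts: list[PartitionTract] = []
        start = 0
        for end in range(1, idx.size + 1):
            if end - start < min_loci:
                continue
            means, sd = window_stats(start, end)
            if _separated(means, sd, alpha):
                tracts.append(PartitionTract(start, end, 0, 0, means, sd, True))
                start = end
        if start < idx.size or not tracts:
            if tracts:  # merge the trailing failed window into the last tract
                last = tracts.pop()
                means, sd = window_stats(last.start, idx.size)
                tracts.append(PartitionTract(last.start, idx.size, 0, 0, means, sd,
                                             _separated(means, sd, alpha)))
            else:
                means, sd = window_stats(0, idx.size)
                tracts.append(PartitionTract(0, idx.size, 0, 0, means, sd, False))
        p = pos[idx]
        for t in tracts:
            t.start_bp = 0 if t.start == 0 else int((p[t.start - 1] + p[t.start]) // 2)
            t.end_bp = lengths[c] if t.end == idx.size else int((p[t.end - 1] + p[t.end]) // 2)
        tracts_by_chrom[c] = tracts
    return TractPartition(ils.pc, list(group_labels), alpha, loci_by_chrom,
                          tracts_by_chrom, gamma.copy(), row_means.copy(), lengths)


def classify_tracts(test: PhasedGenotypeMatrix, partition: TractPartition,
                    max_missing: float = 0.5) -> pd.DataFrame:
    """Label every tract of every test haplotype by nearest reference centroid.

    Returns one row per (subject, haplotype, tract) with the per-PC label and
    the separation z-score (margin between best and second-best centroid in
    pooled-SD units).  Tracts with more than ``max_missing`` missing loci, an
    exact centroid tie, or a low-confidence partition are labeled
    ``unassigned`` (ties keep the first-listed group under the relaxed
    criterion downstream via ``tie_label``).
    """
    rows = []
    chroms = test.loci["chrom"].to_numpy()
    for c, idx in partition.loci_by_chrom.items():
        if idx.size == 0:
            continue
        contrib, missing = _hap_contributions(test.alleles, idx,
                                              partition.gamma, partition.row_means)
        csum = np.vstack([np.zeros(contrib.shape[1]), np.cumsum(contrib, axis=0)])
        msum = np.vstack([np.zeros(contrib.shape[1]),
                          np.cumsum(missing, axis=0, dtype=np.float64)])
        n_hap = contrib.shape[1]
        for t in partition.tracts_by_chrom[c]:
            proj = csum[t.end] - csum[t.start]
            miss_frac = (msum[t.end] - msum[t.start]) / (t.end - t.start)
            d = np.abs(proj[:, None] - t.centroids[None, :])
            best = np.argmin(d, axis=1)
            dsort = np.sort(d, axis=1)
            margin = dsort[:, 1] - dsort[:, 0]
            sd = t.pooled_sd if t.pooled_sd > 0 else 1.0
            score = margin / sd
            for h in range(n_hap):
                tie = margin[h] == 0.0
                usable = t.ok and miss_frac[h] <= max_missing
                label = partition.group_labels[best[h]] if usable else UNASSIGNED
                rows.append((test.subjects[h // 2], h % 2, c,
                             t.start_bp, t.end_bp,
                             UNASSIGNED if (tie and usable) else label,
                             label if usable else UNASSIGNED,
                             float(score[h]) if usable else 0.0))
    return pd.DataFrame(rows, columns=["subject", "haplotype", "chrom", "start",
                                       "end", "label", "tie_label", "score"])


def _segments_from_calls(calls: pd.DataFrame) -> dict[tuple, list]:
    """Group per-tract calls into {(subject, hap, chrom): [(s, e, label,
    tie_label, score), ...]} sorted by start."""
    out: dict[tuple, list] = {}
    for row in calls.itertuples(index=False):
        out.setdefault((row.subject, row.haplotype, row.chrom), []).append(
            (row.start, row.end, row.label, row.tie_label, row.score))
    for v in out.values():
        v.sort()
    return out


def _combine_decision(per_pc: list[dict], key: tuple, criterion: str) -> list:
    """Merge one decision's per-PC segmentations of one haplotype-chromosome
    into refinement intervals with a single label per interval."""
    seg_lists = [d.get(key, []) for d in per_pc]
    bounds = sorted({b for segs in seg_lists for s, e, *_ in segs for b in (s, e)})
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        mid = (s + e) / 2
        votes = []
        for segs in seg_lists:
            for ts, te, label, tie_label, score in segs:
                if ts <= mid < te:
                    votes.append((label, tie_label, score))
                    break
        if not votes:
            continue
        labels = [v[0] for v in votes]
        assigned = [v for v in votes if v[0] != UNASSIGNED]
        if criterion == "stringent":
            if assigned and len(votes) == len(assigned) and len(set(labels)) == 1:
                label, score = labels[0], max(v[2] for v in votes)
            else:
                label, score = UNASSIGNED, 0.0
        else:  # relaxed: strongest assigned vote; exact ties fall back to
            # the tie_label (first-listed group) of the strongest vote
            if assigned:
                label, _, score = max(assigned, key=lambda v: v[2])
            else:
                strongest = max(votes, key=lambda v: v[2])
                label, score = strongest[1], strongest[2]
        out.append((s, e, label, score))
    return _coalesce(out)


def _coalesce(segments: list) -> list:
    """Merge adjacent segments sharing a label (keep the max score)."""
    out: list = []
    for s, e, label, score in segments:
        if out and out[-1][2] == label and out[-1][1] == s:
            out[-1] = (out[-1][0], e, label, max(out[-1][3], score))
        else:
            out.append((s, e, label, score))
    return out


def aggregate_hierarchy(calls_by_decision: dict[str, list[pd.DataFrame]],
                        hierarchy: AncestryHierarchy,
                        criterion: str = "relaxed") -> pd.DataFrame:
    """Combine per-PC tract labels through the hierarchy, root to leaf.

    ``calls_by_decision`` maps decision names to the per-PC call tables from
    :func:`classify_tracts`.  Within a decision, overlapping per-PC tracts
    are intersected into refinement intervals; the relaxed criterion takes
    the strongest score, the stringent criterion requires unanimity and
    otherwise leaves the interval unassigned.  Child decisions only refine
    intervals carrying their parent's label; final labels are hierarchical
    paths (e.g. ``nonAFR/EUR``).
    """
    if criterion not in ("relaxed", "stringent"):
        raise ValueError("criterion must be 'relaxed' or 'stringent'")
    maps_by_decision = {
        name: [_segments_from_calls(df) for df in dfs]
        for name, dfs in calls_by_decision.items()
    }
    keys = sorted({k for maps in maps_by_decision.values() for d in maps for k in d})

    def refine(decision: Decision, key: tuple, parent_segments: list,
               prefix: str) -> list:
        own = _combine_decision(maps_by_decision[decision.name], key, criterion)
        out = []
        for ps, pe, plabel, pscore in parent_segments:
            pieces = []
            cursor = ps
            for s, e, label, score in own:
                s2, e2 = max(s, ps), min(e, pe)
                if s2 >= e2:
                    continue
                if s2 > cursor:  # child cannot refine here: parent label stands
                    pieces.append((cursor, s2, plabel, pscore))
                path = f"{prefix}{label}" if label != UNASSIGNED else UNASSIGNED
                pieces.append((s2, e2, path, score))
                cursor = e2
            if cursor < pe:
                pieces.append((cursor, pe, plabel, pscore))
            out.extend(pieces)
        result = _coalesce(sorted(out))
        final = []
        for s, e, path, score in result:
            leaf = path.rsplit("/", 1)[-1]
            kids = hierarchy.children_of(leaf) if path != UNASSIGNED else []
            segs = [(s, e, path, score)]
            for child in kids:
                segs = refine(child, key, segs, prefix=f"{path}/")
            final.extend(segs)
        return _coalesce(sorted(final))

    rows = []
    root = hierarchy.root
    for key in keys:
        # whole-chromosome parent interval spanning the root decision's calls
        root_segs = _combine_decision(maps_by_decision[root.name], key, criterion)
        if not root_segs:
            continue
        span = [(root_segs[0][0], root_segs[-1][1], "", 0.0)]
        segs = refine(root, key, span, prefix="")
        subject, hap, chrom = key
        for s, e, path, score in segs:
            rows.append((subject, hap, chrom, s, e, path,
                         path.rsplit("/", 1)[-1], score, criterion))
    return pd.DataFrame(rows, columns=["subject", "haplotype", "chrom", "start",
                                       "end", "label", "leaf", "score", "criterion"])


def summarize_proportions(tracts: pd.DataFrame, by: str = "leaf") -> pd.DataFrame:
    """Per-subject bp-weighted tract-length proportions over labels.

    Both haplotypes contribute; proportions over labels (including
    ``unassigned``) sum to 1 per subject.
    """
    df = tracts.copy()
    df["length"] = df["end"] - df["start"]
    table = df.pivot_table(index="subject", columns=by, values="length",
                           aggfunc="sum", fill_value=0.0)
    return table.div(table.sum(axis=1), axis=0)


@dataclass
class ReferenceModel:
    """Trained reference: loadings, informative sets, and tract partitions
    for every (decision, PC) of the hierarchy."""

    hierarchy: AncestryHierarchy
    partitions: dict[str, list[TractPartition]]  # decision name -> per-PC
    informative: dict[int, InformativeLociSet] = field(default_factory=dict)


def train_reference(reference: PhasedGenotypeMatrix, panel: pd.Series,
                    hierarchy: AncestryHierarchy, threshold: float = 0.9,
                    alpha: float = 3.0, step: int | None = None,
                    min_loci: int = 1,
                    chrom_lengths: dict[str, int] | None = None) -> ReferenceModel:
    """Fit PCA on the reference cohort, select each needed PC's necessary
    informative loci, and partition chromosomes into minimal tracts for every
    decision of the hierarchy."""
    gm = collapse_genotypes(reference)
    cgm = center_matrix(gm)
    eig = eigen_decompose(cgm)
    loadings = compute_loadings(cgm, eig)
    panel = panel.loc[reference.subjects]
    needed_pcs = sorted({k for d in hierarchy.decisions for k in d.pcs})
    informative = {
        k: select_necessary(cgm, loadings, k, threshold=threshold, step=step,
                            loci=reference.loci)
        for k in needed_pcs
    }
    partitions: dict[str, list[TractPartition]] = {}
    for decision in hierarchy.decisions:
        labels = list(decision.groups)
        pop_to_group = {p: gi for gi, lab in enumerate(labels)
                        for p in decision.groups[lab]}
        sub_idx = np.flatnonzero(panel.map(lambda p: p in pop_to_group).to_numpy())
        sub = PhasedGenotypeMatrix(
            alleles=reference.alleles[:, sub_idx, :], loci=reference.loci,
            subjects=[reference.subjects[i] for i in sub_idx])
        group_of_hap = np.repeat(
            [pop_to_group[panel.iloc[i]] for i in sub_idx], 2)
        partitions[decision.name] = [
            partition_tracts(sub, informative[k], loadings.values[:, k],
                             cgm.row_means, np.asarray(group_of_hap), labels,
                             alpha=alpha, min_loci=min_loci,
                             chrom_lengths=chrom_lengths)
            for k in decision.pcs
        ]
    return ReferenceModel(hierarchy, partitions, informative)


def infer_tracts(model: ReferenceModel, test: PhasedGenotypeMatrix,
                 criterion: str = "relaxed") -> pd.DataFrame:
    """Classify every test haplotype on every (decision, PC) partition and
    aggregate through the hierarchy."""
    if not test.all_phased:
        raise ValueError("local-ancestry inference requires phased genotypes")
    calls = {
        name: [classify_tracts(test, part) for part in parts]
        for name, parts in model.partitions.items()
    }
    return aggregate_hierarchy(calls, model.hierarchy, criterion)
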