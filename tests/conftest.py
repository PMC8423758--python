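"""Shared fixtures: simulated cohorts and their PCA decompositions.

The expensive cohorts are session-scoped; all tests that need population
structure share them rather than re-simulating.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from infoloci import ancestry, demography, pca, vcfio
from infoloci.demography import DemographicScenario, FoundingEvent


@dataclass
class CohortBundle:
    cohort: demography.SimulatedCohort
    gm: vcfio.GenotypeMatrix
    cgm: pca.CenteredGenotypeMatrix
    eig: pca.EigenSystem
    loadings: pca.LoadingsMatrix
    projections: np.ndarray

    @property
    def pops(self) -> np.ndarray:
        return self.cohort.panel.to_numpy()


def _bundle(cohort: demography.SimulatedCohort) -> CohortBundle:
    gm = vcfio.collapse_genotypes(cohort.phased)
    cgm = pca.center_matrix(gm)
    eig = pca.eigen_decompose(cgm)
    loadings = pca.compute_loadings(cgm, eig)
    return CohortBundle(cohort, gm, cgm, eig, loadings,
                        pca.project(cgm, eig, route="eigen"))


@pytest.fixture(scope="session")
def five_pop() -> CohortBundle:
    """The five-population preset (AFR -> EUA -> {EUR, EAS} -> {SAS, AMR})."""
    cohort = demography.run_scenario(
        demography.preset_scenario("five-population", seed=1))
    return _bundle(cohort)


def two_population_scenario(seed: int = 7) -> DemographicScenario:
    """Two strongly drift-separated populations for local-ancestry tests."""
    return DemographicScenario(
        n_loci=4000,
        chromosomes=tuple((str(i + 1), 800) for i in range(5)),
        generations=20,
        events=(FoundingEvent(1, "POPB", (("POPA", 1.0),), 4, 400),),
        ancestral="POPA",
        capacity_default=400,
        sample_per_pop=80,
        seed=seed,
    )


@pytest.fixture(scope="session")
def two_pop() -> CohortBundle:
    return _bundle(demography.run_scenario(two_population_scenario()))


@pytest.fixture(scope="session")
def two_pop_hierarchy() -> ancestry.AncestryHierarchy:
    return ancestry.AncestryHierarchy([
        ancestry.Decision("root", (0,), {"POPA": ("POPA",), "POPB": ("POPB",)}),
    ])


def subset_phased(pgm: vcfio.PhasedGenotypeMatrix,
                  idx: np.ndarray) -> vcfio.PhasedGenotypeMatrix:
    return vcfio.PhasedGenotypeMatrix(
        alleles=pgm.alleles[:, idx, :], loci=pgm.loci,
        subjects=[pgm.subjects[i] for i in idx])


def length_weighted_accuracy(tracts, truth: demography.AncestryTruth,
                             subjects: list[str], loci,
                             bp_per_locus: int) -> float:
    """Fraction of locus-bp where the inferred leaf label matches the truth
    lineage, over all haplotypes (unassigned counts as wrong)."""
    chroms = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    sub_index = {s: i for i, s in enumerate(subjects)}
    total = 0
    hit = 0
    by_key = {}
    for row in tracts.itertuples(index=False):
        by_key.setdefault((row.subject, row.haplotype, row.chrom), []).append(
            (row.start, row.end, row.leaf))
    for (subject, hap, chrom), segs in by_key.items():
        s_idx = sub_index[subject]
        mask = chroms == chrom
        p = pos[mask]
        labels = truth.labels[s_idx, hap][mask]
        names = np.array(truth.lineage_names)[labels]
        for start, end, leaf in segs:
            in_seg = (p > start) & (p <= end)
            total += int(in_seg.sum())
            if leaf != ancestry.UNASSIGNED:
                hit += int((names[in_seg] == leaf).sum())
    return hit / total
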