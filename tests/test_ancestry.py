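"""Tract partitioning, nearest-centroid classification, and hierarchical
aggregation, validated against exact mosaic truth."""

import numpy as np
import pandas as pd
import pytest

from infoloci import ancestry, demography, vcfio
from infoloci.ancestry import (AncestryHierarchy, Decision, PartitionTract,
                               TractPartition, UNASSIGNED)
from infoloci.informative import InformativeLociSet

from tests.conftest import length_weighted_accuracy, subset_phased


def _fixed_difference_reference(n_loci=60, per_pop=4):
    """Two populations with fixed opposite alleles at every locus."""
    loci = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_loci + 1) * 100,
                         "major": "A", "minor": "G", "call_rate": 1.0})
    alleles = np.zeros((n_loci, 2 * per_pop, 2), dtype=np.int8)
    alleles[:, per_pop:, :] = 1
    subs = [f"x{i}" for i in range(per_pop)] + [f"y{i}" for i in range(per_pop)]
    pgm = vcfio.PhasedGenotypeMatrix(alleles=alleles, loci=loci, subjects=subs)
    group_of_hap = np.repeat([0, 1], 2 * per_pop)
    ils = InformativeLociSet(
        pc=0, indices=np.arange(n_loci), loadings=np.ones(n_loci),
        sign_group=np.ones(n_loci, np.int8),
        provenance=np.array(["truncation"] * n_loci),
        achieved_correlation=1.0, threshold=0.9)
    gamma = np.ones(n_loci)
    row_means = np.full(n_loci, 1.0)  # mean genotype over the two populations
    return pgm, ils, gamma, row_means, group_of_hap


class TestPartitionTracts:
    def test_saturated_separation_gives_minimal_tracts(self):
        pgm, ils, gamma, means, groups = _fixed_difference_reference()
        part = ancestry.partition_tracts(pgm, ils, gamma, means, groups,
                                         ["X", "Y"], alpha=3.0)
        tracts = part.tracts_by_chrom["1"]
        assert len(tracts) == pgm.n_loci  # every tract is one locus wide
        assert all(t.ok for t in tracts)
        assert all(t.end - t.start == 1 for t in tracts)

    def test_no_signal_flags_whole_chromosome(self):
        # one population duplicated under two labels: separation unreachable
        pgm, ils, gamma, means, groups = _fixed_difference_reference()
        pgm.alleles[:] = np.tile(pgm.alleles[:, :4, :], (1, 2, 1))
        part = ancestry.partition_tracts(pgm, ils, gamma, means, groups,
                                         ["X", "Y"], alpha=3.0)
        tracts = part.tracts_by_chrom["1"]
        assert len(tracts) == 1
        assert not tracts[0].ok
        calls = ancestry.classify_tracts(pgm, part)
        assert set(calls["label"]) == {UNASSIGNED}

    def test_boundaries_are_midpoints_and_chromosome_ends(self):
        pgm, ils, gamma, means, groups = _fixed_difference_reference(n_loci=4)
        part = ancestry.partition_tracts(pgm, ils, gamma, means, groups,
                                         ["X", "Y"], alpha=3.0,
                                         chrom_lengths={"1": 500})
        tracts = part.tracts_by_chrom["1"]
        assert tracts[0].start_bp == 0
        assert tracts[-1].end_bp == 500
        assert tracts[0].end_bp == (100 + 200) // 2

    def test_emitted_tracts_are_minimal(self, two_pop, two_pop_hierarchy):
        # each tract passes the separation test, and no strictly shorter
        # prefix of it does (re-evaluating the criterion per boundary)
        model = ancestry.train_reference(two_pop.cohort.phased,
                                         two_pop.cohort.panel,
                                         two_pop_hierarchy)
        part = model.partitions["root"][0]
        chrom, tracts = "1", part.tracts_by_chrom["1"]
        idx = part.loci_by_chrom[chrom]
        contrib, _ = ancestry._hap_contributions(
            two_pop.cohort.phased.alleles, idx, part.gamma, part.row_means)
        groups = np.repeat(
            (two_pop.cohort.panel.to_numpy() == "POPB").astype(int), 2)

        def separated(a, b):
            win = contrib[a:b].sum(axis=0)
            m0, m1 = win[groups == 0].mean(), win[groups == 1].mean()
            sq = (np.sum((win[groups == 0] - m0) ** 2)
                  + np.sum((win[groups == 1] - m1) ** 2))
            sd = np.sqrt(sq / max(win.size - 2, 1))
            return abs(m0 - m1) > 0 if sd == 0 else abs(m0 - m1) >= 3.0 * sd

        for t in [t for t in tracts if t.ok][:-1]:
            assert separated(t.start, t.end)
            if t.end - t.start > 1:
                assert not separated(t.start, t.end - 1)


class TestClassification:
    def test_training_haplotype_recovers_own_label(self, two_pop,
                                                   two_pop_hierarchy):
        model = ancestry.train_reference(two_pop.cohort.phased,
                                         two_pop.cohort.panel,
                                         two_pop_hierarchy)
        idx = np.array([0, len(two_pop.cohort.panel) - 1])
        test = subset_phased(two_pop.cohort.phased, idx)
        tracts = ancestry.infer_tracts(model, test, criterion="relaxed")
        props = ancestry.summarize_proportions(tracts)
        for i, s in enumerate(test.subjects):
            own = two_pop.cohort.panel.iloc[idx[i]]
            # a verbatim training haplotype lands on its own centroids:
            # its own label dominates the genome
            assert props.loc[s, own] > 0.75
        assert np.mean([props.loc[s, two_pop.cohort.panel.iloc[idx[i]]]
                        for i, s in enumerate(test.subjects)]) > 0.9

    def test_exact_tie_rule(self):
        pgm, ils, gamma, means, groups = _fixed_difference_reference(n_loci=8)
        part = TractPartition(
            pc=0, group_labels=["X", "Y"], alpha=3.0,
            loci_by_chrom={"1": np.arange(8)},
            tracts_by_chrom={"1": [PartitionTract(0, 8, 0, 800,
                                                  np.array([-4.0, 4.0]),
                                                  1.0, True)]},
            gamma=gamma, row_means=means, chrom_lengths={"1": 800})
        # a haplotype with half 0s and half 1s projects to exactly 0
        test = subset_phased(pgm, np.array([0]))
        test.alleles[:4] = 1 - test.alleles[:4]
        calls = ancestry.classify_tracts(test, part)
        assert list(calls["label"]) == [UNASSIGNED] * 2
        assert list(calls["tie_label"]) == ["X", "X"]  # first-listed group
        hier = AncestryHierarchy([Decision("root", (0,),
                                           {"X": ("X",), "Y": ("Y",)})])
        relaxed = ancestry.aggregate_hierarchy({"root": [calls]}, hier,
                                               "relaxed")
        stringent = ancestry.aggregate_hierarchy({"root": [calls]}, hier,
                                                 "stringent")
        assert set(relaxed["leaf"]) == {"X"}
        assert set(stringent["leaf"]) == {UNASSIGNED}

    def test_missing_loci_above_half_unassigned(self):
        pgm, ils, gamma, means, groups = _fixed_difference_reference(n_loci=8)
        part = ancestry.partition_tracts(pgm, ils, gamma, means, groups,
                                         ["X", "Y"], alpha=3.0, min_loci=8)
        test = subset_phased(pgm, np.array([0]))
        test.alleles[:5, 0, 0] = -1  # >50% of tract loci missing on hap 0
        calls = ancestry.classify_tracts(test, part)
        by_hap = calls.set_index("haplotype")["label"]
        assert by_hap[0] == UNASSIGNED
        assert by_hap[1] == "X"


class TestHierarchy:
    def _calls(self, labels_scores, start=0, end=100):
        rows = [("s", 0, "1", start, end, lab, lab, sc)
                for lab, sc in [labels_scores]]
        return pd.DataFrame(rows, columns=["subject", "haplotype", "chrom",
                                           "start", "end", "label",
                                           "tie_label", "score"])

    def test_agreement_and_disagreement_across_pcs(self):
        hier = AncestryHierarchy([
            Decision("root", (1, 2), {"EUR": ("EUR",), "AMR": ("AMR",)})])
        agree = {"root": [self._calls(("EUR", 2.0)),
                          self._calls(("EUR", 1.0))]}
        for criterion in ("relaxed", "stringent"):
            out = ancestry.aggregate_hierarchy(agree, hier, criterion)
            assert list(out["leaf"]) == ["EUR"]
        disagree = {"root": [self._calls(("EUR", 2.0)),
                             self._calls(("AMR", 5.0))]}
        relaxed = ancestry.aggregate_hierarchy(disagree, hier, "relaxed")
        stringent = ancestry.aggregate_hierarchy(disagree, hier, "stringent")
        assert list(relaxed["leaf"]) == ["AMR"]  # strongest score wins
        assert list(stringent["leaf"]) == [UNASSIGNED]

    def test_child_decisions_only_refine_parent_label(self):
        hier = AncestryHierarchy([
            Decision("root", (0,), {"AFR": ("A",), "nonAFR": ("B", "C")}),
            Decision("eurasian", (1,), {"EUR": ("B",), "EAS": ("C",)},
                     parent="nonAFR"),
        ])
        calls = {
            "root": [self._calls(("AFR", 3.0))],
            "eurasian": [self._calls(("EUR", 2.0))],
        }
        out = ancestry.aggregate_hierarchy(calls, hier, "relaxed")
        # an AFR interval never receives a label from the nonAFR subtree
        assert list(out["label"]) == ["AFR"]

    def test_hierarchical_path_labels(self):
        hier = AncestryHierarchy([
            Decision("root", (0,), {"AFR": ("A",), "nonAFR": ("B", "C")}),
            Decision("eurasian", (1,), {"EUR": ("B",), "EAS": ("C",)},
                     parent="nonAFR"),
        ])
        calls = {
            "root": [self._calls(("nonAFR", 3.0))],
            "eurasian": [self._calls(("EUR", 2.0))],
        }
        out = ancestry.aggregate_hierarchy(calls, hier, "relaxed")
        assert list(out["label"]) == ["nonAFR/EUR"]
        assert list(out["leaf"]) == ["EUR"]


class TestProportions:
    def test_single_label_genome(self):
        tracts = pd.DataFrame([
            ("s", 0, "1", 0, 100, "A", "A", 1.0, "relaxed"),
            ("s", 1, "1", 0, 100, "A", "A", 1.0, "relaxed"),
        ], columns=["subject", "haplotype", "chrom", "start", "end", "label",
                    "leaf", "score", "criterion"])
        props = ancestry.summarize_proportions(tracts)
        assert props.loc["s", "A"] == 1.0

    def test_half_and_half_across_haplotypes(self):
        tracts = pd.DataFrame([
            ("s", 0, "1", 0, 100, "A", "A", 1.0, "relaxed"),
            ("s", 1, "1", 0, 100, "B", "B", 1.0, "relaxed"),
        ], columns=["subject", "haplotype", "chrom", "start", "end", "label",
                    "leaf", "score", "criterion"])
        props = ancestry.summarize_proportions(tracts)
        assert props.loc["s", "A"] == 0.5
        assert props.loc["s", "B"] == 0.5


@pytest.fixture(scope="module")
def mosaic_setup(two_pop, two_pop_hierarchy):
    rng = np.random.default_rng(21)
    model = ancestry.train_reference(two_pop.cohort.phased,
                                     two_pop.cohort.panel,
                                     two_pop_hierarchy)
    mosaic = demography.make_mosaic_subjects(
        two_pop.cohort.phased, two_pop.cohort.panel, 12, rng,
        mean_tract_loci=150)
    relaxed = ancestry.infer_tracts(model, mosaic.phased, "relaxed")
    stringent = ancestry.infer_tracts(model, mosaic.phased, "stringent")
    return model, mosaic, relaxed, stringent


class TestMosaicRecovery:

    def test_top_level_accuracy_at_least_80_percent(self, two_pop,
                                                    mosaic_setup):
        _, mosaic, relaxed, _ = mosaic_setup
        acc = length_weighted_accuracy(relaxed, mosaic.truth,
                                       mosaic.phased.subjects,
                                       mosaic.phased.loci,
                                       bp_per_locus=1)
        assert acc >= 0.80

    def test_relaxed_assigns_at_least_as_much_as_stringent(self, mosaic_setup):
        _, _, relaxed, stringent = mosaic_setup

        def unassigned_fraction(tracts):
            props = ancestry.summarize_proportions(tracts)
            if UNASSIGNED not in props.columns:
                return 0.0
            return float(props[UNASSIGNED].mean())

        assert unassigned_fraction(relaxed) <= unassigned_fraction(stringent)

    def test_proportions_within_five_points_of_truth(self, mosaic_setup):
        _, mosaic, relaxed, _ = mosaic_setup
        props = ancestry.summarize_proportions(relaxed)
        for label in ("POPA", "POPB"):
            truth = mosaic.truth.fraction_of(label)
            got = props.get(label, pd.Series(0.0, index=props.index)).mean()
            assert abs(got - truth) <= 0.05

    def test_halving_a_reference_population_is_robust(self, two_pop,
                                                      two_pop_hierarchy,
                                                      mosaic_setup):
        _, mosaic, relaxed, _ = mosaic_setup
        panel = two_pop.cohort.panel
        keep = np.flatnonzero(panel.to_numpy() == "POPA")[::2]
        keep = np.sort(np.concatenate(
            [keep, np.flatnonzero(panel.to_numpy() == "POPB")]))
        half_model = ancestry.train_reference(
            subset_phased(two_pop.cohort.phased, keep), panel.iloc[keep],
            two_pop_hierarchy)
        half = ancestry.infer_tracts(half_model, mosaic.phased, "relaxed")
        full_props = ancestry.summarize_proportions(relaxed)
        half_props = ancestry.summarize_proportions(half)
        cols = full_props.columns.union(half_props.columns)
        diff = (full_props.reindex(columns=cols, fill_value=0)
                - half_props.reindex(columns=cols, fill_value=0)).abs()
        # typical per-subject change and the population-level shift both stay
        # under 5 points; individual subjects can move more at this genome
        # size when a single tract boundary is re-drawn
        assert float(diff.mean().mean()) < 0.05
        assert float((full_props.mean() - half_props.mean()).abs().max()) < 0.05


class TestSelfClassification:
    def test_held_out_reference_subjects(self, two_pop, two_pop_hierarchy):
        panel = two_pop.cohort.panel
        pops = panel.to_numpy()
        train_idx, test_idx = [], []
        for p in ("POPA", "POPB"):
            idx = np.flatnonzero(pops == p)
            train_idx.append(idx[: int(0.7 * idx.size)])
            test_idx.append(idx[int(0.7 * idx.size):])
        train_idx = np.sort(np.concatenate(train_idx))
        test_idx = np.sort(np.concatenate(test_idx))
        model = ancestry.train_reference(
            subset_phased(two_pop.cohort.phased, train_idx),
            panel.iloc[train_idx], two_pop_hierarchy)
        test = subset_phased(two_pop.cohort.phased, test_idx)
        tracts = ancestry.infer_tracts(model, test, "relaxed")
        props = ancestry.summarize_proportions(tracts)
        own = np.array([props.loc[s, panel.iloc[i]]
                        for s, i in zip(test.subjects, test_idx)])
        assert own.mean() >= 0.90
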