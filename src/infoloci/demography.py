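"""Forward-time diploid simulator of population splits and admixed foundings.

Populations evolve by Wright-Fisher-style random mating with recombination
and no mutation; new populations are founded by isolating a small number of
members from one parent population (pure split) or two (admixed founding
with stated mixing proportions), then grow exponentially (doubling) until a
carrying capacity.  Every haplotype carries per-locus founding-lineage
labels: at each founding event a founder's whole genome is relabeled with
the parent population it was drawn from, and labels thereafter propagate
through the same crossovers as the alleles.  The labels are exact ground
truth for ancestry-proportion and local-ancestry benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InvalidScenarioError",
    "FoundingEvent",
    "DemographicScenario",
    "Population",
    "AncestryTruth",
    "SimulatedCohort",
    "init_ancestral_population",
    "advance_generation",
    "found_population",
    "run_scenario",
    "make_mosaic_subjects",
    "preset_scenario",
    "load_scenario",
    "PRESETS",
]


class InvalidScenarioError(ValueError):
    """Raised when a demographic scenario is internally inconsistent."""


@dataclass(frozen=True)
class FoundingEvent:
    """Creation of a new population at a given generation.

    ``parents`` maps parent population labels to mixing proportions; a single
    parent with proportion 1.0 is a pure split, two parents with proportions
    in (0, 1) an admixed founding.
    """

    generation: int
    new_population: str
    parents: tuple[tuple[str, float], ...]
    founder_size: int
    capacity: int

    def __post_init__(self):
        props = [p for _, p in self.parents]
        if not self.parents or abs(sum(props) - 1.0) > 1e-9:
            raise InvalidScenarioError(
                f"mixing proportions of {self.new_population!r} must sum to 1"
            )
        if len(self.parents) == 1 and props[0] != 1.0:
            raise InvalidScenarioError("single-parent founding requires proportion 1.0")
        if len(self.parents) > 1 and any(not 0 < p < 1 for p in props):
            raise InvalidScenarioError("admixed founding requires proportions in (0, 1)")
        if not 1 <= self.founder_size <= self.capacity:
            raise InvalidScenarioError("need 1 <= founder_size <= capacity")


@dataclass(frozen=True)
class DemographicScenario:
    """Full description of a founder-drift simulation.

    ``init_freq_law`` is ``("uniform", lo, hi)`` or ``("fixed", p)`` for the
    per-locus ancestral minor-allele frequency; ``crossover_rate`` is the
    expected number of crossovers per chromosome per meiosis;
    ``bp_per_locus`` spaces loci on a physical map for BED/VCF export.
    """

    n_loci: int
    chromosomes: tuple[tuple[str, int], ...]
    generations: int
    events: tuple[FoundingEvent, ...]
    ancestral: str = "ANC"
    capacity_default: int = 200
    founder_size_default: int = 20
    init_freq_law: tuple = ("uniform", 0.05, 0.95)
    crossover_rate: float = 1.0
    bp_per_locus: int = 10_000
    sampled: tuple[str, ...] | None = None  # cohort populations; None = all
    sample_per_pop: int | None = None  # subjects sampled per population; None = all
    seed: int = 0

    def __post_init__(self):
        if sum(c for _, c in self.chromosomes) != self.n_loci:
            raise InvalidScenarioError("chromosome locus counts must sum to n_loci")
        born = {self.ancestral: 0}
        for ev in sorted(self.events, key=lambda e: e.generation):
            if ev.new_population in born:
                raise InvalidScenarioError(f"population {ev.new_population!r} founded twice")
            for parent, _ in ev.parents:
                if parent not in born or born[parent] >= ev.generation:
                    raise InvalidScenarioError(
                        f"{ev.new_population!r} founded at generation {ev.generation} "
                        f"from {parent!r} which does not exist strictly earlier"
                    )
            born[ev.new_population] = ev.generation

    @property
    def chrom_slices(self) -> list[tuple[str, slice]]:
        out, start = [], 0
        for name, count in self.chromosomes:
            out.append((name, slice(start, start + count)))
            start += count
        return out


@dataclass
class Population:
    """A generation of diploid individuals with lineage-labeled haplotypes."""

    name: str
    haplotypes: np.ndarray  # (n_ind, 2, n_loci) uint8 alleles in {0,1}
    lineage: np.ndarray  # (n_ind, 2, n_loci) int16 founding-lineage codes
    capacity: int
    founder_freqs: np.ndarray | None = None  # sampled ancestral frequencies

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class AncestryTruth:
    """Per-haplotype per-locus founding-lineage labels.

    Stored densely as an ``(n_subjects, 2, n_loci)`` code matrix with a code
    -> lineage-name table; run-length tract views are derived on demand.
    """

    labels: np.ndarray
    lineage_names: list[str]

    def fraction_of(self, lineage: str, subject_idx=None) -> float:
        """Genome fraction carrying ``lineage`` (optionally within a subject subset)."""
        code = self.lineage_names.index(lineage)
        lab = self.labels if subject_idx is None else self.labels[subject_idx]
        return float(np.mean(lab == code))

    def to_tracts(self, loci: pd.DataFrame, subjects: list[str],
                  bp_per_locus: int = 1) -> pd.DataFrame:
        """Run-length tract table (0-based half-open, locus units and bp)."""
        rows = []
        chroms = loci["chrom"].to_numpy()
        for s, name in enumerate(subjects):
            for h in (0, 1):
                lab = self.labels[s, h]
                brk = np.flatnonzero(np.diff(lab) != 0) + 1
                brk = np.concatenate(([0], brk, [lab.size]))
                # also break at chromosome boundaries
                cbrk = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                brk = np.unique(np.concatenate([brk, cbrk]))
                for a, b in zip(brk[:-1], brk[1:]):
                    rows.append(
                        (chroms[a], int(a), int(b), int(a) * bp_per_locus,
                         int(b) * bp_per_locus, name, h,
                         self.lineage_names[lab[a]])
                    )
        return pd.DataFrame(
            rows,
            columns=["chrom", "start_locus", "end_locus", "start_bp", "end_bp",
                     "subject", "haplotype", "lineage"],
        )


@dataclass
class SimulatedCohort:
    """Final-generation phased genotypes, subject panel, and lineage truth."""

    phased: "vcfio.PhasedGenotypeMatrix"  # noqa: F821 - forward ref, see vcfio
    panel: pd.Series
    truth: AncestryTruth
    scenario: DemographicScenario | None = None


def _sample_init_freqs(law, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n_loci)
    if kind == "fixed":
        return np.full(n_loci, float(law[1]))
    raise InvalidScenarioError(f"unknown init_freq_law {law!r}")


def init_ancestral_population(n_loci: int, size: int, init_freq_law,
                              rng: np.random.Generator, name: str = "ANC",
                              capacity: int | None = None,
                              lineage_code: int = 0) -> Population:
    """Draw the ancestral population from per-locus binomial allele sampling.

    Each haplotype allele at locus j is an independent Bernoulli draw with
    that locus's sampled ancestral minor-allele frequency.
    """
    if size < 2:
        raise InvalidScenarioError("population size must be at least 2")
    if n_loci < 1:
        raise InvalidScenarioError("need at least one locus")
    freqs = _sample_init_freqs(init_freq_law, n_loci, rng)
    haps = (rng.random((size, 2, n_loci)) < freqs).astype(np.uint8)
    lineage = np.full((size, 2, n_loci), lineage_code, dtype=np.int16)
    return Population(name, haps, lineage, capacity or size, founder_freqs=freqs)


def _gametes_batch(haps: np.ndarray, lineage: np.ndarray, parent_idx: np.ndarray,
                   chrom_slices: list[tuple[str, slice]], crossover_rate: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product per listed parent.

    Per chromosome, Poisson(rate) crossovers fall on uniform inter-locus
    boundaries; the transmitted haplotype is recovered by an XOR scan of the
    per-boundary crossover parities, seeded at each chromosome start with a
    fresh fair bit (which also makes chromosomes assort independently).
    Lineage labels ride the same crossovers.
    """
    n_g = parent_idx.size
    n_loci = haps.shape[-1]
    parity = np.zeros((n_g, n_loci), dtype=np.uint8)
    starts = [sl.start for _, sl in chrom_slices]
    parity[:, starts] = rng.integers(0, 2, (n_g, len(starts)), dtype=np.uint8)
    for _, sl in chrom_slices:
        if sl.stop - sl.start < 2:
            continue
        k = rng.poisson(crossover_rate, n_g)
        total = int(k.sum())
        if total:
            rows = np.repeat(np.arange(n_g), k)
            cuts = rng.integers(sl.start + 1, sl.stop, total)
            np.add.at(parity, (rows, cuts), 1)
    source = np.bitwise_xor.accumulate(parity & 1, axis=1)
    cols = np.arange(n_loci)[None, :]
    pi = parent_idx[:, None]
    return haps[pi, source, cols], lineage[pi, source, cols]


def advance_generation(pop: Population, crossover_rate: float,
                       chrom_slices: list[tuple[str, slice]],
                       rng: np.random.Generator,
                       n_offspring: int | None = None) -> Population:
    """Produce the next non-overlapping generation by random mating.

    Each offspring draws two distinct parents uniformly (pairs with
    replacement across offspring, selfing forbidden) and receives one
    recombinant gamete from each.
    """
    if pop.size < 2:
        raise InvalidScenarioError("cannot mate a population of size < 2")
    n_off = pop.size if n_offspring is None else n_offspring
    pa = rng.integers(0, pop.size, n_off)
    pb = rng.integers(0, pop.size - 1, n_off)
    pb[pb >= pa] += 1
    g1, l1 = _gametes_batch(pop.haplotypes, pop.lineage, pa, chrom_slices,
                            crossover_rate, rng)
    g2, l2 = _gametes_batch(pop.haplotypes, pop.lineage, pb, chrom_slices,
                            crossover_rate, rng)
    return Population(pop.name, np.stack([g1, g2], axis=1),
                      np.stack([l1, l2], axis=1), pop.capacity)


def _apportion(total: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment; ties favor the first-listed parent."""
    raw = [total * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def found_population(event: FoundingEvent, parents: dict[str, Population],
                     rng: np.random.Generator,
                     lineage_codes: dict[str, int]) -> Population:
    """Sample founders from the parent population(s) and relabel lineages.

    Founder counts per parent follow the mixing proportions under
    largest-remainder rounding; each founder's genome is relabeled with its
    source parent's lineage code, so label mass at founding equals the
    per-parent haplotype share exactly.
    """
    names = [n for n, _ in event.parents]
    counts = _apportion(event.founder_size, [p for _, p in event.parents])
    haps, lin = [], []
    for name, count in zip(names, counts):
        parent = parents[name]
        if count > parent.size:
            raise InvalidScenarioError(
                f"founding {event.new_population!r}: {count} founders requested "
                f"from {name!r} of size {parent.size}"
            )
        chosen = rng.choice(parent.size, size=count, replace=False)
        haps.append(parent.haplotypes[chosen].copy())
        lin.append(np.full_like(parent.lineage[chosen], lineage_codes[name]))
    return Population(event.new_population, np.concatenate(haps),
                      np.concatenate(lin), event.capacity)


def run_scenario(scenario: DemographicScenario) -> SimulatedCohort:
    """Simulate the scenario and collect the final generation of every
    population into a phased cohort with panel and lineage truth.

    Deterministic given ``scenario.seed``.  Populations below capacity double
    each generation until capacity, then stay constant.
    """
    from . import vcfio  # local import: vcfio does not depend on this module

    rng = np.random.default_rng(scenario.seed)
    chrom_slices = scenario.chrom_slices
    lineage_names = [scenario.ancestral] + [e.new_population for e in
                                            sorted(scenario.events, key=lambda e: e.generation)]
    codes = {n: i for i, n in enumerate(lineage_names)}
    pops: dict[str, Population] = {
        scenario.ancestral: init_ancestral_population(
            scenario.n_loci, scenario.capacity_default, scenario.init_freq_law,
            rng, scenario.ancestral, scenario.capacity_default, codes[scenario.ancestral])
    }
    events = sorted(scenario.events, key=lambda e: (e.generation, e.new_population))
    for gen in range(1, scenario.generations + 1):
        for ev in events:
            if ev.generation == gen:
                pops[ev.new_population] = found_population(ev, pops, rng, codes)
        for name in list(pops):
            pop = pops[name]
            n_next = pop.size if pop.size >= pop.capacity else min(2 * pop.size, pop.capacity)
            pops[name] = advance_generation(pop, scenario.crossover_rate,
                                            chrom_slices, rng, n_next)

    subjects, pop_labels, hap_blocks, lin_blocks = [], [], [], []
    sampled = set(scenario.sampled) if scenario.sampled is not None else set(pops)
    unknown = sampled - set(pops)
    if unknown:
        raise InvalidScenarioError(f"sampled populations never founded: {sorted(unknown)}")
    for name in sorted(sampled):
        pop = pops[name]
        if scenario.sample_per_pop is not None and scenario.sample_per_pop < pop.size:
            keep = np.sort(rng.choice(pop.size, scenario.sample_per_pop, replace=False))
        else:
            keep = np.arange(pop.size)
        subjects += [f"{name}_{i:04d}" for i in keep]
        pop_labels += [name] * keep.size
        hap_blocks.append(pop.haplotypes[keep])
        lin_blocks.append(pop.lineage[keep])
    haps = np.concatenate(hap_blocks)  # (m, 2, n_loci)
    lin = np.concatenate(lin_blocks)

    loci = _locus_table(scenario)
    alleles = np.ascontiguousarray(haps.transpose(2, 0, 1)).astype(np.int8)
    phased = vcfio.PhasedGenotypeMatrix(alleles=alleles, loci=loci, subjects=subjects)
    panel = pd.Series(pop_labels, index=subjects, name="population")
    return SimulatedCohort(phased, panel, AncestryTruth(lin, lineage_names), scenario)


def _locus_table(scenario: DemographicScenario) -> pd.DataFrame:
    chroms, positions = [], []
    for name, count in scenario.chromosomes:
        chroms += [name] * count
        positions += [(i + 1) * scenario.bp_per_locus for i in range(count)]
    return pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "major": "A",
        "minor": "G",
        "call_rate": 1.0,
    })


def make_mosaic_subjects(reference: "vcfio.PhasedGenotypeMatrix",  # noqa: F821
                         ref_panel: pd.Series, n_subjects: int,
                         rng: np.random.Generator,
                         mean_tract_loci: float = 500.0,
                         label_weights: dict[str, float] | None = None) -> SimulatedCohort:
    """Build artificial admixed subjects as exact mosaics of reference haplotypes.

    Each haplotype is a concatenation of segments copied from randomly chosen
    reference haplotypes; segment lengths are geometric with mean
    ``mean_tract_loci`` (restarted at chromosome boundaries), segment labels
    drawn from ``label_weights`` (uniform over reference populations by
    default).  The returned truth records copied labels and breakpoints
    exactly.
    """
    from . import vcfio

    labels = sorted(ref_panel.unique())
    if not labels:
        raise ValueError("empty reference set")
    weights = np.array([(label_weights or {}).get(l, 1.0) for l in labels], float)
    weights /= weights.sum()
    hap_pool = {
        l: np.flatnonzero(ref_panel.to_numpy() == l) for l in labels
    }
    n_loci = reference.n_loci
    chrom = reference.loci["chrom"].to_numpy()
    cbrk = np.concatenate(([0], np.flatnonzero(chrom[1:] != chrom[:-1]) + 1, [n_loci]))
    alleles = np.empty((n_loci, n_subjects, 2), dtype=np.int8)
    lin = np.empty((n_subjects, 2, n_loci), dtype=np.int16)
    p_break = 1.0 / mean_tract_loci
    for s in range(n_subjects):
        for h in (0, 1):
            for a, b in zip(cbrk[:-1], cbrk[1:]):
                pos = a
                while pos < b:
                    length = min(int(rng.geometric(p_break)), b - pos)
                    li = rng.choice(len(labels), p=weights)
                    src_subj = hap_pool[labels[li]][rng.integers(len(hap_pool[labels[li]]))]
                    src_hap = rng.integers(0, 2)
                    alleles[pos:pos + length, s, h] = \
                        reference.alleles[pos:pos + length, src_subj, src_hap]
                    lin[s, h, pos:pos + length] = li
                    pos += length
    subjects = [f"MIX_{i:04d}" for i in range(n_subjects)]
    phased = vcfio.PhasedGenotypeMatrix(alleles=alleles, loci=reference.loci.copy(),
                                        subjects=subjects)
    panel = pd.Series(["MIX"] * n_subjects, index=subjects, name="population")
    return SimulatedCohort(phased, panel, AncestryTruth(lin, labels), None)


def _three_pop(order: str, **overrides) -> DemographicScenario:
    if order == "sequential":
        events = (
            FoundingEvent(5, "POP2", (("POP1", 1.0),), 20, 200),
            FoundingEvent(10, "POP3", (("POP2", 1.0),), 20, 200),
        )
    else:
        events = (
            FoundingEvent(5, "POP2", (("POP1", 1.0),), 20, 200),
            FoundingEvent(5, "POP3", (("POP1", 1.0),), 20, 200),
        )
    base = dict(n_loci=10_000, chromosomes=(("1", 10_000),), generations=20,
                events=events, ancestral="POP1")
    base.update(overrides)
    return DemographicScenario(**base)


def _five_pop(**overrides) -> DemographicScenario:
    # Bottleneck severities are ordered by wave (deepest first), and each new
    # population reaches carrying capacity before the next wave founds from
    # it, so the three divergence axes have well-separated drift magnitudes:
    # AFR|rest >> EUR|EAS >> SAS|AMR, the structure the model is meant to
    # exhibit on PCs 1-3.  Capacities are large relative to the per-population
    # sample so within-population kinship stays weak, and the genome is split
    # into 10 recombining chromosomes so founder-haplotype linkage blocks are
    # fine-grained (a single weakly-recombining chromosome leaves so few
    # independent founder segments that within-population mosaic variation
    # competes with the between-population axes).
    cap = 600
    events = (
        FoundingEvent(1, "EUA", (("AFR", 1.0),), 4, cap),
        FoundingEvent(8, "EUR", (("EUA", 1.0),), 6, cap),
        FoundingEvent(8, "EAS", (("EUA", 1.0),), 6, cap),
        FoundingEvent(13, "SAS", (("EUR", 0.6), ("EAS", 0.4)), 50, cap),
        FoundingEvent(13, "AMR", (("EUR", 0.4), ("EAS", 0.6)), 50, cap),
    )
    base = dict(n_loci=10_000,
                chromosomes=tuple((str(i + 1), 1_000) for i in range(10)),
                generations=20, events=events, ancestral="AFR",
                founder_size_default=20, capacity_default=cap,
                sample_per_pop=150,
                sampled=("AFR", "EUR", "EAS", "SAS", "AMR"))
    base.update(overrides)
    return DemographicScenario(**base)


PRESETS = {
    "sequential-3": lambda **kw: _three_pop("sequential", **kw),
    "parallel-3": lambda **kw: _three_pop("parallel", **kw),
    "five-population": _five_pop,
}


def preset_scenario(name: str, seed: int = 0, **overrides) -> DemographicScenario:
    """Named preset scenarios (``sequential-3``, ``parallel-3``,
    ``five-population``), 20 generations, 10,000 loci by default."""
    if name not in PRESETS:
        raise InvalidScenarioError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name](seed=seed, **overrides)


def load_scenario(path) -> DemographicScenario:
    """Read a scenario from a YAML file whose keys mirror DemographicScenario."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    events = tuple(
        FoundingEvent(
            generation=e["generation"], new_population=e["new_population"],
            parents=tuple((p, float(w)) for p, w in e["parents"]),
            founder_size=e["founder_size"], capacity=e["capacity"],
        )
        for e in cfg.pop("events", [])
    )
    cfg["events"] = events
    cfg["chromosomes"] = tuple((str(n), int(c)) for n, c in cfg["chromosomes"])
    if "init_freq_law" in cfg:
        cfg["init_freq_law"] = tuple(cfg["init_freq_law"])
    return DemographicScenario(**cfg)
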