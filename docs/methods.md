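# Methods

## Model and identities

The package operates on a loci × subjects genotype matrix X with entries in
{0,1,2} (minor-allele counts; 0 denotes the cohort-major allele). Rows are
centered, X̃ = X − X̄, and the unscaled subject covariance C = X̃ᵀX̃ is
eigendecomposed CE = ΛE with eigenvalues sorted decreasingly. Writing the
SVD X̃ = UΣVᵀ gives V = E and ΣᵀΣ = Λ, hence two algebraically identical
projection routes — P = EΛ and P = X̃ᵀΓ with loadings Γ = UΣ = X̃V — which
the test suite verifies against a direct SVD to 1e-8. Because P_ik is a sum
over loci, it restricts to any locus subset (a *partial projection*); that
linearity is what the informative-locus selection, the local-ancestry
tracts, and the projection transfer all exploit.

Numerical conventions: eigenvector signs are fixed by making each vector's
largest-|entry| coordinate positive (so loadings, proxy weights, and
transferred projections share one orientation); eigenvalues below
1e-9 × λ_max are treated as null space and truncated; the covariance can be
accumulated in locus blocks so the full matrix need not be resident.
Missing genotypes are imputed to the locus mean over called subjects, which
makes them contribute exactly zero after centering; a locus is only
retained at all if more than 90% of subjects are called. Major/minor
orientation is decided by cohort-wide allele counts with an exact tie kept
at REF-major.

## Necessary informative loci

For each PC, loci are ranked by loading (ties broken by chromosome and
position for determinism) and removed from the top and bottom of the
ranking in steps of max(1, n/1000) per side (*truncation*), or accumulated
from an empty set (*accretion*). The Pearson correlation between full and
truncated/accrued projections defines the two curves; a correlation of an
empty or constant projection is reported as 0 with an explicit degeneracy
flag rather than NaN. The *necessary* set of a PC is every locus removed up
to the last truncation stage whose correlation stays ≥ 0.9 (the threshold
is a parameter), unioned with all loci passing the allele-frequency
criterion: with the PC's reference populations ordered by their projections,
the per-population genotype means μ_l = Σ_g f_g·g must be monotone
(non-strict — equal adjacent means carry zero margin anyway), and for
two-population comparisons the one-SD intervals (μ±σ) must not overlap.
Degenerate (flagged) stages never terminate the threshold scan, so a
threshold near zero selects all loci with a warning, and a threshold near
one selects none.

Proxy projections replace SVD loadings by allele-frequency margins:
w_ik = sign(γ_ik)·min_l |μ^l − μ^{l+1}| when the means are monotone, else 0;
the proxy of a subject is the w-weighted sum of its centered genotypes over
the PC's informative loci. Rescaling all weights rescales the proxy without
changing its correlation with the full projections.

Gene scores are the maximum |loading| over loci inside a gene interval
(BED/GFF3 gene features, 0-based half-open); a gene is *all-informative*
when its score is in the top 25% of the ranked gene list on every PC.

## Patterns of genotype changes

At each locus, every population's genotype-class frequencies (f₀,f₁,f₂) are
quantized to a 3-bit vector marking the maximal class and any class within
δ = 0.2 of it (the margin-to-max rule is monotone, symmetric, and maps
(0.9, 0.1, 0.0) to (1,0,0)). The pattern at a locus is the assignment of
populations to vectors — equivalently the partition it induces — and
patterns are counted genome-wide and ranked. Counts are conserved (they sum
to the number of loci) and independent of population ordering.

## Hotspot scan

Chromosomes are tiled into 1 Mb windows (a locus at 1-based position p falls
in window ⌊(p−1)/1 Mb⌋; trailing partial windows are kept). The all-SNP
counts are smoothed by a hidden Markov model with Poisson emissions: 10 rate
states initialized at count quantiles, sticky transitions (self-transition
0.9, uniform off-diagonal), rates refined by up to 100 Baum–Welch iterations
at log-likelihood tolerance 1e-6; each window's background rate is the
posterior-weighted state rate. A single-state model collapses analytically
to the global mean (the Poisson MLE). The expected informative count in a
window is the background rate thinned by the PC's global informative
fraction, and the p-value is the exact Poisson upper tail P(X ≥ observed),
evaluated in log10 space so magnitudes like 1e-50 are representable. The
default call threshold is 1e-50 as in genome-scale data; desk-scale analyses
use a milder threshold (e.g. 1e-10). Adjacent significant windows merge
into hotspot intervals.

## Local-ancestry deconvolution

Training, per hierarchy decision and per PC: haplotype contributions are
γ_j·(2a_j − m_j), where a_j ∈ {0,1} is the haplotype allele and m_j the
training row mean — doubling puts haploid copies on the diploid scale, so a
haploid copy of a homozygote projects like its diploid source. A greedy
left-to-right scan grows a window of consecutive informative loci until
every pair of reference-group centroids differs by at least α = 3 pooled
within-group standard deviations of the haplotype partial projections
(computed from the exact per-haplotype window sums — per-locus moment sums
understate the SD because within-window contributions are correlated by
linkage). A trailing window that never separates merges into the previous
tract; a chromosome that never separates becomes a single low-confidence
tract whose classifications are reported unassigned. Tract bp boundaries
are midpoints between flanking informative loci, extended to the chromosome
ends.

Testing: a haplotype's tract projection is assigned to the nearest
reference centroid, scored by the margin to the second-nearest centroid in
pooled-SD units; tracts with more than half their loci missing, or an exact
tie, are unassigned (ties fall to the first-listed group under the relaxed
criterion). Aggregation intersects the per-PC segmentations of each
decision into refinement intervals: *relaxed* takes the strongest assigned
vote, *stringent* requires unanimity and otherwise leaves the interval
unassigned, so the relaxed criterion always assigns at least as much of the
genome. Decisions apply root-to-leaf — a child decision only refines
intervals carrying its parent's label, and where a child has no informative
loci the parent's label stands — producing hierarchical path labels such as
`nonAFR/EUR`. Per-subject ancestry proportions are bp-weighted over both
haplotypes and sum to one including the unassigned share.

## Projection transfer

Two cohorts are harmonized to the loci that match on chromosome, position,
and major/minor allele sequences (discordant definitions are dropped and
counted). Loadings are recomputed on the reference cohort restricted to the
harmonized loci — the transfer deliberately uses reference-derived
coefficients only — and each subject of the joint matrix (centered with
joint row means by default; reference means are an option) is projected by
the partial sum over each PC's informative loci. The approximation is
compared with a full joint PCA by greedy matching of PC pairs on |r|
(nearly degenerate eigenvalues can swap PC order between the two analyses);
signed correlations are reported separately for reference and external
subjects, and pairs under |r| = 0.2 are flagged unmatched. Transferring a
cohort onto itself over all loci reproduces the full projections to 1e-9.

## The demographic simulator

Diploid Wright–Fisher-style forward simulation: non-overlapping
generations; each offspring draws two distinct parents uniformly (pairs
with replacement across offspring, selfing forbidden) and receives one
recombinant gamete from each. Meiosis places Poisson(crossover rate)
crossovers per chromosome at uniform inter-locus boundaries — implemented
as per-boundary crossover parities combined by an XOR scan, with a fresh
fair start bit per chromosome so chromosomes assort independently; the
construction is exactly equivalent to the Poisson model and vectorizes over
offspring. There is no mutation, selection, or migration outside founding
events. Ancestral minor-allele frequencies default to Uniform(0.05, 0.95)
per locus, guaranteeing polymorphism with a spread of major/minor
frequencies. New populations are founded by sampling founders without
replacement from the parent population(s) — counts per parent follow the
mixing proportions under largest-remainder rounding (60/40 over 50 founders
gives exactly 30 and 20) — and grow by doubling each generation until a
carrying capacity. Founders are copied rather than removed from the parent:
generations are non-overlapping, so removal would only shrink the parent
for a single generation. The unit tests verify neutrality (zero expected
allele-frequency change), the Wright–Fisher drift variance p(1−p)/2N, and
the heterozygosity decay (1 − 1/2N)^t against the closed form.

Lineage truth: at every founding event each founder's whole genome is
relabeled with the parent population it was drawn from, and labels then
propagate through the same crossovers as the alleles. Label mass at the
founding generation therefore equals the per-parent founder share exactly,
and the final label matrix is exact tract-level truth for ancestry
benchmarks. `make_mosaic_subjects` provides sharper truth still: artificial
haplotypes concatenated from reference segments (geometric segment lengths,
configurable label mixture) with recorded breakpoints.

### The five-population preset

`five-population` emulates the continental-scale history the projections of
real data display: an ancestral AFR population (capacity 600); a severe
out-of-Africa bottleneck (EUA, 4 founders, generation 1); EUR and EAS split
from EUA (6 founders each, generation 8, after EUA has regrown); and two
admixed foundings at generation 13 — SAS from 60% EUR + 40% EAS and AMR
from 40% EUR + 60% EAS, 50 founders each; 20 generations in total; genome
of 10 chromosomes × 1,000 loci with Poisson(1) crossovers per chromosome;
150 subjects sampled per final population (EUA is ancestral-only and not
sampled). Two structural choices matter and were chosen so the model
exhibits the population structure it is meant to emulate:

- *Bottleneck severity is ordered by wave* (4 ≪ 6 ≪ 50 founders), and each
  population reaches carrying capacity before the next wave founds from it.
  The three divergence axes then have well-separated variances
  (AFR|rest ≫ EUR|EAS ≫ SAS|AMR), so they occupy PCs 1–3 distinctly
  rather than mixing.
- *The genome recombines across 10 chromosomes.* On a single
  weakly-recombining chromosome, every non-ancestral population is a mosaic
  of a handful of founder haplotypes, and that within-population block
  variation creates eigenvalues that compete with the between-population
  axes; 10 independently assorting chromosomes make the mosaics an order of
  magnitude finer. Likewise, carrying capacity is large relative to the
  150-subject sample so within-population kinship stays weak.

Under these conditions PC 1 separates the AFR analog with no range overlap,
PC 2 has EUR/EAS at its extremes, and PC 3 has SAS/AMR at its extremes in
9–10 of 10 seeds; the tracked EUR-lineage fraction among SAS subjects
averages ≈ 0.60 (founding value 0.60, between-replicate SD ≈ 0.07 from
post-founding drift), and the local-ancestry pipeline recovers an AMR EUR
proportion averaging ≈ 34–36% against the 40% founding share — the deficit
is the ≈ 9% of tract mass misassigned to AFR at the root decision plus a
few percent left unassigned, both consequences of the desk-scale locus
density (10⁴ loci versus the ~3×10⁷ of a sequencing cohort).

## What the synthetic data do and do not show

The simulator reproduces the mechanisms the analysis depends on — founder
drift, admixture with known proportions, recombination, exact lineage truth
— but not several features of real cohorts: no mutation or selection, no
LD structure inherited from a deep coalescent past, uniform recombination
and locus spacing, equilibrium-free 20-generation histories, and locus
densities four orders of magnitude below sequencing data. Passing tests
therefore demonstrate correctness and calibration of the algorithms under
known truth at desk scale, not their statistical performance on real
genomes; in particular, tract resolution and per-subject ancestry-proportion
accuracy improve sharply with locus density, and per-subject proportions at
desk scale can shift by several points when reference panels change, even
though population-level means are stable.

## Problem sizes

Defaults throughout are chosen for interactive work: simulated cohorts of
10,000 loci × 750 subjects, reference panels of 150 subjects per
population, 5 acceptance replicates, ~100-window hotspot scans, and
hypothesis-based property tests with bounded example counts. All of these
are parameters, not limits.
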