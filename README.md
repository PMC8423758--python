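# infoloci

Analysis of the **necessary informative loci** of multi-population genotype
data: the SNPs whose removal degrades the principal-component structure of a
cohort, as opposed to the small "sufficient" marker panels of classical
ancestry-informative-marker (AIM) studies. Necessary informative loci are
abundant and densely cover the genome, which makes them usable not only for
classifying subjects but for dissecting *how* populations split and mixed —
genome-wide patterns of genotype change, genomic hotspots of population
information, local-ancestry mosaics of admixed genomes, and the transfer of
population structure to external cohorts.

## What the package computes

For a biallelic genotype matrix **X** (loci × subjects, minor-allele counts
in {0,1,2}), rows are centered (X̃ = X − X̄) and the subject covariance
C = X̃ᵀX̃ is eigendecomposed, CE = ΛE. Writing the SVD X̃ = UΣVᵀ gives
V = E, ΣᵀΣ = Λ, and the per-locus **SVD loadings** Γ = UΣ = X̃V, so a
subject's projection on PC *k* is the loading-weighted allele sum
P_ik = Σ_j γ_jk X̃_ji — and any locus subset S defines a **partial
projection** Σ_{j∈S} γ_jk X̃_ji. On top of this identity the package builds:

- `pca` — centering, covariance eigendecomposition (blocked for large n),
  loadings, full and partial projections.
- `informative` — truncation/accretion correlation curves; selection of the
  necessary informative loci of each PC (top/bottom loading ranks whose
  removal keeps the truncated-vs-full projection correlation ≥ 0.9, plus an
  allele-frequency monotonicity criterion); proxy projections from
  allele-frequency margin weights; homozygote-fraction summaries;
  max-|loading| gene scores and "all-informative" gene calls.
- `patterns` — quantized per-population genotype-frequency vectors and
  genome-wide counts of the induced population partitions ("patterns of
  genotype changes").
- `hotspots` — 1 Mb window counts, a sticky Poisson-HMM background for the
  position-varying SNP density, and exact log-space Poisson tail p-values
  for windows enriched in informative loci.
- `ancestry` — local-ancestry deconvolution of phased genomes: chromosomes
  are partitioned into minimal tracts whose reference-panel haplotype
  partial projections separate every pair of reference groups by ≥ α pooled
  within-group SDs; test haplotypes are labeled by nearest centroid and
  labels are combined through a configurable population hierarchy (relaxed =
  strongest score, stringent = unanimity).
- `transfer` — locus harmonization between cohorts and approximation of
  joint-data projections from reference-derived loadings
  (P̃ᴶ_ik = Σ_{j∈I_k} γ_jk X̃ᴶ_ji), with greedy |r| PC matching.
- `demography` — a forward-time diploid simulator of population splits
  (small founder isolation) and two-parent admixed foundings with
  recombination, no mutation, and exact founding-lineage tract truth;
  presets `sequential-3`, `parallel-3`, and `five-population`
  (AFR → Eurasian → {EUR, EAS} → {SAS = 0.6·EUR+0.4·EAS,
  AMR = 0.4·EUR+0.6·EAS}, 20 generations, 10,000 loci).
- `vcfio` — phased-VCF ingestion (autosomal, biallelic, >90% called;
  cohort-major allele orientation), panel files, and all tabular outputs.

## Worked example

Simulate the five-population founder/admixture model, decompose it, and
select the necessary informative loci of PC 1:

```python
import numpy as np
from infoloci import demography, pca, vcfio, informative

cohort = demography.run_scenario(
    demography.preset_scenario("five-population", seed=1))
gm = vcfio.collapse_genotypes(cohort.phased)
cgm = pca.center_matrix(gm)
eig = pca.eigen_decompose(cgm)
loadings = pca.compute_loadings(cgm, eig)
proj = pca.project(cgm, eig, route="eigen")

pops = cohort.panel.to_numpy()
for name in ("AFR", "EUR", "EAS", "SAS", "AMR"):
    row = proj[pops == name, :3].mean(axis=0)
    print(f"{name}: PC1 {row[0]:9.0f}  PC2 {row[1]:9.0f}  PC3 {row[2]:9.0f}")

sel = informative.select_necessary(cgm, loadings, 0, threshold=0.9,
                                   loci=gm.loci)
part = pca.partial_projection(cgm, loadings, sel.indices, 0)
print(len(sel), "necessary loci,",
      f"r = {np.corrcoef(proj[:, 0], part)[0, 1]:.3f}")
```

Output:

```
AFR: PC1     19008  PC2     -2215  PC3       -14
EUR: PC1     -2031  PC2      9668  PC3      -335
EAS: PC1     -7303  PC2     -8227  PC3       187
SAS: PC1     -4013  PC2      2704  PC3      1107
AMR: PC1     -5661  PC2     -1930  PC3      -946
8240 necessary loci, r = 1.000
```

PC 1 isolates the African analog, PC 2 puts the European and East-Asian
analogs at opposite extremes with the admixed populations between them (SAS,
founded 60% EUR, sits on the EUR side; AMR, founded 40% EUR, on the EAS
side), and PC 3 contrasts the two admixed populations. 8,240 of 10,000 loci
are *necessary* for PC 1: removing them all still leaves the truncated
projections correlated at exactly the 0.9 threshold, and the selected set's
own partial projections reproduce the full ones almost perfectly.

A command-line pipeline covers the tabular stages:

```bash
infoloci simulate --preset five-population --seed 1 --out sim/
infoloci ingest --vcf sim/cohort.vcf --panel sim/panel.tsv --out mat/
infoloci pca --matrix mat/ --k 3 --out pcs/
infoloci select --matrix mat/ --pca-dir pcs/ --pc 1 --out pc1_loci.tsv
infoloci hotspots --loci mat/loci.tsv --informative pc1_loci.tsv \
    --pvalue 1e-10 --out hotspots.tsv
```

Local-ancestry deconvolution and projection transfer are driven through the
library (`infoloci.ancestry.train_reference` / `infer_tracts` /
`summarize_proportions`, and `infoloci.transfer`); see `docs/methods.md`.

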