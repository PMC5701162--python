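# Methods

This note records the models, conventions and design choices behind
`eruptpop`, in the order data flow through the pipeline.

## Data model

Genotypes are unphased diploid dosages (alternate-allele copy counts
0/1/2, `-1` missing) over biallelic SNPs identified by a target-region
label and a 1-based position. All windowing uses half-open intervals
`[start, end)` on these positions; this convention is set once in
`genio` and used everywhere. Missing data are handled per-site
complete-case by the statistics, never imputed by I/O. VCF v4.2 is the
interchange format (cyvcf2 for reading; multi-allelic and non-SNP records
are skipped with a logged count).

## Synthetic-data generator (`simgen`)

A forward, discrete-generation Wright–Fisher engine: per locus and deme the
allele count is resampled Binomial(2N<sub>g</sub>, p′) each generation,
with p′ the post-migration frequency under a symmetric island model and
N<sub>g</sub> the census size — constant at `ne_pre` until the event
generation, then instantaneously `floor(ne_pre·(1 − decline_fraction))`.
Forward simulation (rather than coalescent) keeps the survivorship event
explicit; the coalescent (msprime) appears only as an independent oracle in
tests. There is no selection, mutation, linkage or age structure; loci are
exchangeable and independent.

Founding minor-allele frequencies follow a neutral-SFS-shaped density
∝ 1/x truncated to [1/(2N<sub>e</sub>), 0.5] (a `uniform` option and fixed
frequencies exist for calibration tests). Sampling draws Hardy–Weinberg
genotypes from the deme frequency at the cohort's generation, except
full-sib pairs, which segregate from two simulated parents; sib pairs are
formed within shared burrows at rate `sibship_rate`. One integer seed
drives every draw; all outputs are byte-identical under a fixed
(preset, seed).

Preset parameters and why:

| parameter | speciesA (colonial) | speciesB (solitary) | basis |
|---|---|---|---|
| decline fraction | 0.40 | 0.25 | observed density declines of the two field populations |
| pre-event N (diploid) | 500 | 500 | not measured in the field; a plausible local effective size for these rodents, stated here as an assumption |
| generations post-event | 2 | 2 | samples collected within 1–2 generations of the event |
| demes / migration | 2 / 0.005 | 1 / 0 | second population 3 km away for the colonial species |
| cohorts | 17 pre (13 burrows), 31 post (9), 9 second-deme | 12 pre, 17 post | the study's sampling design |
| target SNPs | 531 | 449 | the final filtered panel sizes |
| sibship rate | 0.3 | 0 | group living vs one adult per burrow |

Pre-event cohorts are drawn at the last pre-event generation. Loci are
simulated in batches and sites monomorphic in the sample are re-drawn until
the target segregating count is met; SNPs are then scattered uniformly over
2,027 regions of 1,200 bp (≈1 SNP/region, so no LD pruning is needed
downstream). Monomorphic sites can be retained with `keep_monomorphic`
when studying the heterozygosity-denominator question.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: genotyping error and allele dropout, depth-driven
missingness (missingness is absent unless injected), linkage within
regions, mutation, overlapping generations, non-random mate choice, and
any form of selection.

## Site filters

**HWE:** exact conditional test (Levene/Haldane), two-sided by probability
mass — chosen over chi-square because cohort sizes are 12–31 individuals.
Computed per population, removing a site that fails in *any* population, so
Wahlund structure cannot mask genotyping error. Default α = 0.05
uncorrected (optional Bonferroni). Note the exact test is discrete and
conservative: null p-values are super-uniform (rejection rate ≤ nominal),
not uniform — the tests pin this validity property rather than uniformity.

**F<sub>ST</sub>-outlier scan:** a desk-scale analogue of the FDIST family.
Per-site (He, F<sub>ST</sub>) pairs are compared with `n_sims` neutral
sites simulated at the observed multi-locus F<sub>ST</sub>: ancestral
frequencies resampled from the observed pooled frequencies, deme
frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes drawn
HW at the observed sample sizes. Empirical upper-tail p-values are
assigned within 20 heterozygosity quantile bins and BH-controlled at the
given FDR (default 0.1, 50,000 simulations). Only the upper (directional)
tail is flagged; balancing selection is out of scope. The empirical p is
the plain fraction of simulated sites at or above the observed value —
p = 0 beyond the envelope — because a pseudo-count floor of 1/(n+1) would
sit above the rank-1 BH threshold at a ~500-site panel for any feasible
n_sims, leaving the scan unable to flag anything. Resolution is therefore
1/n<sub>bin</sub>, and FDR control under the null is verified by
simulation. The F<sub>ST</sub> inside the scan is the same Weir–Cockerham
estimator used everywhere else.

## Diversity statistics

Heterozygosity has an explicit denominator mode: `snp_sites` (per
individual, heterozygous calls over that individual's non-missing SNP
genotypes) and `all_callable_sites` (over a stated callable length in bp,
giving per-base values ~100× smaller with a ~2.4 Mb target). Both are
reported by the pipeline when a callable length is supplied, because
published per-base values cannot be reconstructed from a SNP panel alone.

Per-site π uses the unbiased pairwise form c(n−c)/C(n,2) on the non-missing
allele count n; per-site θ<sub>W</sub> is S<sub>site</sub>/a<sub>n−1</sub>.
Tajima's D per window uses the 1989 constants with n set to the minimum
non-missing allele count across the window's sites; windows without a
segregating site (or with zero variance estimate) are undefined and
omitted. Window step defaults to the window size (tiling); a step flag
gives overlapping windows.

Folded SFS: each of `reps` (default 20) iterations draws an equalised
subsample of individuals without replacement, folds to minor-allele counts
(ties at n/2 counted once in the top class) and tabulates; classes are
averaged across iterations, and the per-iteration table is kept for
dispersion and tests. Sites with fewer than half the expected alleles
called still contribute via their observed minor count.

Inbreeding F is the method-of-moments excess homozygosity
(O<sub>hom</sub> − E<sub>hom</sub>)/(L − E<sub>hom</sub>) with the
small-sample factor 2n/(2n−1) in E<sub>hom</sub>, frequencies estimated
from all samples.

Private/shared alleles: presence of each allele (ref and alt) per
population within equalised subsamples; private = present in exactly one
population, shared = in exactly two of three. The reported uncertainty is
the SD across iterations (presented as the SE of the resampling design).

## Structure

Weir–Cockerham variance components a/b/c per site, combined as
Σa/Σ(a+b+c); negative multi-locus values are meaningful (no differentiation)
and preserved. A Hudson ratio-of-sums estimator is included as a
cross-check only. PCA: Patterson normalisation, missing dosages mean-imputed
after centring, eigendecomposition of the individual covariance; axis signs
fixed by making the largest-magnitude loading positive. Admixture: plain
EM on the binomial mixture likelihood, 10 random starts by default, best
kept; the trace is monotone and Q rows stay on the simplex. On weakly
structured data the surface is nearly flat and the iteration cap can be
reached before the `tol` criterion — the fit is returned with
`converged=False` and is typically already stable. No acceleration is used:
at ~500 sites × ~60 individuals transparency beats speed.

## Resampling and tests

Schemes: individuals (without replacement), loci (without replacement up
to the panel, with replacement — warned — beyond it, since designs may ask
for more loci than the panel holds; both interpretations of "subsample
10,000 loci from ~500" are thereby supported), one-per-burrow, and
within-sex. Sample order is canonicalised before drawing, so results are
invariant to input row permutation; each iteration re-seeds from
(seed, iteration), so any single iteration is reproducible alone. An
iteration on which a statistic is undefined is redrawn a bounded number of
times. The loci/SD curve uses the grid 50..1000 by 50 then 1500..10000 by
500, 100 iterations per point.

KS: scipy's two-sample test, exact method when min(n,m) ≤ 10, asymptotic
otherwise. The pre/post comparison feeds per-site heterozygosity
distributions by default (configurable to bootstrap replicate values); KS
on lattice-valued data is only well calibrated for equal-size samples, and
the type-I test uses equal splits accordingly. Welch t with Satterthwaite
df; zero variance in both samples is undefined and flagged.

## Demographic signals

Pairwise difference = L1 distance between dosage vectors over co-called
sites (allele-copy differences; an IBS-mismatch alternative is available
and the metric is always recorded). Raggedness convention, pinned by
tests: classes made contiguous 0..K, one zero class appended, r =
Σ<sub>i=1..K+1</sub>(x<sub>i</sub> − x<sub>i−1</sub>)²; a point mass in an
interior class gives r = 2 (rise and fall both counted). Published
raggedness values from other software may use different boundary handling;
this repo's convention is self-consistent, not claimed identical.
The centred/re-scaled comparison standardises the per-pair values (not the
binned frequencies) before the KS test, and rounds the standardised values
to 9 decimals so float noise cannot split integer tie groups; location and
scale shifts therefore do not register, shape changes do.

The survivorship simulation draws ⌊fraction·N⌋ survivors uniformly, 100×,
and reports the survivor mean ± SD next to the full-sample value with a
Welch t of full-sample per-individual heterozygosities against the
replicate means (the unit of that t test is a package convention; the
mean ± SD band is the primary output). Random survivorship preserves
expected heterozygosity exactly; contrast runs that simulate forward at the
reduced size do lose heterozygosity, separating "who died" from "drift
afterwards".

## Pipeline

`run_compare` executes filter → stats → structure → resample → demography
and writes a single `report.json` (sorted keys) plus the filtered VCF,
PCA/Q TSVs and optional loci-curve TSVs. Defaults: 100 resampling
iterations, 20 SFS iterations, 50,000 outlier simulations at FDR 0.1,
100-bp windows, K ∈ {2, 3}, survivor fraction 0.5. All KS/t p-values are
reported raw and BH-adjusted. The output directory is excluded from the
report payload so one configuration written to two places is byte-identical.

## Problem sizes in the test and acceptance runs

Estimator unbiasedness uses 100 neutral coalescent loci (~2,000 segregating
sites, 10 diploids); Tajima's D calibration 50 loci; bottleneck recovery 20
runs at Ne=50, 50% decline, 5 post-event generations, 531 loci; outlier
null control 20 × 300 sites at 2,000 simulations per scan; the loci/SD
scaling a 50,000-site simulated panel so the full default grid stays in the
without-replacement regime. These sizes give Monte-Carlo error comfortably
inside the asserted 3-SE bands while keeping the default suite fast.

## Known limitations

No genotype likelihoods (hard-called genotypes in, garbage in → garbage
out at low depth); no haplotype or LD-aware statistics; the outlier scan's
island-model envelope is an approximation, appropriate for flagging gross
directional outliers rather than fine-mapping selection; mismatch
distributions on ~500-SNP diploid panels are shallow (small pairwise
counts), so raggedness comparisons between cohorts are more informative
than absolute values; Bayesian migration-model comparison is out of scope.
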