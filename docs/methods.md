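# Methods

This note records the statistical models implemented in `finesgs`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Genotype model and filtering

Genotypes are biallelic SNP dosages (0/1/2 alternate alleles) with a
single missing sentinel; half-called diploid genotypes are treated as
missing.  Site-level hard filtering uses the usual GATK annotations with
the thresholds FS ≤ 60, HaplotypeScore ≤ 13.0, MQ ≥ 40, QD ≥ 2,
ReadPosRankSum ≥ −8.0 and MQRankSum > −12.5 (the MQRankSum bound is
deliberately strict: a site at exactly −12.5 is removed).  The MAF filter
is likewise strict — a locus at minor-allele frequency exactly 0.05 is
dropped — and frequencies are always computed over the non-missing calls
of the analysis group at hand.  Both filters are idempotent.

Age classes follow the DBH rule used for long-lived trees: sapling
(DBH < 7.5 cm), adult (7.5 ≤ DBH < 22.5 cm), mature (DBH ≥ 22.5 cm).

## Diversity

Per locus, over a group's non-missing calls: H_O is the heterozygote
fraction; H_E is Nei's unbiased expectation `2n/(2n−1) · (1 − p² − q²)`
(n = genotyped individuals); F_is,l = 1 − H_O/H_E where H_E > 0.  Group
values are unweighted means over loci polymorphic *within the group*;
`num_indv` is the mean number of genotyped individuals per locus.  The
H_O-vs-H_E comparison across patches is a pooled-variance two-sample
t-test (df = n₁ + n₂ − 2); with three patches per population df = 4,
matching the published worked examples to their printed precision.  The
choice of per-locus averaging set can shift group F_is appreciably, which
is why only H_O/H_E/t are treated as reproducible surfaces.

## Kinship and SGS

Pairwise kinship is the Loiselle et al. (1995) estimator.  For a
biallelic locus with reference-group frequency p and individual allele
frequencies x = dosage/2:

    F_ij,l = (x_i − p)(x_j − p) / (p(1−p)) + 1/(n_genes − 1),

with `n_genes` the gene copies sampled at the locus (2 × genotyped
individuals).  The bias term's denominator counts gene copies, not
individuals: with frequencies estimated from the sample the cross-product
averages −1/(2(n−1)) over unrelated pairs, and only the gene-copy form
re-centres the estimator at zero — verified in the tests against a
brute-force transcription and against Hardy–Weinberg simulations.
Multilocus kinship averages loci weighted by p(1−p) over the loci
genotyped in both members.

The SGS profile bins pairs into distance classes — by default ten
equal-pair-count classes (quantile edges, half-open lower-closed
intervals, last edge inclusive), fully overridable with explicit edges —
and reports per-class mean kinship.  The slope b_F regresses *pairwise*
kinship on ln(pairwise distance) (all usable pairs, not class means;
zero-distance pairs are excluded and counted), and

    Sp = −b_F / (1 − F_(1)),

with F_(1) the first-class mean.  Reported Sp always equals this identity
applied to the same result object.  The slope's standard error is a
leave-one-locus-out jackknife.  Significance uses 999 permutations (99
minimum) of spatial locations among individuals — kinship fixed,
positions shuffled — giving a 2.5/97.5% envelope per class and for b_F.
Permutations act on an id-sorted canonical labelling, so a fixed seed
yields the same envelope whatever the row order of the input.  Each
stratum (population, age class, patch; minimum 10 individuals) is
analysed with its own internal allele frequencies.

## Spatial autocorrelation

The multilocus codominant autocorrelation of Smouse & Peakall (1999):
squared genotypic distance per pair is the dosage difference squared
summed over loci (pairs with missing data use shared loci rescaled by
L/L_shared); the distance matrix is double-centred (Gower) into a
covariance matrix C, and per class h

    r(h) = Σ_{(i,j)∈h} 2 c_ij / Σ_{(i,j)∈h} (c_ii + c_jj),

bounded in [−1, 1] for PSD C (clipped otherwise, which can only arise
through missing-data rescaling).  Under the null of spatially random
genotypes the expectation of r is −1/(n−1), not zero, so calibration is
assessed as coverage of the observed r by the permutation envelope
(~95% on null simulations) rather than containment of zero.  Per-class
standard errors bootstrap pairs within the class.  The correlogram
x-intercept is located by linear interpolation between class midpoints
(midpoint = arithmetic centre of the class edges); a correlogram that
starts non-positive reports the first midpoint flagged "immediate", and
one that never crosses reports no intercept.

## Parentage

Trio LOD per offspring/candidate-pair, summed over loci genotyped in all
three members:

    LOD = Σ_l ln[ P(g_o | g_p1, g_p2, ε) / P_HWE(g_o) ],

where the numerator is `(1−e)·M + e·P_HWE` with `e = 1 − (1−ε)²` (the
observed genotype is the transmitted one when both allele reads are
correct, otherwise a random Hardy–Weinberg genotype) and M the Mendelian
transmission probability.  A Mendelian-impossible trio at ε = 0
contributes a −10⁶ sentinel instead of −∞.  Candidate pairs are
enumerated exhaustively and unordered, selfed pairs included; ties go to
the lexicographically first pair and are flagged.

The critical Δ (LOD gap between best and runner-up) is calibrated by
simulation: offspring of random candidate pairs, each true parent
independently "sampled" with probability 0.9 (an unsampled parent is
replaced by a Hardy–Weinberg genotype), assigned against the candidate
set; the critical Δ is the smallest threshold at which the fraction of
correct assignments among those exceeding it reaches the confidence
level (0.80 default).  An assignment is confident when its Δ reaches the
threshold *and* its Mendelian mismatch fraction stays within tolerance
(0.01 of shared loci).

Converting assignments to dispersal events requires deciding which
parent is the mother of a hermaphroditic tree: the parent *nearer* the
offspring is taken as maternal (gravity-dispersed seeds travel less than
pollen on average).  This is an assumption, flagged in the output; seed
distance is offspring→mother, pollen distance mother→father, zero for
selfed pairs.  Unassigned or non-confident offspring are excluded from
dispersal summaries.

## Dispersal summaries

Direct: per patch, mean and maximum seed and pollen distance, combined
into the effective gene-dispersal distance σ_g = √(σ_s² + σ_p²/2) — the
axial variance decomposition in which pollen movement carries a haploid
genome.  Population rows are unweighted arithmetic means of the patch
values (including for σ_g: the mean of patch σ_g values, not the formula
applied to mean inputs).

Indirect: the correlogram is fitted with a cubic in ln distance,
F(r) = a + b ln r + c ln²r + d ln³r (least squares on class values, ≥ 4
finite classes required; exact on noise-free cubics).  Real roots inside
[first midpoint, last midpoint] are mapped back to metres.  The curvature
statistic is emitted in two labelled forms — the conventional printed
K = 2c + 6 ln(r₁) and the second-derivative form K = 2c + 6d ln(r₁)
(r₁ = first-class midpoint) — because the printed form omits the cubic
coefficient; neither is used downstream.  The indirect dispersal interval
is bounded by the interpolated x-intercept and the first cubic root;
when only one exists the interval collapses with a flag, and when
neither does the patch is labelled spatially random.

## The simulator

The forward simulator generates the sampling universe the estimators
assume: rectangular patches (default three, 200 × 200 m, 1 km apart —
patches of a single population), founders uniform within patches with
Hardy–Weinberg genotypes from per-locus founder frequencies (uniform on
[0.05, 0.5]), non-overlapping generations in which mothers are drawn
uniformly from all previously created individuals, fathers are the
mother with probability `selfing_rate` (0.1 default — a plausible
placeholder for a predominantly outcrossing tree, not an inference)
or otherwise drawn with isotropic bivariate-Gaussian pollen-kernel
weights, and offspring are displaced from the mother by an isotropic
bivariate Gaussian, resampled until inside the mother's patch.  Defaults
σ_seed = 25 m and σ_pollen = 35 m give realized mean distances
(σ·√(π/2) ≈ 31 and 44 m) in the range of the restricted patches of the
study system; 36 founders + 2 generations × 36 offspring ≈ 108 trees and
200 loci keep every stage well-conditioned while staying fast.  The
observation layer flips each allele independently with probability
0.01 and masks calls with probability 0.05, for founders and offspring
alike.  Age classes follow generation (founders mature, intermediate
adult, last sapling) with DBH synthesized per class so the DBH rule
round-trips.

Because displacements are resampled at patch edges, realized kernels are
slightly truncated for edge mothers; kernel-recovery checks therefore use
patches large relative to σ.  The simulator does *not* emulate
overlapping generations, demographic change, anisotropy or wind fields,
linkage (loci are unlinked), null alleles, or locus-specific error rates
— so passing recovery tests demonstrates correctness of the estimators
under the stated model, not robustness to those real-data features.

## Problem sizes and determinism

Test and example runs use tens of founders, one or two generations,
100–200 loci and 49–199 permutations — sizes chosen so each stage is
well-identified yet the whole suite runs in seconds; production runs
simply raise the counts (999 permutations being the conventional
envelope resolution).  One global pipeline seed derives per-stage seeds
by hashing the stage name, so a rerun with the same configuration and
seed is byte-identical, including table provenance headers (package
version, seed, configuration hash; no timestamps).

## Known limitations

- Group F_is depends on the per-locus averaging set; it is reported but
  not treated as a reproducible surface.
- The mother/father disambiguation by proximity mislabels pairs whenever
  pollen happened to travel less than the seed; seed/pollen distance
  summaries inherit that noise even when the pair itself is correct.
- The autocorrelation handles missing data by rescaling shared-locus
  distances, which can break positive semi-definiteness slightly at high
  missingness (values are clipped into [−1, 1] when it does).
- Distance-class edges are estimated from the observed distances;
  published significant-SGS intervals depend on unstated class edges and
  are therefore not comparison surfaces.
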