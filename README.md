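# finesgs

Fine-scale spatial genetic structure (FSGS) and gene-flow analysis for
georeferenced SNP data.

`finesgs` is aimed at population geneticists and conservation biologists
studying how restricted seed and pollen movement shapes the spatial
arrangement of genotypes inside natural plant populations — the classic
setting of a relict tree sampled in a handful of patches, each tree with
GPS coordinates, a diameter at breast height (DBH), and a few hundred
biallelic SNPs in a VCF.  It provides, as one pipeline or as individual
scikit-learn-style estimators:

- **SNP input and filtering** — biallelic-SNP VCF reading (cyvcf2),
  GATK-style hard filters (FS ≤ 60, HaplotypeScore ≤ 13, MQ ≥ 40,
  QD ≥ 2, ReadPosRankSum ≥ −8, MQRankSum > −12.5) and a strict
  MAF > 0.05 cut-off.
- **Diversity** — per-patch and per-population H<sub>O</sub>, unbiased
  H<sub>E</sub>, F<sub>is</sub>, plus the pooled-variance t-test of
  H<sub>O</sub> vs H<sub>E</sub> across patches.
- **Kinship SGS** — pairwise Loiselle kinship F<sub>ij</sub>, the
  regression slope *b<sub>F</sub>* of kinship on ln(distance), the mean
  first-class kinship F<sub>(1)</sub>, and the SGS intensity

  &nbsp;&nbsp;&nbsp;&nbsp;*Sp* = −*b<sub>F</sub>* / (1 − F<sub>(1)</sub>),

  with 999-permutation envelopes and a jackknife-over-loci standard
  error, at population, age-class and patch levels.
- **Spatial autocorrelation** — the multilocus codominant
  autocorrelation coefficient *r* per distance class (Smouse–Peakall),
  permutation envelopes, bootstrap errors, and the correlogram
  x-intercept read as the effective gene-dispersal extent.
- **Parentage** — trio LOD scores with a genotyping-error kernel,
  simulated critical-Δ confidence thresholds (candidate proportion 0.9,
  error 0.01, 80% confidence by default), and conversion of confident
  assignments into seed and pollen dispersal distances.
- **Dispersal** — per-patch direct summaries with the effective
  gene-dispersal distance σ<sub>g</sub> = √(σ<sub>s</sub>² + σ<sub>p</sub>²/2),
  and indirect estimation via the cubic fit
  F(r) = a + b ln r + c ln²r + d ln³r whose in-range roots bound the
  dispersal interval.
- **A spatially explicit forward simulator** — patchy populations with
  bivariate-Gaussian seed and pollen kernels, partial selfing, three
  DBH age classes, genotyping error and missingness, and full pedigree
  truth, so every estimator is validated by parameter recovery.

## Worked example

Simulate one population of three patches (108 trees, 200 SNPs) and run
the full pipeline:

```sh
finesgs simulate --out demo/data --seed 11
# wrote 108 individuals x 200 loci
```

```python
from finesgs import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    vcf="demo/data/genotypes.vcf",
    metadata="demo/data/metadata.tsv",
    out_dir="demo/out",
    seed=42,
    n_permutations=199,
    n_bootstraps=199,
    n_sim_offspring=500,
)
written = run_pipeline(cfg)
print(open(written["sgs_population"]).read())
```

```
# finesgs 0.1.0 seed=42 config=29e199507c22
stratum  bF                    F1                   Sp                    se_bF                 bf_significant  n_pairs
SIM      -0.02110871819895917  0.09155577409612344  0.023236119067140956  0.001453510487225651  True            5778
```

With the default restricted kernels (σ<sub>seed</sub> = 25 m,
σ<sub>pollen</sub> = 35 m inside ~200 m patches) the population shows
strong SGS: kinship declines with ln(distance) at slope
*b<sub>F</sub>* ≈ −0.021 (outside the 95% permutation envelope), mean
first-class kinship F<sub>(1)</sub> ≈ 0.092, and *Sp* ≈ 0.023 — the
range reported for strongly structured tree populations.  The direct
gene-flow table from the same run:

```
population  patch  seed_max  seed_mean  pollen_max  pollen_mean  gene_effective
SIM         P1     35.3      24.56      36.72       24.1         29.9
SIM         P2     35.72     35.72      38.92       38.92        45.09
SIM         P3     36.17     22.16      84.15       46.37        39.58
SIM         means            27.48                  36.47        38.19
```

`gene_effective` combines each patch's mean seed and pollen distances as
√(24.56² + 24.1²/2) ≈ 29.9 m, and the `means` row averages the patch
values.  Per-patch correlogram x-intercepts (≈ 57–68 m here) land in
`autocorr_intercepts.tsv`, and the indirect dispersal interval combining
the intercept with the first cubic-fit root in `dispersal_indirect.tsv`.

The same stages are available as estimators
(`SGSAnalysis`, `SpatialAutocorrelation`, `TrioParentage`,
`DispersalCurve`, `LoiselleKinship`) with scikit-learn `fit`/`predict`
semantics and `get_params`/`set_params`, and as CLI subcommands
(`finesgs simulate | diversity | sgs | autocorr | run`).

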