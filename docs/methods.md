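# Methods

This note documents the models, numerical choices and defaults behind
`domqtl`, and what the synthetic-data generator does and does not
emulate.

## Haplotype-dosage mixed-model scan

The trait model at marker $m$ is
$y = Xc + P_m\beta + g + \varepsilon$ with $g \sim N(0,\sigma_g^2 K)$,
$\varepsilon \sim N(0,\sigma_e^2 I)$. $P_m$ holds the eight
founder-dosage probabilities; because its columns sum to one, the marker
model drops the explicit intercept (the founders span it) while the null
model keeps it. Fitting proceeds in the eigenbasis of $K$: with
$K = U\,\mathrm{diag}(\lambda)\,U^\top$ and
$h^2 = \sigma_g^2/(\sigma_g^2+\sigma_e^2)$, rotated observations have
diagonal covariance $w_i = h^2\lambda_i + (1-h^2)$ and every fit is a
weighted least squares.

- **Null heritability.** $h^2$ is estimated by REML under the
  covariates-only model: a 101-point grid on $[0, 0.99]$ followed by
  bounded scalar refinement (tolerance $10^{-6}$). It is estimated once
  per (trait, LOCO chromosome) and held fixed across that chromosome's
  markers (the EMMAX-style approximation standard for this design);
  per-marker re-estimation is deliberately not done — the LOD then
  compares weighted RSS at fixed variance ratio, which is the standard
  likelihood-ratio reading. If the kinship is numerically the identity
  the variance split is unidentifiable; the fit returns $h^2 = 0$ with a
  flag.
- **LOD.** $\mathrm{LOD}_m = \tfrac{n}{2}\log_{10}(\mathrm{RSS}_0 /
  \mathrm{RSS}_m)$, clipped at 0 (the marker model nests the null, so
  negative values are pure round-off). $n$ counts the individuals used
  for that trait.
- **Kinship.** $K[i,j] = \tfrac1M \sum_m \sum_f p_{imf}\,p_{jmf}$,
  rescaled so the mean diagonal is 1. LOCO matrices exclude the scanned
  chromosome's markers and require at least two chromosomes;
  eigendecompositions are cached per chromosome because every trait
  scanned against the same genotypes reuses them.
- **Missing data.** Individuals missing the trait are dropped for that
  trait only (kinship rows/columns subset accordingly); covariate rows
  must be complete or the run errors, naming the problem. Rank-deficient
  covariate designs error with the collinear column names. Collinear
  *founder* columns at a marker (common with one-hot probabilities when a
  founder is absent locally) are absorbed by the minimum-norm
  least-squares solution — the RSS, and hence the LOD, is unaffected and
  the scan never fails.

## Permutation thresholds

Trait values are shuffled against genotypes and covariates; each
permutation records the genome-wide maximum LOD, and the threshold at
level $\alpha$ is the $\lfloor\alpha N\rfloor + 1$-th largest maximum
(for $N = 1000$, $\alpha = 0.05$: the 51st). The null $h^2$ is re-fitted
within each permutation by default (`refit_h2=False` reuses the
unpermuted fit). The shuffle ignores relatedness structure — a known
approximation of the simple permutation scheme; the calibration test
verifies the resulting per-trait genome-wide type-I error empirically. A
study-wide threshold aggregating permutations across thousands of
phenotypes is out of scope; only per-trait genome-wide thresholds are
computed.

## Peaks, support intervals, allele effects, SNPs

- **Peaks.** One peak per chromosome per trait: the marker of maximum
  LOD if it clears the threshold, ties broken to the lower position. No
  multi-peak splitting.
- **Bayesian support interval.** Posterior mass
  $p_m \propto 10^{\mathrm{LOD}_m}$ over the chromosome's markers
  (computed after subtracting the maximum, so no overflow); the interval
  runs from the position at cumulative $(1-c)/2$ to cumulative
  $1-(1-c)/2$ at coverage $c = 0.95$. If no maximum-LOD marker falls
  inside, the interval is expanded to include the first one; with a flat
  curve the unexpanded central interval stands (a single spike collapses
  the interval onto itself; a single-marker chromosome returns that
  marker).
- **BLUP founder effects.** At a peak the founder effect is modelled as
  random, $u \sim N(0, \sigma_u^2 I_8)$, on top of the null mixed model.
  Data are whitened by the null fit, the variance ratio
  $\lambda = \sigma_u^2/\sigma_e^2$ is estimated by maximum likelihood
  (grid on $\log_{10}\lambda \in [-6, 6]$ plus bounded refinement) and
  $\hat u = E[u \mid y]$ is returned — a ridge-shrunk GLS solution whose
  norm never exceeds the unshrunk ($\lambda \to \infty$) fixed-effect
  limit. An optimum at the lower edge returns a zero vector flagged
  `shrunk_to_null`. Founder order is fixed globally: A/J, B6, 129, NOD,
  NZO, CAST, PWK, WSB.
- **SNP association.** A biallelic SNP is described by its strain
  distribution pattern (SDP), an 8-bit founder-allele assignment; the
  dosage of individual $i$ is $\sum_f \mathrm{sdp}_f\, p_{if}$ at the
  marker nearest the SNP, tested with 1 degree of freedom against the
  same null fit. Complementary SDPs give identical LODs (affine
  equivalence); all-0/all-1 SDPs are skipped with a warning.

## Mediation

`lod_adj` is the outcome's LOD at its original peak marker with the
candidate mediator added as an additive covariate (rank-normalized like
any trait), computed on the subset of individuals where outcome,
covariates and mediator are all observed; the original LOD is recomputed
on the same subset so the drop is never an artifact of sample change. The
null $h^2$ is re-fitted with the mediator in the design. A full
chromosome re-scan under conditioning is available via `rescan=True`.

- **Sign and flag.** `drop = lod_adj − lod_orig`, so mediation is
  negative; candidates are flagged at $z \le -6$.
- **Standardization.** $z_i = (\mathrm{drop}_i - \mu_0)/\sigma_0$ with
  $\mu_0, \sigma_0$ the mean/sd of drops over the declared null candidate
  set (default: all candidates). A robust median/MAD option exists and is
  the *pipeline* default: with a small candidate set $k$, a genuine
  mediator inflates a mean/sd null enough to cap $|z|$ near
  $\sqrt{k-1}$, which would make the $-6$ flag unreachable for
  $k \lesssim 40$ however strong the mediation; the robust null is
  outlier-insensitive. With hundreds of candidates the two agree and the
  op-level default stays mean/sd.
- **Groups.** The group-level statistic is the group's mean drop
  standardized by the same null sd, deliberately without $\sqrt{n}$
  inflation (conservative; a flag enables it). Groups below 5 candidates
  are excluded and reported; unmapped candidates pool into `ungrouped`.
- **Defaults.** Minimum overlap 50 individuals; suggestive-outcome
  threshold LOD 6; all configurable.
- **Direction.** Conditioning is symmetric, so the bidirectional scan
  reports both directions over co-located peaks (same chromosome,
  default window 4 Mbp; self-pairs excluded) and asserts neither as
  causal.

## Integration statistics

- **Co-mapping**: all same-chromosome peak pairs within a window
  (default 4 Mbp, the scale at which loci are typically reported);
  symmetric in the two peak sets.
- **Allele-effect correlation**: Spearman on the two 8-vectors with the
  *exact* permutation p-value over all $8! = 40{,}320$ orderings
  (two-sided); Pearson with the t approximation as an alternative.
  Zero-variance vectors are an error.
- **Hotspots**: peaks with LOD ≥ 6 binned into fixed 1-Mbp windows;
  bins with ≥ `min_traits` peaks seed hotspots and adjacent qualifying
  bins merge, counting distinct traits once.
- **Enrichment**: two-sided Fisher exact tests on 2×2 tables built from
  a hit set, a many-to-many annotation and a background;
  Benjamini-Hochberg adjustment across the categories tested. BH here is
  monotone in p-order and satisfies $q \ge p$; it is not a functionally
  idempotent map.
- **Correlation tables**: Spearman over all A×B trait pairs on
  pairwise-complete observations, BH across the full table; constant
  columns yield flagged rows rather than errors.
- **Differential screen**: Welch's t per feature, BH across features,
  kept = fold-change > 10 and q < 0.05. Fold change uses a pseudocount of
  half the smallest positive value observed in either matrix, so
  zero-mean features are comparable. Features constant and equal in both
  groups get p = 1 by convention, flagged.

## Synthetic cohorts

The generator produces the study conditions the analysis stages are
validated under.

- **Map**: near-evenly spaced markers with sub-half-spacing jitter;
  density 0.5 cM/Mbp (mouse genome-average scale), so a 100-Mbp
  chromosome is 0.5 Morgan. Defaults: 20 chromosomes × 100 markers.
- **Mosaics**: breakpoints arrive as a Poisson process at
  `n_generations` per Morgan (default 20, DO-like block lengths); the
  founder after each breakpoint is drawn uniformly from the seven
  *other* founders, so every breakpoint is visible and the expected
  count per chromosome is exactly rate × length while occupancy stays
  exchangeable at 1/8.
- **Probabilities**: the true founder gets $1-s$, the rest share $s$
  uniformly (default softness $s = 0.02$, emulating reconstruction
  uncertainty). Rows sum to 1 to $10^{-12}$.
- **Covariates**: sex balanced to ±1, integer days-on-diet, cohort
  waves as dummy columns — mirroring the standard additive covariates of
  this design.
- **Traits**: each variance component (per-QTL genetic value
  $P\beta$ with centred $\beta$, a polygenic draw with covariance
  $\propto K$, i.i.d. noise) is standardized to its exact target
  fraction, so realized fractions match specs by construction and
  recovery tests are sharp. Abundance-like traits are exponentiated and
  zero-inflated; downstream mapping always rank-normalizes, so only the
  non-Gaussian margin matters. Truth records (snapped marker, scaled
  effects, fractions) are serialized next to the data.
- **Mediation triplets**: mediated mode sets $L = \alpha M +
  \varepsilon$; independent mode gives $L$ its own QTL at the same
  marker with effects drawn independently of $M$'s.
- **Default cohort**: 200 mice, 2,000 markers, 40 microbial + 20 lipid
  traits plus one planted mediated triplet (61 scans), 8 microbial
  traits carrying 20%-variance QTL on a 30% polygenic background.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic DO linkage disequilibrium and
pedigree structure (the mosaic process is Markovian with exchangeable
founders), compositional closure of abundance matrices (traits are
independent given genotype), batch/library-size artifacts, trait-specific
missingness patterns, X-chromosome inheritance, and any sequence-level
or spectral detail. Calibration results transfer to real cohorts only to
the extent these features do not dominate.

## Lipid mass bookkeeping

Di-acyl ornithine lipid formulas follow condensation bookkeeping:
ornithine C5H12N2O2 + 3-hydroxy acyl C$_n$H$_{2n-2d}$O3 + acyl
C$_m$H$_{2m-2d'}$O2 − 2 H2O; the result depends only on the sum
composition, not the chain split. Monoisotopic masses use an explicit
C/H/N/O table with electron and proton masses so the two protonation
conventions are first-class: `M+H_atom` (adds a neutral H atom) is the
default because it reproduces printed "calculated" values for the
synthetic standard; `M+H_proton` (one electron lighter) is the
physically correct [M+H]+ ion mass. The convention behind any given
printed value is rarely stated, which is why both are exposed.

## Pipeline

Stages run in a fixed order (simulate/load → prevalence filter →
rank-normal transform → kinship → scans → permutation thresholds → peaks
and BLUPs → mediation → integration), each writing stable filenames and
appending retained counts, wall time and output checksums to the
manifest. All randomness descends from the root seed through a fixed
`SeedSequence` spawn order, so reruns are bit-identical for deterministic
outputs; the manifest fingerprint hashes the deterministic content and
excludes wall times. The prevalence filter defaults (`min_value` 0.01 in
≥ 20% of samples) are scaled to the synthetic abundance units; for real
CPM matrices set the threshold in CPM (e.g. 10). With `n_perm = 0` the
thresholds stage is skipped with a notice and peak calling falls back to
the suggestive LOD (default 6); by default permutation thresholds are
computed for the first trait and shared (`threshold_traits: all` computes
per-trait thresholds at proportional cost). A stage failure aborts the
run with the stage name and persists the partial manifest. Exit codes: 0
ok, 2 config error, 3 data error.

## Problem sizes in the test suite

Study-scale checks use the sizes at which their claims are stated:
planted-QTL recovery and BLUP accuracy at n = 200 on 20 × 100 markers
over 50 replicates; permutation calibration with 300 permutations and
200 null traits (n = 200, 10 × 50 markers); mediation sensitivity with
999 noise candidates + 1 true mediator over 50 replicates and
specificity over 20 independent-mode replicates (5 × 50 markers);
interval coverage over 200 simulations. Replicates share genotype sets
in small batches where the claim is conditional on genotype (threshold
calibration) or averages over traits (coverage, recovery) — statistically
valid and considerably cheaper than regenerating genotypes per replicate.

## Known limitations

No X-chromosome special handling, no interactive covariates or QTL×sex
scans, no multi-QTL model selection, no kinship-aware permutations, no
haplotype reconstruction from SNP genotypes (probabilities are consumed
or simulated directly), and no formal causal-inference machinery — the
mediation scan ranks conditioning effects and deliberately does not
assert direction.
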