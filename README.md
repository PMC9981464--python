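# domqtl

Multi-omics QTL mapping for Diversity Outbred (DO) mice: linear-mixed-model
haplotype genome scans with leave-one-chromosome-out (LOCO) kinship,
permutation significance thresholds, Bayesian QTL support intervals, BLUP
founder allele effects, SNP association via strain distribution patterns,
LOD-drop mediation analysis, and cross-dataset integration statistics —
plus a synthetic DO cohort simulator so every stage is testable without
external data.

## Who this is for

Systems-genetics analyses in multiparent mouse populations relate
quantitative traits — microbial taxon/gene-family abundances, lipid
feature intensities, transcript levels — to host genetic loci. Each DO
genome is a mosaic of eight founder haplotypes (A/J, B6, 129, NOD, NZO,
CAST, PWK, WSB), so a locus is tested through the eight founder-dosage
probabilities at each marker rather than a single SNP. `domqtl` packages
that workflow as an importable Python library (with a thin `domqtl` CLI
for pipeline runs) for method development, teaching and power studies on
simulated cohorts, and for analysing real dosage-probability exports in
the same formats.

## The model

For a rank-normalized trait $y$ with covariates $X$ (sex, days on diet,
cohort wave), the scan fits at every marker $m$

$$y = X c + P_m \beta + g + \varepsilon,\qquad
  g \sim N(0, \sigma_g^2 K_{-c}),\ \varepsilon \sim N(0, \sigma_e^2 I),$$

where $P_m$ is the $n \times 8$ founder-dosage matrix and $K_{-c}$ the
kinship computed from all chromosomes except the scanned one. The null
heritability $h^2 = \sigma_g^2/(\sigma_g^2+\sigma_e^2)$ is estimated once
per (trait, chromosome) by REML and held fixed across markers; the
statistic is the LOD score
$\mathrm{LOD}_m = \tfrac{n}{2}\log_{10}(\mathrm{RSS}_0/\mathrm{RSS}_m)$.
Genome-wide thresholds come from phenotype permutations (threshold at
$\alpha$ = the $\lfloor\alpha N\rfloor{+}1$-th largest of $N$ max-LODs);
support intervals are 95% Bayesian credible intervals over
$p_m \propto 10^{\mathrm{LOD}_m}$; founder effects at a peak are BLUPs of
a random 8-level founder effect. Mediation adds a candidate trait as a
covariate and standardizes the LOD drop at the peak against a null
candidate set; $z \le -6$ flags potential mediators.

## Worked example

`examples/02_genome_scan.py` simulates 200 mice on a 5-chromosome map,
plants a QTL at chr3: 50 Mbp explaining 30% of variance (A/J allele up,
NZO and WSB down) and scans it:

```
peak: chr3: 50.76 Mbp, LOD 18.42 (true locus 50.76 Mbp)
95% Bayesian support interval: 50.76-50.76 Mbp
null heritability on chr3 (LOCO kinship): 0.32
BLUP founder effects (shrunken toward 0):
    A/J: +1.148
     B6: +0.068
    129: -0.064
    NOD: -0.141
    NZO: -0.652
   CAST: +0.013
    PWK: +0.259
    WSB: -0.632
```

The scan recovers the planted marker exactly, the interval collapses onto
it at this LOD, and the allele-effect sign pattern (A/J positive, NZO/WSB
negative) matches the planted vector. `examples/04_mediation.py` plants a
mediated microbe→lipid triplet and shows the mediation scan singling out
the true mediator among 200 candidates:

```
lipid QTL: chr2: 50.1 Mbp, LOD 12.2
best candidate: am_metagene, LOD 12.2 -> 1.2 when added as covariate (drop -11.0, z -13.5)
flagged at z <= -6: ['am_metagene']
```

The other examples cover cohort simulation, permutation thresholds,
integration statistics (co-mapping, allele-effect correlation with the
exact 8!-permutation p-value, hotspots, enrichment, differential
screens) and ornithine-lipid mass bookkeeping. The full pipeline runs
from a YAML config:

```bash
domqtl run --config config.yaml --out-dir results/
```

writing scans, peaks, allele effects, mediation records, co-mapping
pairs, hotspots and a manifest whose fingerprint is reproducible under a
fixed seed.

## Layout

- `src/domqtl/` — library: `simulate`/`genmap`/`lipids` (synthetic data),
  `transform`/`kinship`/`lmm`/`scan` (QTL core), `mediate`, `integrate`,
  `io`/`config`/`pipeline`/`cli` (formats and orchestration)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, defaults and limitations
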