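# targetmr

Drug-target mendelian randomisation (MR) for lipid-modifying therapeutic
targets, as a tested, reusable Python pipeline.

## The problem

Variants in or near the gene encoding a drug target that associate with the
target's biomarker (e.g. *HMGCR* variants with LDL cholesterol) act as
genetic proxies for pharmacological modulation of that target. Using them as
instrumental variables gives a causal estimate of what modulating the target
does to any downstream outcome — disease risk or a metabolite panel — long
before (or without) a trial. `targetmr` implements that workflow end to end:

1. **Association scans** — covariate-adjusted per-variant GWAS of
   rank-inverse-normalised lipid traits, metabolites (linear) and disease
   outcomes (logistic), producing `SNP CHR POS EA NEA EAF BETA SE P N`
   summary statistics.
2. **cis instrument selection** — variants within a flanking window of the
   encoding gene (default 100 kb either side, 50-kb sensitivity option) at
   *P* < 1×10⁻⁶, greedily LD-pruned to pairwise r² < 0.1 against a
   reference genotype panel.
3. **Causal estimation** — the inverse-variance weighted (IVW) estimator
   generalised to correlated instruments. With instrument–exposure effects
   β_X, instrument–outcome effects β_Y with standard errors σ_Y, and signed
   reference-panel LD ρ, let Ω_jk = σ_Yj σ_Yk ρ_jk; then

       θ̂ = (β_Xᵀ Ω⁻¹ β_X)⁻¹ β_Xᵀ Ω⁻¹ β_Y,   se(θ̂) = (β_Xᵀ Ω⁻¹ β_X)^(-1/2)

   which reduces exactly to the standard fixed-effect IVW when ρ = I and to
   the Wald ratio β_Y/β_X for a single instrument. Instrument strength is
   summarised by the mean squared z-score F = k⁻¹ Σ (β_Xj/σ_Xj)².
4. **Metabolome-wide screening** — every target against every metabolite
   trait, with Benjamini–Hochberg FDR control applied within each target's
   family of traits, and estimates oriented to the therapeutic direction
   (per 1 SD *lower* LDL/triglycerides, *higher* HDL).
5. **Signature concordance** — after rescaling each target's signature by
   its genetically predicted CAD effect, pairwise coefficients of
   determination (r²) compare metabolome-wide signatures across targets.
6. **GRS strata** — an individual-level sensitivity analysis: weighted
   genetic risk scores regressed on phenotypes within age strata, probing
   age-linked contingent factors (e.g. statin use) without conditioning on
   them, which would induce collider bias.

Because the analyses the pipeline mirrors were built on individual-level
biobank data that cannot be redistributed, the package ships a synthetic
cohort generator (`targetmr.simulate` / `targetmr.study`) with controllable
LD (latent AR(1) haplotypes), exposures of known architecture, a metabolite
panel with pathway-shared loadings, logistic disease outcomes, and
non-overlapping discovery / outcome / reference partitions emulating the
two-sample MR design — so every stage is verifiable against known ground
truth.

## Worked example

Run the built-in demo design (3 targets on 2 exposure pathways, 12
metabolite traits, n = 20,000):

```bash
targetmr run --out out
```

`out/mr_disease.tsv` then contains the oriented disease estimates
(abridged):

| target | outcome | n_snps | theta | se | p | f_stat | OR |
|--------|---------|--------|-------|------|------|--------|------|
| GENE1  | CAD     | 3      | −0.058 | 0.20 | 0.77 | 75.9 | 0.94 |
| GENE2  | CAD     | 3      | −0.524 | 0.27 | 0.053 | 41.4 | 0.59 |
| GENE3  | CAD     | 3      | −0.864 | 0.25 | 4.7×10⁻⁴ | 46.5 | 0.42 |

Each `theta` is the CAD log-odds per 1 SD of exposure lowering through that
target (the generative truth is −0.35 for the LDL-pathway targets GENE1/2
and −0.25 for the TG-pathway GENE3; at this demo sample size the per-target
SEs of 0.2–0.27 make individual estimates scatter widely, and GENE3's
estimate overshoots while GENE1's sits near the null). `out/concordance/r2_matrix.tsv`
shows the signature concordance after CAD-effect scaling:

```
        GENE1   GENE2   GENE3
GENE1   1.000   0.919   0.005
GENE2   0.919   1.000   0.003
GENE3   0.005   0.003   1.000
```

— the two same-pathway targets agree metabolome-wide (r² = 0.92) while the
cross-pathway pairs are uncorrelated, the qualitative fingerprint of
targets acting through a shared lipid pathway.

The same stages are available individually (`targetmr simulate`, `gwas`,
`select-instruments`, `mr`, `screen`, `concordance`, `grs`) and as library
functions; see `docs/methods.md` for the model and its assumptions.

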