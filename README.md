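# fwdgwas

Forward-time simulation of realistic samples for genome-wide association
studies (GWAS).

Statistical gene-mapping methods need test data that look like real human
genomes: dense SNP markers with block-wise linkage disequilibrium (LD), a
realistic allele-frequency spectrum, and — when the question calls for it —
signatures of natural selection, population structure or admixture.
`fwdgwas` builds such data by *evolving* a diploid population seeded from a
real (or synthetic) phased haplotype panel, rather than by resampling or
coalescent simulation. The evolved population is then turned into
analysis-ready case-control, trio, or admixed samples under explicit
penetrance models.

## What the simulator does

1. **Initial population.** A phased panel (VCF with `|` genotypes, or
   Oxford `.haps/.sample`) is filtered by region, marker name and minor
   allele frequency; each source individual becomes one or more diploid
   founders. A bundled generator (`fwdgwas synth`) emulates the panel's
   statistical structure — haplotype blocks with high within-block D',
   kb-scale spacing, a MAF floor — so everything runs with no downloads.
2. **Forward evolution.** Wright–Fisher mating with fitness-weighted parent
   choice, symmetric diallelic mutation (default rate 1e-8), recombination
   from a fine-scale genetic map via Haldane's map function
   r = (1 − e^(−2d))/2, linear or exponential population expansion
   (e.g. 993 → 10^5 diploids over 500 generations), stepping-stone or
   continuous-gene-flow migration, and admixture with positive assortative
   mating by ancestry. An optional scaling factor λ runs N/λ individuals
   for T/λ generations with λ-magnified forces — a diffusion-justified
   speed-up valid for weak additive selection.
3. **Controlled disease loci.** The frequency of each disease-predisposing
   allele (DPA) follows a pre-simulated trajectory: forward in time with
   restart until the present-day frequency lands in a target range, or
   backward in time for recent mutants until the allele is lost. During the
   main run a controlled mating scheme accepts/rejects offspring so the
   realised allele count at every controlled locus is
   round(2·N_t·x_t) — exact, every generation.
4. **Sampling.** Affection status comes from a penetrance model:
   a two-locus logistic model with gene–gene and gene–environment terms
   (logit P = α + β₁g₁ + β₂g₂ + β₃g₁g₂ + γ₁g₁e + γ₂g₂e, with the intercept
   calibrated to a target prevalence), a single-locus logistic model, a
   genotype-penetrance table, or an ancestry-linear model
   (P = 0.05 + ancestry/6). Samples are drawn directly (random or
   stratified case-control) or by rejection sampling for rare diseases
   (case-control offspring, affected-offspring trios), and exported as
   PLINK PED/MAP plus a covariate TSV. An allele-based χ² scan is built in.

## Worked example

```sh
fwdgwas synth --out-prefix panel --n-haplotypes 100 --n-loci 60 --seed 4
fwdgwas init --vcf panel.vcf --genetic-map panel.map --out init.snap --seed 1
cat > run.yaml <<'EOF'
demography: {N0: 50, NT: 400, T: 40, schedule: linear}
forces:
  mu: 1.0e-8
  selection:
    - {locus: snp10, w: [1, 0.996, 0.994]}
trajectory:
  - {locus: snp10, mode: forward, w: [1, 0.996, 0.994], x_T_range: [0.0, 1.0]}
watched_loci: [snp10]
EOF
fwdgwas evolve init.snap --config run.yaml --seed 2 --out evolved.snap
cat > samp.yaml <<'EOF'
disease: {kind: single_locus, locus: snp10, intercept: -0.5, slope: -1}
sampling: {design: trios, n_trios: 20}
EOF
fwdgwas sample evolved.snap --config samp.yaml --seed 3 --out-prefix trios
```

which prints

```
wrote panel.vcf (100 haplotypes, 60 loci) and panel.map
wrote init.snap: 50 individuals, 60 loci
wrote evolved.snap: 400 individuals at generation 40
wrote trios.ped/.map (60 individuals)
```

`evolved.snap` is a versioned JSON snapshot of the 400-individual
population after 40 generations of linear growth from 50 founders; its
companion `evolved.snap.trajectory.tsv` holds the per-generation target
frequency of the controlled locus `snp10` (purifying fitness
1 / 0.996 / 0.994 for 0/1/2 copies), which the controlled mating hit
exactly at every generation, and `evolved.snap.summary.tsv` logs sizes and
watched-locus frequencies. `trios.ped` contains 20 families — father,
mother, affected child — sampled by rejection under the logistic penetrance
logit P(affected) = −0.5 − g, with covariates in `trios.cov.tsv`.

The same workflow drives the library API (`fwdgwas.evolve.evolve`,
`fwdgwas.trajectory`, `fwdgwas.sampling`, `fwdgwas.stats`) for scripted
studies; see `docs/methods.md` for the model details and design choices.

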