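# Methods

This note documents the models implemented in `fwdgwas`, the parameters
that matter, the numerical choices, and what the synthetic test conditions
do and do not demonstrate about real data.

## The forward model

The population is a set of diploid individuals partitioned into
subpopulations, each individual carrying two phased 0/1 haplotypes over a
shared locus list. Generations are discrete and non-overlapping. One
generation applies, in order: migration (if configured), then one mating
step that produces the next generation at the scheduled size.

**Demography.** The total size follows a schedule N_0 … N_T with endpoints
pinned exactly. `linear` adds the same number of individuals each
generation (N_t = round(N_0 + t(N_T−N_0)/T)); `exponential` uses
N_t = round(N_0 (N_T/N_0)^(t/T)). Linear expansion grows fastest early,
which preserves more founder diversity: for 993 → 100,000 diploids over
500 generations the harmonic-mean effective size
Ne = T / Σ_{t<T} 1/N_t is ≈ 21,000 for the linear schedule versus ≈ 4,604
for the exponential one. (The convention excludes the final census from
the harmonic mean; with it included the exponential value changes by
~0.2%.) With several subpopulations the scheduled total is apportioned by
the initial size fractions (largest-remainder rounding).

**Mating.** For each offspring a father and a mother are drawn
independently, with replacement, with probability proportional to fitness
within the subpopulation (uniform when no selection is configured). The
child receives one recombined, mutated gamete from each parent, a
fair-coin sex, and the mean of the parental ancestry values. Sex is
tracked so both parent roles exist, but if a (tiny) subpopulation lacks
one sex the roles fall back to the whole subpopulation with a logged
warning rather than aborting the run.

**Recombination.** Genetic positions come from a map table (linear
interpolation in physical position; extrapolation at the ends uses the
nearest interval's rate) or from a constant physical-map fallback of
0.01 cM per Mbp. Adjacent-interval recombination probabilities use
Haldane's map function r = (1 − e^(−2d))/2 with d in Morgans; chromosome
boundaries recombine freely (r = 1/2). Meiosis starts from a fair-coin
parental strand and switches strands at interval i with probability r_i.

**Mutation.** Symmetric diallelic: every site flips 0↔1 independently with
probability μ per generation (default 1e-8). This keeps marker identity
fixed — appropriate for SNP panels, not for sequence evolution.

**Selection.** Viability selection via relative fitness triples
(w11, w12, w22) for 0/1/2 copies of the alternate allele, combined
multiplicatively across selected loci. Parent choice ∝ fitness is the only
selective step; fecundity and survival are not modelled separately.

**Migration.** Stepping-stone: each generation, round(m·N_i) uniformly
chosen individuals move from deme i to each neighbour on a 1-D chain,
reciprocally and simultaneously from the frozen pre-migration state.
Continuous gene flow: round(p·N_sink) uniformly chosen sink individuals
are replaced by copies of individuals drawn with replacement from the
source, so the expected sink composition follows
a_{t+1} = (1−p)a_t + p — after G generations of flow from an
ancestry-1 source into an ancestry-0 sink the sink mean ancestry is
1 − (1−p)^G (0.4013 for p = 0.05, G = 10). Replacement (rather than
letting the sink grow and be resized by the next mating) is what makes
"5% of individuals migrated per generation" mean exactly 5%.

**Admixture.** Individuals are split at an ancestry threshold (default
0.5). For a fraction `assort_within` (default 0.8) of matings, both
parents are drawn from the ancestry group of a uniformly chosen index
individual; the rest draw both parents population-wide. Offspring ancestry
is the parental mean, so mating alone conserves the population mean
ancestry in expectation while assortment slows the homogenisation of
individual ancestry values.

**λ-scaling.** `scale_config` converts a run (N_t, T, μ, r_i, w) into
(round(N_{round(tλ)}/λ), round(T/λ), λμ, min(λ·r_i, 1/2),
1 + λ(w−1) clipped at 0). The transformation follows the diffusion
approximation, which holds only for weak additive forces; the CLI refuses
λ>1 with a non-additive fitness triple unless `--force` is given. Scaling
multiplies the recombination *probability*, not the map distance, and
caps at free recombination.

**Reproducibility.** A run is a pure function of (config, seed). The root
seed spawns one child RNG stream per generation, so the subpopulation
processing order cannot perturb downstream draws; population snapshots are
versioned JSON that round-trips bit-exactly, including ancestry values
serialised as hex floats.

## Disease-allele trajectories and controlled mating

A genetic disease with a selected DPA needs the allele's present-day
frequency under control. The trajectory module pre-simulates a
per-generation frequency path and the engine then *enforces* it.

The deterministic one-generation update is standard viability selection,
x′ = (x²w22 + x(1−x)w12)/w̄ with w̄ the mean fitness; drift adds a binomial
kernel, x_{t+1} = Binomial(2N_{t+1}, x′_t)/(2N_{t+1}).

*Forward mode* (allele older than the expansion): simulate from the
initial frequency and restart the whole path until the endpoint falls in
the requested range. The acceptance half-width defaults to ±10% relative
around a target frequency; on failure the error carries the mean ending
frequency over all attempts so the selection parameters can be adjusted.

*Backward mode* (recent mutant): step back from the present-day frequency
using the inverse of the deterministic update (monotone bisection, checked
to 1e-10) inside the binomial kernel, until the allele is lost; the loss
generation is the mutant's origin. Paths that fix, reach generation 0
still segregating, or exceed the allowed mutant age are redrawn. The
inverse-then-binomial kernel is the package's choice; the backward
transition is not uniquely defined by the model, but the inverse property
makes it testable and it reproduces forward behaviour at large N.

With several controlled loci under a multiplicative model, each locus uses
its *marginal* fitness triple — the expectation of multilocus fitness over
Hardy–Weinberg genotypes at the other (necessarily unlinked) loci — which
for the multiplicative model is the locus's own triple up to a constant.

*Controlled mating*: per generation, offspring are produced by the usual
mating scheme and accepted iff, for every controlled locus, the offspring's
allele count c_l does not exceed the remaining quota R_l and leaves the
quota reachable by the remaining slots (R_l − c_l ≤ 2(S−1)). When the
generation fills, every controlled locus carries exactly
round(2N_t·x_t) copies. Quotas convert frequencies to integers by
round-half-up, only at this point; trajectories themselves stay real-
valued. A bounded try-multiplier guards against infeasible quotas (e.g. an
allele absent from the parental pool), which raise an error naming the
locus.

## Penetrance models and sampling

The two-locus logistic model
logit P(Y=1) = α + β₁g₁ + β₂g₂ + β₃g₁g₂ + γ₁g₁e + γ₂g₂e takes a binary
exposure e with P(e=1) = env_p (default 0.5 — the exposure is specified
only as a two-state random factor). A constructor variant enforces
β₁ = β₂/2, γ₁ = γ₂/2 for the "first locus has half the effect" design.
The intercept is calibrated to a target prevalence by bisection against
the exact 3×3×2 genotype-exposure enumeration (HWE, unlinked loci,
independent exposure), to |error| < 1e-10. The shipped reference values
β₂ = 0.4, β₃ = 0.2, γ₂ = 0.4 with 1% prevalence are repository defaults
chosen to give detectable but not overwhelming marginal effects; they are
not published estimates. The single-locus logistic model defaults to
logit P = −0.5 − g as printed in its source description; because the
negative slope makes the positively selected allele protective (a likely
transcription slip), a `positive_risk` switch flips the sign without
changing the magnitude. The ancestry-linear model is
P = 0.05 + ancestry/6, clipped to [0,1].

Direct sampling draws uniformly (optionally stratified on affection) from
the assigned population. Rejection sampling draws a *fresh uniform* parent
pair per offspring — postprocessing applies no selection, and redrawing
parents avoids sibship correlation — produces one child by standard
transmission, assigns affection, and fills quotas (cases/controls, or
affected-offspring trios) until complete; a cap on produced offspring
turns a rare-disease dead end into an error carrying the achieved counts.
Controls in the rejection design are unaffected offspring from the same
stream. For a single locus with HWE parents, the case genotype
distribution is the Bayes posterior P(g|affected) ∝ HWE(g)·f(g); the
worked example with allele frequency 1/2 and penetrances (0.1, 0.2, 0.4)
gives (1/9, 4/9, 4/9) and is the sampling module's central oracle.

## Statistics

LD is computed from phased haplotype counts directly (no EM):
D = p11 − p1q1, D′ = D/Dmax with the sign-dependent bound, r² =
D²/(p1p0q1q0); monomorphic loci are flagged and excluded from decay
profiles, which bin same-chromosome pairs into half-open 10-kb distance
bins. F_ST is the Weir–Cockerham (1984) estimator as a multi-locus
ratio of variance-component sums. Note the estimator's finite-sample
behaviour: two *identical* demes give a small negative value of order
1/n, not exactly 0 — tests assert |F_ST| < 0.01 at n = 200 rather than
machine zero. The association scan counts alleles (two per individual) in
a 2×2 table per locus and applies the Pearson χ² test without continuity
correction.

## The synthetic panel generator

`synthetic_init` builds a mosaic-of-blocks panel: loci fall into blocks of
geometric mean length (default 10 loci); each block carries up to
`n_block_haps` (default 4) founder haplotypes with frequencies drawn once
from a symmetric Dirichlet(1); every output haplotype chains one founder
per block, independently across blocks. Founder allele columns are
resampled until the realised minor-allele frequency of every locus clears
the floor (default 0.05, checked in integer counts so the emitted matrix
satisfies it exactly); the accompanying map places a hotspot rate
(10 cM/Mb) at block boundaries and a background rate (0.1 cM/Mb) inside
blocks, with ~2 kb mean marker spacing. This construction was chosen over
a coalescent simulation because it is O(H·L), dependency-free, and forces
exactly the two properties the simulator relies on: strong within-block
LD with between-block independence, and a MAF floor. It does *not*
provide mutation–drift equilibrium, a population-specific site-frequency
spectrum, or genealogical correlation between blocks — so tests passing
on synthetic panels validate the evolutionary machinery, not the realism
of any particular human population.

## Test and verification conditions

The verification suite runs scaled-down versions of the study conditions
so the whole suite completes in minutes on one CPU; sizes were fixed in
advance from standard power considerations, not tuned to outcomes:

- neutral fixation: N = 50, p0 = 0.2, 2000 replicate runs to absorption
  (binomial 3·SE band ±0.027 around 0.2);
- Hardy–Weinberg restoration: one generation at N = 10^4, 20 seeds,
  1-df goodness of fit p > 0.001;
- Haldane check: 10^5 meioses of a coupling double-het across a 10 cM
  interval (expected recombinant fraction 0.0906);
- LD decay: E[D_t] = D_0(1−r)^t at N = 10^4, r = 0.1, t = 10 over
  100–200 replicates, starting from a random union of gametes (a
  population of identical-haplotype homozygotes cannot recombine in its
  first meiosis, which would shift the exponent by one generation);
- controlled sweep: a purifying triple (1, 0.98, 0.96) moves ~0.28 to
  ~0.05 within 100 generations at N ≤ 2000 — the heterozygote deficit was
  set from the deterministic requirement
  ln((0.28/0.72)/(0.05/0.95))/100 ≈ 0.02; exactness is asserted at every
  generation;
- scaling consistency: λ = 1 (N = 500, T = 100) versus λ = 5
  (N = 100, T = 20) from one 200-locus synthetic panel, six replicates
  each; the scaled mean-r² decay curve must stay within 3× the unscaled
  inter-replicate spread per distance bin, and a five-fold larger scaled
  run must show smaller allele-frequency drift dispersion;
- admixture: 5% gene flow for 10 generations into a 1000-individual sink
  with 80% assortative mating, 50 replicates, against 1 − 0.95^10.

`scripts/acceptance.py` re-runs these measurements from a command-line
seed and additionally simulates the full-schedule (993 → 100,000, 500
generations) DPA trajectories whose accepted endpoints average 0.05 and
0.15 under the purifying/positive fitness pairs, and a backward rapid
sweep (fitness 1, 1.05, 1.11 to 99%) whose mutant age distribution has a
mean of a few hundred generations.

## Known limitations

- Generations are discrete and non-overlapping; within-generation (yearly)
  growth substeps are not modelled — no observable event could distinguish
  them.
- The linear-schedule effective size reported by some sources for the
  993 → 100,000 expansion does not match the harmonic mean of that
  schedule; this package reports the directly computed value.
- Gamete formation treats all chromosomes through one interval list with
  r = 1/2 at boundaries; sex-specific maps and interference are out of
  scope, as are X/Y inheritance, missing genotypes and multi-allelic
  markers.
- λ-scaling is unsound for non-additive or strong selection; the guard can
  be overridden but results are then outside the diffusion regime.
- Rejection sampling assumes the penetrance model applies to offspring of
  the final generation only; parental affection in trios is exported as
  missing unless previously assigned.
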