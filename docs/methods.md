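# Methods

This note records the models the package implements, the choices made
where a design was genuinely open, the default parameters and why, and
what the synthetic-data tests do and do not demonstrate about real data.

## NFDS model (`mimicrylab.nfds`)

One locus, two alleles (mimetic *m* dominant, non-mimetic *n*), discrete
non-overlapping generations, random mating.  Genotype frequencies are
reconstituted under Hardy–Weinberg from the allele frequency each
generation; fitnesses are

w_mm = a(1 − z·f_mm − z·f_mn), w_mn = b(1 − z·f_mm − z·f_mn),
w_nn = 1 − z·f_nn,

i.e. frequency dependence acts on *phenotype* frequencies (the dominant
mimetic phenotype is f_mm + f_mn).  With z < 1 all fitnesses are strictly
positive.

**Normalization.**  The selection recursion is normalized by the
current-generation mean fitness W̄ = p²w_mm + 2pq·w_mn + q²w_nn, so that
p′ + q′ = 1 holds exactly.  A definition of the normalizer in terms of the
*updated* frequencies would be circular; note that any common normalizer
leaves the ratio p′/q′ — hence every equilibrium and all fixation
behavior — unchanged, so this choice affects bookkeeping only.

**Equilibria.**  For a = b the interior equilibrium solves equality of
marginal allele fitnesses: q*² = (1 − a + az)/(z(a + 1)).  For a = b = 1
this is q*² = ½ independent of z — the two phenotypes equally common —
giving p* = 1 − √½ ≈ 0.292893.  These closed forms are used as oracles for
the iterated map.

**Drift.**  Wright–Fisher binomial resampling of 2·Ne allele copies from
the post-selection frequency.  Terminal states after a fixed horizon are
classified fixed/lost/segregating; absorbed trajectories stay absorbed.
Each run draws from its own `SeedSequence`-spawned child stream, so
replicate sets are reproducible and parallelizable.

**Defaults** mirror the study design: 400 generations, p0 = 0.25,
z = 0.25 for the drift-interaction grid, scenario grids for
(a, b) ∈ {(1,1), (1.5,1.5), (3,3), (5,5), (1.5,2), (2,3), (4,5), (1.5,5)},
z and p0 ∈ {0.05, 0.25, 0.5, 0.75, 0.95}, and a = b ∈
{1, 1.25, 1.5, 1.75, 2} × Ne ∈ {10², 10³, 10⁴, 10⁵} for the fixation
analysis.  Replicate counts are configurable (the presets default to 10;
the validation suite uses 100–2000 where a proportion is being estimated).

## Forward codon simulation (`mimicrylab.codon`)

The original analyses used a coalescent codon simulator; this package
re-expresses the same scenarios forward in time, which handles the
founder/growth phase naturally and keeps every quantity observable.
ω is implemented with substitution-model semantics: point mutations are
proposed per nucleotide at rate μ × (per-codon gamma multiplier), with
transitions weighted κ-fold over transversions; synonymous proposals are
always realized, nonsynonymous proposals are realized with probability ω,
and proposals creating a stop codon are rejected (resampled as no-event).
This gives realized dN/dS = ω by construction, which the calibration test
verifies against an exhaustive enumeration of all 9L single-nucleotide
neighbors of the ancestor.  κ defaults to 2 (unspecified in the source
design); the discrete gamma uses K = 3 categories with shape α = 0.8,
assigned per codon and fixed for a run; category rates are the exact
conditional means of equal-probability gamma bins (mean 1).

**Recombination** is a single crossover per offspring with probability
r·(L−1), r = 6 × 10⁻⁶ per adjacent site per generation by default.

**Scenarios.**  The non-mimetic class is a constant-size population
evolving from the GMRCA under ω = 0.05.  The mimetic class starts from one
haplotype drawn uniformly at the end of a burn-in phase and grows
logistically (1 → N over a tenth of phase 2 by default) while the source
population continues evolving; both classes are sampled (20 haplotypes) at
the end.

**Desk-scale defaults** (chosen once for runtime and estimator stability;
the published simulations themselves used elevated mutation rates for the
same reason): L = 300 codons, N = 800 haplotypes, μ = 8 × 10⁻⁵ per site
per generation, burn-in 1600 generations, founder phase 200 generations.
Under these conditions the founder lineage carries ≈ 30 realized mutations
(≈ 27 synonymous, ≈ 4 nonsynonymous at ω = 0.05), the background
fixation lag (~4N = 3200 generations) exceeds the simulated span so few
background substitutions complete, and the founder event is recent
relative to the background pairwise coalescence time (~N = 800
generations) — the regime in which hitchhiking produces its signature of
elevated fixed differences and reduced within-class diversity.

For ω *recovery* by the counting estimator the package uses longer,
smaller populations (N = 100, 1500 generations, μ = 2 × 10⁻⁴) averaged
over 5 replicates: the estimate's numerator is a small Poisson count on
the shared trunk lineage (≈ 10 nonsynonymous changes per lineage at these
settings), so shallower simulations give heavy-tailed single-replicate
estimates.  NG86 with κ = 2 underestimates synonymous sites slightly and
hence biases ω̂ a little below the simulated value; the recovery band
(0.02, 0.10) for ω = 0.05 absorbs this counting-estimator bias.

## MK statistics (`mimicrylab.mk`)

Sites are polarized against the known ancestor.  A derived allele with
sample frequency ≥ 1 − MAF counts as fixed, in [MAF, 1 − MAF) as
polymorphic, below MAF it is ignored; the same cutoff (default 0.05)
governs both categories.  Each counted change is classified by amino-acid
effect holding the other codon positions at the ancestral state; missing
calls are excluded from a site's frequency denominator.

Exact tests use the probability method for two-sidedness (sum of
probabilities of tables no more probable than observed, with a 1 + 10⁻⁷
tie tolerance).  The 2×2 test enumerates the hypergeometric support
directly; the r×c test enumerates all tables with the observed margins
when feasible (≤ 10⁷ tables) and otherwise uses ≥ 10⁵ Patefield
margin-preserving Monte-Carlo draws with a reported standard error.
Degenerate margins give p = 1 by convention.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous-site fractions averaged
between the two sequences; observed differences resolved by equal-weighted
shortest mutational pathways (pathways through stop codons excluded when a
stop-free pathway exists); Jukes–Cantor correction applied to each
proportion and reported as missing when the proportion reaches 3/4.
Changes *to* stop codons count as nonsynonymous in site counting.  The
statistic is symmetric in its arguments.  Scenario fit is summarized as
the fraction of simulated replicate tables whose 2×4 Fisher comparison
with the observed table is non-significant.

## Haplotype analyses (`mimicrylab.haplotypes`)

Phased VCF input (two haplotype rows per diploid sample; unphased
heterozygotes are an error naming the record, unphased homozygotes are
accepted as unambiguous).  Coordinates are 1-based VCF positions.

A site is *group-specific* if some allele is carried by the target group
with at most `max_exceptions_target` exceptions — a missing call and a
discordant allele both count as exceptions, applied per site — and at most
`max_exceptions_reference` (default 0) reference haplotypes carry that
allele.  This mirrors the tolerance rules used for 2-haplotype (no
exceptions) and 6-haplotype (one exception) target groups.  Groups are
free label sets, so panels mixing populations are expressed by labeling
alone.

Association mapping runs a per-site exact allele × group test (monomorphic
sites report p = 1) and applies Benjamini–Hochberg step-up across all
tested sites.

## Vision model (`mimicrylab.vision`)

Luminance is the per-pixel sum over bands; conspicuousness in luminance is
the per-butterfly-pixel percent change against the mean background
luminance.  Granularity partitions mean-subtracted, complement-zero-filled
2-D Fourier power into 7 equal-width radial-frequency annuli between the
full-image scale and Nyquist ("equipartition" read as equal width; the
option is exposed); constant regions return a uniform spectrum with a
degeneracy flag.  KL divergence is computed butterfly‖background with
additive smoothing ε = 10⁻⁹.

Chromatic JND follows the receptor-noise-limited model with constant noise
(bright-light assumption) and no achromatic channel (luminance is analyzed
separately).  Contrasts are Δf_i = ln(Q_i(pixel)/Q_i(reference)) against
the mean background spectrum, so a global illumination scaling cancels
exactly.  The general n-class quadratic form weights each receptor-pair
contrast difference by the squared noise product of the remaining classes;
for two classes it reduces to |Δf₁ − Δf₂|/√(e₁² + e₂²), which serves as
the closed-form oracle.  Per-class noise is e_i = ν√(η_ref/η_i) with the
most abundant class as reference.

**Receptor curves are placeholders.**  Measured pigment absorbances and
cone abundances are not bundled; the built-in observers use synthetic
Gaussian templates (trichromat 420/534/564 nm, abundances 1:2:4;
tetrachromat 370/445/508/565 nm, abundances 1:2:2:4; Weber fraction 0.05,
σ = 40 nm) and every component is replaceable via JSON.  Conclusions about
real plumage-vs-wing discrimination require measured curves.

## Synthetic data (`mimicrylab.synth`)

Generators are pure functions of (spec, seed) with byte-reproducible
outputs.  The haplotype panel draws inversion-like fixed differences with
a per-site probability rather than from a coalescent, keeping the truth
record exact; planted group-specific sites are exempt from missing-call
injection so they satisfy the group-specific predicate exactly.  The scene
background is a Gaussian "leaf green" spectral profile modulated by an
isotropic 1/f spatial texture — a minimal stand-in for leaf litter that
provides a non-flat spatial-frequency spectrum, not a model of real
foliage.

**What passing tests show.**  Synthetic panels and scenes validate the
*filters and statistics* (recovery of planted truth, exactness of tests,
invariances of the JND model).  They do not validate biological claims
about *P. polytes*: real panels carry linkage disequilibrium, calling
error and phasing switch errors the generator does not model, and real
scenes carry measured illumination and receptor spectra.  The equivalence
of a background-matched synthetic butterfly and a background-only control
is a consistency check of the measures, not evidence that real mimetic and
non-mimetic morphs are equally conspicuous.

## Numerical conventions

Deterministic equilibria iterate to |Δp| < 10⁻¹²; allele-frequency
boundaries 0 and 1 are exact fixed points and absorbing under drift.
Exact-test tie comparison uses relative tolerance 1 + 10⁻⁷.  Gamma
category rates come from regularized incomplete-gamma differences, not
quadrature.  All simulations accept a root seed and derive independent
child streams via `numpy.random.SeedSequence`.

## Known limitations

No diploid individual tracking in the NFDS model (allele-frequency
dynamics only); no spatial structure; no ancestral-state inference (the
ancestor is an input everywhere); no indels, no amino-acid fitness
landscapes, and no ARG-based coalescent machinery in the codon simulator;
no camera calibration or behavioral detectability modeling in the vision
module.
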