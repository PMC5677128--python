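# mimicrylab

Analyses of how a Batesian-mimicry supergene polymorphism is maintained —
and sometimes lost — built around the *doublesex* inversion of *Papilio
polytes* swallowtails.  The package re-implements, as a tested and reusable
Python library, four pieces of bespoke analysis that usually live in
one-off scripts, and pairs each with a synthetic-data generator carrying
known ground truth, so the whole pipeline runs and is validated without any
sequencing download.

## What it computes

**1. Negative frequency-dependent selection (NFDS) with drift**
(`mimicrylab.nfds`).  A one-locus, two-allele Wright–Fisher model where
genotype fitness declines with the frequency of the matching phenotype:

    w_mm = a (1 − z f_mm − z f_mn)
    w_mn = b (1 − z f_mm − z f_mn)
    w_nn =    1 − z f_nn

with selection strength `z ∈ [0, 1)` and mimetic benefits `a`, `b`.  The
deterministic recursion p′ = (p²w_mm + pq·w_mn)/W̄ is followed by binomial
resampling of 2·Ne allele copies.  With `a = b = 1` the map converges to
the phenotype-parity point p* = 1 − √½ ≈ 0.2929 for every `z`; for
`a = b > 1` the interior equilibrium is q*² = (1 − a + az)/(z(a + 1)).
Preset parameter grids reproduce the published scenario sweep
(8 selection scenarios × 5 `z` × 5 starting frequencies) and the
selection-by-drift fixation analysis.

**2. Forward codon evolution with founder hitchhiking**
(`mimicrylab.codon`).  A GY94-flavoured forward simulator (ω as the
acceptance probability of nonsynonymous point mutations, κ
transition/transversion weighting, discrete-gamma among-codon rates,
single-crossover recombination) descending from a known grand most recent
common ancestor (GMRCA).  The two-phase scenario draws one haplotype from
a purifying-selection burn-in to found a rapidly expanding "mimetic"
class: the founder's accumulated variants hitchhike to instant fixation in
the new class, producing more fixed differences and lower within-class
diversity without any change in selection.

**3. McDonald–Kreitman statistics** (`mimicrylab.mk`).  Variant
classification against the ancestor into fixed/polymorphic ×
synonymous/non-synonymous (MAF cutoff 0.05), exact 2×2 and r×c Fisher
tests (full enumeration, Patefield Monte-Carlo fallback), Nei–Gojobori
Ka/Ks with Jukes–Cantor correction, and Benjamini–Hochberg FDR.

**4. Haplotype-panel analyses** (`mimicrylab.haplotypes`).  Phased-VCF
input, morph-specific SNP discovery with per-group exception tolerances
(the rule used to count *theseus*-specific sites), and per-site exact
association mapping with FDR correction.

**5. Predator-vision conspicuousness** (`mimicrylab.vision`).  16-band
hyperspectral cubes (360–660 nm): luminance change, 7-band granularity
spectra with KL divergence, and chromatic just-noticeable differences
(JND) under the receptor-noise-limited model for any number of receptor
classes; log quantum-catch contrasts make JND exactly invariant to global
illumination.

**6. Ground-truth generators** (`mimicrylab.synth`): stop-free ancestral
coding sequences, phased panels with planted group-specific SNPs, and
hyperspectral scenes with programmed contrast.

## Worked example

```sh
python examples/nfds_equilibria.py
```

prints

```
z=0.05  a=b=1    equilibrium p* = 0.292893
...
z=0.25 a=b=1.25 equilibrium p* = 0.666667 (analytic 2/3)

fixation frequency of the mimetic allele (z=0.25, p0=0.25):
  a=b=1.0  Ne=100     fixed 0.00
  a=b=1.0  Ne=10000   fixed 0.00
  a=b=2.0  Ne=100     fixed 1.00
  a=b=2.0  Ne=100000  fixed 0.00
```

Pure NFDS holds the mimetic allele at ~0.29 regardless of `z` or drift; a
two-fold mimetic benefit pushes the deterministic equilibrium toward — but
never onto — fixation, and only small populations (strong drift) actually
fix it within 400 generations.  That interaction is the proposed route to
the secondary loss of polymorphism.

The other examples follow the same pattern, one capability each:
`hitchhiking_mk.py` (founder-event MK tables and Ka/Ks recovery),
`theseus_snps.py` (planted morph-specific SNP recovery under both
tolerance rules), `association_mapping.py` (exact tests + FDR along a
panel) and `vision_jnd.py` (luminance, granularity KL, tri- vs
tetrachromat JND).

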