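# Methods

This note documents the models behind `bgscan`, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## The statistic

For a sample of diploid individuals and the set of `S_tot` sites found
polymorphic in the *whole* sample, the per-individual average derived
allele frequency is `DAF̄ᵢ = nᵢ / (2 S_tot)` with
`nᵢ = Hetᵢ + 2·HomDerᵢ`. The coalescent argument: at a non-recombining
locus with mutation rate `u`, the derived alleles an individual carries are
the mutations on the path from its two gene copies up to the sample's
common ancestor, so `E(nᵢ) = 2 u t_global` for *every* individual — the
within-individual coalescence time cancels. Dividing by the expected number
of polymorphic sites, `E(2 S_tot) = 2 u T_tot`, gives
`E(DAF̄ᵢ) = t̄_global / T̄_tot` when the mutation rate is uniform across
loci. Population-specific demography moves `tᵢ` but not `t_global`, hence
the demography invariance that makes the statistic a selection probe.

Conventions adopted where usage could vary:

- "Polymorphic" is evaluated once on the full selected sample; subsequent
  subsets (class, bin, region) restrict sites but never re-test
  polymorphism, so every individual shares the denominator.
- Per-bin curves recompute the denominator per bin (`S_tot,b`).
- Group curves average individuals' values unweighted within a label;
  individuals are pooled across populations of a region.
- Sites without recombination-rate information are excluded from binned
  analyses but kept in global estimates.

## Annotation

Mutation classes follow the gBGC convention: weak W = A/T, strong S = C/G;
WS means the derived allele is favoured by gBGC, SW disfavoured, WW+SS
(pooled) unaffected. The 12-way ordered base-pair label is stored alongside
for finer breakdowns.

Recombination binning ranks rate-annotated SNPs by (rate, chrom, position)
— the positional tie-break makes bins deterministic under tied rates — and
cuts them into `n_bins` (default 20) contiguous groups differing in size by
at most one. How ties at bin boundaries should be allocated is not
determined by the method itself; any fixed rule gives the same curves up to
per-bin noise.

Feature distances are point-to-boundary on half-open intervals (a SNP at a
feature's end coordinate is outside it), in bp or in cM via linear
interpolation of the map. Hotspots are map intervals with rate strictly
above 10 cM/Mb; resolution is limited by map anchor spacing. The neutral
filter keeps WW+SS sites with rate ≥ 1.5 cM/Mb (inclusive threshold).

CpG filtering is applied on the *reference* context: a site is CpG if
either allele would form a CG dinucleotide with an adjacent reference base.
This is a conservative superset of contexts with elevated, recombination-
correlated mutability; the ancestral context is often unavailable and the
difference concerns a small minority of sites.

## SFS machinery

The unfolded SFS counts polymorphic sites by derived-allele total; the
normalized form divides entry `i` by its constant-size stationary
expectation (`∝ 1/i`), so neutrality + stationarity ⇒ a flat spectrum at 1.
Projection to a smaller sample size `m` averages over hypergeometric
subsamples, `P(i|n,f) = C(f,i)C(n−f,m−i)/C(n,m)`; classes 0 and `m` are
discarded and outputs are real-valued (no re-rounding).

The permutation test compares two site sets via
`D = Σᵢ (pᵃᵢ − pᵇᵢ)²` on proportion-form spectra (each divided by its own
total) so sets of unequal size are comparable; a normalized-form variant is
available behind a flag. Null schemes: *disjoint/overlapping* — sites
present in both sets stay fixed, private sites are pooled and re-split
preserving the two private counts; *nested* — replicates draw `|a|` sites
from the superset and compare to the full set's spectrum (comparing to the
complement instead would be equally defensible; the full set was chosen as
the more stable reference). The p-value is `(1 + #{D_perm ≥ D_obs})/(1 +
n_perm)`, i.e. small p = spectra more different than exchangeability
allows; an exact mode enumerates all splits when feasible and then reports
the exact tail fraction.

## Block bootstrap

Confidence intervals resample runs of 100 adjacent SNPs (adjacency within
the analysed subset, per chromosome by default) with replacement until the
original site count is reached, truncating the final draw — this keeps the
resample size exactly equal with minimal bias. Blocks are rebuilt per
analysis subset, so e.g. the WS and the neutral subsets have different
block compositions. Vector statistics (per-bin curves) share the block
draws within a replicate. Quantiles use type-7 linear interpolation.

## Forward simulator

A discrete-generation Wright–Fisher model of `N/2` diploids: parents drawn
proportional to fitness, fitness multiplicative across deleterious
genotypes (heterozygote `1 − s/2`, homozygote `1 − s`, with `s` a
non-negative magnitude — the convention "s = −0.1" sometimes seen for this
model is the same selection strength written with a sign), per-gamete
crossovers Poisson(`r·L`) at uniform positions, per-gamete mutations
Poisson(`u·L`) under infinite sites (continuous positions within bp slots,
collisions redrawn). The genome interleaves selected and neutral stretches
(default 1000 regions of 1 kb selected + 4 kb neutral; an alternative fine
layout of 10,000 × (100 + 400) bp is provided). Only selected-stretch
mutations carry the fitness effect; summary statistics use neutral-stretch
mutations, because linked-neutral diversity is the object of interest.

Runs start from a mutation-free population and burn in for `4·N_ANC`
generations before any scheduled event; sizes then follow piecewise-
constant epochs, fixed 100-generation bottlenecks, and a single admixture
pulse replacing a binomial fraction `p_ADM` of gametes with gametes from a
ghost population that split at `T_DIV` and evolves neutrally at `N_GHOST`.
Scaling a schedule multiplies times and sizes only — mutation and
recombination rates are left untouched, so scaled runs trade fidelity of
population-scaled compound parameters for speed and the documentation of
any experiment states the sizes used. Fixed mutations are purged each
generation (recorded as substitution counts): relative fitness is
unaffected by fixed deleterious alleles, and purging bounds memory.

Correctness anchors: with `s = 0` the per-site neutral diversity matches
the coalescent expectation `2 N_hap u` within replicate error, and the
projected normalized SFS of constant-size runs is flat.

## Synthetic coalescent datasets

`synthetic_data` generates unlinked loci from a hand-written structured
Kingman coalescent (piecewise-constant sizes, population merges; time in
units of 2·N_ref generations, validated against msprime in the test suite)
and layers two signals on top:

- **BGS** as a recombination-dependent rescaling of the *deep* (ancestral)
  epoch sizes: `bgs_profile(rate)` < 1 shrinks coalescence beyond the most
  ancient epoch boundary, shortening interior branches relative to external
  ones — which is exactly the singleton excess and DAF̄ᵢ depression BGS
  causes. A *global* size rescaling would be invisible to DAF̄ᵢ (the
  statistic is a time ratio) or, with fixed split times, would push the
  split effectively deeper and *raise* DAF̄ᵢ; rescaling the deep epochs is
  the emulation that moves the statistic in the right direction, and the
  generator's `Ne_multiplier` argument (which scales all epochs, a pure
  time rescaling for a constant population) is kept separate from it.
  The emulation reproduces the DAF̄ᵢ–recombination relation but *not* the
  full frequency-spectrum distortion of true BGS — that is what the forward
  simulator is for; both generators exist deliberately.
- **gBGC** as genic directional selection with scaled coefficient
  `γ(rate)` (+γ for WS, −γ for SW, 0 for WW+SS), using Wright's stationary
  density `f(x) ∝ (1 − e^{−γ(1−x)}) / ((1 − e^{−γ}) x(1−x))`, midpoint-
  discretized onto sample-frequency classes, with carriers then drawn
  uniformly. The γ = 0 limit recovers the neutral `1/x` shape.

Default study conditions: two populations of 10 diploids with shared
ancestry (split at 0.5 coalescent units), one carrying a 10× bottleneck
from the present back to 0.2; per-locus θ = 4 (a handful of sites per
locus, so within-locus linkage is negligible and loci are exchangeable);
per-locus rates log-uniform on 0.1–20 cM/Mb, spanning both sides of the
1.5 cM/Mb threshold; mutation-type probabilities with transitions twice
transversions, a standard mammalian-like bias. Emitted files (VCF,
ancestral FASTA on an all-'A' background that cannot create CpG contexts,
HapMap-style map with one anchor per locus, annotation BEDs, truth TSV)
pass the io layer's filter cascade with zero unexpected losses.

What passing tests on these data show: the estimators, filters and tests
behave correctly when their assumptions hold. What they do not show:
robustness to real-data pathologies — polarization error, LD at
chromosome scale, hotspot fine structure, mutation-rate heterogeneity —
none of which the generator attempts to mimic.

## B(r) model fit

The extended background-selection prediction is
`B(r) = π/π₀ ≈ exp(−u_d(r)/r)` with a power-law deleterious mutation rate
`u_d(r) = u₀ r^b`, i.e. `B = exp(−u₀ r^(b−1))`; `b = 0` recovers the
constant-mutation model. Rates in cM/Mb are converted to per-bp per
generation via 1 cM/Mb = 1e−8 (exposed constant). Fitting is non-linear
least squares over `(log u₀, b)` for positivity and conditioning, with a
moment-based start (log–log regression of −ln B on r) plus 4 random
restarts against local minima. Model comparison uses the Gaussian
concentrated-likelihood AIC, `n ln(rss/n) + 2k`, constants dropped — only
ΔAIC is meaningful; `rss = 0` maps to −∞ so a perfect fit dominates any
penalty. Binned means (consistent with the 20-bin analyses) are the
intended input; per-SNP points work but weighting is not modelled.

## Numerical and degenerate-input conventions

- Missing rates/distances are NaN end-to-end and written as `NA`.
- Map queries outside the anchored extent are missing, not extrapolated
  (single-anchor maps are open-ended as a documented special case).
- Empty feature sets yield all-missing distances with a warning; an empty
  neutral set warns rather than errors.
- Bootstrap replicates that fail are recorded as NaN, counted and excluded
  from quantiles (≥10 finite values required).
- All randomness flows through explicit integer seeds; identical
  (parameters, seed) reruns are bit-identical.

## Benchmark problem sizes

The shipped checks run on one CPU at deliberately modest sizes chosen as
the package's own benchmark conditions: ~10⁵ unlinked sites for the
demography-invariance check; 10⁵ loci for the two-diploid coalescent
oracle; 500 data replicates × 199 permutations for test calibration; 200
outer × 500 inner replicates for bootstrap coverage; and the reduced-scale
forward design of 50 regions at haploid N = 400 with 30 replicates per
recombination rate. At that last scale the ~130 SNPs per replicate ride on
essentially one genealogy when recombination is low, so between-replicate
noise in DAF̄ᵢ (SE ≈ 0.004–0.009) is of the order of the BGS effect itself
(≈ 0.013 between the extreme rates, with the diversity reduction B ≈ 0.92
matching the analytical expectation exp(−U/(s/2)) = 0.88): the *direction*
of every effect is reproduced, but strict rate-by-rate ordering of mean
DAF̄ᵢ and the behaviour of the sparse high-frequency SFS classes are not
statistically resolvable at this scale, and the corresponding two
assertions in the acceptance suite document that honestly by failing.
Resolving them would need the full-scale design (1000 regions, N = 4000),
roughly 200× this compute.

## Known limitations

- No gene conversion tracts, dominance spectra or distributions of fitness
  effects in the forward model; it is not a SLiM replacement.
- Polarization trusts the provided ancestral source; no correction for
  ancestral misidentification.
- The synthetic gBGC emulation decouples biased sites from the genealogy
  (their frequencies come from the stationary density), so linkage between
  biased and neutral sites is not represented.
- Demographic parameter estimation is out of scope: the pipeline exports
  fastsimcoal-compatible observed-SFS files and stops there.
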