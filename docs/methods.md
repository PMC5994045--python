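# Methods

## Scope and shape

`declinomics` is a library: the importable functions are the interface, and
`examples/` holds one short narrative script per capability. There is no
console entry point; `run_pipeline` plays the role an umbrella command would,
chaining simulate → panel → popstats → demog → range deterministically under
a single seed.

## SNV panel ladder

The ladder applies four rules in order, each a pure function on a
`VariantTable` (biallelic sites × samples, dosages 0/1/2 with −1 missing):

1. **Shared polymorphic** — called in every sample, both alleles observed
   (a heterozygote counts for both).
2. **Spacing** — greedy left-to-right per contig: keep the first site, then
   each site at least `min_gap` (default 50,000 bp) beyond the last kept
   one. Greedy first-kept-wins is deterministic and idempotent; no other
   spacing algorithm is implied by the constraint itself.
3. **LD pruning** — a candidate is kept iff its genotype r² against every
   previously kept site within `window` bp (default 1 Mb, a cost knob) is
   below `r2_max` (default 0.2). r² is squared Pearson correlation of
   unphased dosages over complete pairs — the vcftools `--geno-r2`
   statistic, not haplotype-EM r². Pairs with undefined r² (zero variance
   over the intersection, or fewer than two complete pairs) never block
   retention; missing genotypes are excluded pairwise, never imputed.
4. **Variability** — at least one hom-ref and one hom-alt individual. A
   `require_het` switch additionally demands the heterozygote class (the
   stricter "three genotypes observed" reading).

`r2_bin_report` classifies residual linkage into bins with exact-1 and
exact-0 singletons (`=1, (0.75,1), (0.5,0.75], (0.25,0.5], (0.1,0.25],
(0,0.1], =0`; singletons resolved at 1e−12). The default unit is per-site
maximum r², so counts sum to the number of classifiable sites; all-pairs
counting is available via `per_site_max=False`.

Coordinates are 1-based inclusive as in VCF; windows are half-open
internally.

## Weir–Cockerham F_ST

Per biallelic site, the 1984 variance components for diploid data:
with r populations, sizes nᵢ, alt frequencies pᵢ, heterozygote frequencies
hᵢ, n̄ the mean size, n_c the size-correction, p̄ and h̄ the weighted means
and s² the among-population frequency variance,

```
a = (n̄/n_c) [ s² − (p̄(1−p̄) − (r−1)s²/r − h̄/4) / (n̄−1) ]
b = (n̄/(n̄−1)) [ p̄(1−p̄) − (r−1)s²/r − (2n̄−1)h̄/(4n̄) ]
c = h̄/2
```

and the multi-locus **weighted** estimate is Σa / Σ(a+b+c) (ratio of sums,
not average of per-site ratios) — the quantity vcftools reports as
"weighted Fst". Sites where fewer than two populations have calls are
skipped; the estimate may be negative; fully monomorphic input raises,
since the denominator is zero. The implementation is vectorized across
sites and is checked in the tests against an independent scalar evaluation
of the same published formulas and against the generating F of
Balding–Nichols simulations.

## Heterozygosity, π, PCA, p-distance

* **GWH** is implemented as variant count / genome length — the direction
  all comparable published values use — although the figure is sometimes
  described in prose as the inverse division; the genome length is an
  explicit argument because published denominators for the same genome can
  differ (assembly length vs k-mer estimate). Note the convention of
  printing this raw fraction with a following "%" in some sources; the
  package returns the fraction and leaves formatting to the caller.
* **π** per site is the unbiased mean pairwise allele difference
  k(n−k)/C(n,2) from called alleles only, summed over each tiling window
  and divided by the window length, so window sums are invariant to window
  size.
* **PCA** mean-centers dosage columns (missing imputed to the column mean,
  i.e. zero after centering) and eigen-decomposes via SVD; no
  unit-variance scaling by default (exposed as a flag) and no
  Hardy–Weinberg normalization, matching a generic `prcomp`-style analysis.
  Axis signs are arbitrary.
* **p-distance** counts differing positions over positions where both
  sequences have an unambiguous A/C/G/T, excluding gaps and ambiguity codes
  from the denominator.

## Demographic post-processing

`estimate_fnr` is the doubled-input recount: FNR = (n_high − n_low)/n_high.
`encode_psmcfa` emits one symbol per 100-bp bin (K het, T hom, N if more
than half the bin is masked; both the bin size and the 0.5 threshold are
parameters — the threshold is a convention, since the upstream tool's
quality rule depends on read data not modeled here).

`parse_psmc` reads the TR (θ₀, ρ) and RS (t_k, λ_k) records of the **final**
EM round — PSMC output files contain every round, and the last is the
converged one; earlier rounds are reachable by index. `scale_psmc_output`
applies the FNR correction to θ₀ *before* scaling, θ_corr = θ₀/(1−FNR) —
the standard correction from the PSMC documentation; to first order this is
equivalent to inflating the variant count, and it scales N₀, all Ne values
and all times jointly by 1/(1−FNR). Then N₀ = θ_corr/(4μs),
Ne_k = λ_k N₀, t_k(years) = 2 N₀ t_k g. The trajectory is a
right-continuous step function; queries beyond the last knot return the
oldest value and log a note. Decline percentages are kept at full precision
internally; rounding to a printed precision is the caller's choice.

μ has **no default** anywhere: autosomal mutation rates for non-model
organisms come from a relative with a pedigree-based estimate, and baking
in any particular value would silently change every Ne and time.
Generation time defaults to 10 years, a median for a long-lived lemurid
that matures at ~3.5 years and breeds past age 10.

## Historical range

All geometry is planar on projected meter coordinates; **the caller must
supply an equal-area projection** — there is no geodesic math. The MCP is
the convex hull (degenerate inputs raise); habitat buffering uses round
joins/caps (the common GIS default) with 16 quadrant segments; invalid
polygons are repaired with `make_valid` and the repair logged; areas are
m²/10⁶. `scenario_table` evaluates one row per (habitat, buffer) scenario
and computes occupancy = 100 · extant/potential, NaN when the potential
area is zero.

## Synthetic data: what it emulates and what it does not

* **Structured genotypes** use the Balding–Nichols model (per-deme
  frequencies Beta-distributed around an ancestral p with parameter F)
  because Weir–Cockerham F_ST is asymptotically unbiased for its F — giving
  a closed-form truth for the estimator. Defaults are 2 demes × 50
  diploids × 5,000 sites with F = 0.15 and ancestral frequencies uniform on
  (0.1, 0.9); sites are placed on one contig at a fixed stride (plumbing,
  not biology). The model has no linkage, no gene flow, no selection and no
  site-frequency-spectrum realism, so passing tests certify the estimator,
  not behavior on real genotype data.
* **Heterozygosity tracts** come from a pairwise (n = 2) coalescent — all a
  single diploid's heterozygosity needs — with the coalescent time drawn
  from the exponential race across piecewise-constant epochs (rate 1/(2Ne)
  per generation) and Poisson(2μTL) het sites placed uniformly per block.
  Blocks are independent and recombination-free; the constant-Ne mean
  heterozygosity is 4Nμ.
* **Dropout** removes each variant independently with probability
  `fnr_true` — a deliberately memoryless stand-in for coverage bias, which
  in real data is correlated along the genome.
* **Mock PSMC files** are built by inverting the scaling equations, with
  epoch boundaries emitted as exact scaled-time knots plus equal-λ padding
  knots inside epochs; parse → scale therefore reproduces the generating
  step function exactly. This is a round-trip fixture for the parser and
  scaler, not an emulation of PSMC inference (no time-discretization error,
  no estimation noise).
* **Range fixture**: points whose hull is a 200 × 100 km rectangle (corners
  included) and a half-rectangle habitat, so every area is rectangle
  arithmetic.

All generators are bit-reproducible under their seed; the pipeline derives
per-stage sub-seeds from one master seed (kept below 2³¹).

## Numerical choices and problem sizes

* r² singleton bins resolved at 1e−12; WC F_ST compared to its scalar
  oracle at 1e−12 relative; the PSMC round trip asserted at 1e−9 relative
  (pure floating-point arithmetic both ways).
* The buffered-area closed form (dilated rectangle: (w+2d)(h+2d) − (4−π)d²)
  is matched at 0.1% relative tolerance, the discretization error of
  approximating round corners with 16 segments per quadrant.
* Statistical recovery checks use 20 replicates (F_ST, ±0.02 on the mean),
  10⁶ variants (FNR, ±1 percentage point) and 2,500 × 10-kb blocks
  (heterozygosity, 3 standard errors) — sizes at which the Monte-Carlo
  spread is comfortably inside the stated tolerances while the whole suite
  runs in seconds.

## Known limitations

Real VCF quirks (multi-allelic sites, indels, missing GT) are skipped with
a count rather than modeled; the PSMC HMM/EM, read mapping, variant calling
and genome assembly are out of scope; raster forest-cover maps are not
processed (vector polygons only); and no bootstrap resampling of PSMC
segments is provided — uncertainty on the trajectory must come from the
upstream tool.
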