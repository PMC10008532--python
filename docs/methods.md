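# Methods

## The measurement model

A mock community (MC) of two taxa is spiked into each sample before DNA
extraction: *Imtechella halotolerans* (gram-negative) contributes
`c_Ih = 6.0×10⁷` 16S gene copies per manufacturer dose and *Allobacillus
halotolerans* (gram-positive) `c_Ah = 1.4×10⁸`, both from 2×10⁷ cells
(3 and 7 copies per cell). After extraction, amplification and
sequencing, each library is a draw of reads over the pooled 16S copies of
sample taxa and MC taxa. Two facts drive everything downstream:

- read shares estimate copy shares (multinomial sampling), so the spiked
  taxon's read share converts its known copy input into an estimate of
  the library's total copy pool;
- DNA extraction recovers gram-positive cells less efficiently, so the
  observed gram-negative : gram-positive read ratio exceeds the dosed
  copy ratio `c_Ih/c_Ah = 0.43`; the excess is a direct bias diagnostic.

### Copy-number estimator

For library *j* with quality-filtered read total `N_j`, reference-taxon
reads `ih_j` (primary + secondary variants of *I. halotolerans*) and dose
fraction `d_j`:

```
GCN_j = (N_j / ih_j) × d_j × c_Ih
```

The dose term uses only the reference taxon's copy input: the estimator
divides by that taxon's reads, so only then do the units cancel to total
copies. The estimate targets the *effective* (post-extraction) copy pool;
gram-positive sample taxa suffering the same extraction bias are
correspondingly under-counted, which is inherent to any spike-based
calibration. The gram-negative taxon is the default reference because its
extraction is unbiased; the gram-positive taxon can be selected instead
via `reference_taxon` where a study prefers it.

### Absolute-scale transformation

Sample-SV counts are rescaled by the per-library factor
`GCN_j × (1 − ih_j/counts_j) / counts_j`, with `counts_j` the
pre-stripping library total (the spike-discount factor is only meaningful
when spike reads are part of the denominator; the gram-positive taxon's
reads are deliberately not subtracted). The transformation preserves
within-sample proportions exactly and carries an exact row-sum identity
used as a test oracle.

### QC metrics and dose guidance

Per library: MC read fraction (all assigned MC-SVs over the total), the
Ih:Ah read ratio (undefined when Ah has no reads), and a verdict against
the recommended band of 1–10% spike reads — enough reads for a stable
estimate, few enough not to distort the community. Dose bounds for a new
sample type invert the expected read-share model
`f(d) = dE / (dE + S)` with `E = c_Ih + g·c_Ah` (g the gram-positive
extraction efficiency) and sample copy pool `S`, giving
`d = S·f / ((1−f)·E)` at each band edge.

### Outlier screen

Within replicate groups (pool × condition), the fold deviation
`2^|log₂GCN − median|` flags libraries beyond a 2.5-fold threshold — a
quantification of the visual call one would make on a log₂ GCN strip
plot. The threshold comfortably separates genuine extraction failures
(near 10-fold) from ordinary replicate scatter (below 2-fold); it is a
parameter, not a constant.

## MC-SV detection

SVs are compared to each reference by semi-global alignment (edlib,
infix mode: free end-gaps in the longer sequence), identity = matches /
aligned columns. The default assignment threshold is 97% — observed MC
variant clusters sit at 98–100% identity, and 97% leaves margin without
capturing sample taxa. Per taxon, the most abundant assigned SV *that has
100% identity* is the primary variant (abundance ties broken by sv_id);
if the most abundant assigned SV is below 100% it is flagged, not
promoted. All other assigned SVs are secondary — whether they reflect
intragenomic 16S variation or residual sequencing error is left open, and
both interpretations are consistent with how the simulator generates
them. Stripping MC columns conserves reads exactly and keeps the original
totals for the estimator.

## Synthetic experiment generator

The generator emulates the spike-in design at the copy-pool level:

- **Community**: one log-normal(0, 2) relative-abundance profile per pool
  over 300 taxa by default — a plausible fecal-like rank-abundance curve;
  samples of a pool are technical replicates sharing the profile.
- **Copy pools**: sample pool = `mass × copies_per_mg × outlier_fold`
  (default density 4.3×10⁷ copies/mg, chosen so that the two-mass ×
  three-dose design spans spike read shares from ~0.05% to ~50%, the
  range the method must handle); MC pools = `dose × copies_per_dose`,
  gram-positive pools multiplied by efficiency `g` (default 0.336, the
  value implied by an observed read ratio of ≈1.28 against the 0.43 copy
  ratio).
- **Reads**: one multinomial draw per library at fixed depth (default
  30 000), so the per-library read sum is exact by construction. Each MC
  taxon's reads are then split between its primary variant and two
  secondary variants (reference sequence with 2 point mutations) with
  expected secondary:primary ratio 0.01 — binomial thinning at read
  level, agnostic about the biological vs technical origin of secondary
  variants.
- **Outliers**: `inject_outlier` multiplies one sample's true copy pool,
  modelling extraction failure (fold < 1) or over-input (fold > 1).

What it does **not** model: PCR-cycle dynamics, chimeras, taxon-specific
amplification efficiency beyond the single gram factor, overdispersion
beyond multinomial sampling, read-level errors outside the fixed
secondary variants. Consequences for interpretation: after rarefaction,
dosed and undosed libraries of the same community are *identically
distributed* in this generator, so passing the "alpha diversity
unaffected" check demonstrates correct null behaviour of the statistics,
not robustness to PCR competition effects present in real data; the
beta-diversity distortion at high spike fractions arises purely from read
sampling noise and zero-inflation under CLR, a conservative stand-in for
the amplification competition seen in real libraries.

## Diversity stack

- **CLR**: `ln(x+1)` centred per sample (offset 1 keeps zeros finite);
  row means are exactly zero.
- **Rarefaction**: multivariate hypergeometric subsampling without
  replacement, default depth = ⌊0.99 × minimum library total⌋.
- **Alpha**: richness S, Shannon H in natural log (so Hill q=1 is
  exp(H)), inverse Simpson D₂. Alpha comparisons default to rarefied
  counts (a flagged choice — raw counts conflate depth with diversity).
- **Rarefaction curves**: Hill numbers on nested prefix subsamples of a
  shuffled read vector, 200 bootstrap resamples, percentile CIs; nesting
  makes the q=0 curve monotone in subsample size for every resample.
  Extrapolation beyond the observed depth is out of scope.
- **Distances**: Euclidean (intended for CLR input) and Bray–Curtis
  (counts); exact symmetry enforced.
- **PCoA**: Gower-centred `−½JD²J` eigendecomposition; negative
  eigenvalues are reported, not corrected.
- **PERMANOVA**: sequential (Type-I) partitioning via hat matrices of the
  cumulative design, pseudo-F against the full-model residual, p-values
  by simultaneous permutation of the Gower matrix rows/columns
  (999 default), `p = (1 + #{F* ≥ F}) / (1 + n_perm)`; term order is the
  user's, mirroring `adonis2(by = "terms")`. Small designs can enumerate
  all n! permutations exactly. Categorical terms are dummy-coded;
  numeric terms enter as covariates.
- **Rank-sum**: exact two-sided p by exhaustive enumeration (midranks)
  for groups ≤ 10, normal approximation with tie correction otherwise.

## Numerical and design choices

- All randomised operations take an explicit seed; the pipeline reuses
  one seed for every stage and logs it, and identical seeds yield
  byte-identical result tables.
- Metadata stores the MC dose as a fraction of one manufacturer dose;
  conversion to copies happens only in quantification. A dose of 0
  encodes "no MC added" and yields a null estimate rather than an error.
  The MC : biomass covariate for PERMANOVA is computed as
  `dose_fraction / mass` directly from metadata.
- BIOM support targets the 1.0 JSON dialect (rows = observations),
  written and parsed directly; TSV defaults to samples-as-rows with a
  flag for the common transposed orientation.
- Identity is computed internally (no external BLAST); the bundled
  default reference sequences are deterministic synthetic stand-ins and
  are clearly labelled as such.
- Problem sizes in the validation suite (depths 10⁴–10⁵, 100–300 taxa,
  150–500 replicate simulations) were chosen as the smallest scales at
  which the Monte-Carlo standard errors are well below the effect sizes
  being checked.

## Known limitations

- Copy-number estimates quantify 16S gene copies, not cell counts
  (per-genome 16S copy number varies across taxa).
- Estimates inherit extraction bias: gram-positive sample taxa are
  under-represented in the effective copy pool.
- Low-dose libraries yield noisy estimates (few spike reads); the dose
  recommendation exists precisely to avoid that regime.
- The sequential PERMANOVA permutes raw labels; restricted permutation
  schemes (strata) are not implemented.
- UniFrac and other phylogeny-aware metrics are out of scope (no tree
  handling), as are fastq processing and denoising — the package starts
  from SV tables.
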