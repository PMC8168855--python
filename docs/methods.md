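# Methods

## Setting

The package implements a two-sample Mendelian randomization (MR) analysis
of a continuous exposure — circulating 25-hydroxy-vitamin-D (25OHD),
standardized on the log scale — on binary outcomes (COVID-19
susceptibility, hospitalization, severe disease) using only GWAS summary
statistics. Exposure effects γⱼ are per effect-allele copy in SD units of
log-25OHD; outcome effects Γⱼ are log odds ratios. The reference exposure
distribution is a mean of 48.6 nmol/L with SD 21.1 nmol/L, so one unit of
the causal estimate corresponds to a supplementation-sized shift in
vitamin D status.

Two-sample MR rests on three assumptions: instruments are associated with
the exposure (enforced here by the genome-wide significance filter);
instruments affect the outcome only through the exposure (probed by the
Egger intercept, heterogeneity tests, robust estimators, the
pathway-gene restriction and the annotation screen); and instruments are
independent of exposure–outcome confounders (untestable from summary
data). The linearity assumption is interpreted population-averaged, as
usual.

## Instrument selection

Filters, in pipeline order, with their defaults:

| filter | rule | default |
|---|---|---|
| significance | exposure p strictly below threshold | 5×10⁻⁸ |
| MAF | min(eaf, 1−eaf) strictly above threshold | 0.01 |
| LD pruning | greedy by ascending exposure p; keep iff tabled r² with every kept variant is strictly below threshold | 0.05 |
| proxy search | tabled partners with r² at least the threshold, present in the outcome GWAS, not palindromic-intermediate | 0.90 |
| pathway restriction | position within gene interval ± window | 100 kb window |
| annotation screen | drop listed variant IDs | 2-entry default list |

Boundary readings are literal: "more than 1%" and "less than 5%" are
strict, "90% or more" is inclusive; all are configurable. Greedy pruning
ordered by exposure p-value follows standard clumping practice (the
ordering is otherwise under-determined). "Closest gene" assignment is
approximated by windowed interval membership because exact gene assignment
requires an annotation source out of scope here; the 100 kb default window
captures the regulatory neighborhoods of the four vitamin-D-pathway genes
(*DHCR7*/*NADSYN1*, *CYP2R1*, *GC*, *CYP24A1*, GRCh37 coordinates shipped
in `pipeline.VITD_GENE_REGIONS`). The annotation screen replaces a live
phenotype-database query with a local exclusion list; the default list
carries the two instruments known to associate with white blood cell count
(rs11723621) and glomerular filtration rate (rs6127099).

A proxy inherits the index variant's exposure effect re-keyed through the
tabled haplotype phase only when the proxy has no exposure-side record of
its own; its own record is preferred when available. Phase alleles are
complement-tolerant, since LD references and GWAS may report opposite
strands; a missing phase for the winning pair is an error because the
effect direction cannot be oriented.

## Harmonization

Standard variants are aligned by allele labels: a swapped pair negates the
outcome beta and reflects its allele frequency; a complemented pair is a
strand flip; both may combine. For palindromic variants the labels cannot
distinguish swap from flip, so orientation falls back on allele-frequency
concordance (both frequencies on the same side of 0.5 after label
alignment). When either study's frequency lies strictly inside (0.42,
0.58) — applied to *either* side, the conservative reading — the variant
is unresolvable and is dropped, as it is when a palindrome lacks a
frequency on either side. Harmonization never raises on a bad pair; drops
are statuses with machine-readable reasons, and the audit log covers every
input variant.

## Estimators

All point estimators work on Wald ratios θⱼ = Γ̂ⱼ/γ̂ⱼ with first-order
delta-method SEs σ_Γⱼ/|γ̂ⱼ| (a second-order form adding the γ̂ noise term
is available behind a flag; at the default simulated instrument strengths
the correction is below 0.2% and is omitted from the pipeline).

* **IVW**: weighted mean of the ratios, wⱼ = 1/se(θⱼ)²; algebraically the
  zero-intercept weighted regression of Γ̂ on γ̂ with weights 1/σ_Γ².
  Fixed-effect SE 1/√Σwⱼ; multiplicative random effects multiplies by
  max(1, √(Q/(J−1))), so heterogeneity can widen but never narrow the
  interval. The pipeline defaults to the random-effects variant and labels
  the choice in the report header: published intervals of this design are
  wider than fixed-effect intervals whenever heterogeneity is present.
* **Cochran's Q**: Σwⱼ(θⱼ − θ̂_IVW)² on J−1 df, upper-tail chi-square; the
  Egger analogue uses weighted residuals around the regression line on J−2
  df.
* **MR-Egger**: weighted least squares of Γ̂ⱼ on γ̂ⱼ with intercept after
  orienting all γ̂ⱼ ≥ 0, weights 1/σ_Γⱼ²; both coefficient SEs are
  inflated by max(1, √(Q_egger/(J−2))). The intercept α estimates mean
  directional pleiotropy per variant (valid under InSIDE). The bootstrap
  variant resamples both effect vectors parametrically, refits (including
  re-orientation), and reports the median slope, bootstrap-SD SE, and
  percentile interval.
* **Weighted median**: ratios sorted ascending, normalized weights wⱼ′,
  cumulative midpoints sⱼ = Σ_{k≤j}wₖ′ − wⱼ′/2, linear interpolation at
  s = 0.5. The penalized variant multiplies weights by min(1, 20 qⱼ),
  qⱼ the upper-tail χ²(1) probability of the variant's Q contribution
  around the unpenalized estimate (penalty constant 20 from the robust-MR
  methodology literature; configurable).
* **Mode**: argmax over a 4096-point grid (ratios ± 3 bandwidths) of a
  normal-kernel density with bandwidth φ·0.9·wMAD·J^(−1/5), wMAD the
  weighted median absolute deviation scaled by 1.4826. Simple mode weights
  ratios equally; weighted mode uses 1/se(θⱼ)². Density ties break to the
  lower grid point (deterministic); a degenerate zero bandwidth (all mass
  at one ratio) falls back to the weighted median, which then equals the
  shared ratio.

P-values are two-sided normal for all point estimators and upper-tail
chi-square for Q; confidence intervals are β ± 1.96·se except the
percentile interval of the bootstrap Egger. Odds-ratio columns
exponentiate the log-scale quantities. Bootstrap defaults: 1000 resamples
(the fixture pipeline config uses 200 to keep the end-to-end demo under
ten seconds). Bootstrap RNG streams are split per (outcome, set, method)
from the single run seed, so adding an estimator never perturbs another's
resamples and a manifest-driven rerun is byte-identical.

## Synthetic data generator

The generator emulates the analysis's study conditions: by default J = 80
unlinked instruments jointly explaining target_r2 = 0.04 of exposure
variance, an exposure GWAS of 443,734, and a 14,134-case /
1,284,876-control outcome GWAS (the susceptibility phenotype's counts;
hospitalization 6,406/902,088 and severe disease 4,336/623,902 are used
where those outcomes are emulated).

* Allele frequencies are uniform on maf_range (default 0.05–0.45); the
  effect allele is randomly the minor or major one.
* Raw effect magnitudes are uniform on (0.5, 1.5) — a ~3-fold spread of
  instrument strengths — then rescaled so Σ2pⱼ(1−pⱼ)γⱼ² equals target_r2
  exactly (to 1e-12). At the defaults the per-variant χ² noncentrality
  n·r²ⱼ averages ≈ 222, so simulated instruments are genome-wide
  significant, as the selection filter presumes.
* γⱼ > 0 by construction: effects are oriented to the exposure-raising
  allele, the usual convention for reporting MR instruments. This matters
  for the pleiotropy experiments: with one-signed γ and direct effects
  αⱼ ~ N(mean, sd), the per-ratio biases αⱼ/γⱼ form a right-skewed
  weighted distribution, so IVW (a weighted mean) is displaced further
  than the weighted median or mode — exactly the contrast that motivates
  running robust estimators as sensitivity analyses.
* Sampling noise uses the standard first-order approximations
  se(γ̂ⱼ) = 1/√(2pⱼ(1−pⱼ)n) for a standardized continuous trait and
  se(Γ̂ⱼ) = 1/√(2pⱼ(1−pⱼ)Nφ(1−φ)) for a log-OR with case fraction φ.
* Pleiotropy modes: none (αⱼ = 0), balanced (mean-zero normal), and
  directional (nonzero mean) — the signal the Egger intercept targets.
* `corrupt_allele_coding` plants allele swaps and strand flips with a
  truth ledger, creating exactly the cases harmonization must undo.

What the generator does **not** emulate: LD between instruments (variants
are simulated unlinked, as if pruning upstream were perfect; the LD table
for proxy/pruning tests is constructed as explicit pairs), sample overlap
between the exposure and outcome GWAS, population stratification, allele
frequency differences between studies, and weak-instrument regimes.
Passing calibration tests therefore demonstrate correctness of the
estimators and plumbing under the stated model, not robustness to those
real-data complications.

All randomness flows from a single seed through counter-based stream
splitting (`SeedSequence` keyed by label paths), so per-stage
reproducibility survives reordering of pipeline stages.

## Pipeline and reporting

`run_analysis` crosses three outcomes with three instrument sets (all
filtered instruments; the vitamin-D-pathway subset; that subset minus the
exclusion list) and nine estimator variants, writing one row per
combination — a value or a reasoned NA (for example, `wald` applies only
to single-instrument sets, and median/mode estimators need at least three
instruments). An instrument set emptied by filtering is reported as NA
rows, never a crash. The report header notes the exposure units and the
ancestry caveat for the severe-disease outcome (a European-only
meta-analysis may not exist for it; ancestry handling is upstream of this
package). The manifest records input checksums, thresholds, seed and
version; per-stage counts in the log make the instrument accounting
reconstructable, and per-cell audit and Wald-ratio tables provide
forest/scatter-plot data.

## Numerical choices and degenerate inputs

* Zero exposure beta makes a Wald ratio undefined → error, never silent.
* Egger requires spread in |γ̂|; spread below 1e-12 of the weighted second
  moment is treated as none.
* p-values are clipped to [1e-300, 1] when generated (a p of exactly 0 is
  invalid at the I/O boundary).
* OR columns saturate to +inf rather than overflow for absurd intervals.
* Weighted-median interpolation clamps to the extreme ratios when 0.5
  falls outside the midpoint range.
* LD self-pairs are tolerated on read and ignored by pruning; untabled
  pairs count as unlinked.

## Fixture bundle

`make_fixtures` writes a 100-variant exposure table with planted edge
cases — 2 sub-significant variants, 3 rare ones (MAF 0.5%), one tabled
r²=0.6 pair member behind each of two stronger partners, one palindrome at
frequency exactly 0.50 with no proxy, one instrument absent from the
susceptibility GWAS with an r²=0.95 phased proxy, 11 instruments inside
the pathway gene regions of which 2 are on the exclusion list — plus three
corrupted outcome tables, the LD/region/exclusion side files and a ready
config. The construction margins are large (true instrument z ≈ 15 against
a significance boundary of 5.45; decoys at z ≈ 1) so the stage counts
100 → 98 → 95 → 93, the set sizes 93/11/9, and the 92 harmonized pairs are
invariant to the seed. The bundle doubles as the CLI demo and the
acceptance accounting target.

## Known limitations

* The per-SNP instrument table of the original analysis is not bundled, so
  the published odds ratios are used only for arithmetic-consistency
  checks of the reporting layer, not re-derived from real data.
* Proxy effect inheritance approximates the proxy's true exposure effect
  by the index variant's (exact only at r² = 1).
* No support for indels, multi-allelic sites, VCF input, genome builds or
  liftover; conditional/joint (COJO-style) instrument analysis is out of
  scope.
* Bootstrap SEs for median/mode estimators assume the parametric sampling
  model of the summary statistics.
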