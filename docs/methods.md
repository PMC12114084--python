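# Methods

## The analysis

`tsmr` implements two-sample bidirectional Mendelian randomization (MR)
from GWAS summary statistics, in the configuration used for
microbiome–disease questions: many quantitative exposure traits (bacterial
taxon abundances from a microbiome GWAS of roughly 14,000 participants)
against one large binary outcome (a food-allergy GWAS of 169,716
participants, 3,777 cases), and the reverse direction with the roles
swapped. Genetic variants serve as instrumental variables under the three
IV assumptions: relevance (associated with the exposure), exchangeability
(independent of confounders) and exclusion restriction (no path to the
outcome except through the exposure).

The chain for one exposure/outcome pair is:

1. **Selection.** Keep exposure SNPs with association p strictly below
   5×10⁻⁶. This sub-genome-wide threshold is common in microbiome MR,
   where few taxa have variants at 5×10⁻⁸; it trades some instrument
   validity for instrument count.
2. **Clumping.** Greedy pruning to near-independence: visit SNPs by
   ascending p (ties broken by chromosome and position so runs are
   deterministic); accepting a SNP removes same-chromosome neighbours
   within 10,000 kb whose LD r² ≥ 0.001. LD is supplied as a pairwise
   table; without one, every within-window neighbour is conservatively
   treated as correlated, which at an r² cutoff of 0.001 is close to what
   a reference panel would conclude anyway.
3. **Harmonization.** Outcome effects are re-expressed on the exposure's
   effect allele: textual swaps negate the outcome beta, strand-complement
   pairs are complemented first, and palindromic SNPs (A/T, C/G) are
   oriented by allele frequency — kept only when both frequencies are
   informative (outside [0.42, 0.58], the conventional ambiguity zone) and
   flipped when they fall on opposite sides of 0.5. Ambiguous palindromes
   and incompatible allele pairs are dropped with a recorded reason.
   Missing frequencies are never imputed; operations that need them fail
   loudly.
4. **Strength filter.** Per-SNP variance explained
   R² = 2β²f(1−f) / (2β²f(1−f) + 2·SE²·N·f(1−f)) and F = R²(N−2)/(1−R²).
   The frequency terms of R² cancel algebraically (R² = β²/(β²+SE²N));
   the formula is evaluated as written, and the cancellation is checked to
   machine precision in the tests. Instruments with F < 10 are removed.
5. **Estimation.** Wald ratios θⱼ = Γⱼ/γⱼ with weights wⱼ = γⱼ²/SE_Γⱼ²
   combined by IVW (precision-weighted mean ≡ origin-constrained WLS;
   multiplicative random effects by default, inflating the fixed SE by
   √max(1, Q/(J−1))), MR-Egger (free-intercept WLS after orienting
   exposure effects non-negative; slope = causal effect, intercept =
   directional pleiotropy; SEs floored at the fixed-effect value via
   max(1, √(RSS_w/(J−2))), the same convention as the IVW floor;
   t-distribution p-values with J−2 df), and the weighted median
   (weighted 50th percentile of the ratios, SE by seeded parametric
   bootstrap, 5,000 replicates by default). Estimates are reported on the
   ln(OR) scale and as OR with 95% Wald CI exp(β ± 1.96·SE).
6. **Sensitivity.** Egger intercept test (verdict at α = 0.05); Cochran's
   Q about both the IVW and Egger fits (χ² with J−1 / J−2 df; the Egger Q
   can never exceed the IVW Q); MR-PRESSO (below); leave-one-out IVW with
   an "influential" verdict when one exclusion flips the estimate's sign
   or moves its p across 0.05.

MR-PRESSO computes each SNP's residual from the leave-one-out IVW
prediction, sums the weighted squares (weights 1/SE_Γⱼ², equivalent to
ratio-scale residuals with Wald weights), and compares the observed RSS
with a parametric null built by redrawing outcome effects around the
leave-one-out predictions (default 1,000 simulations, seed required,
leave-one-out refitted inside every simulated dataset). P-values use the
add-one rule so they are never zero; per-SNP outlier p-values are
Bonferroni-adjusted; the distortion test compares the outlier-corrected
IVW estimate against 500 random same-size deletions. With 1,000
simulations the smallest achievable adjusted outlier p is J/1001, so
outlier detection at α = 0.05 is possible for J ≤ 50.

Batch orchestration treats statistical insufficiency as data: a trait
with no selectable, harmonizable or strong instruments yields a
"not analyzable" row with the reason and the attrition log (SNP counts at
every stage, non-increasing by construction), never an exception. Raw
p < 0.05 is the reporting threshold, mirroring common practice in this
literature; a Benjamini–Hochberg column (within direction × method) is
emitted alongside for readers who want multiplicity control across taxa.

## The synthetic-data generator

Real microbiome and allergy GWAS cannot be redistributed, so validation
rests on a generator with known truth. For SNP j: EAF fⱼ ~ U(0.1, 0.9);
instrument effect γⱼ with magnitude U(0.12, 0.25) and random sign; direct
(pleiotropic) effect αⱼ ~ mean `pleio_mean`, sd `pleio_sd`, optionally
correlated with |γⱼ| to violate InSiDE; true outcome effect
Γⱼ = β_causal·γⱼ + αⱼ. Observed effects add N(0, σ) noise with the
standardized-trait sampling law σ = (2·N·f(1−f))^(−1/2) — unit phenotypic
variance on both sides, consistent with the structure of the
variance-explained formula. Reported SEs are the analytic σ, so setting
`noise_scale=0` yields noiseless observations with valid SEs (estimators
then recover β_causal to full precision — a tested invariant).

Defaults are the reference study condition: 7 instruments (the modal
instrument count for the significant taxa in this design), exposure GWAS
N = 14,263 (a typical genus-level microbiome-GWAS size), outcome
N = 169,716, true OR 0.65 (the magnitude of the strongest protective
associations in this literature). The effect-magnitude range was chosen
once so draws clear both p < 5×10⁻⁶ and F ≥ 10 at these sample sizes
(realized F roughly 40–450, matching the strong-instrument regime);
binary-outcome effects are interpreted directly on the ln(OR) scale —
case/control imbalance, LD structure and allele-frequency/effect-size
coupling are deliberately not modelled. Passing tests therefore certify
the statistical machinery, not robustness to those real-data features.
Scenarios differing only in `beta_causal` reuse identical exposure draws
(the RNG stream is consumed in a fixed order), which is how traits with
fully shared instruments are constructed.

## Validation experiments

- **Null calibration** (IVW 1,000 replicates, MR-PRESSO 200 × 1,000
  simulations): rejection at α = 0.05 within 3 binomial SEs of 0.05.
  These experiments set β_causal = 0 and apply harmonization and
  estimation without p-value pre-selection: selection on the exposure
  statistic adds winner's-curse bias these checks deliberately exclude,
  and with a non-zero causal effect, exposure-side noise enters the
  ratios but not the first-order weights, producing genuine
  over-dispersion rather than a type-I error.
- **Recovery** (500 replicates): mean IVW estimate for true OR 0.65
  within Monte-Carlo error (3 SEs of the replicate mean, delta-method on
  the OR scale). Egger recovery under directional pleiotropy
  (mean 0.05, sd 0.02, InSiDE holding, all-positive instrument effects)
  uses a large exposure GWAS (N = 200,000): without an I²_GX attenuation
  correction — an explicit non-goal — Egger's slope shrinks under
  exposure-side noise, so the experiment tests the estimator in the
  strong-instrument regime where its consistency claim applies. The
  attenuation at microbiome-GWAS sample sizes is a known limitation.
- **Robustness** (200 replicates each): with 3 of 11 instruments carrying
  a constant direct effect (about 30% of weight, safely under the
  weighted median's 50% breakdown), IVW drifts by ~0.11 on the beta scale
  while the weighted median stays within ~0.01 of the truth; a 10·SE
  outcome spike on one instrument is flagged by MR-PRESSO in ≥ 95% of
  replicates.
- **Determinism**: every stochastic operation takes an explicit seed (no
  global RNG); full pipeline reruns are byte-identical, asserted on the
  written TSV/JSON bytes.

## Numerical choices and edge cases

- Closed-form 2×2 WLS in the estimators (not a matrix solver); the test
  suite cross-checks against independent normal-equation and statsmodels
  solves at 1e-10.
- Weighted-median percentile: sⱼ = (Σ_{k≤j} w_k) − wⱼ/2 with linear
  interpolation at 0.5, clamped to the extreme ratios when the percentile
  falls outside the grid; the vectorized bootstrap path is tested
  row-by-row against the scalar definition.
- Degenerate inputs: zero exposure effect → undefined Wald ratio error;
  single instrument → IVW falls back to the Wald ratio; J < 3 skips
  Egger/weighted median; J < 4 skips MR-PRESSO; an all-identical
  instrument set gives Q = 0, p = 1.
- Result tables print six significant digits, scientific notation below
  10⁻³; read(write(x)) preserves numeric fields at that precision.

## Scope limits

No LD computation from genotype panels (LD is supplied or absent), no
GWAS-VCF or genome-build liftover, no mode-based/multivariable MR, no
Steiger filtering, no Radial-MR, no I²_GX correction. Indel alleles are
rejected on read; strand logic is SNV-only.
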