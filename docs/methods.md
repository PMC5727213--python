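# Methods

## The screen in statistical terms

The pipeline associates array features with a quantitative trait by
contrasting two pooled DNA samples: the 'H' bulk (individuals with high
compound levels) and the 'L' bulk (low or undetectable levels).  If a
feature's hybridisation signal tracks an allele linked to the trait, its
signal-to-noise ratio (SNR) differs systematically between bulks; unlinked
features differ only by noise.  Three criteria are applied per compound and
intersected:

* **Stepwise discriminant analysis.**  With groups H/L, Wilks' lambda for a
  feature set is Λ = det(W)/det(T), the within-group over total scatter.
  The F-to-enter of a candidate with p variables already in the model is
  F = ((n−g−p)/(g−1))·(Λ_p/Λ_{p+1} − 1) on (g−1, n−g−p) df; the best
  candidate enters while its p-value ≤ 0.05, entered variables leave when
  their F-to-remove p-value ≥ 0.10 (the probability-of-F form of the usual
  stepwise defaults).  Implementation note: the candidate scan uses the
  sweep identity Λ_{E∪j}/Λ_E = w_res(j|E)/t_res(j|E) (residual sums of
  squares of j after regressing out the entered set within groups and
  overall), which is algebraically identical to the determinant ratio; the
  test suite certifies this against a naive determinant-based
  re-implementation on exhaustive small instances.
* **Fisher's ratio** (M₁−M₂)²/(V₁+V₂) with the top 10 features retained.
  It is invariant under affine rescaling of a feature and symmetric in the
  bulks.
* **Independent two-sample t-test** on the 12 + 12 data points, two-sided
  p < 0.01.  Both the pooled form (df = n₁+n₂−2) and the Welch form
  (Welch–Satterthwaite df) are provided.  From raw data the variant is
  chosen by a mean-centred Levene test (pooled when its p > 0.05); from
  printed summary statistics the caller must specify the variant — the
  published tables are interpreted by their printed df (integer 22 →
  pooled, fractional → Welch), since a variance test is not computable
  from summaries.

Classification uses Fisher's linear classification functions
b_k = S_w⁻¹ m_k, c_k = −½ m_kᵀ S_w⁻¹ m_k + ln(prior_k) with
S_w = W/(n−g); equal priors by default (bulks are balanced 12/12).
Reported rates: original (resubstitution), leave-one-out
(classification functions refit per fold with the feature set frozen — the
convention behind "cross-validated" classification tables), and the
holdout accuracy of the replicate-split design: stepwise runs on the six
technical replicates of biological replicate 1 per bulk (n = 12), predicts
biological replicate 2, then the selected features are re-run through
stepwise on all 24 points to form the final model.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_quality` | 80 (strict >) | spectral library match floor for a peak |
| `min_replicates` | 2 | technical replicates that must confirm a peak |
| `mean_floor_pct` | 0.1 % | population mean below which a compound is dropped |
| bulk quantile `q` | 0.2 | symmetric cut for H/L membership; ties included, zeros always eligible for L |
| `min_bulk_size` | 3 | smallest admissible bulk (study range 3–27) |
| `p_enter` / `p_remove` | 0.05 / 0.10 | stepwise probability thresholds |
| `max_steps` | 10 | bound on entries (n = 12 training caps useful entries at 9 anyway) |
| `tolerance` | 1e-4 | minimum within-group 1−R² of a candidate against entered variables |
| t-test alpha | 0.01 | marker-filter significance (no multiplicity correction by default, matching the original analysis; Bonferroni switchable) |
| Fisher top-K | 10 | ranking cut |
| E-value cutoff | 1e-5 (strict <) | significant genomic placement |
| concordance threshold | 10 % | high/low phenotype split; any value between the low cluster (≤5.6 %) and high cluster (≥24.1 %) is equivalent on the validation panel |

Display conventions follow the published tables (percentages and df to one
decimal); all comparisons use full precision internally.

## Synthetic-data generator

`simulate_phenotypes` draws, per compound and individual,
`Bernoulli(1−π) × (Σ_loci dosage·effect + Gamma(shape, scale))` truncated to
[0, 100] %, with disomic inheritance of each locus from the configured
parental dosages and a small multiplicative technical-replicate CV (5 %).
Default compound parameters (zero-inflation 0.2–0.5, one or two loci of
4–12 % effect) produce the right-skewed / zero-inflated distributions with
transgressive segregation that motivated the bulk design; the eight default
compounds mirror the screen's eight key aroma compounds, and the planted
marker counts per compound (1–4) mirror the published model sizes, with
both effect directions represented (H-up and L-up both occurred in the real
screen).

`simulate_array` draws a per-feature baseline SNR from a log-normal across
features (log-mean 5.0, log-SD 0.8 ≈ the printed SNR magnitudes) and
multiplies in log-normal technical noise (σ = 0.25, CV ≈ 0.25, the low end
of the printed SD/mean ratios) and an optional biological-replicate batch
factor.  A planted marker multiplies the favoured bulk by κ solving
(κ−1) = δ·CV·√((1+κ²)/2), which makes the bulk-mean gap exactly δ pooled
within-bulk SDs.  Because both bulks share the noise CV, two positive
log-normal bulks can never sit more than √2/CV pooled SDs apart; δ beyond
that bound raises a configuration error rather than silently delivering a
weaker effect.  An alternative `effect_mode="genotype"` scales the effect
by the realised high-allele frequency contrast between the actual bulk
members, so a misclassified individual (a real failure mode of bulk
construction) dilutes the observed signal; the default `direct` mode is
used for calibration experiments because it delivers δ exactly.

The biological-replicate batch SD defaults to 0: the screen's own
statistics pool both biological replicates and treat the 12 points per bulk
as exchangeable, so the generator's null matches the model the t-test
assumes; setting it positive lets users study the (anti-conservative)
consequences of batch structure on the pooled test.

What the generator does **not** emulate: feature–feature correlation
(real array features share sequence families and cross-hybridise),
spatial/print-tip artefacts, signal saturation, and the octoploid genetics
of cultivated strawberry (inheritance is disomic).  Passing recovery tests
therefore show that the statistics behave as designed under clean
conditions, not that the screen is robust to correlated array noise.

One RNG stream per consumer label (master seed + CRC32 of the label) keeps
fixtures byte-stable and insensitive to adding new draws elsewhere.

## Numerical choices and conventions

* Variances and SDs use the n−1 denominator throughout.
* Wilks' lambda via log-determinants; a singular total scatter raises a
  collinearity error, a singular within scatter with remaining
  between-group spread returns Λ = 0 (complete separation).
* Stepwise ties on F break to the lexicographically smallest feature id;
  classification score ties break to the first group label — both for
  deterministic reproducibility.
* Zero-spread degenerate t inputs: equal means raise an undefined-statistic
  error; distinct means report t = ±∞, p = 0.  Fisher's ratio with zero
  summed variance is 0 for equal means and ∞ otherwise.
* Genomic coordinates are 1-based inclusive; "downstream" means increasing
  linkage-group coordinate.  Minus-strand hit coordinates are normalised to
  start ≤ end on load.
* Transgression: a compound is transgressive when the F1 maximum exceeds
  the larger parental mean or the F1 minimum is *positive* and below the
  smaller parental mean.  Undetectable (0 %) progeny are classed
  "low/undetectable" — the same semantics the L bulk uses — not low-side
  transgression; this is what makes (E)-nerolidol the screen's one
  non-transgressive key compound even though some progeny produced none of
  it.
* Parental aroma profiles in the generator get a nominal 20 %-of-mean SD
  (harvest-to-harvest spread) so parental contrasts are testable.

## Problem sizes

The test suite runs recovery over 20 synthetic screens (8 compounds × 287
features each) and null calibration over 50 screens; `scripts/acceptance.py`
uses 10 recovery and 25 null screens, sizes chosen to make the Monte-Carlo
error small relative to the quantities reported while keeping a full run
interactive.

## Known limitations

* **Multi-marker recovery is capacity-limited by the stepwise criterion.**
  After a strong marker enters, the partial F of every further marker with
  a parallel bulk effect is deflated by 1/(1 + c·Σδ²_entered) and bounded
  above by the residual df, while the maximum partial F over ~280 null
  features is ~18 at n = 12 and ~12 at n = 24.  Beyond the first one or two
  markers per compound, true markers are therefore statistically
  indistinguishable from the best-case noise at any effect size, and the
  greedy selection fills with noise entries up to its step bound.  The
  package's own recovery experiment (`scripts/acceptance.py`) quantifies
  this: with 1–4 planted markers per compound at δ = 4, planted-marker
  recall and precision land near 45 % and 56 %, while leave-one-out
  accuracy stays ≥ 95 % — the selected models predict group membership
  almost perfectly even when they name only a subset of the true markers
  plus an occasional noise feature.  Interpreting stepwise marker sets as
  exhaustive is therefore unsafe; the three-criterion intersection exists
  precisely to temper this.
* Printed summary tables are inputs where raw hybridisations would be
  needed; classification percentages of the original screen are checked
  only for their k/24 granularity, not re-derived.
* The two published FaP1D7 SNR snapshots (bulk means vs the SNP-section
  values) come from different normalisation states and are deliberately
  not reconciled; the package reports ratios for each as printed.
* No multiple-testing correction is applied by default because the original
  analysis applied none; screens with many more features should enable the
  Bonferroni option or expect the documented null entry rate.
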